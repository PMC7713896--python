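"""Distance-based tree reconstruction under balanced minimum evolution.

Trees are unrooted with all internal nodes of degree 3. The search scores a
topology by Pauplin's balanced tree length

    L(T) = Σ_{u<v} 2^(1 - t_uv) d_uv

where t_uv is the number of edges between leaves u and v — the balanced
minimum evolution (BME) criterion. Reconstruction starts from a
neighbor-joining tree, hill-climbs over nearest-neighbor interchanges (NNI),
and escapes local optima with a ratchet: distances are perturbed
multiplicatively, the climb repeated on the perturbed matrix, and the result
re-climbed and re-scored on the original. Branch lengths on the returned
tree are ordinary-least-squares fits clamped at zero.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "PhyloTree",
    "nj_tree",
    "bme_length",
    "nni_neighbors",
    "hill_climb",
    "ratchet_search",
    "rf_distance",
    "random_tree",
    "path_distance_matrix",
]


@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with leaf labels.

    ``adj[u][v]`` is the length of edge (u, v); ``leaves`` maps leaf node ids
    to taxon labels.
    """

    adj: dict[int, dict[int, float]]
    leaves: dict[int, str]

    @property
    def leaf_labels(self) -> set[str]:
        return set(self.leaves.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def copy(self) -> "PhyloTree":
        return PhyloTree({u: dict(nb) for u, nb in self.adj.items()}, dict(self.leaves))

    # -- conversions ---------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        ids: dict = {}

        def nid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
            return ids[node]

        adj: dict[int, dict[int, float]] = {}
        leaves: dict[int, str] = {}
        for node in dtree.preorder_node_iter():
            u = nid(node)
            adj.setdefault(u, {})
            if node.is_leaf():
                leaves[u] = node.taxon.label if node.taxon is not None else (node.label or str(u))
            for child in node.child_nodes():
                v = nid(child)
                adj.setdefault(v, {})
                ln = child.edge.length if child.edge.length is not None else 0.0
                adj[u][v] = ln
                adj[v][u] = ln
        tree = cls(adj, leaves)
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(self.adj):
                if u in self.leaves or len(self.adj[u]) != 2:
                    continue
                (a, la), (b, lb) = self.adj[u].items()
                del self.adj[a][u]
                del self.adj[b][u]
                del self.adj[u]
                self.adj[a][b] = la + lb
                self.adj[b][a] = la + lb
                changed = True

    def to_newick(self) -> str:
        """Canonical Newick: rooted for writing at the internal node next to
        the lexicographically smallest leaf, children ordered by their
        smallest descendant label — byte-identical for identical trees."""
        if self.n_leaves < 2:
            raise ValueError("tree must have at least 2 leaves")
        start_leaf = min(self.leaves, key=lambda u: self.leaves[u])
        root = next(iter(self.adj[start_leaf]))

        def build(u: int, parent: int) -> tuple[str, str]:
            if u in self.leaves:
                return self.leaves[u], self.leaves[u]
            parts = []
            for v in self.adj[u]:
                if v == parent:
                    continue
                s, mn = build(v, u)
                parts.append((mn, f"{s}:{format(self.adj[u][v], '.12g')}"))
            parts.sort()
            return "(" + ",".join(p[1] for p in parts) + ")", min(p[0] for p in parts)

        parts = []
        for v in self.adj[root]:
            s, mn = build(v, root)
            parts.append((mn, f"{s}:{format(self.adj[root][v], '.12g')}"))
        parts.sort()
        return "(" + ",".join(p[1] for p in parts) + ");"

    # -- traversal helpers ---------------------------------------------------

    def leaf_topo_distances(self, order: list[str]) -> np.ndarray:
        """Pairwise edge counts between leaves, in the given label order."""
        return self._leaf_distances(order, weighted=False)

    def leaf_path_distances(self, order: list[str]) -> np.ndarray:
        """Pairwise path-length sums between leaves (additive distances)."""
        return self._leaf_distances(order, weighted=True)

    def _leaf_distances(self, order: list[str], weighted: bool) -> np.ndarray:
        label_to_node = {lab: u for u, lab in self.leaves.items()}
        n = len(order)
        out = np.zeros((n, n))
        for i, lab in enumerate(order):
            src = label_to_node[lab]
            dist = {src: 0.0}
            dq = deque([src])
            while dq:
                u = dq.popleft()
                for v, ln in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + (ln if weighted else 1.0)
                        dq.append(v)
            for jdx, lab2 in enumerate(order):
                out[i, jdx] = dist[label_to_node[lab2]]
        return out


def bme_length(t: PhyloTree, m: DistanceMatrix) -> float:
    """Pauplin's balanced tree length Σ_{u<v} 2^(1-t_uv) d_uv."""
    if t.leaf_labels != set(m.taxa):
        raise ValueError("tree and matrix cover different taxa")
    topo = t.leaf_topo_distances(m.taxa)
    with np.errstate(over="ignore"):
        w = np.power(2.0, 1.0 - topo)
    iu = np.triu_indices(m.n, 1)
    return float(np.sum(w[iu] * m.values[iu]))


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (scikit-bio backend), negative branches clamped."""
    if m.n_missing_pairs > 0:
        raise ValueError("distance matrix has missing entries")
    if m.n < 3:
        raise ValueError("need at least 3 taxa")
    if m.n == 3:
        # closed-form three-leaf star
        (a, b, c) = m.taxa
        dab, dac, dbc = m.values[0, 1], m.values[0, 2], m.values[1, 2]
        la = max(0.0, (dab + dac - dbc) / 2)
        lb = max(0.0, (dab + dbc - dac) / 2)
        lc = max(0.0, (dac + dbc - dab) / 2)
        adj = {0: {3: la}, 1: {3: lb}, 2: {3: lc}, 3: {0: la, 1: lb, 2: lc}}
        return PhyloTree(adj, {0: a, 1: b, 2: c})
    import skbio

    vals = (m.values + m.values.T) / 2.0  # exact symmetry for the backend
    np.fill_diagonal(vals, 0.0)
    skdm = skbio.DistanceMatrix(vals, ids=m.taxa)
    tr = skbio.tree.nj(skdm)
    buf = io.StringIO()
    tr.write(buf, format="newick")
    tree = PhyloTree.from_newick(buf.getvalue())
    for u in tree.adj:
        for v in tree.adj[u]:
            if tree.adj[u][v] < 0:
                tree.adj[u][v] = 0.0
    return tree


def _internal_edges(t: PhyloTree) -> list[tuple[int, int]]:
    edges = []
    for u in sorted(t.adj):
        if u in t.leaves:
            continue
        for v in sorted(t.adj[u]):
            if v in t.leaves or v <= u:
                continue
            edges.append((u, v))
    return edges


def nni_neighbors(t: PhyloTree):
    """Yield the two NNI rearrangements of every internal edge."""
    for u, v in _internal_edges(t):
        u_side = sorted(x for x in t.adj[u] if x != v)
        v_side = sorted(x for x in t.adj[v] if x != u)
        b = u_side[1]
        for c in v_side:
            nb = t.copy()
            lb = nb.adj[u].pop(b)
            nb.adj[b].pop(u)
            lc = nb.adj[v].pop(c)
            nb.adj[c].pop(v)
            nb.adj[u][c] = lc
            nb.adj[c][u] = lc
            nb.adj[v][b] = lb
            nb.adj[b][v] = lb
            yield nb


def hill_climb(t: PhyloTree, m: DistanceMatrix) -> tuple[PhyloTree, float]:
    """Best-improvement NNI descent on the BME length; deterministic."""
    cur, cur_len = t, bme_length(t, m)
    while True:
        best, best_len = None, cur_len
        for nb in nni_neighbors(cur):
            ln = bme_length(nb, m)
            if ln < best_len - 1e-12:
                best, best_len = nb, ln
        if best is None:
            return cur, cur_len
        cur, cur_len = best, best_len


def _perturbed(m: DistanceMatrix, eps: float, rng: np.random.Generator) -> DistanceMatrix:
    f = rng.uniform(1.0 - eps, 1.0 + eps, size=m.values.shape)
    f = (f + f.T) / 2.0
    vals = m.values * f
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(m.taxa), vals)


def ratchet_search(
    m: DistanceMatrix,
    rounds: int = 16,
    perturb_strength: float = 0.2,
    seed: int = 0,
) -> PhyloTree:
    """NJ start, NNI hill-climbing, and a perturbation ratchet on the distances.

    Each round multiplies every distance by U(1-eps, 1+eps) noise, climbs on
    the perturbed matrix, re-climbs on the original, and keeps the best
    original-matrix score seen. Deterministic given the seed; never worse
    than the NJ starting tree. Branch lengths of the returned tree are OLS
    fits clamped at zero.
    """
    if m.n_missing_pairs > 0:
        raise ValueError("distance matrix has missing entries; impute first")
    rng = np.random.default_rng(seed)
    best, best_len = hill_climb(nj_tree(m), m)
    for _ in range(rounds):
        noisy = _perturbed(m, perturb_strength, rng)
        cand, _ = hill_climb(best, noisy)
        cand, cand_len = hill_climb(cand, m)
        if cand_len < best_len - 1e-12:
            best, best_len = cand, cand_len
    return fit_branch_lengths(best, m)


def fit_branch_lengths(t: PhyloTree, m: DistanceMatrix) -> PhyloTree:
    """OLS branch lengths from the distance matrix, clamped at zero."""
    t = t.copy()
    edges = []
    edge_index = {}
    for u in sorted(t.adj):
        for v in sorted(t.adj[u]):
            if u < v:
                edge_index[(u, v)] = len(edges)
                edges.append((u, v))
    label_to_node = {lab: u for u, lab in t.leaves.items()}
    pairs = [(i, j) for i in range(m.n) for j in range(i + 1, m.n)]
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        src, dst = label_to_node[m.taxa[i]], label_to_node[m.taxa[j]]
        parent = {src: None}
        dq = deque([src])
        while dq:
            u = dq.popleft()
            for v in t.adj[u]:
                if v not in parent:
                    parent[v] = u
                    dq.append(v)
        node = dst
        while parent[node] is not None:
            u, v = parent[node], node
            A[row, edge_index[(min(u, v), max(u, v))]] = 1.0
            node = parent[node]
        b[row] = m.values[i, j]
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    x = np.maximum(x, 0.0)
    for (u, v), ln in zip(edges, x):
        t.adj[u][v] = float(ln)
        t.adj[v][u] = float(ln)
    return t


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson–Foulds distance (bipartitions in exactly one tree)."""
    import dendropy
    from dendropy.calculate import treecompare

    if t1.leaf_labels != t2.leaf_labels:
        only1 = t1.leaf_labels - t2.leaf_labels
        only2 = t2.leaf_labels - t1.leaf_labels
        raise ValueError(f"leaf sets differ: {sorted(only1)} vs {sorted(only2)}")
    tns = dendropy.TaxonNamespace(sorted(t1.leaf_labels))
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
    return int(treecompare.symmetric_difference(d1, d2))


def random_tree(
    labels: list[str],
    rng: np.random.Generator,
    blen_range: tuple[float, float] = (0.05, 0.5),
) -> PhyloTree:
    """Random unrooted binary topology with U(blen_range) branch lengths.

    Grown by attaching each new leaf to a uniformly chosen existing edge.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    lo, hi = blen_range
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}, 2: {}, 3: {}}
    for leaf in (0, 1, 2):
        adj[leaf][3] = 0.0
        adj[3][leaf] = 0.0
    leaves = {0: labels[0], 1: labels[1], 2: labels[2]}
    next_id = 4
    for label in labels[3:]:
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        u, v = edges[rng.integers(len(edges))]
        mid, leaf = next_id, next_id + 1
        next_id += 2
        del adj[u][v]
        del adj[v][u]
        adj[mid] = {u: 0.0, v: 0.0, leaf: 0.0}
        adj[u][mid] = 0.0
        adj[v][mid] = 0.0
        adj[leaf] = {mid: 0.0}
        leaves[leaf] = label
    tree = PhyloTree(adj, leaves)
    for u in sorted(tree.adj):
        for v in sorted(tree.adj[u]):
            if u < v:
                ln = float(rng.uniform(lo, hi))
                tree.adj[u][v] = ln
                tree.adj[v][u] = ln
    return tree


def path_distance_matrix(t: PhyloTree) -> DistanceMatrix:
    """The additive distance matrix induced by a tree's path lengths."""
    taxa = sorted(t.leaf_labels)
    return DistanceMatrix(taxa, t.leaf_path_distances(taxa))
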