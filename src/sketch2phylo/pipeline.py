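"""End-to-end drivers: genomes → tree, pair benchmarks, tree-recovery benchmarks.

Three entry points mirror the three experiments the package is built around:

* :func:`run_genomes_to_tree` — the production path: sketch a genome set,
  estimate Jaccard indices, transform to evolutionary distances, impute any
  missing entries, and search for a balanced-minimum-evolution tree.
* :func:`run_pair_benchmark` — simulate sequence pairs over a divergence
  grid under GTR / GTR+Γ with three base-composition regimes, fit the EI+Γ
  equivalence shape a to the (p, d) clouds, and score sketch-based p̂
  accuracy.
* :func:`run_tree_benchmark` — simulate sequences along reference trees and
  score how often each p-distance transform recovers the true topology.

Benchmarks default to desk scale (10⁵-base sequences, tens of replicates);
``paper_scale=True`` restores the full published protocol (5-Mb sequences,
200 pairs per divergence step), which is far beyond interactive scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import distances, metree, simulate, stats
from .distances import DistanceMatrix, build_distance_matrix, fit_a_to_points, impute_missing, write_phylip
from .metree import PhyloTree, ratchet_search, rf_distance
from .simulate import (
    ALPHA_RANGE,
    F1,
    F2,
    F3,
    JC_RATES,
    REPRESENTATIVE_RATES,
    EvoModelParams,
    evolve_along_tree,
    evolve_pair,
)
from .sketch import GenomeRecord, Sketch, bottom_sketch, estimate_jaccard, read_fasta, resolve_sketch_params

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_genomes_to_tree",
    "simulate_phat_pairs",
    "run_pair_benchmark",
    "run_tree_benchmark",
]


class PipelineError(RuntimeError):
    """A stage-labelled pipeline failure."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a genomes→tree run needs; mirrors the CLI flags.

    Exactly one of (k, q) and one of (sigma, s) must be set; q = 10⁻⁹ and
    s = 0.5 reproduce the recommended production parameters.
    """

    k: int | None = None
    q: float | None = 1e-9
    sigma: int | None = None
    s: float | None = 0.5
    hash_seed: int = 42
    model: str = "ei-gamma"  # pc | ei | ei-gamma
    gamma_a: float = 1.5
    freq_mode: str = "global"  # global | per_pair
    rounds: int = 16
    perturb: float = 0.2
    tree_seed: int = 0


def _load_genomes(genomes: Sequence) -> list[GenomeRecord]:
    records = []
    for g in genomes:
        records.append(g if isinstance(g, GenomeRecord) else read_fasta(g))
    return records


def run_genomes_to_tree(
    genomes: Sequence,
    cfg: RunConfig = RunConfig(),
    outdir=None,
) -> tuple[PhyloTree, DistanceMatrix]:
    """Sketch → Jaccard → p̂ → d → impute → BME ratchet search.

    ``genomes`` are FASTA paths or :class:`GenomeRecord` objects. Writes
    sketches, the PHYLIP matrix and the Newick tree to ``outdir`` when
    given. Fully deterministic for a fixed configuration.
    """
    records = _load_genomes(genomes)
    if len(records) < 3:
        raise PipelineError("input stage: need at least 3 genomes")
    try:
        params = resolve_sketch_params(records, k=cfg.k, q=cfg.q, sigma=cfg.sigma, s=cfg.s, seed=cfg.hash_seed)
        sketches = [bottom_sketch(rec, params) for rec in records]
    except ValueError as exc:
        raise PipelineError(f"sketch stage: {exc}") from exc
    try:
        dm = build_distance_matrix(sketches, model=cfg.model, gamma_a=cfg.gamma_a, freq_mode=cfg.freq_mode)
        dm_full = impute_missing(dm)
    except ValueError as exc:
        raise PipelineError(f"distance stage: {exc}") from exc
    off = dm_full.values[np.triu_indices(dm_full.n, 1)]
    if np.all(off <= 0.0):
        raise PipelineError("tree stage: degenerate distance matrix (all pairwise distances are zero)")
    try:
        tree = ratchet_search(dm_full, rounds=cfg.rounds, perturb_strength=cfg.perturb, seed=cfg.tree_seed)
    except ValueError as exc:
        raise PipelineError(f"tree stage: {exc}") from exc
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .sketch import write_sketch

        for sk in sketches:
            write_sketch(sk, out / f"{sk.taxon}.sketch")
        write_phylip(dm_full, out / "matrix.phy")
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        distances.pair_table(sketches, model=cfg.model, gamma_a=cfg.gamma_a, freq_mode=cfg.freq_mode).to_csv(
            out / "pairs.tsv", sep="\t", index=False
        )
    return tree, dm_full


# -- pair benchmark ----------------------------------------------------------


def simulate_phat_pairs(
    d_values: Iterable[float],
    model: EvoModelParams,
    length: int,
    seed: int,
    *,
    k: int | None = None,
    q: float | None = None,
    s: float | None = None,
    sigma: int | None = None,
    hash_seed: int = 42,
) -> pd.DataFrame:
    """Simulate one pair per divergence value and estimate p̂ by sketching.

    Returns a frame with columns d_true, p_true, j_hat, p_hat (NaN when
    ĵ = 0), g_x, g_y. The k-mer size resolves per pair from the longer
    sequence; sigma from the mean pair length.
    """
    rows = []
    for i, d in enumerate(d_values):
        pair = evolve_pair(float(d), model, length, seed=seed + i)
        rec_x = GenomeRecord.from_sequence(f"x{i}", pair.seq_x)
        rec_y = GenomeRecord.from_sequence(f"y{i}", pair.seq_y)
        params = resolve_sketch_params([rec_x, rec_y], k=k, q=q, sigma=sigma, s=s, seed=hash_seed)
        je = estimate_jaccard(bottom_sketch(rec_x, params), bottom_sketch(rec_y, params))
        p_hat = distances.p_from_jaccard(je.j_hat, params.k) if je.shared > 0 else math.nan
        rows.append(
            {
                "d_true": float(d),
                "p_true": pair.true_p,
                "j_hat": je.j_hat,
                "p_hat": p_hat,
                "k": params.k,
                "sigma": params.sigma,
                "g_x": rec_x.g,
                "g_y": rec_y.g,
            }
        )
    return pd.DataFrame(rows)


_FREQ_PANELS = {"f1": F1, "f2": F2, "f3": F3}


def _draw_model(
    freqs: np.ndarray,
    gamma: bool,
    rng: np.random.Generator,
    indel_rate: float,
    rates_library: Sequence[np.ndarray],
) -> EvoModelParams:
    rates = rates_library[rng.integers(len(rates_library))]
    alpha = rng.uniform(*ALPHA_RANGE) if gamma else math.inf
    return EvoModelParams(pi=freqs, rates=rates, gamma_shape=alpha, indel_rate=indel_rate)


def run_pair_benchmark(
    seed: int = 0,
    length: int = 100_000,
    n_per_d: int = 20,
    d_grid: np.ndarray | None = None,
    indel_rate: float = 0.01,
    scenarios: Sequence[tuple[str, str]] | None = None,
    rates_library: Sequence[np.ndarray] | None = None,
    sketch: bool = False,
    s: float = 0.8,
    q: float = 1e-9,
    paper_scale: bool = False,
) -> dict:
    """The six-scenario (GTR / GTR+Γ × f1/f2/f3) pair simulation benchmark.

    For each scenario, n_per_d pairs are simulated at every divergence of
    ``d_grid`` with exchangeabilities drawn from ``rates_library`` and (for
    GTR+Γ) a Γ shape drawn from the representative range. Returns per-
    scenario (p_true, d_true) clouds, an EI+Γ shape fitted to each cloud,
    pooled fits per model row, and (optionally) sketch-based accuracy
    reports.
    """
    if paper_scale:
        length, n_per_d = 5_000_000, 200
    if d_grid is None:
        d_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 9)
    if scenarios is None:
        scenarios = [(m, f) for m in ("gtr", "gtr-gamma") for f in ("f1", "f2", "f3")]
    if rates_library is None:
        rates_library = REPRESENTATIVE_RATES
    rng = np.random.default_rng(seed)
    results: dict = {"scenarios": {}, "pooled_fit": {}}
    pooled: dict[str, list] = {}
    for model_name, freq_name in scenarios:
        freqs = _FREQ_PANELS[freq_name]
        gamma = model_name == "gtr-gamma"
        b = distances.b1_from_freqs(freqs)
        p_list, d_list = [], []
        frames = []
        for d in d_grid:
            for _ in range(n_per_d):
                model = _draw_model(freqs, gamma, rng, indel_rate, rates_library)
                sub_seed = int(rng.integers(2**31))
                if sketch:
                    frame = simulate_phat_pairs([d], model, length, sub_seed, q=q, s=s)
                    frames.append(frame)
                    p_list.append(float(frame["p_true"].iloc[0]))
                else:
                    pair = evolve_pair(float(d), model, length, seed=sub_seed)
                    p_list.append(pair.true_p)
                d_list.append(float(d))
        p_arr, d_arr = np.array(p_list), np.array(d_list)
        fit_a = fit_a_to_points(p_arr, d_arr, b, b)
        entry = {"p_true": p_arr, "d_true": d_arr, "b": b, "fit_a": fit_a}
        if sketch:
            table = pd.concat(frames, ignore_index=True)
            entry["pairs"] = table
            entry["report"] = stats.accuracy_report(table["p_true"], table["p_hat"], p_max=0.25)
        results["scenarios"][(model_name, freq_name)] = entry
        pooled.setdefault(model_name, []).append((p_arr, d_arr, np.full_like(p_arr, b)))
    for model_name, parts in pooled.items():
        p_all = np.concatenate([x[0] for x in parts])
        d_all = np.concatenate([x[1] for x in parts])
        b_all = np.concatenate([x[2] for x in parts])
        results["pooled_fit"][model_name] = fit_a_to_points(p_all, d_all, b_all, b_all)
    return results


# -- tree benchmark ----------------------------------------------------------


def run_tree_benchmark(
    reference_trees: Sequence[PhyloTree],
    transforms: Sequence[tuple[str, float | None]] = (("pc", None), ("ei", None), ("ei-gamma", 1.5)),
    length: int = 100_000,
    seed: int = 0,
    cfg: RunConfig = RunConfig(s=0.5, q=1e-9, rounds=8),
    indel_rate: float = 0.01,
    gamma_shape: float | None = None,
    rates_library: Sequence[np.ndarray] | None = None,
    freqs: np.ndarray | None = None,
) -> dict:
    """Simulate down each reference tree, infer with each transform, score recovery.

    ``transforms`` pairs a policy name with its Γ shape (ignored unless the
    policy is ``ei-gamma``). The same simulated sequences and sketches feed
    every transform, so differences reflect the transforms alone. Returns
    {"recovery": {(model, a): percent}, "rf": {...: list of RF distances}}.
    """
    if rates_library is None:
        rates_library = REPRESENTATIVE_RATES
    if freqs is None:
        freqs = F2
    rng = np.random.default_rng(seed)
    inferred: dict[tuple, list[PhyloTree]] = {t: [] for t in transforms}
    refs: list[PhyloTree] = []
    for ref in reference_trees:
        alpha = gamma_shape if gamma_shape is not None else rng.uniform(*ALPHA_RANGE)
        model = _draw_model(freqs, False, rng, indel_rate, rates_library)
        model = replace(model, gamma_shape=alpha)
        sim_seed = int(rng.integers(2**31))
        seqs = evolve_along_tree(ref.to_newick(), model, length, seed=sim_seed)
        records = [GenomeRecord.from_sequence(name, seq) for name, seq in sorted(seqs.items())]
        params = resolve_sketch_params(records, k=cfg.k, q=cfg.q, sigma=cfg.sigma, s=cfg.s, seed=cfg.hash_seed)
        sketches = [bottom_sketch(rec, params) for rec in records]
        refs.append(ref)
        for model_name, a in transforms:
            dm = build_distance_matrix(
                sketches,
                model=model_name,
                gamma_a=a if a is not None else cfg.gamma_a,
                freq_mode=cfg.freq_mode,
            )
            dm = impute_missing(dm)
            tree = ratchet_search(dm, rounds=cfg.rounds, perturb_strength=cfg.perturb, seed=cfg.tree_seed)
            inferred[(model_name, a)].append(tree)
    out = {"recovery": {}, "rf": {}}
    for key, trees in inferred.items():
        out["recovery"][key] = stats.recovery_percentage(trees, refs)
        out["rf"][key] = [rf_distance(t, r) for t, r in zip(trees, refs)]
    return out
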