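"""p-distances, evolutionary distance transforms, and distance matrices.

The estimated Jaccard index j of two genomes' k-mer sets converts to an
uncorrected p-distance via

    p = 1 - (2j / (j + 1))^(1/k)

and p converts to an evolutionary distance d (expected substitutions per
site) under one of three transforms:

* Poisson correction (PC):          d = -ln(1 - p)
* equal-input / F81 (EI):           d = -b1 ln(1 - p/b2)
* equal-input with Γ rates (EI+Γ):  d = a b1 [(1 - p/b2)^(-1/a) - 1]

with b1 = 1 - Σ π_r² and b2 = 1 - Σ π_r^x π_r^y derived from nucleotide
frequencies, and a > 0 the Γ shape parameter (a → ∞ recovers EI, and EI with
b1 = b2 = 1 is PC). EI+Γ is the exact inverse of the F81+Γ expected
p-distance curve, which makes a identifiable by least squares against any
empirical or analytic (p, d) relationship — see :func:`fit_equiv_a`.

Pairs with ĵ = 0 or p̂ ≥ b2 yield no finite distance; the matrix builder
records them as explicitly missing, to be filled by the triangle-inequality
imputation d_uv = min_x (d_xu + d_xv).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .sketch import Sketch, estimate_jaccard

__all__ = [
    "TransformParams",
    "DistanceMatrix",
    "p_from_jaccard",
    "p_from_mash_distance",
    "b1_from_freqs",
    "b2_from_freq_pair",
    "pc_distance",
    "ei_log_distance",
    "ei_gamma_distance",
    "delta_v11",
    "fit_equiv_a",
    "fit_a_to_points",
    "build_distance_matrix",
    "pair_table",
    "impute_missing",
    "write_phylip",
    "read_phylip",
    "J_ZERO",
    "P_EXCEEDS_B2",
    "IMPUTED",
]

# reason codes for missing / imputed entries
OK, J_ZERO, P_EXCEEDS_B2, IMPUTED = 0, 1, 2, 3
REASON_LABELS = {OK: "", J_ZERO: "j_zero", P_EXCEEDS_B2: "p_exceeds_b2", IMPUTED: "imputed"}

DEFAULT_P_GRID = np.round(np.arange(1, 351) * 0.001, 9)  # (0, 0.35] step 0.001


@dataclass(frozen=True)
class TransformParams:
    """(b1, b2, a) triple parameterizing the EI(+Γ) transforms.

    ``a = inf`` selects the pure logarithmic (EI) form; b1 = b2 = 1 gives PC.
    """

    b1: float = 1.0
    b2: float = 1.0
    a: float = math.inf

    def __post_init__(self):
        if not 0.0 < self.b1 <= 1.0:
            raise ValueError(f"b1 must lie in (0, 1], got {self.b1}")
        if not 0.0 < self.b2 <= 1.0:
            raise ValueError(f"b2 must lie in (0, 1], got {self.b2}")
        if not self.a > 0.0:
            raise ValueError(f"a must be positive, got {self.a}")


def p_from_jaccard(j: float, k: int):
    """Uncorrected p-distance from a Jaccard index: p = 1 - (2j/(j+1))^(1/k).

    j = 0 carries no distance information and returns NaN (the matrix builder
    records such pairs as missing with reason ``j_zero``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    j_arr = np.asarray(j, dtype=float)
    if np.any((j_arr < 0) | (j_arr > 1)):
        raise ValueError("Jaccard index must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(j_arr > 0, 1.0 - (2.0 * j_arr / (j_arr + 1.0)) ** (1.0 / k), np.nan)
    return float(p) if np.isscalar(j) else p


def p_from_mash_distance(D: float):
    """Invert a Mash-reported PC distance back to a p-distance: p = 1 - e^-D."""
    D_arr = np.asarray(D, dtype=float)
    if np.any(D_arr < 0):
        raise ValueError("Mash distance must be non-negative")
    p = -np.expm1(-D_arr)
    return float(p) if np.isscalar(D) else p


def _check_freqs(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,):
        raise ValueError("frequency vector must have 4 entries")
    if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"invalid frequency vector {pi}")
    return pi


def b1_from_freqs(pi) -> float:
    """Equal-input coefficient b1 = 1 - Σ π_r²."""
    pi = _check_freqs(pi)
    return float(1.0 - np.sum(pi**2))


def b2_from_freq_pair(pix, piy) -> float:
    """Cross-genome coefficient b2 = 1 - Σ π_r^x π_r^y."""
    pix = _check_freqs(pix)
    piy = _check_freqs(piy)
    return float(1.0 - np.sum(pix * piy))


def _as_p(p) -> np.ndarray:
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= 1):
        raise ValueError("p-distance must lie in [0, 1)")
    return p_arr


def ei_log_distance(p, tp: TransformParams):
    """EI distance d = -b1 ln(1 - p/b2); NaN where p >= b2 (missing)."""
    p_arr = _as_p(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(p_arr < tp.b2, -tp.b1 * np.log1p(-p_arr / tp.b2), np.nan)
    return float(d) if np.isscalar(p) else d


def pc_distance(p):
    """Poisson correction d = -ln(1 - p), the b1 = b2 = 1 special case."""
    return ei_log_distance(p, TransformParams(1.0, 1.0))


def _ei_gamma(p_arr: np.ndarray, b1, b2, a) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        base = 1.0 - p_arr / b2
        d = a * b1 * (np.power(base, -1.0 / a) - 1.0)
        return np.where(p_arr < b2, d, np.nan)


def ei_gamma_distance(p, tp: TransformParams):
    """EI+Γ distance d = a b1 [(1 - p/b2)^(-1/a) - 1]; a = inf delegates to EI."""
    if math.isinf(tp.a):
        return ei_log_distance(p, tp)
    p_arr = _as_p(p)
    d = _ei_gamma(p_arr, tp.b1, tp.b2, tp.a)
    return float(d) if np.isscalar(p) else d


def delta_v11(p, tp: TransformParams):
    """The accidental transform δ = -b1 ln(1 + ln(1 - p)/b2).

    This is EI applied to a PC distance as if it were a p-distance (the
    historical JolyTree v1.1 behaviour); NaN where its argument is
    non-positive.
    """
    p_arr = _as_p(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = 1.0 + np.log1p(-p_arr) / tp.b2
        d = np.where(inner > 0, -tp.b1 * np.log(np.maximum(inner, 1e-300)), np.nan)
    return float(d) if np.isscalar(p) else d


def fit_equiv_a(
    target: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    b1: float,
    b2: float,
    p_grid: np.ndarray | None = None,
    a_bounds: tuple[float, float] = (0.01, 100.0),
) -> float:
    """Least-squares EI+Γ shape parameter matching a target d(p) curve.

    Minimizes Σ_grid [a b1 ((1-p/b2)^(-1/a) - 1) - target(p)]² over log a in
    [ln a_lo, ln a_hi] by bounded scalar minimization; deterministic given
    the grid (default: p = 0.001 ... 0.35 step 0.001).
    """
    grid = DEFAULT_P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= b2):
        raise ValueError("p grid must lie within (0, b2)")
    t = np.asarray(target(grid) if callable(target) else target, dtype=float)
    if t.shape != grid.shape or not np.all(np.isfinite(t)):
        raise ValueError("target curve must be finite on the whole grid")
    return fit_a_to_points(grid, t, b1, b2, a_bounds=a_bounds)


def fit_a_to_points(
    p: np.ndarray,
    d: np.ndarray,
    b1,
    b2,
    a_bounds: tuple[float, float] = (0.01, 100.0),
) -> float:
    """Fit the EI+Γ shape a to scattered (p, d) points by least squares.

    b1/b2 may be scalars or per-point arrays (for pooled fits across
    frequency regimes).
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    keep = np.isfinite(p) & np.isfinite(d) & (p < np.minimum(b2, 1.0) * (1 - 1e-12)) & (p >= 0)
    if keep.sum() < 2:
        raise ValueError("need at least 2 usable (p, d) points")
    p, d = p[keep], d[keep]
    b1k = b1[keep] if b1.ndim else b1
    b2k = b2[keep] if b2.ndim else b2

    def sse(u: float) -> float:
        pred = _ei_gamma(p, b1k, b2k, math.exp(u))
        return float(np.sum((pred - d) ** 2))

    lo, hi = a_bounds
    res = minimize_scalar(sse, bounds=(math.log(lo), math.log(hi)), method="bounded", options={"xatol": 1e-10})
    return float(math.exp(res.x))


def fit_bias_compensated_a(
    a_target: float,
    b1: float,
    b2: float,
    beta: float = 1.15,
    p_grid: np.ndarray | None = None,
) -> float:
    """Shape a such that EI+Γ(a) on the biased estimate p̂ = βp matches EI+Γ(a_target) on p.

    Sketch-based p̂ overestimates p by a roughly constant factor β; applying
    the transform to p̂ therefore calls for a larger shape parameter than the
    one that fits the unbiased curve. Least squares over the default
    (0, 0.35] grid.
    """
    grid = DEFAULT_P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
    target = _ei_gamma(grid, b1, b2, a_target)
    return fit_a_to_points(beta * grid, target, b1, b2)


# -- distance matrices -------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric taxa x taxa evolutionary distances with explicit missingness.

    ``values`` holds NaN wherever an entry is missing; ``reasons`` records
    why (j_zero, p_exceeds_b2) or that an entry was later imputed.
    """

    taxa: list[str]
    values: np.ndarray
    reasons: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if self.reasons is None:
            self.reasons = np.zeros((n, n), dtype=np.int8)
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            np.where(finite, self.values, 0.0), np.where(finite, self.values, 0.0).T
        ):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def n_missing_pairs(self) -> int:
        return int(np.triu(self.missing_mask, 1).sum())

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(list(self.taxa), self.values.copy(), self.reasons.copy())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def _pair_transform_params(
    model: str,
    gamma_a: float,
    freq_mode: str,
    pool_pi: np.ndarray,
    pi_x: np.ndarray,
    pi_y: np.ndarray,
) -> TransformParams:
    if model == "pc":
        return TransformParams(1.0, 1.0, math.inf)
    if freq_mode == "global":
        b1 = b1_from_freqs(pool_pi)
        b2 = b2_from_freq_pair(pool_pi, pool_pi)
    elif freq_mode == "per_pair":
        b1 = 0.5 * (b1_from_freqs(pi_x) + b1_from_freqs(pi_y))
        b2 = b2_from_freq_pair(pi_x, pi_y)
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    a = math.inf if model == "ei" else gamma_a
    if model not in ("ei", "ei-gamma"):
        raise ValueError(f"unknown transform model {model!r}")
    return TransformParams(b1, b2, a)


def pair_table(
    sketches: Sequence[Sketch],
    model: str = "ei-gamma",
    gamma_a: float = 1.5,
    freq_mode: str = "global",
):
    """Per-pair (ĵ, p̂, d) records for a set of compatible sketches."""
    import pandas as pd

    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches")
    for sk in sketches[1:]:
        if not sketches[0].compatible_with(sk):
            raise ValueError(f"incompatible sketches: {sketches[0].taxon} vs {sk.taxon}")
    weights = np.array([sk.n_acgt for sk in sketches], dtype=float)
    pool_pi = np.sum([sk.freqs * w for sk, w in zip(sketches, weights)], axis=0) / weights.sum()
    rows = []
    for i in range(len(sketches)):
        for jdx in range(i + 1, len(sketches)):
            a, b = sketches[i], sketches[jdx]
            je = estimate_jaccard(a, b)
            tp = _pair_transform_params(model, gamma_a, freq_mode, pool_pi, a.freqs, b.freqs)
            if je.shared == 0:
                p_hat, d, reason = np.nan, np.nan, J_ZERO
            else:
                p_hat = p_from_jaccard(je.j_hat, a.k)
                d = ei_gamma_distance(p_hat, tp)
                reason = OK if np.isfinite(d) else P_EXCEEDS_B2
            rows.append(
                {
                    "taxon_a": a.taxon,
                    "taxon_b": b.taxon,
                    "j_hat": je.j_hat,
                    "shared": je.shared,
                    "denom": je.denom,
                    "p_hat": p_hat,
                    "b1": tp.b1,
                    "b2": tp.b2,
                    "d": d,
                    "flag": REASON_LABELS[reason],
                }
            )
    return pd.DataFrame(rows)


def build_distance_matrix(
    sketches: Sequence[Sketch],
    model: str = "ei-gamma",
    gamma_a: float = 1.5,
    freq_mode: str = "global",
) -> DistanceMatrix:
    """All-pairs evolutionary distances from sketches under a transform policy.

    ``model`` is one of ``pc`` (Poisson), ``ei`` (equal-input), ``ei-gamma``
    (equal-input with Γ shape ``gamma_a``); ``freq_mode`` selects pooled
    (``global``) or per-pair frequency coefficients. Pairs with ĵ = 0 or
    p̂ ≥ b2 are left missing.
    """
    if len(sketches) < 3:
        raise ValueError("need at least 3 sketches to build a distance matrix")
    table = pair_table(sketches, model=model, gamma_a=gamma_a, freq_mode=freq_mode)
    taxa = [sk.taxon for sk in sketches]
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    values = np.zeros((n, n))
    reasons = np.zeros((n, n), dtype=np.int8)
    for row in table.itertuples(index=False):
        i, j = index[row.taxon_a], index[row.taxon_b]
        values[i, j] = values[j, i] = row.d
        code = {v: k for k, v in REASON_LABELS.items()}[row.flag]
        reasons[i, j] = reasons[j, i] = code
    return DistanceMatrix(taxa, values, reasons)


def impute_missing(m: DistanceMatrix) -> DistanceMatrix:
    """Fill missing entries by d_uv = min over x of (d_xu + d_xv).

    All imputations read the *original* matrix (no chaining); the rule is the
    tight upper bound implied by the triangle inequality. A pair with no
    third taxon resolving it raises an error naming the pair.
    """
    out = m.copy()
    vals = m.values
    miss = np.argwhere(np.triu(m.missing_mask, 1))
    for u, v in miss:
        cand = vals[:, u] + vals[:, v]
        cand[[u, v]] = np.nan
        if not np.any(np.isfinite(cand)):
            raise ValueError(f"cannot impute distance between {m.taxa[u]!r} and {m.taxa[v]!r}: no resolving third taxon")
        d = float(np.nanmin(cand))
        out.values[u, v] = out.values[v, u] = d
        out.reasons[u, v] = out.reasons[v, u] = IMPUTED
    return out


def write_phylip(m: DistanceMatrix, path) -> None:
    """Write a relaxed square PHYLIP matrix (tab-separated, full precision)."""
    if m.n_missing_pairs > 0:
        raise ValueError("matrix has missing entries; run impute_missing first")
    for t in m.taxa:
        if any(ch.isspace() for ch in t):
            raise ValueError(f"taxon label {t!r} contains whitespace")
    with open(path, "w") as fh:
        fh.write(f"{m.n}\n")
        for i, t in enumerate(m.taxa):
            row = "\t".join(format(x, ".17g") for x in m.values[i])
            fh.write(f"{t}\t{row}\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        taxa, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.array(rows)
    if values.shape != (n, n):
        raise ValueError(f"{path}: malformed PHYLIP matrix")
    return DistanceMatrix(taxa, values)
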