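"""Accuracy statistics for estimated vs. true p-distances, and tree recovery.

Given paired observations (p, p̂) — true p-distance from the simulated
alignment and sketch-based estimate — the module computes, over the subset
Ψ(p_max) of pairs with p ≤ p_max:

* the slope β of the least-squares regression through the origin p̂ = βp,
  and its coefficient of determination R²;
* the largest p_max on a grid for which the correlation within Ψ exceeds
  0.99, assessed by a one-sided Fisher z-test at the 1% level;
* the fraction of pairs whose Jaccard estimate was zero (no information).

Tree accuracy is the percentage of inference replicates whose unrooted
topology matches the reference exactly (Robinson–Foulds distance 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .metree import PhyloTree, rf_distance

__all__ = [
    "AccuracyReport",
    "origin_regression",
    "fisher_r_exceeds",
    "find_p_r99",
    "f_zero_j",
    "recovery_percentage",
    "accuracy_report",
    "DEFAULT_PMAX_GRID",
]

DEFAULT_PMAX_GRID = np.round(np.arange(0.10, 0.55 + 1e-9, 0.005), 9)


def _usable(p_true, p_hat, p_max=None):
    p = np.asarray(p_true, dtype=float)
    ph = np.asarray(p_hat, dtype=float)
    mask = np.isfinite(p) & np.isfinite(ph)
    if p_max is not None:
        mask &= p <= p_max
    return p[mask], ph[mask]


def origin_regression(p_true, p_hat, p_max=None) -> tuple[float, float]:
    """Through-origin slope β = Σ p·p̂ / Σ p² and its R² over Ψ(p_max).

    Pairs with p̂ = NaN (ĵ = 0) are excluded. R² uses the conventional
    mean-centered total sum of squares.
    """
    p, ph = _usable(p_true, p_hat, p_max)
    if p.size < 2:
        raise ValueError("need at least 2 usable (p, p_hat) pairs")
    denom = float(np.sum(p**2))
    if denom == 0:
        raise ValueError("all p-distances are zero; slope undefined")
    beta = float(np.sum(p * ph)) / denom
    ss_res = float(np.sum((ph - beta * p) ** 2))
    ss_tot = float(np.sum((ph - ph.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return beta, r2


def fisher_r_exceeds(r: float, n: int, rho0: float = 0.99, alpha: float = 0.01) -> bool:
    """One-sided Fisher z-test of H0: rho <= rho0 against rho > rho0."""
    if n < 4:
        raise ValueError("Fisher z-test needs n >= 4")
    r = min(max(float(r), -1.0 + 1e-12), 1.0 - 1e-12)
    z = (math.atanh(r) - math.atanh(rho0)) * math.sqrt(n - 3)
    return bool(norm.sf(z) < alpha)


def find_p_r99(p_true, p_hat, grid=None, rho0: float = 0.99, alpha: float = 0.01) -> float:
    """Largest grid p_max whose Ψ-subset shows correlation > rho0 (Fisher test).

    Grid values whose subset holds fewer than 4 usable pairs are skipped;
    returns 0.0 when no grid value passes.
    """
    grid = DEFAULT_PMAX_GRID if grid is None else np.asarray(grid, dtype=float)
    best = 0.0
    for p_max in grid:
        p, ph = _usable(p_true, p_hat, p_max)
        if p.size < 4 or np.std(p) == 0 or np.std(ph) == 0:
            continue
        r = float(np.corrcoef(p, ph)[0, 1])
        if fisher_r_exceeds(r, p.size, rho0=rho0, alpha=alpha):
            best = float(p_max)
    return best


def f_zero_j(p_true, p_hat, p_max) -> float:
    """Fraction of pairs with p ≤ p_max whose estimate was ĵ = 0 (p̂ = NaN)."""
    p = np.asarray(p_true, dtype=float)
    ph = np.asarray(p_hat, dtype=float)
    window = p <= p_max
    if not np.any(window):
        return 0.0
    return float(np.mean(~np.isfinite(ph[window])))


@dataclass(frozen=True)
class AccuracyReport:
    """Summary of p̂-vs-p agreement for one benchmark condition."""

    beta: float
    r2: float
    r: float
    n: int
    p_max: float
    p_r99: float
    f_zero_j: float


def accuracy_report(p_true, p_hat, p_max: float, grid=None) -> AccuracyReport:
    beta, r2 = origin_regression(p_true, p_hat, p_max)
    p, ph = _usable(p_true, p_hat, p_max)
    r = float(np.corrcoef(p, ph)[0, 1]) if p.size >= 2 and np.std(p) > 0 and np.std(ph) > 0 else float("nan")
    return AccuracyReport(
        beta=beta,
        r2=r2,
        r=r,
        n=int(p.size),
        p_max=float(p_max),
        p_r99=find_p_r99(p_true, p_hat, grid=grid),
        f_zero_j=f_zero_j(p_true, p_hat, p_max),
    )


def recovery_percentage(inferred: list[PhyloTree], reference: list[PhyloTree]) -> float:
    """Percentage of slots whose trees match exactly (unrooted RF = 0)."""
    if len(inferred) != len(reference):
        raise ValueError("tree lists differ in length")
    if not inferred:
        raise ValueError("empty tree lists")
    hits = 0
    for slot, (ti, tr) in enumerate(zip(inferred, reference)):
        try:
            if rf_distance(ti, tr) == 0:
                hits += 1
        except ValueError as exc:
            raise ValueError(f"slot {slot}: {exc}") from exc
    return 100.0 * hits / len(inferred)
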