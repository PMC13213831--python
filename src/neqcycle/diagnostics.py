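"""Work-distribution overlap and convergence diagnostics.

The Crooks fluctuation theorem relates the forward work distribution
P_f(W) to the negated reverse one P_r(−W); bidirectional estimators are
reliable only where the two share support. The overlap coefficient here
is the histogram intersection Σ_bins min(p_f, p_r⁻) on shared bins
(Freedman–Diaconis width from the pooled sample, at least 10 bins) —
a distribution-free choice that handles non-Gaussian work distributions.

The convergence sweep re-runs BAR on subsamples of increasing size so
users can judge how many transitions their system actually needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import BarConvergenceError, WorkSet, bar


@dataclass(frozen=True)
class OverlapReport:
    """Forward / negated-reverse distribution overlap summary."""

    overlap_coefficient: float
    n_forward: int
    n_reverse: int
    forward_mean: float
    reverse_mean_negated: float
    gap: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_coefficient <= 1.0 + 1e-12:
            raise ValueError("overlap coefficient must lie in [0, 1]")


def _shared_bins(pooled: np.ndarray, min_bins: int = 10) -> np.ndarray:
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        hi = lo + 1e-9
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    width = 2.0 * iqr * pooled.size ** (-1.0 / 3.0)
    n_bins = min_bins if width <= 0 else max(min_bins, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n_bins + 1)


def overlap(workset: WorkSet, min_samples: int = 5) -> OverlapReport:
    """Histogram-intersection overlap of forward and negated-reverse works.

    Returns 1.0 for identical distributions, 0.0 for disjoint supports.
    Requires at least ``min_samples`` works per direction.
    """
    wf = workset.forward
    wrn = -workset.reverse  # Crooks compares P_f(W) with P_r(−W)
    if wf.size < min_samples or workset.reverse.size < min_samples:
        raise ValueError(
            f"overlap needs >= {min_samples} samples per direction "
            f"(got {wf.size} forward, {workset.reverse.size} reverse)"
        )
    edges = _shared_bins(np.concatenate([wf, wrn]))
    pf, _ = np.histogram(wf, bins=edges)
    pr, _ = np.histogram(wrn, bins=edges)
    coeff = float(np.minimum(pf / wf.size, pr / wrn.size).sum())
    return OverlapReport(
        overlap_coefficient=min(coeff, 1.0),
        n_forward=int(wf.size),
        n_reverse=int(wrn.size),
        forward_mean=float(wf.mean()),
        reverse_mean_negated=float(wrn.mean()),
        gap=float(abs(wf.mean() - wrn.mean())),
    )


def convergence_sweep(
    workset: WorkSet,
    grid: list[int],
    n_draws: int = 50,
    seed: int = 2024,
) -> pd.DataFrame:
    """BAR stability under subsampling.

    For each n in ``grid``, draws n forward and n reverse works without
    replacement ``n_draws`` times, re-runs BAR, and reports the mean and
    SD of |ΔG_BAR(n) − ΔG_BAR(full)|. Deterministic under ``seed``.
    Returns a DataFrame with columns (n, mean_abs_dev, sd_abs_dev,
    n_draws_ok).
    """
    nf, nr = workset.forward.size, workset.reverse.size
    for n in grid:
        if n > min(nf, nr):
            raise ValueError(f"grid value {n} exceeds sample count {min(nf, nr)}")
    full = bar(workset).value
    rng = np.random.default_rng(seed)
    rows = []
    for n in grid:
        devs = []
        for _ in range(n_draws):
            f = rng.choice(workset.forward, size=n, replace=False)
            r = rng.choice(workset.reverse, size=n, replace=False)
            try:
                devs.append(abs(bar(WorkSet(f, r, workset.temperature)).value - full))
            except BarConvergenceError:
                continue
        if devs:
            rows.append({
                "n": n,
                "mean_abs_dev": float(np.mean(devs)),
                "sd_abs_dev": float(np.std(devs, ddof=1)) if len(devs) > 1 else 0.0,
                "n_draws_ok": len(devs),
            })
    return pd.DataFrame(rows, columns=["n", "mean_abs_dev", "sd_abs_dev", "n_draws_ok"])
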