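"""Free-energy estimators for nonequilibrium work distributions.

Three estimators operate on the work samples collected from fast
alchemical transitions:

* Jarzynski's equality, ΔG = −kT ln⟨exp(−W/kT)⟩, over one direction;
* its Gaussian approximation, ΔG = ⟨W⟩ − var(W)/(2kT), exact when the
  work distribution is Gaussian;
* the Bennett Acceptance Ratio (BAR), which combines forward (0→1) and
  reverse (1→0) works through the self-consistent Bennett equation and
  is the minimum-variance choice when both directions are sampled.

Sign conventions: forward works live in the 0→1 frame, reverse works in
the 1→0 frame. BAR returns ΔG of the forward transformation; under the
Crooks fluctuation theorem P_f(W)/P_r(−W) = exp((W−ΔG)/kT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .constants import kT as _kT

Method = Literal["jarzynski", "gaussian", "bar"]

DEFAULT_BOOTSTRAP_N = 1000
DEFAULT_SEED = 2024


class BarConvergenceError(RuntimeError):
    """The Bennett equation had no sign change in the expanded bracket."""


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse work samples (kcal/mol) at one temperature (K)."""

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.forward, dtype=float))
        r = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        object.__setattr__(self, "forward", f)
        object.__setattr__(self, "reverse", r)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if (f.size and not np.all(np.isfinite(f))) or (
            r.size and not np.all(np.isfinite(r))
        ):
            raise ValueError("work values must be finite")

    @property
    def kT(self) -> float:
        return _kT(self.temperature)


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG value (kcal/mol) with uncertainty, method tag and sample counts."""

    value: float
    uncertainty: float
    method: Method
    n_forward: int = 0
    n_reverse: int = 0

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def _bootstrap_se(works: np.ndarray, stat, n_boot: int, seed: int) -> float:
    if n_boot <= 0 or works.size < 2:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, works.size, size=(n_boot, works.size))
    vals = np.array([stat(works[row]) for row in idx])
    return float(np.std(vals, ddof=1))


def jarzynski(
    works: Sequence[float],
    temperature: float = 298.15,
    direction: Literal["forward", "reverse"] = "forward",
    n_bootstrap: int = DEFAULT_BOOTSTRAP_N,
    seed: int = DEFAULT_SEED,
) -> FreeEnergyEstimate:
    """Exponential-average (Jarzynski) estimate from one work direction.

    ΔG = −kT ln( (1/n) Σ_i exp(−W_i/kT) ), evaluated with a log-sum-exp
    shift so arbitrarily large |W| cannot overflow. A reverse-direction
    input returns the estimate in the reverse (1→0) frame; negate it to
    compare with forward-frame values. Uncertainty is a seeded bootstrap
    standard error (0 for a single sample).
    """
    w = np.atleast_1d(np.asarray(works, dtype=float))
    if w.size == 0:
        raise ValueError("jarzynski requires at least one work sample")
    kT = _kT(temperature)

    def stat(sample: np.ndarray) -> float:
        return -kT * (logsumexp(-sample / kT) - np.log(sample.size))

    value = stat(w)
    se = _bootstrap_se(w, stat, n_bootstrap, seed)
    n = int(w.size)
    nf, nr = (n, 0) if direction == "forward" else (0, n)
    return FreeEnergyEstimate(value, se, "jarzynski", nf, nr)


def gaussian_estimate(
    works: Sequence[float],
    temperature: float = 298.15,
    direction: Literal["forward", "reverse"] = "forward",
    n_bootstrap: int = DEFAULT_BOOTSTRAP_N,
    seed: int = DEFAULT_SEED,
) -> FreeEnergyEstimate:
    """Gaussian approximation ΔG = ⟨W⟩ − var(W)/(2kT), unbiased variance."""
    w = np.atleast_1d(np.asarray(works, dtype=float))
    if w.size < 2:
        raise ValueError("gaussian estimator requires >= 2 work samples")
    kT = _kT(temperature)

    def stat(sample: np.ndarray) -> float:
        return float(np.mean(sample) - np.var(sample, ddof=1) / (2.0 * kT))

    value = stat(w)
    se = _bootstrap_se(w, stat, n_bootstrap, seed)
    n = int(w.size)
    nf, nr = (n, 0) if direction == "forward" else (0, n)
    return FreeEnergyEstimate(value, se, "gaussian", nf, nr)


def _bar_residual(dg: float, wf: np.ndarray, wr: np.ndarray, beta: float, M: float) -> float:
    # Fermi-function form of the Bennett self-consistency condition:
    # sum_i f(β(M + W_f,i − ΔG)) − sum_j f(β(−M + W_r,j + ΔG)) = 0
    lhs = expit(-beta * (M + wf - dg)).sum()
    rhs = expit(-beta * (-M + wr + dg)).sum()
    return float(lhs - rhs)


def _bar_solve(wf: np.ndarray, wr: np.ndarray, kT: float) -> float:
    beta = 1.0 / kT
    M = kT * np.log(wf.size / wr.size)
    lo = float(min(wf.min(), -wr.max())) - 50.0 * kT
    hi = float(max(wf.max(), -wr.min())) + 50.0 * kT
    f_lo = _bar_residual(lo, wf, wr, beta, M)
    f_hi = _bar_residual(hi, wf, wr, beta, M)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise BarConvergenceError(
            f"Bennett equation has no sign change on [{lo:.6g}, {hi:.6g}] "
            f"(residuals {f_lo:.3g}, {f_hi:.3g})"
        )
    return float(brentq(_bar_residual, lo, hi, args=(wf, wr, beta, M),
                        xtol=1e-8, rtol=8.9e-16))


def bar_asymptotic_variance(workset: WorkSet, dg: float) -> float:
    """Bennett's asymptotic variance of the BAR estimate (kcal/mol)²."""
    wf, wr = workset.forward, workset.reverse
    kT = workset.kT
    beta = 1.0 / kT
    nf, nr = wf.size, wr.size
    N = nf + nr
    M = kT * np.log(nf / nr)
    uf = beta * (M + wf - dg)
    ur = beta * (-M + wr + dg)
    # 1/(2+2cosh x) = f(x) f(−x), numerically safe via expit
    terms = np.concatenate([expit(uf) * expit(-uf), expit(ur) * expit(-ur)])
    avg = float(terms.mean())
    if avg <= 0:
        return np.inf
    var = (1.0 / (beta ** 2 * N)) * (1.0 / avg - (N / nf + N / nr))
    return max(var, 0.0)


def bar(
    workset: WorkSet,
    uncertainty: Literal["analytic", "bootstrap"] = "analytic",
    n_bootstrap: int = DEFAULT_BOOTSTRAP_N,
    seed: int = DEFAULT_SEED,
) -> FreeEnergyEstimate:
    """Bennett Acceptance Ratio estimate from bidirectional works.

    Solves the self-consistent Bennett equation (with the sample-count
    constant M = kT ln(n_f/n_r)) by bracketed root finding; the bracket
    is the pooled work range expanded by 50 kT on each side. The default
    uncertainty is Bennett's asymptotic variance; a seeded bootstrap over
    both directions is available as a cross-check.
    """
    wf, wr = workset.forward, workset.reverse
    if wf.size == 0 or wr.size == 0:
        raise ValueError("BAR requires non-empty forward and reverse work sets")
    kT = workset.kT
    dg = _bar_solve(wf, wr, kT)
    if uncertainty == "analytic":
        se = float(np.sqrt(bar_asymptotic_variance(workset, dg)))
    else:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_bootstrap):
            bf = wf[rng.integers(0, wf.size, wf.size)]
            br = wr[rng.integers(0, wr.size, wr.size)]
            try:
                vals.append(_bar_solve(bf, br, kT))
            except BarConvergenceError:
                continue
        se = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return FreeEnergyEstimate(dg, se, "bar", int(wf.size), int(wr.size))


def estimate_all(
    workset: WorkSet,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_N,
    seed: int = DEFAULT_SEED,
) -> dict[str, FreeEnergyEstimate]:
    """All three estimates for one WorkSet (BAR is the headline value).

    Jarzynski and the Gaussian approximation are computed on the forward
    works and kept for diagnostics; BAR uses both directions.
    """
    out: dict[str, FreeEnergyEstimate] = {}
    if workset.forward.size:
        out["jarzynski"] = jarzynski(
            workset.forward, workset.temperature, "forward", n_bootstrap, seed
        )
        if workset.forward.size >= 2:
            out["gaussian"] = gaussian_estimate(
                workset.forward, workset.temperature, "forward", n_bootstrap, seed
            )
    if workset.forward.size and workset.reverse.size:
        out["bar"] = bar(workset, n_bootstrap=n_bootstrap, seed=seed)
    return out
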