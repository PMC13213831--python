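"""Gaussian-weighted combination of replicate ΔG estimates.

Independent replicas of the same transformation rarely agree exactly;
rather than discarding outliers, each replica i receives a weight

    ω_i = Σ_j exp(−(ΔG_i − ΔG_j)² / (2σ²))

measuring its proximity to the other replicas, and the combined value is
the ω-weighted average ΔG_env = Σ ω_i ΔG_i / Σ ω_i. The bandwidth σ is
set by the rule of thumb σ = std(ΔG)·n^(−1/5); σ → ∞ makes the average
arithmetic (equal weights), σ = 0 (all replicas identical) falls back to
the arithmetic mean as well.

The combined uncertainty blends inter-replica scatter with the
per-replica estimator errors in quadrature:

    err² = weighted SEM² + mean(per-replica err²) / n

so that when replicas disagree, the scatter term dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .estimators import FreeEnergyEstimate

Environment = Literal["water", "membrane", "protein"]

#: Sentinel for sigma_mode="infinite": exact equal weights.
SIGMA_INFINITE = math.inf


class BandwidthError(ValueError):
    """Rule-of-thumb bandwidth needs >= 2 replicas; use the arithmetic mean."""


@dataclass(frozen=True)
class ReplicaSet:
    """Per-replica ΔG estimates for one environment.

    ``sigma_mode`` is "rule_of_thumb", "infinite" (equal weights) or
    "fixed" (with ``sigma_value``). All estimates must share one method
    tag.
    """

    environment: Environment
    estimates: tuple[FreeEnergyEstimate, ...]
    sigma_mode: Literal["rule_of_thumb", "infinite", "fixed"] = "rule_of_thumb"
    sigma_value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "estimates", tuple(self.estimates))
        if len(self.estimates) < 1:
            raise ValueError("ReplicaSet requires at least one estimate")
        methods = {e.method for e in self.estimates}
        if len(methods) > 1:
            raise ValueError(f"estimates mix methods {sorted(methods)}")
        if self.sigma_mode == "fixed" and (
            self.sigma_value is None or self.sigma_value < 0
        ):
            raise ValueError("sigma_mode='fixed' requires sigma_value >= 0")

    @property
    def values(self) -> np.ndarray:
        return np.array([e.value for e in self.estimates])

    @property
    def errors(self) -> np.ndarray:
        return np.array([e.uncertainty for e in self.estimates])


def bandwidth(values: Sequence[float]) -> float:
    """Rule-of-thumb kernel bandwidth σ = std(values)·n^(−1/5).

    Uses the unbiased (n−1) sample standard deviation. Identical values
    give σ = 0, which signals the arithmetic fallback downstream.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise BandwidthError(
            "rule-of-thumb bandwidth needs >= 2 values; "
            "combine a single replica with the arithmetic mean instead"
        )
    return float(np.std(v, ddof=1) * v.size ** (-0.2))


def weights(
    values: Sequence[float],
    sigma: float,
    kernel: Literal["gaussian", "printed"] = "gaussian",
) -> np.ndarray:
    """Replica weights ω_i for bandwidth σ (unnormalized).

    σ = 0 or σ = ∞ gives exact equal weights. ``kernel="printed"`` is an
    expert option using the linear, unsquared exponent
    exp((ΔG_i−ΔG_j)/(2σ²)) for comparison; the Gaussian kernel is the
    default because only it downweights distant replicas symmetrically.
    """
    v = np.asarray(values, dtype=float)
    if sigma == 0 or math.isinf(sigma):
        return np.ones(v.size)
    d = v[:, None] - v[None, :]
    if kernel == "gaussian":
        return np.exp(-(d ** 2) / (2.0 * sigma ** 2)).sum(axis=1)
    return np.exp(d / (2.0 * sigma ** 2)).sum(axis=1)


def combine(
    replicas: ReplicaSet,
    kernel: Literal["gaussian", "printed"] = "gaussian",
) -> FreeEnergyEstimate:
    """Combine replicate estimates into one per-environment ΔG.

    Returns a FreeEnergyEstimate whose sample counts are summed over
    replicas. A single replica is returned as-is.
    """
    ests = replicas.estimates
    n = len(ests)
    nf = sum(e.n_forward for e in ests)
    nr = sum(e.n_reverse for e in ests)
    method = ests[0].method
    v = replicas.values
    errs = replicas.errors

    if n == 1:
        e = ests[0]
        return FreeEnergyEstimate(e.value, e.uncertainty, method, nf, nr)

    if replicas.sigma_mode == "infinite":
        sigma = SIGMA_INFINITE
    elif replicas.sigma_mode == "fixed":
        sigma = float(replicas.sigma_value)  # type: ignore[arg-type]
    else:
        sigma = bandwidth(v)

    w = weights(v, sigma, kernel=kernel)
    wn = w / w.sum()
    value = float(wn @ v)
    weighted_var = float(wn @ (v - value) ** 2)
    sem2 = weighted_var / n
    err = float(np.sqrt(sem2 + np.mean(errs ** 2) / n))
    return FreeEnergyEstimate(value, err, method, nf, nr)
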