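"""Ligand affinity networks: absolute ΔG by maximum likelihood and
comparison statistics.

Relative edges (ΔΔG between ligand pairs) determine absolute ΔG values
only up to one additive constant per connected component (the gauge
freedom). The maximum-likelihood estimate minimizes

    Σ_edges (ΔG_to − ΔG_from − ΔΔG_edge)² / err²

via the weighted graph-Laplacian normal equations; each component is
then anchored so its mean predicted ΔG equals the mean experimental ΔG
of its nodes (components without experimental data stay mean-zero).
Node uncertainties come from the diagonal of the Laplacian
pseudo-inverse.

Experimental inhibition constants convert to free energies as
ΔG = −RT ln(K_i) at 298.15 K — note this printed convention yields
positive ΔG for sub-molar K_i; the conventional binding free energy
+RT ln(K_i) is available via ``convention="binding"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, kT as _kT

logger = logging.getLogger(__name__)

DEFAULT_ZERO_BAND = 0.4  # kcal/mol: experimental |ΔΔG| below this is "essentially 0"


@dataclass(frozen=True)
class Edge:
    """A directed relative free-energy edge (kcal/mol)."""

    ligand_from: str
    ligand_to: str
    ddG: float
    err: float = 0.0

    def __post_init__(self) -> None:
        if self.err < 0:
            raise ValueError("edge error must be >= 0")


@dataclass(frozen=True)
class AffinityNetwork:
    """Ligand nodes, ΔΔG edges, and optional experimental ΔG anchors."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    experimental: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "experimental", dict(self.experimental))
        node_set = set(self.nodes)
        for e in self.edges:
            if e.ligand_from not in node_set or e.ligand_to not in node_set:
                raise ValueError(f"edge {e.ligand_from}->{e.ligand_to} has unknown endpoint")

    @classmethod
    def from_edges(
        cls,
        edges: Sequence[Edge | tuple],
        experimental: Mapping[str, float] | None = None,
    ) -> "AffinityNetwork":
        es = tuple(e if isinstance(e, Edge) else Edge(*e) for e in edges)
        nodes: list[str] = []
        for e in es:
            for n in (e.ligand_from, e.ligand_to):
                if n not in nodes:
                    nodes.append(n)
        return cls(tuple(nodes), es, experimental or {})

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.ligand_from, e.ligand_to) for e in self.edges)
        return g


@dataclass(frozen=True)
class NodeEstimates:
    """Absolute ΔG per ligand with uncertainty and component id."""

    values: Mapping[str, float]
    errors: Mapping[str, float]
    component: Mapping[str, int]


def ki_to_dG(
    Ki: float,
    temperature: float = DEFAULT_TEMPERATURE,
    convention: Literal["printed", "binding"] = "printed",
) -> float:
    """Convert an inhibition constant K_i (molar) to ΔG (kcal/mol).

    ``convention="printed"`` returns −RT ln(K_i); ``"binding"`` returns
    the conventional +RT ln(K_i). Pairwise ΔΔG magnitudes are identical
    under either convention.
    """
    if Ki <= 0:
        raise ValueError(f"K_i must be positive, got {Ki}")
    rt = _kT(temperature)
    dg = -rt * math.log(Ki)
    return dg if convention == "printed" else -dg


def mle_absolute(network: AffinityNetwork) -> NodeEstimates:
    """Weighted least-squares absolute ΔG from relative edges.

    Zero edge errors are replaced by the smallest positive error present
    (logged); if every error is zero, unit weights are used.
    """
    if not network.edges:
        raise ValueError("network has no edges")
    errs = np.array([e.err for e in network.edges], dtype=float)
    pos = errs[errs > 0]
    if pos.size and np.any(errs == 0):
        logger.warning(
            "replacing %d zero edge error(s) with minimum positive err %.4g",
            int((errs == 0).sum()), pos.min(),
        )
        errs = np.where(errs == 0, pos.min(), errs)
    elif not pos.size:
        errs = np.ones_like(errs)

    index = {n: i for i, n in enumerate(network.nodes)}
    values: dict[str, float] = {}
    errors: dict[str, float] = {}
    component: dict[str, int] = {}

    for cid, comp in enumerate(nx.connected_components(network.graph())):
        comp_nodes = sorted(comp, key=index.__getitem__)
        local = {n: i for i, n in enumerate(comp_nodes)}
        m = len(comp_nodes)
        L = np.zeros((m, m))
        b = np.zeros(m)
        n_comp_edges = 0
        for e, err in zip(network.edges, errs):
            if e.ligand_from not in local:
                continue
            i, j = local[e.ligand_from], local[e.ligand_to]
            w = 1.0 / err ** 2
            L[i, i] += w
            L[j, j] += w
            L[i, j] -= w
            L[j, i] -= w
            b[i] -= w * e.ddG
            b[j] += w * e.ddG
            n_comp_edges += 1
        if m > 1 and n_comp_edges == 0:
            raise ValueError(f"component {cid} is disconnected from all edges")
        Lp = np.linalg.pinv(L, rcond=1e-10)
        x = Lp @ b
        x -= x.mean()  # mean-zero gauge before anchoring
        var = np.clip(np.diag(Lp), 0.0, None)

        anchors = [network.experimental[n] for n in comp_nodes
                   if n in network.experimental]
        if anchors:
            pred_at_anchors = [x[local[n]] for n in comp_nodes
                               if n in network.experimental]
            x += float(np.mean(anchors)) - float(np.mean(pred_at_anchors))

        for n in comp_nodes:
            values[n] = float(x[local[n]])
            errors[n] = float(np.sqrt(var[local[n]]))
            component[n] = cid

    return NodeEstimates(values=values, errors=errors, component=component)


def compare_stats(
    predicted: Sequence[float],
    reference: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 2024,
) -> dict:
    """Agreement statistics between paired predicted and reference values.

    Returns RMSD, MUE (kcal/mol), squared Pearson correlation r², and
    Kendall τ (tau-b) with its two-sided p-value, plus seeded bootstrap
    95% confidence intervals over pairs for RMSD/MUE/r²/τ. Requires at
    least three pairs.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.size != r.size:
        raise ValueError(f"length mismatch: {p.size} predicted vs {r.size} reference")
    if p.size < 3:
        raise ValueError("need >= 3 pairs for correlation statistics")

    def point(pp: np.ndarray, rr: np.ndarray) -> tuple[float, float, float, float]:
        diff = pp - rr
        rmsd = float(np.sqrt(np.mean(diff ** 2)))
        mue = float(np.mean(np.abs(diff)))
        if np.std(pp) == 0 or np.std(rr) == 0:
            r2 = np.nan
            tau = np.nan
        else:
            r2 = float(stats.pearsonr(pp, rr).statistic ** 2)
            tau = float(stats.kendalltau(pp, rr).statistic)
        return rmsd, mue, r2, tau

    rmsd, mue, r2, tau = point(p, r)
    tau_res = stats.kendalltau(p, r)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, 4))
    for k in range(n_bootstrap):
        idx = rng.integers(0, p.size, p.size)
        boots[k] = point(p[idx], r[idx])
    ci = {}
    for name, col in zip(("rmsd", "mue", "r2", "tau"), boots.T):
        finite = col[np.isfinite(col)]
        if finite.size:
            lo, hi = np.percentile(finite, [2.5, 97.5])
            ci[name] = (float(lo), float(hi))
        else:
            ci[name] = (np.nan, np.nan)

    return {
        "rmsd": rmsd,
        "mue": mue,
        "r2": r2,
        "tau": float(tau_res.statistic),
        "tau_pvalue": float(tau_res.pvalue),
        "n": int(p.size),
        "ci95": ci,
    }


def sign_concordance(
    edges: Sequence[tuple[float, float]],
    zero_band: float = DEFAULT_ZERO_BAND,
) -> float:
    """Fraction of edges whose predicted ΔΔG direction matches experiment.

    Each pair is (ddG_pred, ddG_exp). An edge is concordant when the two
    share a sign, or when |ddG_exp| <= zero_band (an experimentally null
    edge cannot be called wrong). Returns the concordant fraction.
    """
    pairs = list(edges)
    if not pairs:
        raise ValueError("sign_concordance requires at least one edge")
    ok = 0
    for pred, exp in pairs:
        if abs(exp) <= zero_band or np.sign(pred) == np.sign(exp):
            ok += 1
    return ok / len(pairs)
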