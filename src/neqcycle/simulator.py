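"""Crooks-consistent synthetic work generator and study-directory writer.

Forward and reverse work distributions of a real alchemical switch are
linked by the Crooks fluctuation theorem P_f(W)/P_r(−W) = exp(β(W−ΔG)).
The Gaussian family satisfying it exactly has

    W_f ~ N(ΔG + W_d, 2 kT W_d)        (forward, 0→1 frame)
    W_r ~ N(−ΔG + W_d, 2 kT W_d)       (reverse, 1→0 frame)

where W_d ≥ 0 is the dissipated work. Any equal-weight mixture of such
components sharing one ΔG is also exactly Crooks-consistent, which
supplies a non-Gaussian stress test. Planting a known ΔG this way gives
every estimator a ground truth without running any molecular dynamics.

The module also writes synthetic dH/dλ trace files whose trapezoidal
integral equals a prescribed work, and synthetic ligand networks with
known node free energies, so the full pipeline — parse → integrate →
BAR → replica combine → cycle decomposition → network MLE — is testable
end-to-end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT as _kT
from .estimators import WorkSet
from .network import AffinityNetwork, Edge
from .work_io import WorkValue


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic transition ensemble.

    dG_true and dissipation in kcal/mol; defaults mirror the benchmark
    protocol of 50 transitions per direction at 298.15 K.
    """

    dG_true: float
    dissipation: float = 1.0
    n_forward: int = 50
    n_reverse: int = 50
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 2024
    shape: Literal["gaussian", "mixture"] = "gaussian"

    def __post_init__(self) -> None:
        if self.dissipation < 0:
            raise ValueError("dissipation must be >= 0")
        if self.n_forward < 1 or self.n_reverse < 1:
            raise ValueError("transition counts must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.shape not in ("gaussian", "mixture"):
            raise ValueError(f"unknown shape {self.shape!r}")


def sample_works(spec: SimSpec) -> WorkSet:
    """Draw a Crooks-consistent WorkSet for the given spec.

    gaussian: single component with σ² = 2 kT W_d. mixture: equal-weight
    two-component mixture with dissipations W_d and 2 W_d (same ΔG in
    both components, hence still exactly Crooks-consistent). Zero
    dissipation collapses both distributions to the deterministic limit
    W_f = ΔG, W_r = −ΔG.
    """
    rng = np.random.default_rng(spec.seed)
    kT = _kT(spec.temperature)

    def draw(n: int, sign: float) -> np.ndarray:
        # sign=+1 forward frame, -1 reverse frame; mean = sign*dG + W_d
        if spec.shape == "gaussian":
            wds = np.full(n, spec.dissipation)
        else:
            comp = rng.integers(0, 2, size=n)
            wds = np.where(comp == 0, spec.dissipation, 2.0 * spec.dissipation)
        sigma = np.sqrt(2.0 * kT * wds)
        return sign * spec.dG_true + wds + sigma * rng.standard_normal(n)

    forward = draw(spec.n_forward, +1.0)
    reverse = draw(spec.n_reverse, -1.0)
    return WorkSet(forward=forward, reverse=reverse, temperature=spec.temperature)


def write_synthetic_dhdl(
    work: WorkValue,
    path: str | os.PathLike,
    n_points: int = 51,
    profile: Literal["constant", "bump"] = "constant",
    units: Literal["kJ/mol", "kcal/mol"] = "kJ/mol",
    x_kind: Literal["time", "lambda"] = "time",
    duration_ps: float = 100.0,
) -> Path:
    """Write an xvg-dialect trace whose trapezoidal integral is ``work``.

    constant: flat integrand at the target work. bump: a smooth raised-
    cosine integrand rescaled so the trapezoidal integral hits the
    target exactly (to 1e-9). Time traces span ``duration_ps`` (the
    default matches 100 ps switches).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    lam = np.linspace(0.0, 1.0, n_points)
    target = work.value * (4.184 if units == "kJ/mol" else 1.0)
    if profile == "constant":
        y = np.full(n_points, target)
    else:
        base = 1.0 - np.cos(2.0 * np.pi * lam)  # zero at endpoints, integral ~1
        base_int = np.trapezoid(base, lam)
        if target == 0.0:
            y = np.zeros(n_points)
        else:
            y = base * (target / base_int)
    x = lam * duration_ps if x_kind == "time" else lam
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write('@    title "Synthetic dH/dλ trace"\n')
        fh.write(f'@    subtitle "direction={work.direction} units={units}"\n')
        fh.write(f'# x_kind={x_kind} profile={profile}\n')
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.10g} {yi:.12g}\n")
    return path


def sample_network(
    n_ligands: int,
    topology: Literal["star", "random_tree", "cyclic"] = "star",
    true_dGs: Sequence[float] | None = None,
    edge_noise_sd: float = 0.3,
    seed: int = 2024,
) -> tuple[AffinityNetwork, dict[str, float]]:
    """Synthetic ligand network with known node free energies.

    Edges carry ddG = ΔG_true(to) − ΔG_true(from) + N(0, edge_noise_sd)
    and err = edge_noise_sd (or a small floor when noiseless). Returns
    (network, ground truth map). star: every ligand attached to ligand
    L0; random_tree: uniform spanning-tree attachment; cyclic: a ring.
    """
    if n_ligands < 2:
        raise ValueError("need at least 2 ligands")
    rng = np.random.default_rng(seed)
    names = [f"L{i}" for i in range(n_ligands)]
    if true_dGs is None:
        truth = dict(zip(names, rng.normal(-7.0, 2.0, n_ligands)))
    else:
        if len(true_dGs) != n_ligands:
            raise ValueError("true_dGs length must equal n_ligands")
        truth = dict(zip(names, map(float, true_dGs)))

    if topology == "star":
        pairs = [(names[0], names[i]) for i in range(1, n_ligands)]
    elif topology == "random_tree":
        pairs = [(names[int(rng.integers(0, i))], names[i])
                 for i in range(1, n_ligands)]
    elif topology == "cyclic":
        pairs = [(names[i], names[(i + 1) % n_ligands]) for i in range(n_ligands)]
    else:
        raise ValueError(f"unknown topology {topology!r}")

    err = edge_noise_sd if edge_noise_sd > 0 else 1e-6
    edges = [
        Edge(a, b, truth[b] - truth[a] + rng.normal(0.0, edge_noise_sd), err)
        for a, b in pairs
    ]
    return AffinityNetwork.from_edges(edges), truth


ENVIRONMENTS = ("water", "membrane", "protein")


def write_study(
    out_dir: str | os.PathLike,
    dG_by_env: Mapping[str, float],
    dissipation: float = 1.0,
    n_transitions: int = 50,
    n_replicas: int = 3,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 2024,
    edge: str = "lig0->lig1",
    n_points: int = 51,
) -> Path:
    """Emit a full synthetic study directory plus a truth JSON.

    Layout: {edge}/{environment}/replica_{k}/{forward|reverse}/t{j}.xvg,
    one trace per transition, each integrating to a Crooks-consistent
    work draw for that environment's planted ΔG. The study truth
    (planted ΔG per environment and derived ΔΔG triple) is written to
    truth.json at the study root.
    """
    out = Path(out_dir)
    lig_from, lig_to = edge.split("->") if "->" in edge else ("lig0", "lig1")
    edge_name = f"{lig_from}__{lig_to}"
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.spawn(len(dG_by_env) * n_replicas))
    for env in dG_by_env:
        if env not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {env!r}")
    for env, dg in dG_by_env.items():
        for k in range(n_replicas):
            sub_seed = int(next(child_seeds).generate_state(1)[0] % (2 ** 31))
            ws = sample_works(SimSpec(
                dG_true=dg, dissipation=dissipation,
                n_forward=n_transitions, n_reverse=n_transitions,
                temperature=temperature, seed=sub_seed,
            ))
            for direction, works in (("forward", ws.forward), ("reverse", ws.reverse)):
                d = out / edge_name / env / f"replica_{k}" / direction
                for j, w in enumerate(works):
                    write_synthetic_dhdl(
                        WorkValue(float(w), direction, f"t{j}"),
                        d / f"t{j}.xvg", n_points=n_points,
                        profile="bump" if j % 2 else "constant",
                    )
    truth = {
        "edge": f"{lig_from}->{lig_to}",
        "temperature": temperature,
        "dG_by_env": dict(dG_by_env),
        "ddG_obs": dG_by_env["protein"] - dG_by_env["water"],
        "ddG_int": dG_by_env["protein"] - dG_by_env["membrane"],
        "ddG_mem": dG_by_env["membrane"] - dG_by_env["water"],
        "dissipation": dissipation,
        "n_transitions": n_transitions,
        "n_replicas": n_replicas,
        "seed": seed,
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out
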