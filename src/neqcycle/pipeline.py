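"""End-to-end analysis pipeline over a study directory.

A study directory holds one subdirectory per alchemical edge, each with
the three environment legs and their replica transition traces:

    {edge}/{water|membrane|protein}/replica_{k}/{forward|reverse}/*.xvg

``run_pipeline`` parses and integrates every trace, estimates ΔG per
(edge, environment, replica) with BAR (Jarzynski and the Gaussian
approximation are stored alongside for diagnostics), combines replicas
with the Gaussian-weighted average, closes the thermodynamic cycles,
and writes an edge-decomposition CSV plus a machine-readable summary
JSON. All stochastic steps are seeded, so re-running with the same
inputs and config reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import work_io
from .constants import DEFAULT_TEMPERATURE
from .cycles import decompose
from .estimators import WorkSet, estimate_all
from .replicas import ReplicaSet, combine

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
ENVIRONMENTS = ("water", "membrane", "protein")

_LAYOUT_HELP = (
    "expected layout: {edge}/{water|membrane|protein}/replica_{k}/"
    "{forward|reverse}/*.xvg"
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide configuration, echoed into every output."""

    temperature: float = DEFAULT_TEMPERATURE
    units: str = "kJ/mol"
    bootstrap_n: int = 1000
    seed: int = 2024
    sigma_mode: str = "rule_of_thumb"
    zero_band: float = 0.4
    estimator: str = "bar"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat JSON config file; missing keys take defaults."""
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def collect_works(study_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    """Parse and integrate every trace under a study directory.

    Returns the per-transition work table (one row per trace) with
    columns (source_id, edge, environment, replica, direction,
    work_kcal_mol).
    """
    root = Path(study_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"{root}: not a directory; {_LAYOUT_HELP}")
    rows = []
    edge_dirs = sorted(d for d in root.iterdir()
                       if d.is_dir() and any(d.glob("*/replica_*")))
    if not edge_dirs:
        raise FileNotFoundError(f"{root}: no edge directories found; {_LAYOUT_HELP}")
    for edge_dir in edge_dirs:
        env_dirs = {d.name for d in edge_dir.iterdir() if d.is_dir()}
        missing = set(ENVIRONMENTS) - env_dirs
        if missing:
            raise FileNotFoundError(
                f"{edge_dir}: missing environment directorie(s) "
                f"{sorted(missing)}; {_LAYOUT_HELP}"
            )
        for env in ENVIRONMENTS:
            for rep_dir in sorted((edge_dir / env).glob("replica_*")):
                for direction in ("forward", "reverse"):
                    ddir = rep_dir / direction
                    if not ddir.is_dir():
                        logger.warning("%s: no %s traces; proceeding", rep_dir, direction)
                        continue
                    for xvg in sorted(ddir.glob("*.xvg")):
                        trace = work_io.parse_dhdl(
                            xvg, units=config.units, x_kind="time",
                            direction=direction,
                        )
                        w = work_io.integrate_work(trace)
                        rows.append({
                            "source_id": str(xvg),
                            "edge": edge_dir.name.replace("__", "->"),
                            "environment": env,
                            "replica": rep_dir.name,
                            "direction": direction,
                            "work_kcal_mol": w.value,
                        })
    return pd.DataFrame(rows)


def estimate_works(works: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-(edge, environment, replica) free-energy estimates.

    Returns a table with one row per estimator method per replica.
    """
    rows = []
    for (edge, env, rep), grp in works.groupby(["edge", "environment", "replica"]):
        wf = grp.loc[grp.direction == "forward", "work_kcal_mol"].to_numpy()
        wr = grp.loc[grp.direction == "reverse", "work_kcal_mol"].to_numpy()
        ws = WorkSet(wf, wr, temperature=config.temperature)
        for method, est in estimate_all(
            ws, n_bootstrap=config.bootstrap_n, seed=config.seed
        ).items():
            rows.append({
                "edge": edge, "environment": env, "replica": rep,
                "method": method, "dG": est.value, "err": est.uncertainty,
                "n_forward": est.n_forward, "n_reverse": est.n_reverse,
            })
    return pd.DataFrame(rows)


def combine_replicas(estimates: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Combine per-replica estimates (headline estimator only) per environment."""
    from .estimators import FreeEnergyEstimate

    sel = estimates[estimates.method == config.estimator]
    rows = []
    for (edge, env), grp in sel.groupby(["edge", "environment"]):
        ests = [
            FreeEnergyEstimate(r.dG, r.err, config.estimator,
                               int(r.n_forward), int(r.n_reverse))
            for r in grp.itertuples()
        ]
        rs = ReplicaSet(environment=env, estimates=tuple(ests),
                        sigma_mode=config.sigma_mode)
        c = combine(rs)
        rows.append({
            "edge": edge, "environment": env, "dG": c.value, "err": c.uncertainty,
            "n_replicas": len(ests), "method": config.estimator,
        })
    return pd.DataFrame(rows)


def decompose_edges(combined: pd.DataFrame) -> pd.DataFrame:
    """Cycle decomposition per edge from the combined environment table."""
    from .estimators import FreeEnergyEstimate

    rows = []
    for edge, grp in combined.groupby("edge"):
        by_env = {r.environment: FreeEnergyEstimate(r.dG, r.err, "bar")
                  for r in grp.itertuples()}
        lf, _, lt = edge.partition("->")
        dec = decompose(by_env.get("water"), by_env.get("membrane"),
                        by_env.get("protein"), ligand_from=lf or "0",
                        ligand_to=lt or "1")
        rows.append({
            "edge": edge,
            "ddG_obs": dec.ddG_obs, "err_obs": dec.err_obs,
            "ddG_int": dec.ddG_int, "err_int": dec.err_int,
            "ddG_mem": dec.ddG_mem, "err_mem": dec.err_mem,
        })
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    study_dir: str | Path,
    out_dir: str | Path | None = None,
) -> dict:
    """Full analysis: parse → estimate → combine → cycle.

    Writes works.csv, estimates.csv, combined.csv, edges.csv and
    summary.json to ``out_dir`` (default: ``study_dir``/analysis) and
    returns the summary dict.
    """
    study_dir = Path(study_dir)
    out = Path(out_dir) if out_dir is not None else study_dir / "analysis"
    out.mkdir(parents=True, exist_ok=True)

    works = collect_works(study_dir, config)
    estimates = estimate_works(works, config)
    combined = combine_replicas(estimates, config)
    edges = decompose_edges(combined)

    works.to_csv(out / "works.csv", index=False)
    estimates.to_csv(out / "estimates.csv", index=False)
    combined.to_csv(out / "combined.csv", index=False)
    edges.to_csv(out / "edges.csv", index=False)

    summary = {
        "schema_version": SCHEMA_VERSION,
        "config": config.as_dict(),
        "n_traces": int(len(works)),
        "edges": edges.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
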