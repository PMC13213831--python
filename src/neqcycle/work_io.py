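"""Parsing of per-transition dH/dλ traces and their integration into work.

Each fast alchemical transition produces one trace of the derivative of
the Hamiltonian with respect to the coupling parameter λ, sampled either
directly on λ or on simulation time. The work of the transition is the
trapezoidal integral W = ∫₀¹ (∂H/∂λ) dλ; for time-indexed traces, time
is mapped linearly onto λ ∈ [0, 1] between the first and last sample
(the transitions are fixed-length switches). Reverse (1→0) traces are
written in their own transformation frame — their progress variable
also runs 0→1 — so the integral is the work of the reverse switch.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import KJ_PER_KCAL

logger = logging.getLogger(__name__)

Direction = Literal["forward", "reverse"]
XKind = Literal["time", "lambda"]
Units = Literal["kJ/mol", "kcal/mol"]


class DhdlParseError(ValueError):
    """Malformed trace file (bad numeric line, reported with line number)."""


class InsufficientDataError(ValueError):
    """Trace has fewer than two data rows."""


@dataclass(frozen=True)
class DhdlTrace:
    """One transition's dH/dλ series.

    Parameters
    ----------
    x : ndarray
        Strictly increasing abscissa: time in ps or λ (dimensionless).
    dhdl : ndarray
        dH/dλ values, in ``units`` per unit λ.
    x_kind : {"time", "lambda"}
    direction : {"forward", "reverse"}
        Forward is the 0→1 switch; reverse traces are expressed in the
        1→0 frame with their own 0→1 progress variable.
    units : {"kJ/mol", "kcal/mol"}
        Units of ``dhdl``. Conversion to kcal/mol happens only at
        integration time, never silently on parse.
    source_id : str
        Identifier for provenance (usually the file path).
    """

    x: np.ndarray
    dhdl: np.ndarray
    x_kind: XKind
    direction: Direction
    units: Units = "kJ/mol"
    source_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        dhdl = np.asarray(self.dhdl, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "dhdl", dhdl)
        if x.ndim != 1 or dhdl.ndim != 1 or len(x) != len(dhdl):
            raise ValueError("x and dhdl must be 1-D sequences of equal length")
        if len(x) < 2:
            raise InsufficientDataError(
                f"trace {self.source_id!r} has {len(x)} data rows; need >= 2"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(dhdl))):
            raise ValueError(f"trace {self.source_id!r} contains non-finite values")
        if np.any(np.diff(x) <= 0):
            raise ValueError(f"trace {self.source_id!r}: x must be strictly increasing")


@dataclass(frozen=True)
class WorkValue:
    """A scalar transition work in kcal/mol, tagged with its direction."""

    value: float
    direction: Direction
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"work value must be finite, got {self.value}")


def parse_dhdl(
    path: str | os.PathLike,
    units: Units = "kJ/mol",
    x_kind: XKind = "time",
    direction: Direction = "forward",
) -> DhdlTrace:
    """Parse an xvg-dialect dH/dλ trace file.

    Lines starting with ``#`` or ``@`` are metadata and skipped. Data
    lines must carry at least two whitespace-separated numeric columns:
    column 1 is the abscissa (time or λ), column 2 is dH/dλ. Extra
    columns are ignored (with a logged warning on first occurrence).

    Raises
    ------
    DhdlParseError
        If a data line is not numeric (the message names the line number).
    InsufficientDataError
        If fewer than two data rows are present.
    """
    xs: list[float] = []
    ys: list[float] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "@")):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise DhdlParseError(
                    f"{path}: line {lineno}: expected >= 2 columns, got {len(fields)}"
                )
            if len(fields) > 2 and not warned_extra:
                logger.warning(
                    "%s: line %d has %d columns; using column 2 as dH/dλ",
                    path, lineno, len(fields),
                )
                warned_extra = True
            try:
                xs.append(float(fields[0]))
                ys.append(float(fields[1]))
            except ValueError as exc:
                raise DhdlParseError(
                    f"{path}: line {lineno}: non-numeric field: {exc}"
                ) from None
    if len(xs) < 2:
        raise InsufficientDataError(
            f"{path}: found {len(xs)} data rows; need >= 2"
        )
    return DhdlTrace(
        x=np.array(xs), dhdl=np.array(ys), x_kind=x_kind,
        direction=direction, units=units, source_id=str(path),
    )


def integrate_work(trace: DhdlTrace) -> WorkValue:
    """Trapezoidal work of one transition, in kcal/mol.

    Time abscissae are mapped linearly onto λ ∈ [0, 1] between the first
    and last sample; λ abscissae are used directly. kJ/mol integrands
    are divided by 4.184 here.
    """
    x = trace.x
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError(f"trace {trace.source_id!r}: zero-length λ span")
    if trace.x_kind == "time":
        lam = (x - x[0]) / span
    else:
        lam = x
    w = float(np.trapezoid(trace.dhdl, lam))
    if trace.units == "kJ/mol":
        w /= KJ_PER_KCAL
    return WorkValue(value=w, direction=trace.direction, source_id=trace.source_id)


WORK_TABLE_COLUMNS = ["source_id", "environment", "replica", "direction", "work_kcal_mol"]


def write_work_table(rows: Sequence[dict], path: str | os.PathLike) -> pd.DataFrame:
    """Write a per-transition work table as CSV.

    Each row dict needs keys source_id, environment, replica, direction,
    work_kcal_mol. Returns the DataFrame written.
    """
    df = pd.DataFrame(list(rows), columns=WORK_TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_work_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a work CSV produced by :func:`write_work_table`."""
    df = pd.read_csv(path)
    missing = set(WORK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: work table missing columns {sorted(missing)}")
    return df
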