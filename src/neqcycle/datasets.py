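"""Bundled benchmark data.

The P2Y1 receptor / BPTU-analogue benchmark: twelve alchemical edges in
two star maps (one centred on ligand 11a, one on 6a), each with an
experimental relative binding free energy (from radioligand K_i data),
a published equilibrium-FEP literature value (``ddG_obs_D``, the sum of
its interaction and membrane components from a single edge), and the
nonequilibrium-pipeline values for ΔΔG_obs and its ΔΔG_int / ΔΔG_mem
decomposition. All values in kcal/mol, transcribed at printed precision.
"""

from __future__ import annotations

import pandas as pd

# (from, to, ddG_exp, err_exp, ddG_obs_D, err_obs_D,
#  ddG_obs, err_obs, ddG_int, err_int, ddG_mem, err_mem)
_BENCHMARK_ROWS = [
    ("11a", "11b", -2.8, 0.5, -6.0, 0.5, -5.6, 0.2, -3.0, 0.5, -2.6, 0.4),
    ("11a", "11f", -1.5, 0.5, -1.4, 0.8, -2.27, 0.16, -0.5, 0.3, -1.8, 0.3),
    ("11a", "11c", -2.4, 0.6, -2.4, 0.9, -3.1, 0.4, -0.8, 0.5, -2.3, 0.3),
    ("11a", "1", -2.0, 0.4, -1.8, 0.8, -1.85, 0.16, 0.6, 0.2, -2.46, 0.16),
    ("6a", "6i", -1.0, 0.4, -2.7, 0.2, -2.6, 0.2, 1.0, 0.3, -3.6, 0.2),
    ("6a", "6f", -0.1, 0.5, -1.5, 0.1, 0.76, 0.08, -0.4, 0.3, 1.2, 0.3),
    ("6a", "6h", -0.8, 0.7, -0.8, 0.3, -0.67, 0.12, 1.06, 0.19, -1.73, 0.17),
    ("6a", "6m", 0.6, 0.5, -0.7, 0.9, 2.7, 0.2, 2.7, 0.3, 0.0, 0.2),
    ("6a", "6g", -0.5, 0.6, -1.6, 0.3, -3.4, 0.4, -3.1, 0.6, -0.3, 0.5),
    ("6a", "6L", -1.2, 0.7, -0.0, 0.4, 1.18, 0.19, 0.9, 0.2, 0.3, 0.2),
    ("6a", "6j", 0.4, 0.7, -3.1, 0.3, -0.1, 0.3, 1.0, 0.3, -1.0, 0.2),
    ("6a", "6n", 0.7, 0.5, -0.3, 0.5, 2.46, 0.15, 0.34, 0.19, 2.13, 0.14),
]

_COLUMNS = [
    "ligand_from", "ligand_to",
    "ddG_exp", "err_exp",
    "ddG_obs_D", "err_obs_D",
    "ddG_obs", "err_obs",
    "ddG_int", "err_int",
    "ddG_mem", "err_mem",
]


def p2y1_bptu_benchmark() -> pd.DataFrame:
    """The twelve-edge P2Y1–BPTU benchmark table as a DataFrame.

    Columns: ligand_from, ligand_to, then (value, error) pairs for the
    experimental ΔΔG (``ddG_exp``), the equilibrium-FEP literature value
    (``ddG_obs_D``), and the nonequilibrium results ``ddG_obs``,
    ``ddG_int``, ``ddG_mem``. A ``group`` column marks the star map each
    edge belongs to (its hub ligand, "11a" or "6a").
    """
    df = pd.DataFrame(_BENCHMARK_ROWS, columns=_COLUMNS)
    df["group"] = df["ligand_from"]
    df["edge"] = df["ligand_from"] + "->" + df["ligand_to"]
    return df
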