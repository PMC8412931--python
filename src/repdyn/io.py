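"""Readers and writers for per-trial tabular data.

The canonical per-trial schema is the one the synthetic generator writes:
subject, block, orientation, repetition, trial plus measure columns
(gamma_power, gamma_freq, pupil_constriction, rt_ms, correct, ms_rate,
erf_c1, erf_c2, iti_s). External tables (e.g. a deposited per-trial data
set) are adapted through a column-name mapping.
"""

from __future__ import annotations

import pathlib

import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_pertrial_table", "write_pertrial_table"]

REQUIRED_COLUMNS = ("subject", "block", "orientation", "repetition", "trial")


def read_pertrial_table(path, mapping: dict | None = None) -> pd.DataFrame:
    """Read a per-trial table (TSV or CSV by extension), applying a
    column-name mapping {external_name: canonical_name}.

    Raises a schema error naming any missing required column; unmapped
    columns are preserved untouched.
    """
    path = pathlib.Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if mapping:
        df = df.rename(columns=dict(mapping))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"per-trial table {path} is missing required columns: {missing}")
    return df


def write_pertrial_table(df: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
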