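"""Reading and writing the pipeline's delimited-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import META_COLUMNS, item_columns


def read_response_csv(path, sep: str = ",") -> pd.DataFrame:
    """Read a response table: header ``participant_id,time_point,<item columns>``."""
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    table["participant_id"] = table["participant_id"].astype(str)
    table["time_point"] = table["time_point"].astype(str)
    for col in item_columns(table):
        table[col] = pd.to_numeric(table[col], errors="raise")
    return table


def write_response_csv(table: pd.DataFrame, path, sep: str = ",") -> None:
    out = table.copy()
    for col in item_columns(out):
        vals = out[col]
        if vals.notna().all() and np.allclose(vals, np.round(vals)):
            out[col] = vals.astype(int)
    out.to_csv(path, sep=sep, index=False)


def write_lines(lines, path) -> None:
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
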