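"""Reading and writing the pipeline's tab-delimited tables.

Cohort tables carry two embedded creatinine series per row (history and
follow-up), serialized as ordered ``timestamp:value`` entries joined with
``;`` in a single field. All other tables are plain TSV round-tripped by
pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

SERIES_COLUMNS = ("prior_scr_series", "followup_scr_series")
_TIME_COLUMNS = ("arrival_time", "departure_time")


def _serialize_series(series: List[Tuple[object, float]]) -> str:
    return ";".join(
        f"{pd.Timestamp(ts).isoformat()}:{float(v):g}" for ts, v in series
    )


def _parse_series(text) -> List[Tuple[pd.Timestamp, float]]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    out = []
    for entry in str(text).split(";"):
        ts, val = entry.rsplit(":", 1)
        out.append((pd.Timestamp(ts), float(val)))
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    df = cohort.copy()
    for col in SERIES_COLUMNS:
        if col in df:
            df[col] = df[col].map(_serialize_series)
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"visit_id": str, "patient_id": str})
    for col in SERIES_COLUMNS:
        if col in df:
            df[col] = df[col].map(_parse_series)
    for col in _TIME_COLUMNS:
        if col in df:
            df[col] = pd.to_datetime(df[col])
    if "rrt_within_72h" in df:
        df["rrt_within_72h"] = df["rrt_within_72h"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
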