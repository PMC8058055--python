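"""Reading and writing the package's delimited-text interchange formats.

All tables are TSV with a header row: the cohort table (one subject per
row), subjects x regions feature matrices (subject_id index column), and
the two-column parcel -> ROI membership map.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "read_cohort_table",
    "write_cohort_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_roi_map",
    "write_roi_map",
]

REQUIRED_COHORT_COLUMNS = ("subject_id", "age", "sex")

_SEX_CODES = {
    "m": 1, "male": 1, "1": 1,
    "f": 0, "female": 0, "0": 0,
}


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, normalizing sex coding dialects to 0/1.

    Accepts sex coded as M/F (any case), male/female, or 0/1 (1 = male).
    Raises on missing required columns or duplicate subject ids; warns on
    implausible ages (outside 5-95 years).
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks required columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id values: {sorted(set(dup))}")
    try:
        df["sex"] = [
            _SEX_CODES[str(v).strip().lower()] for v in df["sex"]
        ]
    except KeyError as e:
        raise ValueError(f"unrecognized sex code {e.args[0]!r}") from None
    df["age"] = df["age"].astype(float)
    if ((df["age"] < 5) | (df["age"] > 95)).any():
        warnings.warn("ages outside the plausible 5-95 year range", stacklevel=2)
    return df


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a subjects x regions matrix (TSV, subject_id index column)."""
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    if df.isna().any().any():
        raise ValueError(f"feature matrix {path} contains missing values")
    return df


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


def read_roi_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (parcel_id, roi_name) TSV into roi -> parcels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("parcel_id", "roi_name"):
        if col not in df.columns:
            raise ValueError(f"ROI map {path} lacks column {col!r}")
    out: dict[str, list[str]] = {}
    for parcel, roi in zip(df["parcel_id"], df["roi_name"]):
        out.setdefault(roi, []).append(parcel)
    return out


def write_roi_map(roi_map: dict[str, list[str]], path: str | Path) -> None:
    rows = [
        {"parcel_id": parcel, "roi_name": roi}
        for roi, parcels in roi_map.items()
        for parcel in parcels
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
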