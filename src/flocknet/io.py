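"""CSV interfaces: detection streams, phenotype tables and group matrices.

All files are plain UTF-8 CSV with headers.  Readers validate the schema
and report offending lines; writers are exact inverses of the readers so
round-trips are lossless.

* detections: ``time_s, day, sampling_period, feeder_id, individual_id``
* phenotypes: ``individual_id, sex, age_class, residency, wing_mm,
  tarsus_mm`` (empty cell = unknown)
* groups: long CSV ``group_id, individual_id`` plus a metadata CSV
  ``group_id, feeder_id, day, sampling_period, time_s``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .groups import GroupByIndividualMatrix, matrix_from_truth

__all__ = [
    "SchemaError",
    "read_detections",
    "write_detections",
    "read_phenotypes",
    "write_phenotypes",
    "read_groups",
    "write_groups",
    "unknown_individuals",
]

DETECTION_COLUMNS = ["time_s", "day", "sampling_period", "feeder_id", "individual_id"]
PHENOTYPE_COLUMNS = ["individual_id", "sex", "age_class", "residency", "wing_mm", "tarsus_mm"]
GROUP_META_COLUMNS = ["group_id", "feeder_id", "day", "sampling_period", "time_s"]

_SEX_LEVELS = {"male", "female", "unknown"}
_AGE_LEVELS = {"juvenile", "adult", "unknown"}
_RES_LEVELS = {"immigrant", "local", "unknown"}


class SchemaError(ValueError):
    """A file does not conform to its CSV schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _bad_lines(mask: pd.Series) -> str:
    # +2: header line plus 1-based indexing
    lines = (np.flatnonzero(mask.to_numpy()) + 2).tolist()
    shown = ", ".join(map(str, lines[:10]))
    more = "" if len(lines) <= 10 else f" (+{len(lines) - 10} more)"
    return shown + more


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DETECTION_COLUMNS, path)
    for col in ("time_s",):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            raise SchemaError(f"{path}: non-numeric {col} on line(s) {_bad_lines(bad)}")
        df[col] = vals
    for col in ("day", "sampling_period"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise SchemaError(f"{path}: non-integer {col} on line(s) {_bad_lines(bad)}")
        df[col] = vals.astype(int)
    return df[DETECTION_COLUMNS]


def write_detections(df: pd.DataFrame, path) -> None:
    df[DETECTION_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    dup = df["individual_id"].duplicated(keep=False)
    if dup.any():
        raise SchemaError(f"{path}: duplicate individual_id on line(s) {_bad_lines(dup)}")
    for col, levels in (("sex", _SEX_LEVELS), ("age_class", _AGE_LEVELS), ("residency", _RES_LEVELS)):
        df[col] = df[col].fillna("unknown")
        bad = ~df[col].isin(levels)
        if bad.any():
            raise SchemaError(f"{path}: invalid {col} on line(s) {_bad_lines(bad)}")
    for col in ("wing_mm", "tarsus_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            raise SchemaError(f"{path}: non-numeric {col} on line(s) {_bad_lines(bad)}")
        nonpos = vals.notna() & (vals <= 0)
        if nonpos.any():
            raise SchemaError(f"{path}: non-positive {col} on line(s) {_bad_lines(nonpos)}")
        df[col] = vals
    return df[PHENOTYPE_COLUMNS]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_groups(members_path, meta_path) -> GroupByIndividualMatrix:
    members = pd.read_csv(members_path, dtype={"group_id": str, "individual_id": str})
    _require_columns(members, ["group_id", "individual_id"], members_path)
    meta = pd.read_csv(meta_path, dtype={"group_id": str, "feeder_id": str})
    _require_columns(meta, GROUP_META_COLUMNS, meta_path)
    dup = meta["group_id"].duplicated(keep=False)
    if dup.any():
        raise SchemaError(f"{meta_path}: duplicate group_id on line(s) {_bad_lines(dup)}")
    orphan = ~members["group_id"].isin(set(meta["group_id"]))
    if orphan.any():
        raise SchemaError(
            f"{members_path}: group_id missing from metadata on line(s) {_bad_lines(orphan)}"
        )
    return matrix_from_truth(members, meta)


def write_groups(matrix: GroupByIndividualMatrix, members_path, meta_path) -> None:
    rows = []
    for g in range(matrix.n_groups):
        gid = matrix.meta["group_id"].iloc[g]
        for ind in sorted(matrix.members_of(g)):
            rows.append((gid, ind))
    pd.DataFrame(rows, columns=["group_id", "individual_id"]).to_csv(members_path, index=False)
    matrix.meta[GROUP_META_COLUMNS].to_csv(meta_path, index=False)


def unknown_individuals(detections: pd.DataFrame, phenotypes: pd.DataFrame) -> list[str]:
    """Detected individuals absent from the phenotype table (kept, flagged)."""
    known = set(phenotypes["individual_id"])
    return sorted(set(detections["individual_id"]) - known)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
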