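"""Validated CSV readers and writers for the pipeline's file dialects.

All files use the literal token ``NA`` for missing values (empty cells are
also accepted on read); microRNA ids are canonicalized on read.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .discrimination import validate_cohort
from .panels import normalize_mir_id
from .qpcr import MirCallMatrix, WellRecord
from .topography import TissueProfileSet

__all__ = [
    "read_wells_csv",
    "write_wells_csv",
    "read_reference_tm_csv",
    "write_call_matrix_csv",
    "read_call_matrix_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_delta_ct_csv",
]

NA_TOKEN = "NA"
_NA_VALUES = ["NA", ""]


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, **kw)


def read_wells_csv(path) -> list[WellRecord]:
    """Well export: ``sample_id,mir_id,replicate,ct,tm,is_positive_control``.

    Empty or NA ct/tm fields mean no amplification / no visible melt curve.
    """
    df = _read_csv(path)
    required = {"sample_id", "mir_id", "replicate", "ct", "tm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wells file {path} missing columns: {sorted(missing)}")
    wells = []
    for _, row in df.iterrows():
        wells.append(
            WellRecord(
                sample_id=str(row["sample_id"]),
                mir_id=normalize_mir_id(row["mir_id"]),
                replicate_index=int(row["replicate"]),
                ct=None if pd.isna(row["ct"]) else float(row["ct"]),
                tm=None if pd.isna(row["tm"]) else float(row["tm"]),
                is_positive_control=bool(row.get("is_positive_control", False))
                and not pd.isna(row.get("is_positive_control", False)),
            )
        )
    return wells


def write_wells_csv(wells: Sequence[WellRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": w.sample_id,
                "mir_id": w.mir_id,
                "replicate": w.replicate_index,
                "ct": w.ct,
                "tm": w.tm,
                "is_positive_control": w.is_positive_control,
            }
            for w in wells
        ]
    )
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_reference_tm_csv(path) -> dict[str, float]:
    """Positive-control melt temperatures: ``mir_id,reference_tm``."""
    df = _read_csv(path)
    missing = {"mir_id", "reference_tm"} - set(df.columns)
    if missing:
        raise ValueError(f"reference-Tm file {path} missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        if pd.isna(row["reference_tm"]):
            continue
        out[normalize_mir_id(row["mir_id"])] = float(row["reference_tm"])
    return out


def write_call_matrix_csv(matrix: MirCallMatrix, path) -> None:
    matrix.to_csv(path)


def read_call_matrix_csv(path) -> MirCallMatrix:
    return MirCallMatrix.from_csv(path)


def write_delta_ct_csv(delta: pd.DataFrame, path) -> None:
    out = delta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep=NA_TOKEN)


def write_profiles_csv(pset: TissueProfileSet, path) -> None:
    """Long-format profiles: ``individual_id,tissue,mir_id,call``."""
    pset.to_long_frame().to_csv(path, index=False, na_rep=NA_TOKEN)


def read_profiles_csv(path) -> TissueProfileSet:
    df = _read_csv(path)
    if "mir_id" in df.columns:
        df = df.assign(mir_id=df["mir_id"].map(normalize_mir_id))
    return TissueProfileSet.from_long_frame(df)


def read_cohort_csv(path, panel: Sequence[str] | None = None) -> pd.DataFrame:
    """Cohort sheet with clinical covariates plus 1/0/NA microRNA columns."""
    df = _read_csv(path)
    rename = {
        c: normalize_mir_id(c)
        for c in df.columns
        if normalize_mir_id(c) != c and c not in ("subject_id", "status")
    }
    df = df.rename(columns=rename)
    mir_cols = validate_cohort(df, panel)
    for c in mir_cols:
        df[c] = df[c].astype("Int64")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep=NA_TOKEN)
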