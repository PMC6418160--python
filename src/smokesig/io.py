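"""Plain-text serialization of the pipeline's tables.

Formats: annotation TSV (genes ';'-joined), cohort CSV, summary-statistics
TSV (probe_id, estimate, se, p + extra columns preserved), beta / detection
matrices as TSV with probes as rows and samples as columns, and a raw
intensity container as a directory of TSVs (M, U, oob, neg_M, neg_U) —
a documented stand-in layout, not IDAT.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthdata import RawIntensities

SUMMARY_COLUMNS = ("probe_id", "estimate", "se", "p")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    ann["genes"] = ann["genes"].fillna("")
    ann["cross_reactive"] = ann["cross_reactive"].astype(bool)
    return ann


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary_stats(table: pd.DataFrame, path) -> None:
    """Summary-statistics TSV; requires the canonical columns, keeps extras."""
    for col in SUMMARY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup}")
    # %.17g guarantees exact float round trips through the text format
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str}, float_precision="round_trip")
    for col in SUMMARY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup}")
    return table


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_intensities(raw: RawIntensities, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    raw.M.to_csv(d / "M.tsv", sep="\t", index_label="probe_id")
    raw.U.to_csv(d / "U.tsv", sep="\t", index_label="probe_id")
    raw.oob.to_csv(d / "oob.tsv", sep="\t", index_label="control_id")
    raw.neg_M.to_csv(d / "neg_M.tsv", sep="\t", index_label="control_id")
    raw.neg_U.to_csv(d / "neg_U.tsv", sep="\t", index_label="control_id")


def read_intensities(directory) -> RawIntensities:
    d = Path(directory)
    return RawIntensities(
        M=pd.read_csv(d / "M.tsv", sep="\t", index_col="probe_id"),
        U=pd.read_csv(d / "U.tsv", sep="\t", index_col="probe_id"),
        oob=pd.read_csv(d / "oob.tsv", sep="\t", index_col="control_id"),
        neg_M=pd.read_csv(d / "neg_M.tsv", sep="\t", index_col="control_id"),
        neg_U=pd.read_csv(d / "neg_U.tsv", sep="\t", index_col="control_id"),
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
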