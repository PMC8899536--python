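"""Table readers and writers.

Genomic tables are TSV, assay tables CSV, both UTF-8 with LF newlines
and ``NA`` for missing annotation fields.  Readers validate records and
point at the offending line on malformed input.  Rounding happens only
at the reporting layer; everything written here carries full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .screen import TermWhitelist

__all__ = [
    "read_counts",
    "read_annotations",
    "read_assay",
    "read_curve_table",
    "read_whitelist",
    "write_table",
]

COUNT_COLUMNS = ["gene_id", "count_group1", "count_group2"]
ANNOTATION_COLUMNS = ["gene_id", "kegg_ko", "go_terms"]


class TableFormatError(ValueError):
    """Malformed input table; the message names the file and line."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")


def read_counts(path) -> tuple[pd.DataFrame, tuple[int, int] | None]:
    """Read a gene count TSV: gene_id, count_group1, count_group2.

    Returns the validated table and, second, the library sizes computed
    as column sums (callers may override with externally known totals,
    since reads aligning outside the gene set are invisible here).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    _require_columns(df, COUNT_COLUMNS, path)
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    for col in ("count_group1", "count_group2"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TableFormatError(
                f"{path}, line {line}: {col} must be a non-negative integer, "
                f"got {df[col].iloc[int(bad.idxmax())]!r}"
            )
        df[col] = numeric.astype(int)
    dup = df["gene_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise TableFormatError(
            f"{path}, line {line}: duplicate gene_id {df['gene_id'].iloc[int(dup.idxmax())]!r}"
        )
    if df["gene_id"].str.len().eq(0).any():
        raise TableFormatError(f"{path}: empty gene_id")
    sums = (int(df["count_group1"].sum()), int(df["count_group2"].sum()))
    return df[COUNT_COLUMNS], sums if min(sums) > 0 else None


def read_annotations(path) -> pd.DataFrame:
    """Read an annotation TSV: gene_id, kegg_ko, go_terms[, annotation_label]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    dup = df["gene_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise TableFormatError(f"{path}, line {line}: duplicate gene_id")
    if "annotation_label" not in df.columns:
        df["annotation_label"] = ""
    return df


def read_assay(path) -> pd.DataFrame:
    """Read an assay CSV: sample_id, substrate_acid, ester, initial_acid_mM,
    and response and/or ester_mM (exactly one non-missing per row)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "ester", "initial_acid_mM"], path)
    if "response" not in df.columns and "ester_mM" not in df.columns:
        raise TableFormatError(f"{path}: needs a response or ester_mM column")
    bad = df["initial_acid_mM"] <= 0
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TableFormatError(f"{path}, line {line}: initial_acid_mM must be positive")
    return df


def read_curve_table(path) -> pd.DataFrame:
    """Read a standard-curve CSV: analyte, conc_mM, response."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["analyte", "conc_mM", "response"], path)
    return df


def read_whitelist(path) -> TermWhitelist:
    """Read a whitelist override (JSON or YAML) with keys ``kegg``, ``go``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: whitelist file must be a mapping")
    return TermWhitelist(
        kegg_set=frozenset(data.get("kegg", [])),
        go_set=frozenset(data.get("go", [])),
    )


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a table as UTF-8 TSV/CSV with LF newlines, full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    # frozensets (matched_terms) serialise as semicolon-joined strings
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (set, frozenset))).any():
            out[col] = out[col].map(lambda v: ";".join(sorted(v)))
    out.to_csv(path, sep=sep, index=False, lineterminator="\n", encoding="utf-8")
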