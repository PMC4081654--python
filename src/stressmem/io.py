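"""Readers and writers for every external table the pipeline touches.

Four tabular dialects are supported, all UTF-8, tab-separated, decimal point
only:

* differential-expression tables in the cuffdiff ``gene_exp.diff`` dialect
  (header as emitted by cufflinks 2.x; a minimal column subset is required);
* protein homology hits in BLAST tabular ``outfmt 6`` (12 columns, no header);
* GO annotations as a 4-column TSV (gene_id, go_id, domain, term);
* FPKM expression matrices, wide (``gene_id, W_1, W_2, S1_1, ...``) or long
  (``gene_id, condition, replicate, fpkm``), autodetected by header.

Readers return :class:`pandas.DataFrame` objects with canonical column names
and never silently drop data rows: malformed rows raise, duplicate GO rows are
collapsed with a logged warning.  Infinite fold changes (cuffdiff prints
``inf``/``-inf`` when one condition has zero FPKM) are kept as signed IEEE
infinities because the sign carries the response-direction information.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

# -- canonical schemas -------------------------------------------------------

CONTRASTS = ("S1_vs_W", "S3_vs_S1")
#: (reference condition, test condition) per contrast
CONTRAST_CONDITIONS = {"S1_vs_W": ("W", "S1"), "S3_vs_S1": ("S1", "S3")}
CONDITIONS = ("W", "S1", "S3")

DIFF_COLUMNS = [
    "gene_id", "contrast", "value_a", "value_b",
    "log2_fc", "p_value", "q_value", "status",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GO_DOMAINS = ("cellular_component", "molecular_function", "biological_process")

GO_COLUMNS = ["gene_id", "go_id", "domain", "term"]

_CUFFDIFF_REQUIRED = ["value_1", "value_2", "log2(fold_change)",
                      "p_value", "q_value", "status"]
_CUFFDIFF_GENE_COLUMNS = ("gene_id", "gene", "test_id")


def _check_contrast(contrast: str) -> str:
    if contrast not in CONTRASTS:
        raise ValidationError(
            f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    return contrast


# -- differential-expression tables ------------------------------------------

def read_diff_table(path, contrast: str) -> pd.DataFrame:
    """Read a cuffdiff-style ``gene_exp.diff`` table for one contrast.

    Returns a frame with :data:`DIFF_COLUMNS`.  ``inf``/``-inf`` fold changes
    are mapped to signed infinities; FPKM columns must be non-negative and
    gene ids unique within the table.
    """
    _check_contrast(contrast)
    df = pd.read_csv(path, sep="\t", dtype={"status": str})
    gene_col = next((c for c in _CUFFDIFF_GENE_COLUMNS if c in df.columns), None)
    if gene_col is None:
        raise FormatError(
            f"{path}: no gene id column (need one of {_CUFFDIFF_GENE_COLUMNS})")
    for col in _CUFFDIFF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame({
        "gene_id": df[gene_col].astype(str),
        "contrast": contrast,
        "value_a": pd.to_numeric(df["value_1"]),
        "value_b": pd.to_numeric(df["value_2"]),
        "log2_fc": pd.to_numeric(df["log2(fold_change)"]),
        "p_value": pd.to_numeric(df["p_value"]),
        "q_value": pd.to_numeric(df["q_value"]),
        "status": df["status"].astype(str),
    })
    for col in ("value_a", "value_b"):
        bad = out.index[out[col] < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative FPKM in column {col} at data row {bad[0] + 1}")
    for col, lo, hi in (("p_value", 0, 1), ("q_value", 0, 1)):
        vals = out[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"{path}: {col} outside [0, 1]")
    dup = out["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene_id {out.loc[dup.idxmax(), 'gene_id']!r}")
    return out


def write_diff_table(df: pd.DataFrame, path) -> None:
    """Write a canonical diff frame back to the cuffdiff dialect.

    Infinities render as ``inf``/``-inf``, matching what cuffdiff prints for
    zero-denominator fold changes; :func:`read_diff_table` round-trips them.
    """
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "value_1": df["value_a"],
        "value_2": df["value_b"],
        "log2(fold_change)": df["log2_fc"],
        "p_value": df["p_value"],
        "q_value": df["q_value"],
        "status": df["status"],
    })
    out.to_csv(path, sep="\t", index=False)


# -- BLAST outfmt 6 ----------------------------------------------------------

def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column BLAST ``outfmt 6`` hit table (no header).

    Column 3 is the percent identity, column 4 the alignment length and
    column 11 the e-value; the remaining columns are retained opaquely.
    A line with the wrong column count raises :class:`FormatError` naming it.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(fields)}")
            rows.append(fields)
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=BLAST6_COLUMNS)
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend",
                "sstart", "send"):
        df[col] = df[col].astype(float).astype(int)
    if (df["evalue"] < 0).any():
        raise ValidationError(f"{path}: negative e-value")
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise ValidationError(f"{path}: percent identity outside [0, 100]")
    if (df["length"] < 1).any():
        raise ValidationError(f"{path}: alignment length < 1")
    return df


def write_blast_tab(df: pd.DataFrame, path) -> None:
    df[BLAST6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


# -- GO annotations ----------------------------------------------------------

_DOMAIN_ALIASES = {
    "cellular component": "cellular_component",
    "molecular function": "molecular_function",
    "biological process": "biological_process",
    "cc": "cellular_component",
    "mf": "molecular_function",
    "bp": "biological_process",
}


def normalize_go_domain(domain: str) -> str:
    """Map spelling variants ('molecular function', 'MF') onto the canonical
    underscore form; unknown strings raise :class:`ValidationError`."""
    key = re.sub(r"[\s\-]+", " ", str(domain).strip().lower())
    key = _DOMAIN_ALIASES.get(key, key.replace(" ", "_"))
    if key not in GO_DOMAINS:
        raise ValidationError(f"unknown GO domain {domain!r}")
    return key


def read_go_tsv(path) -> pd.DataFrame:
    """Read a GO annotation TSV (gene_id, go_id, domain, term).

    Duplicate (gene_id, go_id) rows are collapsed to the first occurrence with
    a logged warning; domain spellings are normalized.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in GO_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df[GO_COLUMNS].copy()
    df["domain"] = df["domain"].map(normalize_go_domain)
    dup = df.duplicated(subset=["gene_id", "go_id"])
    if dup.any():
        logger.warning("%s: collapsed %d duplicate (gene_id, go_id) rows",
                       path, int(dup.sum()))
        df = df[~dup]
    return df.reset_index(drop=True)


def write_go_tsv(df: pd.DataFrame, path) -> None:
    df[GO_COLUMNS].to_csv(path, sep="\t", index=False)


def read_descriptions_tsv(path) -> pd.Series:
    """Read a 2-column (gene_id, description) TSV into a Series indexed by
    gene id.  Empty descriptions become empty strings."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "description"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df.set_index("gene_id")["description"]


def write_descriptions_tsv(desc: pd.Series, path) -> None:
    desc.rename("description").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False)


# -- FPKM matrices -----------------------------------------------------------

_SAMPLE_RE = re.compile(r"^(W|S1|S3)_(\d+)$")


def sample_columns(df: pd.DataFrame, condition: str) -> list[str]:
    """Replicate column names of one condition, sorted by replicate number."""
    cols = [(int(m.group(2)), c) for c in df.columns
            if (m := _SAMPLE_RE.match(c)) and m.group(1) == condition]
    return [c for _, c in sorted(cols)]


def read_fpkm_table(path) -> pd.DataFrame:
    """Read an FPKM matrix, wide or long layout autodetected by header.

    Returns a wide frame indexed by gene_id with columns like ``W_1``.
    Entries must be non-negative and every condition present needs at least
    one replicate; the matrix must be rectangular (no missing cells).
    """
    head = pd.read_csv(path, sep="\t", nrows=0)
    if {"condition", "replicate", "fpkm"}.issubset(head.columns):
        long = pd.read_csv(path, sep="\t",
                           dtype={"gene_id": str, "condition": str})
        bad = ~long["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValidationError(
                f"{path}: unknown condition {long.loc[bad.idxmax(), 'condition']!r}")
        wide = long.pivot_table(index="gene_id",
                                columns=["condition", "replicate"],
                                values="fpkm", aggfunc="first")
        wide.columns = [f"{c}_{r}" for c, r in wide.columns]
        df = wide
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in df.columns:
            raise FormatError(f"{path}: missing required column 'gene_id'")
        df = df.set_index("gene_id")
    unknown = [c for c in df.columns if not _SAMPLE_RE.match(c)]
    if unknown:
        raise FormatError(f"{path}: unrecognized sample columns {unknown}")
    df = df.astype(float)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing FPKM entries (not rectangular)")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    return df.sort_index(axis=1)


def write_fpkm_table(df: pd.DataFrame, path) -> None:
    df.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


# -- small generic tables ----------------------------------------------------

def read_two_column_tsv(path, col_a: str, col_b: str) -> pd.DataFrame:
    """Read a headered 2-column TSV (used for homolog maps and class labels)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (col_a, col_b):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df[[col_a, col_b]]
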