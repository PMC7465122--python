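"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-delimited text: expression matrices (genes x samples with a
header row of sample IDs), sample sheets, GMT gene-set libraries, regulatory
edge tables, STRING-style interaction tables and survival tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import SAMPLE_SHEET_COLUMNS, PairedExpressionSet

FLOAT_FMT = "%.6g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV; first column holds gene identifiers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_paired_set(expr_path: str | Path, sheet_path: str | Path) -> PairedExpressionSet:
    return PairedExpressionSet(read_expression(expr_path), read_sample_sheet(sheet_path))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT library: term <tab> description <tab> member genes."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields: {line[:60]!r}")
        name, _desc, *genes = fields
        members = {g for g in genes if g}
        if not members:
            raise ValueError(f"{path}: empty gene set {name!r}")
        terms[name] = members
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description] + sorted(genes)) for name, genes in terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Regulatory edge table with columns source/target/type/score/binding_region/p_value/species."""
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "type"):
        if col not in df.columns:
            raise ValueError(f"{path}: edge table missing column {col!r}")
    return df


def write_edge_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gene_list(path: str | Path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(list(genes)) + "\n")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table missing column {col!r}")
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
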