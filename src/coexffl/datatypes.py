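"""Shared data containers used across the pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

CONDITIONS = ("tumor", "normal")

SAMPLE_SHEET_COLUMNS = ["sample_id", "subject_id", "condition", "dataset_id"]


@dataclass
class PairedExpressionSet:
    """A gene-by-sample log2 expression matrix with tumor/normal pairing.

    Parameters
    ----------
    expr
        Genes (rows) by samples (columns), log2 scale. The column order must
        match ``samples["sample_id"]`` as a set (order may differ).
    samples
        Sample sheet with columns ``sample_id, subject_id, condition,
        dataset_id``; every subject contributes exactly one tumor and one
        normal sample.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    dataset_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        sheet = self.samples
        if sheet["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in sample sheet")
        bad = set(sheet["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if set(sheet["sample_id"]) != set(self.expr.columns):
            raise ValueError("sample sheet and expression columns disagree")
        counts = sheet.pivot_table(
            index="subject_id", columns="condition", values="sample_id", aggfunc="count"
        ).reindex(columns=list(CONDITIONS)).fillna(0)
        if not ((counts == 1).all(axis=None)):
            raise ValueError("every subject needs exactly one tumor and one normal sample")
        if self.expr.index.isnull().any():
            raise ValueError("expression matrix contains missing gene identifiers")
        if not self.dataset_id:
            ds = sheet["dataset_id"].unique()
            self.dataset_id = str(ds[0]) if len(ds) == 1 else "mixed"

    @property
    def subjects(self) -> list:
        return sorted(self.samples["subject_id"].unique())

    def condition_columns(self, condition: str) -> list:
        sel = self.samples[self.samples["condition"] == condition]
        return list(sel.sort_values("subject_id")["sample_id"])

    def paired_columns(self) -> tuple[list, list]:
        """(tumor, normal) sample IDs aligned on subject order."""
        return self.condition_columns("tumor"), self.condition_columns("normal")

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class FFLSpec:
    """Identifiers of the planted composite feed-forward loop."""

    mirna: str
    tfs: tuple[str, str]
    gene: str

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.mirna,) + tuple(self.tfs) + (self.gene,)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        """Typed (source, target, type) edges; 5 edges over 4 nodes."""
        out = [(self.mirna, self.gene, "miRNA-gene")]
        for tf in self.tfs:
            out.append((self.mirna, tf, "miRNA-TF"))
            out.append((tf, self.gene, "TF-gene"))
        return out


@dataclass
class GroundTruth:
    """Planted structure underlying one simulated fixture bundle."""

    genes: list[str]
    de_genes_up: set[str]
    de_genes_down: set[str]
    module_assignment: dict[str, str]
    planted_clique: set[str]
    planted_ffl: FFLSpec
    prognostic_genes: dict[str, int]  # gene -> sign of the hazard effect

    def __post_init__(self) -> None:
        universe = set(self.genes)
        for name in ("de_genes_up", "de_genes_down", "planted_clique"):
            extra = set(getattr(self, name)) - universe
            if extra:
                raise ValueError(f"{name} not a subset of the gene universe: {sorted(extra)[:5]}")
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("a gene cannot be both up- and downregulated")
        roles = {self.planted_ffl.gene: "gene"}
        if self.planted_ffl.gene not in universe:
            raise ValueError("planted FFL gene must be in the gene universe")
        del roles

    @property
    def de_genes(self) -> set[str]:
        return self.de_genes_up | self.de_genes_down

    @property
    def hub_genes(self) -> set[str]:
        """Planted hub genes: the differentially expressed members of the clique."""
        return self.planted_clique & self.de_genes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": list(self.genes),
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "module_assignment": self.module_assignment,
            "planted_clique": sorted(self.planted_clique),
            "planted_ffl": {
                "mirna": self.planted_ffl.mirna,
                "tfs": list(self.planted_ffl.tfs),
                "gene": self.planted_ffl.gene,
            },
            "prognostic_genes": self.prognostic_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=list(d["genes"]),
            de_genes_up=set(d["de_genes_up"]),
            de_genes_down=set(d["de_genes_down"]),
            module_assignment=dict(d["module_assignment"]),
            planted_clique=set(d["planted_clique"]),
            planted_ffl=FFLSpec(
                mirna=d["planted_ffl"]["mirna"],
                tfs=tuple(d["planted_ffl"]["tfs"]),
                gene=d["planted_ffl"]["gene"],
            ),
            prognostic_genes={k: int(v) for k, v in d["prognostic_genes"].items()},
        )
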