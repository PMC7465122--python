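"""Meta-differential expression across paired tumor/normal datasets.

Per dataset, each gene gets a classic paired t-test p-value on the
tumor-minus-normal differences; p-values are combined across datasets with
Fisher's combined probability statistic X = -2 * sum(ln p) ~ chi2(2k), adjusted
with the Benjamini–Hochberg step-up procedure, and gated on the pooled log2
fold change. A gene is called up (down) when the adjusted p falls strictly
below ``alpha`` and the log2FC is strictly above (below) ``fc_threshold``
(``-fc_threshold``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PairedExpressionSet

log = logging.getLogger("coexffl.meta_deg")

#: matrices whose maximum exceeds this are assumed to be on the raw intensity
#: scale and are log2(x+1)-transformed with a warning
UNLOGGED_MAX = 30.0

#: p-values of exactly zero are clamped here before taking logs so the Fisher
#: statistic stays finite
P_FLOOR = np.finfo(float).tiny


def ensure_log2(expr: pd.DataFrame) -> pd.DataFrame:
    """Return the matrix on log2 scale, transforming if it looks unlogged."""
    if np.nanmax(expr.to_numpy()) > UNLOGGED_MAX:
        warnings.warn(
            "expression maximum exceeds %.0f; applying log2(x+1)" % UNLOGGED_MAX,
            UserWarning,
            stacklevel=2,
        )
        return np.log2(expr + 1.0)
    return expr


def collapse_probes(probe_matrix: pd.DataFrame, annotation: dict[str, str]) -> pd.DataFrame:
    """Collapse probe rows to gene symbols by averaging duplicate symbols.

    Probes without a symbol in ``annotation`` are dropped; output rows are in
    lexicographic symbol order.
    """
    symbols = probe_matrix.index.map(lambda p: annotation.get(p))
    keep = symbols.notna()
    if not keep.any():
        raise ValueError("no probes map to a gene symbol")
    collapsed = probe_matrix.loc[keep].groupby(symbols[keep].astype(str)).mean()
    collapsed.index.name = "gene"
    return collapsed.sort_index()


def intersect_genes(matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Align >=2 matrices on the sorted intersection of their gene indices."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common: set[str] = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    if not common:
        raise ValueError("gene intersection is empty")
    idx = sorted(common)
    return [m.loc[idx] for m in matrices]


def paired_t_test(dataset: PairedExpressionSet) -> pd.Series:
    """Two-sided classic paired t-test p-value per gene.

    Genes whose tumor-minus-normal differences have zero variance get a
    missing p-value (logged), never a silent zero.
    """
    tumor, normal = dataset.paired_columns()
    if len(tumor) < 2:
        raise ValueError("need at least two subject pairs")
    d = dataset.expr[tumor].to_numpy() - dataset.expr[normal].to_numpy()
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.full(d.shape[0], np.nan)
    ok = sd > 0
    if (~ok).any():
        log.warning(
            "%d gene(s) with zero-variance paired differences; p set to NA",
            int((~ok).sum()),
        )
    t = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return pd.Series(p, index=dataset.expr.index, name=f"p_{dataset.dataset_id}")


def fisher_combine(p_table: pd.DataFrame) -> pd.DataFrame:
    """Fisher's combined probability per gene over k dataset columns.

    Returns a frame with columns ``X`` (the chi-square statistic
    ``-2 * sum(ln p)``) and ``p_combined`` (chi2 survival function with 2k
    degrees of freedom). Rows with any missing p are left missing.
    """
    p = p_table.to_numpy(dtype=float)
    k = p.shape[1]
    if k < 1:
        raise ValueError("need at least one p-value column")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    clamped = np.clip(p, P_FLOOR, 1.0)
    with np.errstate(invalid="ignore"):
        X = -2.0 * np.log(clamped).sum(axis=1)
    p_comb = stats.chi2.sf(X, df=2 * k)
    bad = np.isnan(p).any(axis=1)
    X[bad] = np.nan
    p_comb[bad] = np.nan
    return pd.DataFrame({"X": X, "p_combined": p_comb}, index=p_table.index)


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjustment, preserving input order.

    Missing values are excluded from the number of tests m and returned as
    missing.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="p_bh")
    return out


def compute_log2fc(datasets: list[PairedExpressionSet]) -> pd.DataFrame:
    """Pooled and per-dataset log2 fold changes (tumor mean - normal mean).

    The pooled value averages over all tumor samples across datasets minus all
    normal samples; per-dataset fold changes are emitted alongside for audit.
    """
    t_sum = None
    per_ds = {}
    t_n = n_n = 0
    n_sum = None
    for ds in datasets:
        tumor, normal = ds.paired_columns()
        ts = ds.expr[tumor].to_numpy().sum(axis=1)
        ns = ds.expr[normal].to_numpy().sum(axis=1)
        per_ds[f"log2fc_{ds.dataset_id}"] = ts / len(tumor) - ns / len(normal)
        t_sum = ts if t_sum is None else t_sum + ts
        n_sum = ns if n_sum is None else n_sum + ns
        t_n += len(tumor)
        n_n += len(normal)
    out = pd.DataFrame(per_ds, index=datasets[0].expr.index)
    out.insert(0, "log2fc", t_sum / t_n - n_sum / n_n)
    return out


def call_meta_degs(
    table: pd.DataFrame, alpha: float = 1e-4, fc_threshold: float = 1.5
) -> pd.DataFrame:
    """Classify genes as up/down/not_significant with strict inequalities."""
    out = table.copy()
    sig = out["p_bh"] < alpha
    cls = np.where(
        sig & (out["log2fc"] > fc_threshold),
        "up",
        np.where(sig & (out["log2fc"] < -fc_threshold), "down", "not_significant"),
    )
    out["class"] = cls
    return out


@dataclass
class MetaDEGResult:
    table: pd.DataFrame
    alpha: float
    fc_threshold: float

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["class"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["class"] == "down"])

    @property
    def degs(self) -> list[str]:
        return sorted(self.up + self.down)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.up) + len(self.down),
            "up": len(self.up),
            "down": len(self.down),
        }


def run_meta_deg(
    datasets: list[PairedExpressionSet],
    alpha: float = 1e-4,
    fc_threshold: float = 1.5,
    annotations: list[dict[str, str]] | None = None,
) -> MetaDEGResult:
    """Full meta-analysis: collapse, intersect, test, combine, adjust, gate."""
    if annotations is not None:
        datasets = [
            PairedExpressionSet(collapse_probes(ds.expr, ann), ds.samples, ds.dataset_id)
            for ds, ann in zip(datasets, annotations)
        ]
    datasets = [
        PairedExpressionSet(ensure_log2(ds.expr), ds.samples, ds.dataset_id)
        for ds in datasets
    ]
    aligned = intersect_genes([ds.expr for ds in datasets])
    datasets = [
        PairedExpressionSet(expr, ds.samples, ds.dataset_id)
        for expr, ds in zip(aligned, datasets)
    ]
    pvals = pd.concat([paired_t_test(ds) for ds in datasets], axis=1)
    combined = fisher_combine(pvals)
    combined["p_bh"] = bh_adjust(combined["p_combined"])
    fc = compute_log2fc(datasets)
    table = pd.concat([pvals, combined, fc], axis=1)
    table = call_meta_degs(table, alpha=alpha, fc_threshold=fc_threshold)
    return MetaDEGResult(table=table, alpha=alpha, fc_threshold=fc_threshold)
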