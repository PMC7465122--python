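"""Weighted gene co-expression network: adjacency, TOM, modules, connectivity.

The network is unsigned: similarity is the absolute Pearson correlation
s_ij = |cor(x_i, x_j)|, raised to a soft-thresholding power beta chosen by the
scale-free topology criterion, and converted to the standard unsigned
topological overlap

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,

whose dissimilarity 1 - omega feeds average-linkage hierarchical clustering.
Modules come from an adaptive height cut of the dendrogram (a simplified
variant of dynamic tree cut), are summarized by module eigengenes (first
principal component of the standardized module submatrix) and merged while
eigengene dissimilarity stays below the merge height. Connectivity statistics
(k.in, omega.in, kTotal, kOut, kDiff, kME/module membership) follow the
standard intramodular definitions; degree sums exclude the diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger("coexffl.gcn")

GREY = "grey"

#: module colors in decreasing-size assignment order
COLOR_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]

#: deep_split -> quantile of merge heights above which the cut gap is searched
_DEEP_SPLIT_QUANTILE = {0: 0.90, 1: 0.75, 2: 0.50, 3: 0.25, 4: 0.10}


def similarity_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson correlation between gene expression profiles."""
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if (x.std(axis=1) == 0).any():
        raise ValueError("zero-variance gene(s) in expression matrix")
    s = np.abs(np.corrcoef(x))
    np.fill_diagonal(s, 1.0)
    s = np.clip(s, 0.0, 1.0)
    return pd.DataFrame(s, index=expr.index, columns=expr.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10(frequency) on
    log10(mean k) over occupied bins and returns ``(signed_r2, slope)`` with
    ``signed_r2 = -sign(slope) * R^2`` so only decaying degree distributions
    score positively.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all values equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() for b in range(n_bins) if (which == b).any()])
    freq = np.array([(which == b).sum() for b in range(n_bins) if (which == b).any()], dtype=float)
    freq /= freq.sum()
    if len(mean_k) < 3:
        raise ValueError("too few occupied bins for a scale-free fit")
    lx, ly = np.log10(mean_k), np.log10(freq)
    fit = stats.linregress(lx, ly)
    return float(-np.sign(fit.slope) * fit.rvalue**2), float(fit.slope)


@dataclass
class SoftThresholdResult:
    beta: int
    fit_table: pd.DataFrame  # beta, signed_r2, slope, mean_k
    reached_target: bool


def _default_power(n_samples: int | None) -> int:
    """Recommended unsigned-network default power by sample count."""
    if n_samples is None or n_samples > 40:
        return 6
    if n_samples > 30:
        return 7
    if n_samples > 20:
        return 8
    return 9


def pick_soft_threshold(
    S: pd.DataFrame,
    candidate_powers: range = range(1, 21),
    target_r2: float = 0.80,
    n_samples: int | None = None,
) -> SoftThresholdResult:
    """Smallest power whose signed scale-free R^2 reaches the target.

    When no candidate reaches the target the fallback is the argmax power,
    provided some candidate at least shows a decaying degree distribution
    (signed R^2 > 0); when every candidate has a non-decaying distribution
    (small block-structured networks), the fallback is the standard
    sample-size-dependent default power for unsigned networks. Either
    fallback sets ``reached_target=False`` and warns.
    """
    s = S.to_numpy(dtype=float)
    if s.shape[0] < 30:
        log.warning("fewer than 30 genes; scale-free fit is unreliable")
    rows = []
    for beta in candidate_powers:
        a = s**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append((beta, r2, slope, k.mean()))
    table = pd.DataFrame(rows, columns=["beta", "signed_r2", "slope", "mean_k"])
    hit = table[table["signed_r2"] >= target_r2]
    if len(hit):
        beta = int(hit["beta"].iloc[0])
        reached = True
    else:
        reached = False
        best = table["signed_r2"].max()
        if best > 0:
            beta = int(table.loc[table["signed_r2"].idxmax(), "beta"])
            why = f"falling back to argmax beta={beta}"
        else:
            beta = _default_power(n_samples)
            why = (
                "no candidate shows a decaying degree distribution; "
                f"falling back to the unsigned-network default beta={beta}"
            )
        warnings.warn(
            f"no candidate power reaches signed R^2 {target_r2}; " + why,
            UserWarning,
            stacklevel=2,
        )
    return SoftThresholdResult(beta=beta, fit_table=table, reached_target=reached)


def adjacency_matrix(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Power adjacency a_ij = s_ij ** beta with zero diagonal."""
    a = S.to_numpy(dtype=float) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=S.index, columns=S.columns)


def tom_matrix(A: pd.DataFrame) -> pd.DataFrame:
    """Standard unsigned topological overlap matrix with unit diagonal."""
    a = A.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diagonal(a).any():
        a = a.copy()
        np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # zero diagonal makes the u=i and u=j terms vanish
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    omega = (l + a) / denom
    np.fill_diagonal(omega, 1.0)
    omega = np.clip(omega, 0.0, 1.0)
    return pd.DataFrame(omega, index=A.index, columns=A.columns)


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModulePartition:
    labels: pd.Series  # gene -> color ("grey" = unassigned)
    linkage: np.ndarray
    merge_height: float = 0.2

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _relabel_by_size(raw: pd.Series) -> pd.Series:
    """Map raw cluster ids to palette colors in decreasing size order."""
    out = pd.Series(GREY, index=raw.index, dtype=object)
    sizes = raw[raw != -1].value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], str(c)))
    palette = iter(COLOR_PALETTE)
    for cid in order:
        try:
            color = next(palette)
        except StopIteration:  # pragma: no cover - >20 modules
            color = f"module{cid}"
        out[raw == cid] = color
    return out


def cluster_and_cut(
    dissTOM: pd.DataFrame, min_module_size: int = 30, deep_split: int = 2
) -> ModulePartition:
    """Average-linkage dendrogram plus adaptive height cut into modules.

    Candidate cut heights (midpoints between consecutive merge heights, in
    the upper tail of the dendrogram; ``deep_split`` sets how deep the tail
    reaches, so deeper splits may cut lower) are scanned and the cut is kept
    that maximizes the number of clusters of at least ``min_module_size``
    genes, breaking ties toward fewer unassigned genes and then toward the
    higher (coarser) cut. Clusters smaller than ``min_module_size`` become
    grey, and colors are assigned in decreasing size order. Over-split
    branches of one real module are re-joined later by eigengene merging.
    """
    if deep_split not in _DEEP_SPLIT_QUANTILE:
        raise ValueError("deep_split must be 0..4")
    genes = dissTOM.index
    n = len(genes)
    d = dissTOM.to_numpy(dtype=float)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes grey", UserWarning, stacklevel=2)
        return ModulePartition(pd.Series(GREY, index=genes, dtype=object), Z)

    heights = np.unique(Z[:, 2])
    if len(heights) == 1:
        raw = pd.Series(0, index=genes)  # flat tree: a single module
    else:
        floor = np.quantile(Z[:, 2], _DEEP_SPLIT_QUANTILE[deep_split])
        mids = (heights[:-1] + heights[1:]) / 2.0
        top = float(heights[-1]) * (1.0 + 1e-9) + 1e-12  # whole-tree candidate
        candidates = [float(c) for c in mids if c >= floor] + [top]
        best_key, best_labels = None, None
        for cut in candidates:
            lab = hierarchy.fcluster(Z, t=cut, criterion="distance")
            sizes = np.bincount(lab)
            n_big = int((sizes >= min_module_size).sum())
            n_grey = int(sizes[sizes < min_module_size].sum())
            key = (n_big, -n_grey, cut)
            if best_key is None or key > best_key:
                best_key, best_labels = key, lab
        raw = pd.Series(best_labels, index=genes)
    sizes = raw.value_counts()
    raw = raw.where(raw.map(sizes) >= min_module_size, other=-1)
    return ModulePartition(_relabel_by_size(raw), Z)


# ---------------------------------------------------------------------------
# eigengenes


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    The eigengene is computed on the row-standardized module submatrix and
    oriented so that it correlates non-negatively with the module's average
    expression profile.
    """
    modules = partition.modules
    if not modules:
        raise ValueError("no non-grey modules")
    out = {}
    for mod in modules:
        members = partition.members(mod)
        if len(members) < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 genes")
        x = _standardize_rows(expr.loc[members].to_numpy(dtype=float))
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        me = vt[0]
        avg = x.mean(axis=0)
        if np.corrcoef(me, avg)[0, 1] < 0:
            me = -me
        me = (me - me.mean()) / me.std()
        out[mod] = me
    return pd.DataFrame(out, index=expr.columns).T  # modules x samples


def eigengene_dissimilarity(ME: pd.DataFrame) -> pd.DataFrame:
    """MEdiss = 1 - cor(ME_i, ME_j), in [0, 2]."""
    c = np.corrcoef(ME.to_numpy(dtype=float))
    return pd.DataFrame(1.0 - c, index=ME.index, columns=ME.index)


def merge_close_modules(
    expr: pd.DataFrame, partition: ModulePartition, merge_height: float = 0.2
) -> tuple[ModulePartition, pd.DataFrame]:
    """Iteratively merge the closest eigengene pair while MEdiss < merge_height.

    The label of the larger module survives each merge and eigengenes are
    recomputed before the next iteration. Returns the merged partition and
    its eigengenes.
    """
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(labels, partition.linkage, merge_height)
        mods = part.modules
        ME = module_eigengenes(expr, part)
        if len(mods) < 2:
            return part, ME
        diss = eigengene_dissimilarity(ME.loc[mods])
        tri = diss.where(np.triu(np.ones(diss.shape, dtype=bool), k=1))
        min_val = np.nanmin(tri.to_numpy())
        if not (min_val < merge_height):
            return part, ME
        i, j = np.unravel_index(np.nanargmin(tri.to_numpy()), tri.shape)
        a, b = mods[i], mods[j]
        sizes = labels.value_counts()
        keep, drop = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels[labels == drop] = keep


# ---------------------------------------------------------------------------
# connectivity


def connectivity_table(
    A: pd.DataFrame,
    Omega: pd.DataFrame,
    expr: pd.DataFrame,
    partition: ModulePartition,
    ME: pd.DataFrame,
    kme_floor: float = 0.7,
) -> tuple[pd.DataFrame, ModulePartition]:
    """Per-gene connectivity and module-membership statistics.

    k.in and omega.in sum adjacency/TOM weights over same-module partners;
    kTotal sums over all genes (diagonal excluded); kOut = kTotal - k.in and
    kDiff = k.in - kOut. kME is the correlation of a gene's profile with each
    module eigengene and MM the kME of the gene's own module. Genes whose
    maximum |kME| falls below ``kme_floor`` are reassigned to grey (applied
    once, after module merging).
    """
    genes = list(A.index)
    a = A.to_numpy(dtype=float).copy()
    w = Omega.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(w, 0.0)
    labels = partition.labels.loc[genes]
    lab_arr = labels.to_numpy()
    k_total = a.sum(axis=1)

    k_in = np.zeros(len(genes))
    w_in = np.zeros(len(genes))
    for mod in set(lab_arr):
        mask = lab_arr == mod
        if mod == GREY:
            continue
        k_in[mask] = a[np.ix_(mask, mask)].sum(axis=1)
        w_in[mask] = w[np.ix_(mask, mask)].sum(axis=1)

    x = _standardize_rows(expr.loc[genes].to_numpy(dtype=float))
    me = _standardize_rows(ME.to_numpy(dtype=float))
    n_samp = x.shape[1]
    kme = (x @ me.T) / n_samp  # genes x modules
    kme_df = pd.DataFrame(kme, index=genes, columns=[f"kME_{m}" for m in ME.index])

    mm = np.full(len(genes), np.nan)
    mod_pos = {m: i for i, m in enumerate(ME.index)}
    for i, mod in enumerate(lab_arr):
        if mod in mod_pos:
            mm[i] = kme[i, mod_pos[mod]]

    new_labels = labels.copy()
    weak = np.abs(kme).max(axis=1) < kme_floor
    reassigned = weak & (lab_arr != GREY)
    if reassigned.any():
        log.info("%d gene(s) with max |kME| < %.2f reassigned to grey", int(reassigned.sum()), kme_floor)
        new_labels[reassigned] = GREY
        mm[reassigned] = np.nan
        k_in[reassigned] = 0.0
        w_in[reassigned] = 0.0

    table = pd.DataFrame(
        {
            "module": new_labels,
            "MM": mm,
            "k.in": k_in,
            "omega.in": w_in,
            "kTotal": k_total,
            "kOut": k_total - k_in,
            "kDiff": 2 * k_in - k_total,
        },
        index=pd.Index(genes, name="gene"),
    )
    table = pd.concat([table, kme_df], axis=1)
    return table, ModulePartition(new_labels, partition.linkage, partition.merge_height)


def representative_genes(table: pd.DataFrame, mm_threshold: float = 0.9) -> dict[str, list[str]]:
    """Genes with MM strictly above the threshold, per non-grey module."""
    out: dict[str, list[str]] = {}
    sel = table[(table["module"] != GREY) & (table["MM"] > mm_threshold)]
    for mod, sub in sel.groupby("module", sort=True):
        out[str(mod)] = sorted(sub.index)
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CoexpressionModel:
    similarity: pd.DataFrame
    beta: int
    soft_threshold: SoftThresholdResult
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    partition: ModulePartition
    eigengenes: pd.DataFrame
    connectivity: pd.DataFrame
    representative: dict[str, list[str]] = field(default_factory=dict)

    @property
    def representative_genes_flat(self) -> list[str]:
        return sorted({g for gs in self.representative.values() for g in gs})


def build_coexpression_network(
    expr: pd.DataFrame,
    target_r2: float = 0.80,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_height: float = 0.2,
    mm_threshold: float = 0.9,
    kme_floor: float = 0.7,
    beta: int | None = None,
) -> CoexpressionModel:
    """Run the full co-expression stage on a genes-by-samples matrix."""
    S = similarity_matrix(expr)
    if beta is None:
        st = pick_soft_threshold(S, target_r2=target_r2, n_samples=expr.shape[1])
        beta = st.beta
    else:
        st = SoftThresholdResult(beta=beta, fit_table=pd.DataFrame(), reached_target=True)
    A = adjacency_matrix(S, beta)
    Omega = tom_matrix(A)
    diss = 1.0 - Omega
    part0 = cluster_and_cut(diss, min_module_size=min_module_size, deep_split=deep_split)
    if part0.modules:
        part, ME = merge_close_modules(expr, part0, merge_height=merge_height)
    else:
        part, ME = part0, pd.DataFrame(columns=expr.columns)
    if len(ME):
        conn, part = connectivity_table(A, Omega, expr, part, ME, kme_floor=kme_floor)
        rep = representative_genes(conn, mm_threshold=mm_threshold)
    else:
        conn = pd.DataFrame(index=expr.index)
        rep = {}
    return CoexpressionModel(
        similarity=S,
        beta=beta,
        soft_threshold=st,
        adjacency=A,
        tom=Omega,
        partition=part,
        eigengenes=ME,
        connectivity=conn,
        representative=rep,
    )
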