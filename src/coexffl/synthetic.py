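"""Synthetic fixture bundle with planted ground truth.

Generates every input the pipeline consumes — two paired-cohort expression
datasets with planted up/down-regulated genes, latent-factor co-expression
modules, a scored protein-interaction graph containing one planted near-clique,
GMT gene-set libraries whose significant terms capture the planted hub genes,
regulatory edge tables containing one planted composite feed-forward loop, and
a survival table whose hazard depends on hub-gene expression — so every
downstream stage is testable without any download.

Expression is simulated directly on the log2 scale. Each co-expression module
is driven by a single latent factor per sample: a module gene is
``baseline + loading * factor + N(0, noise_sd)`` (plus a per-condition shift
for differentially expressed genes), so the intra-module Pearson correlation
is analytically ``loading**2 / (loading**2 + noise_sd**2)`` apart from the
condition contrast.

One global integer seed fans out to per-generator substreams by fixed offsets,
so each generator is individually reproducible and the streams are independent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FFLSpec, GroundTruth, PairedExpressionSet
from . import io as cio

# fixed seed offsets per generator substream
_OFFSET = {
    "expression": 11,
    "ppi": 23,
    "genesets": 37,
    "regulatory": 53,
    "survival": 71,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _OFFSET[stream]])


@dataclass
class SimulationConfig:
    """Conditions of the simulated two-cohort paired study.

    Defaults are the fixture used throughout the test suite: 300 genes, two
    datasets of 50 tumor/normal pairs each, half the genes differentially
    expressed with a mean |log2FC| of 2.0, three co-expression modules of
    60/50/40 genes at factor loading 0.9 and residual noise SD 0.5 (log2
    units), a planted 12-gene interaction clique of which 5 genes are
    differentially expressed (the planted hub genes), one composite
    feed-forward loop (1 miRNA, 2 TFs, 1 hub gene) and a log-hazard effect of
    ln(2) per high-expression cohort.
    """

    n_genes: int = 300
    n_pairs_per_dataset: tuple[int, ...] = (50, 50)
    de_fraction: float = 0.5
    de_effect: float = 2.0
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (60, 50, 40)
    factor_loading: float = 0.9
    noise_sd: float = 0.5
    ppi_clique_size: int = 12
    n_hub_genes: int = 5
    ffl_spec: FFLSpec | None = None  # filled from planted hub genes if None
    hazard_coeff: float = math.log(2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or any(p < 2 for p in self.n_pairs_per_dataset):
            raise ValueError("n_genes and every pair count must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.factor_loading < 1.0:
            raise ValueError("factor_loading must lie in (0, 1)")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must list one size per module")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("modules need at least 2 genes")
        if self.ppi_clique_size < 3:
            raise ValueError("planted clique needs at least 3 genes")
        if self.n_hub_genes > self.ppi_clique_size:
            raise ValueError("hub genes are clique members; n_hub_genes too large")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))

    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_genes + 1)]


_MODULE_TRUTH_LABELS = ["m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8"]


def plant_truth(config: SimulationConfig) -> GroundTruth:
    """Deterministic planted structure implied by a configuration.

    Module genes occupy the front of the gene universe (module labels m1, m2,
    ...), and the differential-expression budget is spent module-first so that
    whole modules share a direction of regulation (alternating up/down), as
    co-expressed disease modules do; any leftover budget lands on background
    genes with alternating signs. The planted clique is the first
    ``n_hub_genes`` differentially expressed genes plus background (non-DE)
    genes drawn from the tail of the universe.
    """
    genes = config.gene_names
    module_assignment: dict[str, str] = {}
    cursor = 0
    module_members: list[list[str]] = []
    for label, size in zip(_MODULE_TRUTH_LABELS, config.module_sizes):
        members = genes[cursor : cursor + size]
        for g in members:
            module_assignment[g] = label
        module_members.append(members)
        cursor += size

    up: list[str] = []
    down: list[str] = []
    budget = config.n_de
    sign = +1
    for members in module_members:
        if budget < len(members):
            break
        (up if sign > 0 else down).extend(members)
        budget -= len(members)
        sign = -sign
    background = genes[cursor:]
    for g in background[:budget]:
        (up if sign > 0 else down).append(g)
        sign = -sign

    de_ordered = up + down
    n_hub = min(config.n_hub_genes, len(de_ordered))
    hub = de_ordered[:n_hub]
    non_de_pool = [g for g in reversed(genes) if g not in set(de_ordered)]
    extra = config.ppi_clique_size - n_hub
    if extra > len(non_de_pool):
        raise ValueError("gene universe too small for the requested clique")
    clique = set(hub) | set(non_de_pool[:extra])

    ffl = config.ffl_spec or FFLSpec(
        mirna="hsa-miR-9001-5p", tfs=("TF01", "TF02"), gene=hub[0]
    )
    prognostic = {g: +1 for g in hub}
    return GroundTruth(
        genes=genes,
        de_genes_up=set(up),
        de_genes_down=set(down),
        module_assignment=module_assignment,
        planted_clique=clique,
        planted_ffl=ffl,
        prognostic_genes=prognostic,
    )


# ---------------------------------------------------------------------------
# expression


def simulate_paired_expression(
    config: SimulationConfig,
) -> tuple[list[PairedExpressionSet], GroundTruth]:
    """Simulate the paired tumor/normal datasets with planted structure."""
    truth = plant_truth(config)
    rng = _rng(config.seed, "expression")
    genes = config.gene_names
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(7.0, 1.0, size=n_genes)
    shift = np.zeros(n_genes)
    for g in truth.de_genes_up:
        shift[gene_pos[g]] = config.de_effect
    for g in truth.de_genes_down:
        shift[gene_pos[g]] = -config.de_effect

    loading = np.zeros(n_genes)
    module_idx = np.full(n_genes, -1)
    labels = sorted({m for m in truth.module_assignment.values()})
    for g, m in truth.module_assignment.items():
        loading[gene_pos[g]] = config.factor_loading
        module_idx[gene_pos[g]] = labels.index(m)

    datasets: list[PairedExpressionSet] = []
    for d, n_pairs in enumerate(config.n_pairs_per_dataset, start=1):
        ds_id = f"DS{d}"
        ds_offset = rng.normal(0.0, 0.25, size=n_genes)
        n_samples = 2 * n_pairs
        factors = rng.standard_normal((max(len(labels), 1), n_samples))
        noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
        cond = np.tile([1.0, 0.0], n_pairs)  # tumor, normal per subject

        x = baseline[:, None] + ds_offset[:, None] + noise
        x += shift[:, None] * cond[None, :]
        in_mod = module_idx >= 0
        if in_mod.any():
            x[in_mod] += loading[in_mod, None] * factors[module_idx[in_mod], :]

        cols, rows = [], []
        for s in range(1, n_pairs + 1):
            subject = f"{ds_id}_S{s:03d}"
            for suffix, condition in (("T", "tumor"), ("N", "normal")):
                sid = f"{subject}_{suffix}"
                cols.append(sid)
                rows.append((sid, subject, condition, ds_id))
        expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=cols)
        sheet = pd.DataFrame(rows, columns=["sample_id", "subject_id", "condition", "dataset_id"])
        datasets.append(PairedExpressionSet(expr, sheet, dataset_id=ds_id))
    return datasets, truth


# ---------------------------------------------------------------------------
# protein-interaction graph


def simulate_ppi_graph(
    truth: GroundTruth,
    n_background: int = 50,
    background_edge_prob: float = 0.05,
    seed: int = 0,
    score_threshold: float = 0.9,
) -> pd.DataFrame:
    """Scored interaction edge table containing the planted clique.

    The planted clique is fully connected with combined scores strictly above
    ``score_threshold``; the background is Erdős–Rényi over all remaining node
    pairs with scores mixed below and above the threshold.
    """
    if len(truth.planted_clique) < 3:
        raise ValueError("planted clique must have at least 3 genes")
    rng = _rng(seed, "ppi")
    clique = sorted(truth.planted_clique)
    pool = [g for g in truth.genes if g not in truth.planted_clique]
    background = list(rng.choice(pool, size=min(n_background, len(pool)), replace=False))
    nodes = clique + sorted(background)

    rows: list[tuple[str, str, float]] = []
    clique_set = set(clique)
    for a, b in itertools.combinations(clique, 2):
        hi = score_threshold + (1.0 - score_threshold) * (0.5 + 0.5 * rng.random())
        rows.append((a, b, hi))
    for a, b in itertools.combinations(nodes, 2):
        if a in clique_set and b in clique_set:
            continue
        if rng.random() < background_edge_prob:
            rows.append((a, b, 0.4 + 0.6 * rng.random()))
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


# ---------------------------------------------------------------------------
# gene-set libraries


def simulate_genesets(
    truth: GroundTruth,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 30),
    seed: int = 0,
    n_planted_terms: int = 3,
) -> dict[str, dict[str, set[str]]]:
    """Two GMT libraries whose significant terms pin down the planted hubs.

    ``n_planted_terms`` terms (at least two) each contain the whole planted
    hub set (clique ∩ DE genes) padded with genes from outside the clique, so
    the intersection of their query overlaps is exactly the hub set; the
    remaining terms are random draws from the non-clique universe.
    """
    lo, hi = term_size_range
    if lo < 2:
        raise ValueError("term sizes must be >= 2")
    if hi > len(truth.genes):
        raise ValueError("term size exceeds the gene universe")
    if n_planted_terms < 2:
        raise ValueError("need at least two planted terms")
    rng = _rng(seed, "genesets")
    hubs = sorted(truth.hub_genes)
    pool = [g for g in truth.genes if g not in truth.planted_clique]

    libraries: dict[str, dict[str, set[str]]] = {"GO_SYN": {}, "PATH_SYN": {}}
    lib_names = list(libraries)
    for i in range(n_planted_terms):
        pad = list(rng.choice(pool, size=max(lo - len(hubs), 3), replace=False))
        lib = lib_names[i % len(lib_names)]
        libraries[lib][f"PLANTED_TERM_{i + 1}"] = set(hubs) | set(pad)
    n_decoys = max(n_terms - n_planted_terms, 0)
    for j in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(pool, size=min(size, len(pool)), replace=False))
        lib = lib_names[j % len(lib_names)]
        libraries[lib][f"DECOY_TERM_{j + 1}"] = members
    return libraries


# ---------------------------------------------------------------------------
# regulatory tables


@dataclass
class RegulatoryBundle:
    """Human edge tables, tier-1 screen list and mouse target tables."""

    mirna_gene: pd.DataFrame
    tf_gene: pd.DataFrame
    mirna_tf: pd.DataFrame
    tier1: list[str]
    mouse_mirna_gene: pd.DataFrame
    mouse_mirna_tf: pd.DataFrame

    @property
    def human_tables(self) -> list[pd.DataFrame]:
        return [self.mirna_gene, self.tf_gene, self.mirna_tf]

    @property
    def mouse_tables(self) -> list[pd.DataFrame]:
        return [self.mouse_mirna_gene, self.mouse_mirna_tf]


_EDGE_COLUMNS = ["source", "target", "type", "score", "binding_region", "p_value", "species"]


def _edge_row(source, target, etype, *, score=np.nan, region="", p=np.nan, species="hsa"):
    return dict(
        source=source, target=target, type=etype,
        score=score, binding_region=region, p_value=p, species=species,
    )


def simulate_regulatory_tables(
    truth: GroundTruth, n_decoys: int = 12, seed: int = 0
) -> RegulatoryBundle:
    """Regulatory edge tables in which only the planted FFL survives screening.

    Planted edges pass every filter (miRNA target score > 0.95 in the 3'UTR,
    TF binding p < 0.001) and the planted regulators appear on the tier-1
    literature list and in the mouse target tables. Each decoy edge fails at
    least one filter or one screening tier.
    """
    rng = _rng(seed, "regulatory")
    ffl = truth.planted_ffl
    if any(n.startswith("DECOY") for n in ffl.nodes):
        raise ValueError("decoy identifiers collide with planted identifiers")
    hubs = sorted(truth.hub_genes) or [ffl.gene]

    human: list[dict] = []
    mouse: list[dict] = []
    good_score = lambda: 0.96 + 0.035 * rng.random()
    good_p = lambda: 10 ** rng.uniform(-6, -3.5)

    # planted composite FFL (1 miRNA, 2 TFs, 1 gene)
    human.append(_edge_row(ffl.mirna, ffl.gene, "miRNA-gene", score=good_score(), region="3UTR"))
    for tf in ffl.tfs:
        human.append(_edge_row(ffl.mirna, tf, "miRNA-TF", score=good_score(), region="3UTR"))
        human.append(_edge_row(tf, ffl.gene, "TF-gene", p=good_p()))
    # mouse conservation evidence for the planted miRNA
    mmu = "mmu-" + ffl.mirna.split("hsa-", 1)[-1]
    mouse.append(_edge_row(mmu, ffl.gene, "miRNA-gene", score=good_score(), region="3UTR", species="mmu"))
    for tf in ffl.tfs:
        mouse.append(_edge_row(mmu, tf, "miRNA-TF", score=good_score(), region="3UTR", species="mmu"))

    tier1 = [ffl.mirna, *ffl.tfs]
    # decoys rotate through the failure modes: low score, wrong binding
    # region, weak TF p-value, missing from tier-1, tier-1 but no mouse support
    failure_modes = ["low_score", "bad_region", "weak_p", "no_tier1", "no_mouse"]
    for i in range(n_decoys):
        mode = failure_modes[i % len(failure_modes)]
        target = hubs[i % len(hubs)]
        mir = f"hsa-miR-DECOY{i + 1}-3p"
        tf = f"DECOYTF{i + 1}"
        if mode == "low_score":
            human.append(_edge_row(mir, target, "miRNA-gene", score=0.5 + 0.45 * rng.random(), region="3UTR"))
            tier1.append(mir)
            mouse.append(_edge_row("mmu-" + mir.split("hsa-", 1)[-1], target, "miRNA-gene",
                                   score=good_score(), region="3UTR", species="mmu"))
        elif mode == "bad_region":
            human.append(_edge_row(mir, target, "miRNA-gene", score=good_score(), region="CDS"))
            tier1.append(mir)
        elif mode == "weak_p":
            human.append(_edge_row(tf, target, "TF-gene", p=10 ** rng.uniform(-2.9, -0.5)))
            tier1.append(tf)
        elif mode == "no_tier1":
            human.append(_edge_row(mir, target, "miRNA-gene", score=good_score(), region="3UTR"))
            mouse.append(_edge_row("mmu-" + mir.split("hsa-", 1)[-1], target, "miRNA-gene",
                                   score=good_score(), region="3UTR", species="mmu"))
        elif mode == "no_mouse":
            human.append(_edge_row(mir, target, "miRNA-gene", score=good_score(), region="3UTR"))
            tier1.append(mir)

    hdf = pd.DataFrame(human, columns=_EDGE_COLUMNS)
    mdf = pd.DataFrame(mouse, columns=_EDGE_COLUMNS)
    return RegulatoryBundle(
        mirna_gene=hdf[hdf["type"] == "miRNA-gene"].reset_index(drop=True),
        tf_gene=hdf[hdf["type"] == "TF-gene"].reset_index(drop=True),
        mirna_tf=hdf[hdf["type"] == "miRNA-TF"].reset_index(drop=True),
        tier1=tier1,
        mouse_mirna_gene=mdf[mdf["type"] == "miRNA-gene"].reset_index(drop=True),
        mouse_mirna_tf=mdf[mdf["type"] == "miRNA-TF"].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    truth: GroundTruth,
    n_subjects: int = 500,
    baseline_scale: float = 60.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    hazard_coeff: float | None = None,
) -> pd.DataFrame:
    """Survival table whose hazard tracks hub-gene expression.

    The prognostic (hub) genes are tightly co-expressed, so one latent
    per-subject aggressiveness factor drives all their expression columns
    (plus small measurement noise). Event times are exponential with the
    baseline hazard ``1/baseline_scale`` (months) multiplied by
    ``exp(hazard_coeff * sign * z)``, where ``z`` indicates expression above
    its population median — so the true high/low cohort hazard ratio is
    ``exp(hazard_coeff)`` by construction. Censoring is independent of the
    covariates: each subject is censored with probability ``censor_rate`` at a
    uniform fraction of its event time.
    """
    if baseline_scale <= 0:
        raise ValueError("baseline_scale must be positive")
    if n_subjects < 20:
        raise ValueError("need at least 20 subjects")
    if hazard_coeff is None:
        raise ValueError("hazard_coeff must be set")
    rng = _rng(seed, "survival")
    genes = sorted(truth.prognostic_genes)
    u = rng.standard_normal(n_subjects)
    expr = {g: u * truth.prognostic_genes[g] + 0.1 * rng.standard_normal(n_subjects) for g in genes}
    z = (u > 0.0).astype(float)
    scale = baseline_scale * np.exp(-hazard_coeff * z)
    t_event = rng.exponential(scale)
    censored = rng.random(n_subjects) < censor_rate
    t_obs = np.where(censored, t_event * rng.random(n_subjects), t_event)
    t_obs = np.maximum(t_obs, 1e-9)
    out = pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in range(1, n_subjects + 1)],
            "time_months": t_obs,
            "event": (~censored).astype(int),
        }
    )
    for g in genes:
        out[g] = expr[g]
    return out


# ---------------------------------------------------------------------------
# bundle writer


def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Generate and write every pipeline input under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, truth = simulate_paired_expression(config)
    for ds in datasets:
        cio.write_expression(ds.expr, out / f"{ds.dataset_id}_expr.tsv")
        cio.write_sample_sheet(ds.samples, out / f"{ds.dataset_id}_samples.tsv")
    edges = simulate_ppi_graph(truth, seed=config.seed)
    edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False, float_format="%.6g")
    for lib, terms in simulate_genesets(truth, seed=config.seed).items():
        cio.write_gmt(terms, out / f"{lib.lower()}.gmt")
    reg = simulate_regulatory_tables(truth, seed=config.seed)
    cio.write_edge_table(reg.mirna_gene, out / "mirna_gene.tsv")
    cio.write_edge_table(reg.tf_gene, out / "tf_gene.tsv")
    cio.write_edge_table(reg.mirna_tf, out / "mirna_tf.tsv")
    cio.write_gene_list(reg.tier1, out / "tier1.txt")
    cio.write_edge_table(reg.mouse_mirna_gene, out / "mouse_mirna_gene.tsv")
    cio.write_edge_table(reg.mouse_mirna_tf, out / "mouse_mirna_tf.tsv")
    surv = simulate_survival(truth, seed=config.seed, hazard_coeff=config.hazard_coeff)
    cio.write_survival_table(surv, out / "survival.tsv")
    truth.to_json(out / "ground_truth.json")
    return truth
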