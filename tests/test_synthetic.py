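"""Contracts of the planted-truth generators: determinism, planted structure,
and the statistical properties the simulated data must exhibit."""

import numpy as np
import pandas as pd
import pytest

from coexffl.datatypes import FFLSpec
from coexffl.synthetic import (
    SimulationConfig,
    plant_truth,
    simulate_genesets,
    simulate_paired_expression,
    simulate_ppi_graph,
    simulate_regulatory_tables,
    simulate_survival,
)


def small_config(**kw) -> SimulationConfig:
    base = dict(
        n_genes=60,
        n_pairs_per_dataset=(10, 10),
        de_fraction=0.5,
        n_modules=2,
        module_sizes=(15, 15),
        ppi_clique_size=8,
        seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(noise_sd=0.0),
            dict(noise_sd=-1.0),
            dict(de_fraction=1.5),
            dict(module_sizes=(200, 200), n_modules=2, n_genes=300),
            dict(module_sizes=(10,), n_modules=2),
            dict(ppi_clique_size=2),
            dict(factor_loading=1.0),
        ],
    )
    def test_invalid_configs_raise(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_planted_sets_are_subsets_of_universe(self, default_config):
        truth = plant_truth(default_config)
        universe = set(truth.genes)
        assert truth.de_genes <= universe
        assert truth.planted_clique <= universe
        assert len(truth.hub_genes) == default_config.n_hub_genes
        # FFL edges respect roles by construction
        types = {t for _, _, t in truth.planted_ffl.edges}
        assert types == {"miRNA-gene", "miRNA-TF", "TF-gene"}


class TestPairedExpression:
    def test_determinism_identical_seeds(self):
        cfg = small_config()
        ds1, _ = simulate_paired_expression(cfg)
        ds2, _ = simulate_paired_expression(cfg)
        for a, b in zip(ds1, ds2):
            assert a.expr.to_csv() == b.expr.to_csv()
            assert a.samples.to_csv() == b.samples.to_csv()

    def test_each_subject_paired(self):
        ds, _ = simulate_paired_expression(small_config())
        for d in ds:
            counts = d.samples.groupby(["subject_id", "condition"]).size()
            assert (counts == 1).all()

    def test_null_effect_means_no_shift(self):
        cfg = small_config(de_effect=0.0, n_pairs_per_dataset=(50,))
        ds, truth = simulate_paired_expression(cfg)
        d = ds[0]
        tumor, normal = d.paired_columns()
        diffs = d.expr[tumor].to_numpy() - d.expr[normal].to_numpy()
        de_idx = [i for i, g in enumerate(d.expr.index) if g in truth.de_genes]
        # genes share latent factors, so the independent unit is the subject
        per_subject = diffs[de_idx].mean(axis=0)
        mean = per_subject.mean()
        se = per_subject.std(ddof=1) / np.sqrt(per_subject.size)
        assert abs(mean) < 3 * se + 1e-12

    def test_de_shift_matches_effect(self):
        cfg = small_config(de_effect=2.0, n_pairs_per_dataset=(200,))
        ds, truth = simulate_paired_expression(cfg)
        d = ds[0]
        tumor, normal = d.paired_columns()
        diffs = pd.DataFrame(
            d.expr[tumor].to_numpy() - d.expr[normal].to_numpy(), index=d.expr.index
        ).mean(axis=1)
        up_mean = diffs[sorted(truth.de_genes_up)].mean()
        down_mean = diffs[sorted(truth.de_genes_down)].mean()
        assert up_mean == pytest.approx(2.0, abs=0.3)
        assert down_mean == pytest.approx(-2.0, abs=0.3)

    def test_module_correlation_separation(self):
        cfg = small_config(
            factor_loading=0.9, noise_sd=0.2, de_effect=0.0, n_pairs_per_dataset=(100,)
        )
        ds, truth = simulate_paired_expression(cfg)
        expr = ds[0].expr
        corr = np.abs(np.corrcoef(expr.to_numpy()))
        genes = list(expr.index)
        mod = np.array([truth.module_assignment.get(g, "bg") for g in genes])
        within, between = [], []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if mod[i] == "bg" or mod[j] == "bg":
                    continue
                (within if mod[i] == mod[j] else between).append(corr[i, j])
        assert np.mean(within) - np.mean(between) > 0.4


class TestPPIGraph:
    def test_clique_edges_only_when_no_background(self):
        cfg = small_config(ppi_clique_size=5)
        truth = plant_truth(cfg)
        edges = simulate_ppi_graph(truth, n_background=0, background_edge_prob=0.0, seed=1)
        supra = edges[edges["combined_score"] > 0.9]
        assert len(supra) == 10  # C(5,2)
        nodes = set(supra["protein1"]) | set(supra["protein2"])
        assert nodes == truth.planted_clique

    def test_determinism(self, default_config):
        truth = plant_truth(default_config)
        e1 = simulate_ppi_graph(truth, seed=3)
        e2 = simulate_ppi_graph(truth, seed=3)
        assert e1.to_csv() == e2.to_csv()

    def test_tiny_clique_rejected(self, default_config):
        truth = plant_truth(default_config)
        truth.planted_clique = set(list(truth.planted_clique)[:2])
        with pytest.raises(ValueError):
            simulate_ppi_graph(truth, seed=0)


class TestGenesets:
    def test_planted_terms_contain_hubs(self, default_config):
        truth = plant_truth(default_config)
        libs = simulate_genesets(truth, seed=2)
        planted = [
            genes
            for lib in libs.values()
            for name, genes in lib.items()
            if name.startswith("PLANTED")
        ]
        assert len(planted) >= 2
        for genes in planted:
            assert truth.hub_genes <= genes

    def test_planted_overlap_is_significant_closed_form(self, default_config):
        from oracles import hypergeom_upper_tail

        # 5/5 hub overlap for a 10-gene term, 12-gene query, 300-gene universe
        p = hypergeom_upper_tail(300, 10, 12, 5)
        assert p < 0.001

    def test_determinism(self, default_config):
        truth = plant_truth(default_config)
        a = simulate_genesets(truth, seed=5)
        b = simulate_genesets(truth, seed=5)
        assert a == b


class TestRegulatoryTables:
    def test_planted_only_without_decoys(self, default_config):
        from coexffl import ffl as fl

        truth = plant_truth(default_config)
        reg = simulate_regulatory_tables(truth, n_decoys=0, seed=4)
        filtered = fl.filter_edges(reg.human_tables)
        screened = fl.two_tier_screen(filtered, reg.tier1, reg.mouse_tables)
        net = fl.assemble_network(screened)
        assert (net.n_nodes, net.n_edges) == (4, 5)

    def test_mirna_missing_from_mouse_is_dropped(self, default_config):
        from coexffl import ffl as fl

        truth = plant_truth(default_config)
        reg = simulate_regulatory_tables(truth, n_decoys=0, seed=4)
        filtered = fl.filter_edges(reg.human_tables)
        empty_mouse = [t.iloc[0:0] for t in reg.mouse_tables]
        screened = fl.two_tier_screen(filtered, reg.tier1, empty_mouse)
        net = fl.assemble_network(screened)
        assert truth.planted_ffl.mirna not in set(net.graph.nodes)

    def test_decoy_collision_rejected(self, default_config):
        truth = plant_truth(default_config)
        truth.planted_ffl = FFLSpec(mirna="DECOY-mir", tfs=("TF01", "TF02"), gene=truth.planted_ffl.gene)
        with pytest.raises(ValueError):
            simulate_regulatory_tables(truth, seed=0)

    def test_determinism(self, default_config):
        truth = plant_truth(default_config)
        a = simulate_regulatory_tables(truth, seed=9)
        b = simulate_regulatory_tables(truth, seed=9)
        assert a.mirna_gene.to_csv() == b.mirna_gene.to_csv()
        assert a.tier1 == b.tier1


class TestSurvival:
    def test_no_censoring_means_all_events(self, default_config):
        truth = plant_truth(default_config)
        t = simulate_survival(truth, n_subjects=50, censor_rate=0.0, seed=1, hazard_coeff=0.5)
        assert (t["event"] == 1).all()

    def test_censor_rate_roughly_respected(self, default_config):
        truth = plant_truth(default_config)
        t = simulate_survival(truth, n_subjects=2000, censor_rate=0.3, seed=1, hazard_coeff=0.0)
        assert (t["event"] == 0).mean() == pytest.approx(0.3, abs=0.04)

    def test_bad_arguments_raise(self, default_config):
        truth = plant_truth(default_config)
        with pytest.raises(ValueError):
            simulate_survival(truth, baseline_scale=-1.0, seed=0, hazard_coeff=0.1)
        with pytest.raises(ValueError):
            simulate_survival(truth, n_subjects=5, seed=0, hazard_coeff=0.1)
        with pytest.raises(ValueError):
            simulate_survival(truth, seed=0, hazard_coeff=None)

    def test_determinism(self, default_config):
        truth = plant_truth(default_config)
        a = simulate_survival(truth, seed=6, hazard_coeff=0.7)
        b = simulate_survival(truth, seed=6, hazard_coeff=0.7)
        assert a.to_csv() == b.to_csv()
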