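"""Prioritization and validation statistics: known genes, directionality,
neighbor shells, gene-trait correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from netmsea.containers import GeneSetCollection, WeightedNetwork
from netmsea.msea import EnrichmentConfig
from netmsea.postnet import (bfs_shells, gene_trait_validation,
                             infer_direction, known_gene_enrichment,
                             neighbor_level_overlap, sign_concordance_test)
from netmsea.synth import simulate_gene_stats

from test_annotate import hypergeom_tail_oracle


class TestKnownGeneEnrichment:
    def test_hand_computed_fold(self):
        universe = [f"g{i}" for i in range(1000)]
        subnet = set(universe[:10]) | set(universe[500:510])   # 20 genes
        catalog = set(universe[:10]) | set(universe[800:820])  # 30 genes
        fold, p = known_gene_enrichment(subnet, catalog, universe)
        assert fold == pytest.approx((10 / 20) / (30 / 1000), abs=1e-12)
        assert fold == pytest.approx(16.667, abs=5e-4)
        assert p == pytest.approx(hypergeom_tail_oracle(10, 1000, 30, 20),
                                  abs=1e-12)

    def test_catalog_equals_universe(self):
        universe = [f"g{i}" for i in range(100)]
        fold, p = known_gene_enrichment(set(universe[:20]), set(universe),
                                        universe)
        assert fold == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            known_gene_enrichment(set(), set(), [])


def make_gwas(markers, betas, ea, oa):
    return pd.DataFrame({"marker_id": markers, "beta": betas,
                         "effect_allele": ea, "other_allele": oa,
                         "p_value": 0.5})


def mapping_for(gene, markers):
    return pd.DataFrame({"marker_id": markers, "gene_id": gene,
                         "scheme": "eqtl", "tissue": ""})


class TestInferDirection:
    def test_all_concordant(self):
        markers = [f"m{i}" for i in range(20)]
        betas = np.linspace(0.1, 1.0, 20)
        a = make_gwas(markers, betas, "A", "G")
        b = make_gwas(markers, betas * 0.5, "A", "G")
        call = infer_direction("g1", a, b,
                               {"eqtl": mapping_for("g1", markers)})
        assert call.prop_concordant == 1.0
        assert call.z == pytest.approx(0.5 / math.sqrt(0.25 / 20), abs=1e-9)
        assert call.z == pytest.approx(4.472, abs=5e-4)
        assert call.call == "consistent"

    def test_half_concordant_uncertain(self):
        markers = [f"m{i}" for i in range(20)]
        betas = np.ones(20)
        flip = np.ones(20)
        flip[:10] = -1
        a = make_gwas(markers, betas, "A", "G")
        b = make_gwas(markers, flip, "A", "G")
        call = infer_direction("g1", a, b,
                               {"eqtl": mapping_for("g1", markers)})
        assert call.z == 0.0 and call.call == "uncertain"

    def test_allele_swap_harmonized(self):
        markers = [f"m{i}" for i in range(20)]
        betas = np.linspace(0.1, 1.0, 20)
        a = make_gwas(markers, betas, "A", "G")
        # study b reports the other allele: betas negated, alleles swapped
        b = make_gwas(markers, -betas, "G", "A")
        call = infer_direction("g1", a, b,
                               {"eqtl": mapping_for("g1", markers)})
        assert call.prop_concordant == 1.0 and call.call == "consistent"

    def test_irreconcilable_alleles_dropped(self):
        a = make_gwas(["m1", "m2"], [1.0, 1.0], "A", "G")
        b = make_gwas(["m1", "m2"], [1.0, 1.0], ["A", "C"], ["G", "T"])
        call = infer_direction("g1", a, b,
                               {"eqtl": mapping_for("g1", ["m1", "m2"])})
        assert call.n_variants == 1

    def test_no_variants_uncertain(self):
        a = make_gwas([], [], [], [])
        call = infer_direction("g1", a, a, {"eqtl": mapping_for("g1", [])})
        assert call.call == "uncertain" and call.n_variants == 0

    def test_swap_invariance_of_call_class(self):
        rng = np.random.default_rng(77)
        markers = [f"m{i}" for i in range(30)]
        for _ in range(25):
            beta_a = rng.normal(size=30)
            agree = rng.random(30) < rng.choice([0.05, 0.5, 0.95])
            beta_b = np.where(agree, np.sign(beta_a),
                              -np.sign(beta_a)) * np.abs(rng.normal(size=30))
            a = make_gwas(markers, beta_a, "A", "G")
            b = make_gwas(markers, beta_b, "A", "G")
            mp = {"eqtl": mapping_for("g1", markers)}
            ab = infer_direction("g1", a, b, mp)
            ba = infer_direction("g1", b, a, mp)
            assert ab.call == ba.call

    def test_random_signs_mostly_uncertain(self):
        rng = np.random.default_rng(101)
        markers = [f"m{i}" for i in range(20)]
        uncertain = 0
        n_rep = 50
        for _ in range(n_rep):
            beta_a = rng.normal(size=20)
            beta_b = rng.normal(size=20)
            a = make_gwas(markers, beta_a, "A", "G")
            b = make_gwas(markers, beta_b, "A", "G")
            call = infer_direction("g1", a, b,
                                   {"eqtl": mapping_for("g1", markers)})
            uncertain += call.call == "uncertain"
        assert uncertain / n_rep >= 0.9


def test_sign_concordance_z_formula():
    p_hat, z, p = sign_concordance_test(np.ones(16), np.ones(16))
    assert p_hat == 1.0 and z == pytest.approx(0.5 / math.sqrt(0.25 / 16))


class TestNeighborShells:
    def chain_net(self):
        # kd - a - b - c - d plus side branches
        edges = [("kd", "a", 1.0), ("a", "b", 1.0), ("b", "c", 1.0),
                 ("c", "d", 1.0), ("kd", "a2", 1.0), ("a2", "b2", 1.0)]
        return WeightedNetwork.from_edges(edges, tissue="t")

    def test_shells_partition_reachable_nodes(self):
        net = self.chain_net()
        shells = bfs_shells(net, "kd", 4)
        all_nodes = [n for nodes in shells.values() for n in nodes]
        assert len(all_nodes) == len(set(all_nodes))
        assert set(all_nodes) | {"kd"} == set(net.nodes)
        assert shells[1] == ["a", "a2"]
        assert shells[2] == ["b", "b2"]

    def test_deg_equals_universe_fold_one(self):
        net = self.chain_net()
        out = neighbor_level_overlap(net, "kd", set(net.nodes),
                                     net.nodes, max_level=2)
        valid = out.dropna()
        assert (valid["fold"] == 1.0).all()
        assert (valid["p_value"] == 1.0).all()

    def test_max_level_one_bonferroni_equals_p(self):
        net = self.chain_net()
        out = neighbor_level_overlap(net, "kd", {"a"}, net.nodes,
                                     max_level=1)
        assert out.iloc[0]["bonferroni_p"] == pytest.approx(
            out.iloc[0]["p_value"])

    def test_planted_first_shell_signal(self):
        # level 1 heavily DEG-enriched, levels 3-4 at background
        rng = np.random.default_rng(15)
        edges = []
        universe = []
        deg = set()
        for i in range(20):
            n1 = f"s1_{i}"
            edges.append(("kd", n1, 1.0))
            universe.append(n1)
            if i < 16:
                deg.add(n1)  # 80% of shell 1
        prev = [f"s1_{i}" for i in range(20)]
        for level in (2, 3, 4):
            cur = []
            for i in range(20):
                n = f"s{level}_{i}"
                edges.append((prev[i], n, 1.0))
                universe.append(n)
                if rng.random() < 0.1:
                    deg.add(n)
            prev = cur or [f"s{level}_{i}" for i in range(20)]
        universe += [f"bg{i}" for i in range(400)]
        deg |= {f"bg{i}" for i in range(40)}  # 10% background rate
        net = WeightedNetwork.from_edges(edges, tissue="t")
        out = neighbor_level_overlap(net, "kd", deg, universe, max_level=4)
        assert out.iloc[0]["bonferroni_p"] < 0.05
        assert out.iloc[2]["bonferroni_p"] > 0.05
        assert out.iloc[3]["bonferroni_p"] > 0.05

    def test_disconnected_levels_reported_empty(self):
        net = WeightedNetwork.from_edges([("kd", "a", 1.0)], tissue="t")
        out = neighbor_level_overlap(net, "kd", {"a"}, ["kd", "a"],
                                     max_level=3)
        assert out.iloc[1]["n_genes"] == 0 and np.isnan(
            out.iloc[1]["p_value"])


class TestGeneTraitValidation:
    def test_constant_expression_untested(self):
        corr = pd.DataFrame({"gene_id": ["kd1"], "trait": ["t1"],
                             "r": [np.nan], "p_value": [np.nan]})
        subnets = GeneSetCollection()
        kd_report, _ = gene_trait_validation(corr, ["kd1"], subnets)
        assert kd_report.iloc[0]["status"] == "untested"

    def test_absent_kd_untested(self):
        corr = pd.DataFrame({"gene_id": ["other"], "trait": ["t1"],
                             "r": [0.5], "p_value": [0.01]})
        kd_report, _ = gene_trait_validation(corr, ["kd1"],
                                             GeneSetCollection())
        assert kd_report.iloc[0]["status"] == "untested"

    def test_planted_signal_subnet_significant(self):
        universe = [f"g{i:04d}" for i in range(400)]
        signal = set(universe[:40])
        corr, _, _ = simulate_gene_stats(universe, signal, effect=1.0,
                                         n_strains=100, seed=23)
        subnets = GeneSetCollection({"planted": sorted(signal),
                                     "random": universe[200:240]})
        cfg = EnrichmentConfig(quantile_points=(0.5, 0.8, 0.9, 0.95),
                               n_perm=300, seed=2)
        kd_report, subnet_report = gene_trait_validation(
            corr, ["g0000"], subnets, cfg)
        res = subnet_report.set_index("set_id")
        assert res.loc["planted", "p_value"] < 0.01
        assert res.loc["planted", "p_value"] < res.loc["random", "p_value"]
        assert kd_report.iloc[0]["status"] == "tested"
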