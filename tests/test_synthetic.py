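"""Synthetic-data generators: determinism, validation, planted structure."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from myonet import (
    SyntheticConfig,
    generate_annotations,
    generate_compendium,
    generate_network,
    hypergeom_overlap,
)


class TestConfigValidation:
    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SyntheticConfig(cluster_partition=((0, 1), (1, 2)))

    def test_out_of_range_disease_index_rejected(self):
        with pytest.raises(ValueError, match="range"):
            SyntheticConfig(n_diseases=3, cluster_partition=((0, 5),))

    def test_effect_genes_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SyntheticConfig(n_genes=10, effect_genes_per_cluster=20)

    def test_bad_edge_probability_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            SyntheticConfig(p_within=1.5)

    def test_bad_score_range_rejected(self):
        with pytest.raises(ValueError, match="score_range"):
            SyntheticConfig(edge_score_range=(0.0, 0.5))

    def test_bad_overlap_fraction_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SyntheticConfig(disease_gene_overlap=1.2)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(n_genes=0)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SyntheticConfig(n_genes=120, effect_genes_per_cluster=10, samples_per_arm=4)
        s1, t1 = generate_compendium(cfg)
        s2, t2 = generate_compendium(cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.values.tobytes() == b.values.tobytes()
        assert t1.effect_gene_sets == t2.effect_gene_sets
        e1 = generate_network(cfg, t1)
        e2 = generate_network(cfg, t2)
        assert e1 == e2
        assert generate_annotations(cfg, t1) == generate_annotations(cfg, t2)

    def test_different_seeds_differ(self):
        c1 = SyntheticConfig(n_genes=120, effect_genes_per_cluster=10, seed=0)
        c2 = SyntheticConfig(n_genes=120, effect_genes_per_cluster=10, seed=1)
        s1, _ = generate_compendium(c1)
        s2, _ = generate_compendium(c2)
        assert not np.array_equal(s1[0].values, s2[0].values)


class TestCompendiumStructure:
    def test_planted_shift_appears_only_in_disease_arm(self):
        cfg = SyntheticConfig(
            n_genes=200,
            effect_genes_per_cluster=20,
            samples_per_arm=50,
            n_batches_per_disease=1,
            batch_sd=0.0,
            effect_size=2.0,
            seed=2,
        )
        studies, truth = generate_compendium(cfg)
        s = studies[0]
        program = truth.effect_gene_sets["cluster0"]
        sign = next(iter(program.values()))
        idx = [s.gene_ids.index(g) for g in program]
        d = s.arm_matrix("disease")[idx].mean()
        c = s.arm_matrix("control")[idx].mean()
        assert abs(c) < 0.3
        np.testing.assert_allclose(d - c, sign * 2.0, atol=0.3)

    def test_effect_genes_belong_to_exactly_one_program(self):
        cfg = SyntheticConfig(n_diseases=5, cluster_partition=((0, 1),), n_genes=400)
        _, truth = generate_compendium(cfg)
        seen = []
        for program in truth.effect_gene_sets.values():
            seen.extend(program)
        assert len(seen) == len(set(seen))
        # 1 cluster + 3 unclustered singleton programs
        assert len(truth.effect_gene_sets) == 4

    def test_null_t_statistics_follow_t_distribution(self):
        """With no planted effect, gene-wise Student t is t-distributed."""
        cfg = SyntheticConfig(
            n_diseases=1,
            cluster_partition=(),
            n_genes=10_000,
            effect_size=0.0,
            effect_genes_per_cluster=5,
            samples_per_arm=10,
            n_batches_per_disease=1,
            batch_sd=0.0,
            seed=5,
        )
        studies, _ = generate_compendium(cfg)
        s = studies[0]
        t = sps.ttest_ind(
            s.arm_matrix("disease"), s.arm_matrix("control"), axis=1, equal_var=True
        ).statistic
        ks = sps.kstest(t, sps.t(df=18).cdf)
        assert ks.pvalue > 0.01


class TestNetworkGeneration:
    def test_deterministic_cliques_when_p_within_one(self):
        cfg = SyntheticConfig(
            n_genes=200,
            network_n_nodes=8,
            network_module_sizes=(4, 4),
            p_within=1.0,
            p_between=0.0,
            align_modules_to_effects=False,
            seed=3,
        )
        _, truth = generate_compendium(cfg)
        edges = generate_network(cfg, truth)
        assert len(edges) == 2 * 6  # two 4-cliques
        m0, m1 = truth.planted_modules
        for a, b, s in edges:
            assert ({a, b} <= m0) or ({a, b} <= m1)
            assert 0.86 <= s <= 1.0

    def test_p_between_one_connects_everything(self):
        import networkx as nx

        cfg = SyntheticConfig(
            n_genes=200,
            network_n_nodes=12,
            network_module_sizes=(4, 4),
            p_within=1.0,
            p_between=1.0,
            align_modules_to_effects=False,
            seed=4,
        )
        _, truth = generate_compendium(cfg)
        edges = generate_network(cfg, truth)
        g = nx.Graph((a, b) for a, b, _ in edges)
        assert nx.number_connected_components(g) == 1

    def test_aligned_modules_subset_effect_programs(self):
        cfg = SyntheticConfig(seed=6)
        _, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        for k in range(2):
            assert truth.planted_modules[k] <= set(truth.effect_gene_sets[f"cluster{k}"])

    def test_impossible_sizes_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SyntheticConfig(network_n_nodes=5, network_module_sizes=(4, 4))


class TestAnnotations:
    def test_full_overlap_is_minimum_achievable_p(self):
        cfg = SyntheticConfig(disease_gene_overlap=1.0, seed=7)
        _, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        lists, _, _ = generate_annotations(cfg, truth)
        assert lists["D00"] == lists["D01"]  # identical intra-cluster lists
        universe = {f"G{i:04d}" for i in range(cfg.n_genes)}
        k, p = hypergeom_overlap(lists["D00"], lists["D01"], universe)
        assert k == len(lists["D00"])  # maximal overlap for these sizes
        k2, p2 = hypergeom_overlap(lists["D00"], lists["D03"], universe)
        assert p < p2

    def test_zero_overlap_between_clusters(self):
        cfg = SyntheticConfig(seed=8)
        _, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        lists, _, _ = generate_annotations(cfg, truth)
        assert lists["D00"] & lists["D03"] == set()

    def test_intra_cluster_overlap_fraction_respected(self):
        cfg = SyntheticConfig(disease_gene_overlap=0.5, seed=9)
        _, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        lists, _, _ = generate_annotations(cfg, truth)
        inter = lists["D00"] & lists["D01"]
        assert len(inter) == round(0.5 * cfg.disease_genes_per_disease)

    def test_module_targeted_drugs_enrich_module_genes(self):
        cfg = SyntheticConfig(drug_module_fraction=1.0, n_drugs=20, seed=10)
        _, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        _, _, drugs = generate_annotations(cfg, truth)
        module_genes = set().union(*truth.planted_modules)
        universe = {f"G{i:04d}" for i in range(cfg.n_genes)}
        targets = set().union(*(t for _, t, _ in drugs))
        assert targets <= module_genes
        _, p = hypergeom_overlap(module_genes, targets, universe)
        assert p < 0.05

    def test_functional_sets_in_gmt_shape(self):
        cfg = SyntheticConfig(seed=11)
        _, truth = generate_compendium(cfg)
        generate_network(cfg, truth)
        _, fms, _ = generate_annotations(cfg, truth)
        assert len(fms) == 23
        assert all(fms.values())


class TestWriters:
    def test_round_trip_through_text_formats(self, tmp_path):
        from myonet.functional import load_gene_sets
        from myonet.network import load_edges
        from myonet.preprocessing import load_study
        from myonet.synthetic import (
            write_edge_list,
            write_gmt_sets,
            write_study,
            write_truth,
        )

        cfg = SyntheticConfig(
            n_genes=80,
            effect_genes_per_cluster=8,
            samples_per_arm=3,
            disease_genes_per_disease=6,
            seed=12,
        )
        studies, truth = generate_compendium(cfg)
        edges = generate_network(cfg, truth)
        _, fms, _ = generate_annotations(cfg, truth)

        write_study(studies[0], tmp_path / "e.tsv", tmp_path / "s.tsv")
        back = load_study(tmp_path / "e.tsv", tmp_path / "s.tsv")
        assert back.disease_id == studies[0].disease_id
        np.testing.assert_allclose(back.values, studies[0].values, rtol=1e-10)

        write_edge_list(edges, tmp_path / "edges.tsv")
        net = load_edges(tmp_path / "edges.tsv", threshold=0.85)
        expect = {(min(a, b), max(a, b)) for a, b, s in edges if s > 0.85}
        assert {(a, b) for a, b, _ in net.edges} == expect

        write_gmt_sets(fms, tmp_path / "fm.gmt")
        assert load_gene_sets(tmp_path / "fm.gmt").modules == {
            k: frozenset(v) for k, v in fms.items()
        }

        write_truth(truth, tmp_path / "truth.json")
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert set(payload["cluster_labels"]) == {f"D{i:02d}" for i in range(6)}
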