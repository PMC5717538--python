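"""Partial correlation, permutation nulls, p-values, and disease clustering."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch

from myonet import (
    NullStore,
    cluster_diseases,
    complete_linkage,
    pair_pvalues,
    partial_correlation,
    permutation_null,
    similarity_analysis,
)
from myonet.similarity import STAT_MODULE, STAT_PCOR, _shuffle_arms, cut_tree


def _pcor_via_residuals(X, i, j):
    """Oracle: correlate the residuals of i and j regressed on the rest."""
    others = [k for k in range(X.shape[1]) if k not in (i, j)]
    Z = np.column_stack([X[:, others], np.ones(len(X))])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


class TestPartialCorrelation:
    def test_two_variables_equal_plain_pearson(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        pc = partial_correlation(X)
        np.testing.assert_allclose(pc[0, 1], np.corrcoef(X.T)[0, 1], atol=1e-12)

    def test_three_variable_recursion_oracle(self):
        """Matches r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            X = rng.normal(size=(30, 3)) + 0.5 * rng.normal(size=(30, 1))
            r = np.corrcoef(X.T)
            expect = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
                (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
            )
            np.testing.assert_allclose(partial_correlation(X)[0, 1], expect, atol=1e-10)

    def test_regression_residual_oracle_up_to_six_variables(self):
        rng = np.random.default_rng(2)
        for k in (3, 4, 5, 6):
            for _ in range(25):
                X = rng.normal(size=(40, k)) + 0.3 * rng.normal(size=(40, 1))
                pc = partial_correlation(X)
                i, j = rng.choice(k, size=2, replace=False)
                np.testing.assert_allclose(
                    pc[i, j], _pcor_via_residuals(X, i, j), atol=1e-8
                )

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(3)
        pc = partial_correlation(rng.normal(size=(40, 5)))
        np.testing.assert_array_equal(np.diag(pc), 1.0)
        np.testing.assert_allclose(pc, pc.T, atol=1e-15)
        assert np.all(np.abs(pc) <= 1.0)

    def test_duplicated_column_names_offenders(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, rng.normal(size=50)])
        with pytest.raises(np.linalg.LinAlgError, match=r"\(0, 1\)"):
            partial_correlation(X)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(X)

    def test_more_variables_than_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            partial_correlation(np.ones((3, 5)))


class TestPermutationNull:
    def test_same_seed_identical_store(self, prepared_studies, reg_params):
        a = permutation_null(prepared_studies, reg_params, n_perm=3, seed=5)
        b = permutation_null(prepared_studies, reg_params, n_perm=3, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seed_differs(self, prepared_studies, reg_params):
        a = permutation_null(prepared_studies, reg_params, n_perm=2, seed=5)
        b = permutation_null(prepared_studies, reg_params, n_perm=2, seed=6)
        assert not np.array_equal(a.values, b.values)

    def test_shuffle_preserves_arm_sizes_within_each_study(self, prepared_studies):
        rng = np.random.default_rng(0)
        shuffled = _shuffle_arms(prepared_studies, rng)
        for orig, perm in zip(prepared_studies, shuffled):
            for arm in ("disease", "control"):
                assert np.sum(perm.arms == arm) == np.sum(orig.arms == arm)

    def test_default_permutation_count_is_100(self):
        import inspect

        assert inspect.signature(permutation_null).parameters["n_perm"].default == 100

    def test_unknown_statistic_rejected(self, prepared_studies, reg_params):
        with pytest.raises(ValueError, match="statistic"):
            permutation_null(prepared_studies, reg_params, 1, 0, statistic="bogus")

    def test_null_correlations_centered_near_zero(self, prepared_studies, reg_params):
        store = permutation_null(prepared_studies, reg_params, n_perm=40, seed=2)
        assert abs(store.pooled().mean()) < 0.05


class TestPairPvalues:
    def _store(self, values):
        return NullStore(
            statistic=STAT_PCOR, values=np.asarray(values, float), disease_ids=["a", "b"]
        )

    def test_observed_above_all_null(self):
        store = self._store([np.linspace(-0.5, 0.5, 99)])
        p = pair_pvalues(np.array([[1.0, 0.9], [0.9, 1.0]]), store)
        np.testing.assert_allclose(p[0, 1], 1.0 / 100.0, atol=1e-12)

    def test_observed_below_all_null(self):
        store = self._store([np.linspace(-0.5, 0.5, 99)])
        p = pair_pvalues(np.array([[1.0, -0.9], [-0.9, 1.0]]), store)
        np.testing.assert_allclose(p[0, 1], 1.0, atol=1e-12)

    def test_raw_count_variant_can_reach_zero(self):
        store = self._store([np.linspace(-0.5, 0.5, 100)])
        p = pair_pvalues(np.array([[1.0, 0.9], [0.9, 1.0]]), store, smooth=False)
        assert p[0, 1] == 0.0

    def test_monotone_decreasing_in_observed_value(self):
        rng = np.random.default_rng(1)
        store = self._store(rng.normal(0, 0.2, size=(10, 50)))
        obs = np.linspace(-1, 1, 21)
        pc = np.eye(21)
        pc[0, :] = pc[:, 0] = obs  # abuse row 0 as a sweep
        p = pair_pvalues(pc, store)
        assert np.all(np.diff(p[0, 1:]) <= 0)

    def test_in_unit_interval(self, prepared_studies, reg_params):
        from myonet import dga_matrix

        store = permutation_null(prepared_studies, reg_params, n_perm=10, seed=0)
        pc = partial_correlation(dga_matrix(prepared_studies, reg_params).scores)
        p = pair_pvalues(pc, store)
        assert np.all((p > 0) & (p <= 1))


class TestClustering:
    def test_complete_linkage_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 10)
            X = rng.normal(size=(n, 3))
            d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            ours = complete_linkage(d)
            ref = sch.linkage(d[np.triu_indices(n, k=1)], method="complete")
            np.testing.assert_allclose(ours[:, 2], ref[:, 2], atol=1e-10)
            for t in (0.5, 1.0, 2.0):
                a = cut_tree(ours, t, n)
                # unclustered singletons carry label 0: make them distinct
                a = [lab if lab != 0 else -(i + 1) for i, lab in enumerate(a)]
                b = sch.fcluster(ref, t, criterion="distance")
                from sklearn.metrics import adjusted_rand_score

                assert adjusted_rand_score(a, b) == 1.0

    def test_linkage_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        Z = complete_linkage(d)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def _two_block_pcor(self):
        pc = np.zeros((6, 6))
        for block in ((0, 1, 2), (3, 4, 5)):
            for i in block:
                for j in block:
                    pc[i, j] = 1.0
        return pc

    def test_two_perfect_blocks_give_two_clusters(self):
        store = NullStore(
            statistic=STAT_PCOR,
            values=np.random.default_rng(0).uniform(-0.3, 0.3, size=(100, 15)),
            disease_ids=list("abcdef"),
        )
        _, labels, _ = cluster_diseases(self._two_block_pcor(), store, alpha=0.05)
        assert labels[0] == labels[1] == labels[2] != labels[3]
        assert labels[3] == labels[4] == labels[5]

    def test_alpha_monotonicity_of_partition_blocks(self):
        rng = np.random.default_rng(2)
        pc = self._two_block_pcor() * 0.6 + np.eye(6) * 0.4
        store = NullStore(
            statistic=STAT_PCOR,
            values=rng.uniform(-0.8, 0.8, size=(50, 15)),
            disease_ids=list("abcdef"),
        )
        counts = []
        for alpha in (0.3, 0.1, 0.05, 0.01):
            _, labels, _ = cluster_diseases(pc, store, alpha=alpha)
            n_singletons = sum(1 for v in labels.values() if v == 0)
            n_clusters = len({v for v in labels.values() if v != 0})
            counts.append(n_clusters + n_singletons)
        assert np.all(np.diff(counts) >= 0)  # cut shrinks, partition refines

    def test_invalid_alpha_rejected(self):
        store = NullStore(STAT_PCOR, np.zeros((1, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="alpha"):
            cluster_diseases(np.eye(3), store, alpha=1.5)

    def test_planted_partition_recovered(self, prepared_studies, small_compendium, reg_params):
        _, truth = small_compendium
        res = similarity_analysis(prepared_studies, reg_params, n_perm=40, seed=0)
        from sklearn.metrics import adjusted_rand_score

        ids = res.disease_ids
        assert adjusted_rand_score(
            truth.partition_labels(ids), [res.clusters[d] for d in ids]
        ) == 1.0
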