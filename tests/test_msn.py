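"""Unit and property tests for MSN construction and graph metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msnpred import msn
from msnpred.lexicon import dk_regions, n_possible_edges

from conftest import random_network


class TestZScore:
    def test_hand_computed_column(self):
        # column (2,4,6,8): mean 5, sample SD sqrt(20/3) = 2.5820
        x = np.column_stack([[2.0, 4.0, 6.0, 8.0], [1.0, 0.0, 2.0, 5.0]])
        z = msn.zscore_within_subject(x)
        expected = np.array([-1.161895, -0.387298, 0.387298, 1.161895])
        np.testing.assert_allclose(z[:, 0], expected, atol=1e-6)

    def test_columns_standardized(self, rng):
        z = msn.zscore_within_subject(rng.standard_normal((68, 7)))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.standard_normal((30, 4))
        z = msn.zscore_within_subject(x)
        np.testing.assert_allclose(msn.zscore_within_subject(z), z, atol=1e-12)

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 1] = 7.0
        with pytest.raises(msn.ZeroVarianceError):
            msn.zscore_within_subject(x)


class TestBuildMSN:
    def test_identical_vectors_give_unit_edge(self):
        z = np.vstack([[1, 2, 3, 4, 5, 6, 7]] * 2 + [[2, 1, 4, 3, 6, 5, 8]])
        net = msn.build_msn(np.asarray(z, float))
        assert net.matrix[0, 1] == pytest.approx(1.0)

    def test_reversed_vector_gives_minus_one(self):
        z = np.array([[1, 2, 3, 4, 5, 6, 7], [7, 6, 5, 4, 3, 2, 1],
                      [2, 1, 4, 3, 6, 5, 8]], float)
        net = msn.build_msn(z)
        assert net.matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        a = np.array([1, 2, 3, 4, 5, 6, 7], float)
        b = np.array([2, 1, 4, 3, 6, 5, 8], float)
        net = msn.build_msn(np.vstack([a, b, a * 0.5 + 1.7]))
        # brute-force Pearson on the pair
        am, bm = a - a.mean(), b - b.mean()
        r = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert net.matrix[0, 1] == pytest.approx(r, abs=1e-12)

    def test_symmetric_zero_diagonal_bounded(self, rng):
        net = random_network(rng, n=68)
        m = net.matrix
        np.testing.assert_allclose(m, m.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(m), 0.0)
        assert np.all(np.abs(m) <= 1.0)

    def test_degenerate_region_zeroed_with_warning(self, rng):
        z = rng.standard_normal((6, 7))
        z[2] = 0.3  # constant feature vector: correlation undefined
        with pytest.warns(RuntimeWarning):
            net = msn.build_msn(z)
        assert np.all(net.matrix[2] == 0)
        with pytest.raises(msn.ZeroVarianceError):
            msn.build_msn(z, on_degenerate="error")

    def test_population_vs_sample_sd_zscoring_equivalent(self, rng):
        """Pearson correlation is invariant to a common column rescaling."""
        x = rng.standard_normal((68, 7))
        n1 = msn.build_msn(msn.zscore_within_subject(x, ddof=1))
        n0 = msn.build_msn(msn.zscore_within_subject(x, ddof=0))
        np.testing.assert_allclose(n1.matrix, n0.matrix, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        x = rng.standard_normal((12, 7))
        perm = rng.permutation(12)
        net = msn.build_msn(msn.zscore_within_subject(x))
        net_p = msn.build_msn(msn.zscore_within_subject(x[perm]))
        np.testing.assert_allclose(net_p.matrix, net.matrix[np.ix_(perm, perm)],
                                   atol=1e-12)


class TestThresholding:
    def test_density_one_is_identity(self, rng):
        net = random_network(rng, n=68)
        thr = msn.threshold_by_density(net, 1.0)
        np.testing.assert_allclose(thr.matrix, net.matrix)
        assert thr.retained_edge_count == 2278

    def test_exact_edge_counts_at_standard_densities(self, rng):
        net = random_network(rng, n=68)
        for d, expected in [(0.35, 797), (0.05, 114), (0.40, 911)]:
            assert expected == int(np.rint(d * n_possible_edges(68)))
            assert msn.threshold_by_density(net, d).retained_edge_count == expected

    def test_tied_weights_resolved_deterministically(self):
        regions = dk_regions()
        m = np.full((68, 68), 0.5)
        np.fill_diagonal(m, 0.0)
        net = msn.MSNetwork("s", regions, m)
        t1 = msn.threshold_by_density(net, 0.5)
        t2 = msn.threshold_by_density(net, 0.5)
        assert t1.retained_edge_count == 1139  # round(0.5 * 2278)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)

    def test_out_of_range_density_rejected(self, rng):
        net = random_network(rng)
        for d in (0.0, -0.1, 1.3):
            with pytest.raises(ValueError):
                msn.threshold_by_density(net, d)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), d1=st.floats(0.05, 0.95))
    def test_edge_sets_nested_across_densities(self, seed, d1):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n=20)
        d2 = min(1.0, d1 + 0.2)
        lo = msn.threshold_by_density(net, d1).matrix != 0
        hi = msn.threshold_by_density(net, d2).matrix != 0
        assert np.all(hi[lo])  # every low-density edge survives at high density


class TestNodalMetrics:
    def _toy_net(self):
        # 4 nodes, edges {(0,1), (0,2), (2,3)} with weights .6, -.2, .9
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.6
        m[0, 2] = m[2, 0] = -0.2
        m[2, 3] = m[3, 2] = 0.9
        return msn.MSNetwork("t", ("a", "b", "c", "d"), m)

    def test_degree_hand_count(self):
        np.testing.assert_array_equal(msn.nodal_degree(self._toy_net()), [2, 1, 2, 1])

    def test_degree_complete_and_empty_graphs(self, rng):
        full = random_network(rng, n=68)
        assert np.all(msn.nodal_degree(full) == 67)
        empty = msn.MSNetwork("e", ("a", "b"), np.zeros((2, 2)))
        assert np.all(msn.nodal_degree(empty) == 0)

    def test_strength_uses_absolute_weights(self):
        s = msn.nodal_strength_normalized(self._toy_net())
        assert s[0] == pytest.approx((0.6 + 0.2) / 2)  # |+0.6|, |-0.2|
        assert s[1] == pytest.approx(0.6)

    def test_isolated_node_strength_zero(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.4
        s = msn.nodal_strength_normalized(msn.MSNetwork("i", ("a", "b", "c"), m))
        assert s[2] == 0.0

    def test_unit_weights_give_unit_strength(self):
        m = 1.0 - np.eye(4)
        s = msn.nodal_strength_normalized(msn.MSNetwork("u", tuple("abcd"), m))
        np.testing.assert_allclose(s, 1.0)

    def test_strength_times_degree_equals_abs_weight_sum(self, rng):
        net = random_network(rng, n=30, density=0.3)
        deg = msn.nodal_degree(net)
        s = msn.nodal_strength_normalized(net)
        np.testing.assert_allclose(s * deg, np.abs(net.matrix).sum(axis=1), atol=1e-12)

    def test_global_mean_strength_is_arithmetic_mean(self, rng):
        strengths = rng.random(68)
        assert msn.global_mean_strength(strengths) == pytest.approx(strengths.mean())

    def test_degree_sum_twice_edge_count(self, rng):
        net = random_network(rng, n=25, density=0.2)
        assert msn.nodal_degree(net).sum() == 2 * net.retained_edge_count


def test_metrics_pipeline_shapes(small_cohort):
    spec, features, _ = small_cohort
    values = features.to_numpy().reshape(40, 68, 7)
    metrics = msn.metrics_from_features(values, list(features.index),
                                        spec.regions, 0.35)
    assert metrics.degree.shape == (40, 68)
    assert metrics.strength.shape == (40, 68)
    assert (metrics.degree.sum(axis=1) == 2 * 797).all()
    assert metrics.global_strength.between(0, 1).all()
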