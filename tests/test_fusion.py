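"""Kernel construction, KCCA solving and entropy-weighted fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammofuse.features import FeatureMatrix
from mammofuse.fusion import (
    center_kernel, fuse, gaussian_kernel, linear_kernel, median_bandwidth,
    shannon_entropy, solve_kcca,
)
from mammofuse.synthetic import generate_correlated_pair
from test_synthetic import first_canonical_correlation


class TestGaussianKernel:
    def test_unit_diagonal_and_symmetry(self):
        F = np.random.default_rng(0).random((10, 4))
        K = gaussian_kernel(F, sigma=0.7)
        assert np.allclose(np.diag(K.values), 1.0)
        assert np.allclose(K.values, K.values.T)

    def test_closed_form_off_diagonal(self):
        # rows (0,0) and (1,1), sigma=1: exp(-2 / 2) = exp(-1)
        K = gaussian_kernel(np.array([[0.0, 0.0], [1.0, 1.0]]), sigma=1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_large_bandwidth_limit(self):
        F = np.random.default_rng(1).random((6, 3))
        K = gaussian_kernel(F, sigma=1e6)
        assert K.values == pytest.approx(np.ones((6, 6)), abs=1e-9)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.eye(3), sigma=0.0)


class TestCentering:
    def test_all_ones_kernel_centers_to_zero(self):
        from mammofuse.fusion import KernelMatrix
        K = center_kernel(KernelMatrix(np.ones((5, 5))))
        assert K.values == pytest.approx(np.zeros((5, 5)), abs=1e-12)

    def test_row_means_vanish_and_idempotence(self):
        F = np.random.default_rng(2).random((8, 3))
        K = center_kernel(gaussian_kernel(F, 1.0))
        assert np.abs(K.values.mean(axis=0)).max() < 1e-10
        K2 = center_kernel(K)
        assert K2.values == pytest.approx(K.values, abs=1e-12)


class TestSolveKcca:
    def test_identical_kernels_give_unit_correlation(self):
        F = np.random.default_rng(3).random((30, 4))
        K = center_kernel(gaussian_kernel(F, 1.0))
        sol = solve_kcca(K, K, reg=1e-6)
        assert sol.rho == pytest.approx(1.0, abs=1e-3)

    def test_linear_kernel_hook_matches_classical_cca(self):
        """With plain Gram kernels the solver must reproduce classical
        linear CCA to 1e-3 (dual-route check against QR+SVD)."""
        pair = generate_correlated_pair(80, 5, 5, 0.6, seed=2)
        Ku = center_kernel(linear_kernel(pair.F1))
        Kv = center_kernel(linear_kernel(pair.F2))
        sol = solve_kcca(Ku, Kv, reg=1e-10)
        oracle = first_canonical_correlation(pair.F1.values, pair.F2.values)
        assert sol.rho == pytest.approx(oracle, abs=1e-3)

    def test_recovers_planted_correlation(self):
        pair = generate_correlated_pair(300, 8, 8, 0.8, seed=3)
        Ku = center_kernel(gaussian_kernel(
            pair.F1, median_bandwidth(pair.F1.values)))
        Kv = center_kernel(gaussian_kernel(
            pair.F2, median_bandwidth(pair.F2.values)))
        sol = solve_kcca(Ku, Kv, reg=1e-3)
        assert sol.rho == pytest.approx(0.8, abs=0.15)

    def test_independent_views_within_permutation_null(self):
        """rho on independent views falls inside the 95% band of rho under
        row-shuffling of the second view."""
        pair = generate_correlated_pair(120, 6, 6, 0.0, seed=4)
        s1 = median_bandwidth(pair.F1.values)
        s2 = median_bandwidth(pair.F2.values)
        Ku = center_kernel(gaussian_kernel(pair.F1, s1))

        def rho_of(values):
            Kv = center_kernel(gaussian_kernel(values, s2))
            return solve_kcca(Ku, Kv, reg=1e-1).rho

        observed = rho_of(pair.F2.values)
        rng = np.random.default_rng(0)
        null = [rho_of(pair.F2.values[rng.permutation(120)])
                for _ in range(20)]
        assert observed <= np.quantile(null, 0.975) + 0.05

    def test_rho_invariant_to_common_row_permutation(self):
        pair = generate_correlated_pair(60, 4, 4, 0.7, seed=5)
        perm = np.random.default_rng(1).permutation(60)

        def rho(F1, F2):
            Ku = center_kernel(gaussian_kernel(F1, 1.5))
            Kv = center_kernel(gaussian_kernel(F2, 1.5))
            return solve_kcca(Ku, Kv, reg=1e-3).rho

        assert rho(pair.F1.values, pair.F2.values) == pytest.approx(
            rho(pair.F1.values[perm], pair.F2.values[perm]), abs=1e-8)

    def test_size_mismatch_rejected(self):
        Ka = center_kernel(gaussian_kernel(np.random.rand(5, 2), 1.0))
        Kb = center_kernel(gaussian_kernel(np.random.rand(6, 2), 1.0))
        with pytest.raises(ValueError):
            solve_kcca(Ka, Kb)


class TestEntropy:
    def test_constant_column_has_zero_entropy(self):
        assert shannon_entropy(np.full(100, 3.7)) == 0.0

    @pytest.mark.parametrize("bins", [2, 4, 16])
    def test_uniform_occupancy_reaches_log2_bins(self, bins):
        col = np.repeat(np.arange(bins), 10) / (bins - 1)
        assert shannon_entropy(col, bins=bins) == pytest.approx(np.log2(bins))

    def test_fair_coin_is_one_bit(self):
        col = np.array([0.0, 1.0] * 50)
        assert shannon_entropy(col, bins=2) == pytest.approx(1.0)

    def test_bins_validation(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.arange(5.0), bins=1)


class TestFuse:
    def test_output_width_is_sum_of_inputs(self):
        pair = generate_correlated_pair(40, 6, 10, 0.5, seed=6)
        fused = fuse(pair.F1, pair.F2)
        assert fused.values.shape == (40, 16)
        assert len(fused.provenance) == 16
        assert fused.kcca.rho >= 0.0

    def test_minimal_width_provenance(self):
        F1 = FeatureMatrix(np.random.default_rng(0).random((10, 1)))
        F2 = FeatureMatrix(np.random.default_rng(1).random((10, 1)))
        fused = fuse(F1, F2)
        assert fused.values.shape == (10, 2)
        assert fused.provenance == [("F1", 0), ("F2", 0)]

    def test_constant_columns_get_zero_weight(self):
        rng = np.random.default_rng(2)
        F1 = FeatureMatrix(np.hstack([rng.random((20, 2)),
                                      np.full((20, 1), 5.0)]))
        F2 = FeatureMatrix(rng.random((20, 2)))
        fused = fuse(F1, F2)
        assert fused.weights[2] == 0.0
        assert np.array_equal(fused.values[:, 2], np.zeros(20))

    def test_row_mismatch_rejected(self):
        F1 = FeatureMatrix(np.random.rand(10, 2))
        F2 = FeatureMatrix(np.random.rand(11, 2))
        with pytest.raises(ValueError):
            fuse(F1, F2)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=2, max_value=30), st.integers(0, 10 ** 6))
def test_entropy_is_bounded_by_log2_bins(bins, seed):
    col = np.random.default_rng(seed).random(64)
    h = shannon_entropy(col, bins=bins)
    assert 0.0 <= h <= np.log2(bins) + 1e-9
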