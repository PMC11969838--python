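"""Kernel matrices, HSIC/KCI statistics and their permutation tests."""

import numpy as np
import pytest

from causalcyto.exceptions import ConfigurationError, PairingError, ValidationError
from causalcyto.independence import (
    KernelConfig,
    center_kernel,
    delta_kernel_matrix,
    gaussian_kernel_matrix,
    hsic_statistic,
    hsic_test,
    kci_statistic,
    kci_test,
)
from conftest import brute_force_hsic


class TestGaussianKernel:
    def test_identical_points_give_all_ones(self):
        K = gaussian_kernel_matrix(np.zeros((3, 2)), bandwidth=1.0)
        np.testing.assert_allclose(K.values, np.ones((3, 3)))

    def test_two_point_entry_matches_formula(self):
        K = gaussian_kernel_matrix(np.array([[0.0], [1.0]]), bandwidth=1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_median_heuristic_resolves_to_pairwise_median(self):
        # distances {2}; median 2 -> off-diagonal exp(-4/8)
        K = gaussian_kernel_matrix(np.array([[0.0], [2.0]]), bandwidth="median")
        assert K.bandwidth == pytest.approx(2.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_median_heuristic_zero_distance_falls_back(self):
        K = gaussian_kernel_matrix(np.zeros((4, 1)), bandwidth="median")
        assert K.bandwidth == 1.0

    def test_entries_in_unit_interval_with_unit_diagonal(self, rng):
        K = gaussian_kernel_matrix(rng.normal(size=(20, 3))).values
        assert np.all(K > 0) and np.all(K <= 1)
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_rejects_nonfinite_and_undersized_input(self):
        with pytest.raises(ValidationError):
            gaussian_kernel_matrix(np.array([[np.nan], [1.0]]))
        with pytest.raises(ValidationError):
            gaussian_kernel_matrix(np.array([[1.0]]))


class TestCenterKernel:
    def test_all_ones_centers_to_zero(self):
        C = center_kernel(np.ones((5, 5)))
        np.testing.assert_allclose(C.values, 0.0, atol=1e-12)
        assert C.centered

    def test_row_sums_vanish(self, rng):
        K = rng.random((7, 7))
        K = (K + K.T) / 2
        C = center_kernel(K).values
        assert np.abs(C.sum(axis=0)).max() < 1e-8
        assert np.abs(C.sum(axis=1)).max() < 1e-8

    def test_matches_hand_computed_hkh(self):
        K = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 1.0]])
        H = np.eye(3) - np.ones((3, 3)) / 3
        np.testing.assert_allclose(center_kernel(K).values, H @ K @ H, atol=1e-12)


class TestHsicStatistic:
    def test_constant_variable_gives_zero(self, rng):
        x = rng.normal(size=30)
        assert abs(hsic_statistic(x, np.ones(30), KernelConfig(bandwidth=1.0))) < 1e-10

    def test_small_instance_matches_hand_trace(self):
        x = np.array([0.0, 1.0, 2.0])
        stat = hsic_statistic(x, x, KernelConfig(bandwidth=1.0))
        expected = brute_force_hsic(x, x, 1.0, 1.0)
        assert stat == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n,d", [(4, 1), (7, 2), (10, 3)])
    def test_agrees_with_double_loop_oracle(self, rng, n, d):
        x = rng.normal(size=(n, d))
        y = rng.normal(size=(n, d))
        stat = hsic_statistic(x, y, KernelConfig(bandwidth=0.8))
        assert stat == pytest.approx(
            brute_force_hsic(x, y, 0.8, 0.8), abs=1e-10
        )

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(50):
            x = rng.normal(size=(12, 2))
            y = rng.normal(size=(12, 1))
            cfg = KernelConfig(bandwidth=1.0)
            assert hsic_statistic(x, y, cfg) == pytest.approx(
                hsic_statistic(y, x, cfg), abs=1e-9
            )
            assert hsic_statistic(x, y, cfg) >= -1e-10

    def test_dependence_exceeds_independence(self, rng):
        wins = 0
        for _ in range(100):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            if hsic_statistic(x, x) > hsic_statistic(x, y):
                wins += 1
        assert wins >= 99

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(PairingError):
            hsic_statistic(rng.normal(size=5), rng.normal(size=6))

    def test_squared_scaling_variant(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = hsic_statistic(x, y, KernelConfig(bandwidth=1.0, scaling="paper"))
        b = hsic_statistic(x, y, KernelConfig(bandwidth=1.0, scaling="squared"))
        assert a == pytest.approx(b * 19, rel=1e-12)


class TestHsicTest:
    def test_identical_inputs_hit_permutation_floor(self, rng):
        x = rng.normal(size=50)
        res = hsic_test(x, x, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_seeded_determinism(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        r1 = hsic_test(x, y, n_permutations=99, seed=7)
        r2 = hsic_test(x, y, n_permutations=99, seed=7)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_pvalue_formula_add_one(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = hsic_test(x, y, n_permutations=99, seed=3)
        count = int(np.sum(res.null_samples >= res.statistic - 1e-15))
        assert res.p_value == pytest.approx((1 + count) / 100)

    def test_rejects_bad_permutation_count(self, rng):
        with pytest.raises(ConfigurationError):
            hsic_test(rng.normal(size=10), rng.normal(size=10), n_permutations=0)

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        pvals = []
        for s in range(500):
            r = np.random.default_rng(1000 + s)
            res = hsic_test(
                r.normal(size=30), r.normal(size=30), n_permutations=99, seed=s
            )
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").statistic < 0.10

    def test_power_against_additive_noise(self):
        rejections = 0
        for s in range(50):
            r = np.random.default_rng(2000 + s)
            x = r.normal(size=100)
            y = x + r.normal(0, 0.5, size=100)
            if hsic_test(x, y, n_permutations=99, seed=s).p_value < 0.05:
                rejections += 1
        assert rejections >= 45


class TestIO:
    def test_sample_matrix_csv_round_trip(self, rng, tmp_path):
        import pandas as pd

        from causalcyto.independence import read_sample_matrix

        X = rng.normal(size=(12, 3))
        pd.DataFrame(X, columns=["a", "b", "c"]).to_csv(
            tmp_path / "x.csv", index=False
        )
        np.testing.assert_allclose(read_sample_matrix(tmp_path / "x.csv"), X)

    def test_result_serializes_to_json(self, rng):
        import json

        res = hsic_test(rng.normal(size=20), rng.normal(size=20),
                        n_permutations=99, seed=2)
        payload = json.loads(res.to_json())
        assert payload["test_kind"] == "HSIC"
        assert payload["p_value"] == res.p_value
        assert payload["n_permutations"] == 99


class TestKciStatistic:
    def test_constant_x_gives_zero(self, rng):
        y = rng.normal(size=20)
        z = rng.integers(2, size=20)
        assert abs(kci_statistic(np.ones(20), y, z.astype(float))) < 1e-10

    def test_small_instance_matches_triple_trace(self):
        v = np.array([0.0, 1.0, 2.0])
        cfg = KernelConfig(bandwidth=1.0)
        K = np.exp(-np.subtract.outer(v, v) ** 2 / 2.0)
        H = np.eye(3) - np.ones((3, 3)) / 3
        Kc = H @ K @ H
        expected = np.trace(Kc @ Kc @ Kc) / 9
        got = kci_statistic(v, v, v, cfg, z_kind="continuous")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_swap_symmetry_in_x_and_y(self, rng):
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            z = rng.integers(3, size=10).astype(float)
            cfg = KernelConfig(bandwidth=1.0)
            assert kci_statistic(x, y, z, cfg) == pytest.approx(
                kci_statistic(y, x, z, cfg), abs=1e-9
            )


class TestKciTest:
    def test_seeded_determinism(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.integers(2, size=30)
        r1 = kci_test(x, y, z, n_permutations=99, seed=5)
        r2 = kci_test(x, y, z, n_permutations=99, seed=5)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_singleton_stratum_warns_and_survives(self, rng):
        z = np.array([0] * 10 + [1])
        x, y = rng.normal(size=11), rng.normal(size=11)
        with pytest.warns(UserWarning, match="single member"):
            res = kci_test(x, y, z, n_permutations=99, seed=0)
        assert 0 < res.p_value <= 1

    def test_continuous_z_rejected(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        z = rng.normal(size=100)
        with pytest.raises(ConfigurationError, match="discrete"):
            kci_test(x, y, z, n_permutations=99, seed=0)

    def test_collider_conditioning_induces_dependence(self):
        """X -> y <- Z with X and Z independent: the conditional p-value
        should undercut the marginal one for most seeds."""
        wins = 0
        for s in range(30):
            r = np.random.default_rng(3000 + s)
            x = r.normal(size=200)
            z = r.normal(size=200)
            y = (x + z + r.normal(0, 0.3, size=200) > 0).astype(int)
            p_cond = kci_test(x, z, y, n_permutations=99, seed=s).p_value
            p_marg = hsic_test(x, z, n_permutations=99, seed=s).p_value
            if p_cond < p_marg:
                wins += 1
        assert wins >= 24  # >= 80%
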