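"""Tests for the KS machinery: e.c.d.f., Kolmogorov distribution, node RS."""

import numpy as np
import pytest
import scipy.special
import scipy.stats

from hwks import (
    DEFAULT_CA,
    KSConfig,
    critical_value,
    ecdf_eval,
    kolmogorov_cdf,
    ks_global_test,
    node_rs,
    scaled_ks_point_distance,
    build_trees,
)


class TestEcdf:
    def test_documented_example(self):
        assert ecdf_eval([1.0, 2.0, 3.0, 4.0], 2.0) == 0.5

    def test_right_continuity_and_bounds(self):
        z = [1.0, 1.0, 2.0, 5.0]
        assert ecdf_eval(z, 0.5) == 0.0
        assert ecdf_eval(z, 1.0) == 0.5  # ties counted at their value
        assert ecdf_eval(z, 5.0) == 1.0
        assert ecdf_eval(z, 100.0) == 1.0

    def test_monotone_in_t(self):
        z = np.random.default_rng(1).normal(size=50)
        ts = np.linspace(-3, 3, 41)
        vals = [ecdf_eval(z, t) for t in ts]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestKolmogorov:
    def test_tails(self):
        assert kolmogorov_cdf(-1.0) == 0.0
        assert kolmogorov_cdf(0.0) == 0.0
        assert kolmogorov_cdf(10.0) == pytest.approx(1.0)

    def test_documented_value_at_default_ca(self):
        assert kolmogorov_cdf(DEFAULT_CA) == pytest.approx(0.94054, abs=5e-5)

    def test_matches_scipy_oracle(self):
        for x in np.linspace(0.2, 3.0, 29):
            assert kolmogorov_cdf(x) == pytest.approx(
                1.0 - scipy.special.kolmogorov(x), abs=1e-10)

    def test_critical_value_examples(self):
        assert critical_value(0.05) == pytest.approx(1.3581, abs=1e-4)
        assert critical_value(0.05) == pytest.approx(scipy.special.kolmogi(0.05), abs=1e-8)

    def test_critical_value_round_trip(self):
        for ca in (0.8, 1.0, DEFAULT_CA, 1.6, 2.2):
            assert critical_value(1.0 - kolmogorov_cdf(ca)) == pytest.approx(ca, abs=1e-8)

    def test_critical_value_monotone_decreasing_in_alpha(self):
        alphas = [0.01, 0.05, 0.1, 0.2, 0.5]
        cvs = [critical_value(a) for a in alphas]
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            critical_value(alpha)


class TestKSConfig:
    def test_default_alpha_implied_by_ca(self):
        cfg = KSConfig()
        assert cfg.ca == DEFAULT_CA
        assert cfg.alpha == pytest.approx(1.0 - kolmogorov_cdf(DEFAULT_CA))

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            KSConfig(ca=0.0)
        with pytest.raises(ValueError):
            KSConfig(alpha=1.5)


class TestScaledPointDistance:
    def test_identical_samples_give_zero(self):
        z = np.arange(8.0)
        assert scaled_ks_point_distance(z, z, 3.5) == 0.0

    def test_hand_value(self):
        # nx = nz = 8, F_X(t) = 1, F_Z(t) = 0.5 -> 2 * 0.5 = 1
        x = np.zeros(8)
        z = np.concatenate([np.zeros(4), np.full(4, 10.0)])
        assert scaled_ks_point_distance(x, z, 5.0) == pytest.approx(1.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        x, z = rng.normal(size=16), rng.normal(size=16) + 1
        for t in (-1.0, 0.0, 0.7):
            assert scaled_ks_point_distance(x, z, t) == pytest.approx(
                scaled_ks_point_distance(x + 5, z + 5, t + 5))


class TestNodeRS:
    def _shifted_pair(self, n):
        x = np.linspace(-0.1, 0.1, n)
        z = np.concatenate([np.linspace(-0.1, 0.1, n // 2),
                            9.0 + np.linspace(-0.1, 0.1, n // 2)])
        return x, z

    def test_root_rs_fires_at_n16(self):
        x, z = self._shifted_pair(16)
        tca, tcd = build_trees(z)
        ns = node_rs(x, z, tca, 4, 1, tcd=tcd)
        assert ns.probe_main == pytest.approx(4.5)
        assert ns.probe_alt == pytest.approx(0.0)
        assert ns.d_main == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert ns.d_alt == pytest.approx(np.sqrt(2.0) / 2, abs=1e-9)
        assert ns.rs == pytest.approx(np.sqrt(2.0))

    def test_same_relative_shift_below_threshold_at_n8(self):
        # the scale factor sqrt(4) caps the distance at 1.0 < Ca -> rs = 0
        x, z = self._shifted_pair(8)
        tca, tcd = build_trees(z)
        ns = node_rs(x, z, tca, 3, 1, tcd=tcd)
        assert ns.d_main == pytest.approx(1.0)
        assert ns.rs == 0.0

    def test_identical_series_give_zero(self):
        z = np.random.default_rng(3).normal(size=16)
        tca, tcd = build_trees(z)
        for level in range(tca.depth + 1):
            assert node_rs(z, z, tca, level, 1, tcd=tcd).rs == 0.0

    def test_leaf_probe_degenerates(self):
        x, z = self._shifted_pair(16)
        tca, tcd = build_trees(z)
        ns = node_rs(x, z, tca, 0, 12, tcd=tcd)
        assert ns.probe_alt == ns.probe_main
        assert ns.rs == 0.0  # equal distances always fall to the zero branch

    def test_tcd_optional_recomputation_agrees(self):
        x, z = self._shifted_pair(16)
        tca, tcd = build_trees(z)
        for level in range(tca.depth + 1):
            for pos in (1, (16 >> level)):
                a = node_rs(x, z, tca, level, pos, tcd=tcd)
                b = node_rs(x, z, tca, level, pos)
                assert b.probe_alt == pytest.approx(a.probe_alt, abs=1e-12)
                assert b.rs == pytest.approx(a.rs, abs=1e-12)
                assert b.d_main == a.d_main


class TestGlobalTest:
    def test_identical_samples(self):
        z = np.arange(16.0)
        reject, stat = ks_global_test(z, z)
        assert not reject and stat == 0.0

    def test_documented_example(self):
        reject, stat = ks_global_test(np.zeros(8),
                                      [0, 0, 0, 0, 10, 10, 10, 10.0])
        assert stat == pytest.approx(1.0)
        assert not reject  # 1.0 < critical_value(0.05)

    def test_matches_scipy_sup_statistic(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=40)
            z = rng.normal(size=60) + rng.uniform(-1, 1)
            _, stat = ks_global_test(x, z)
            scale = np.sqrt(40 * 60 / 100)
            assert stat == pytest.approx(
                scale * scipy.stats.ks_2samp(x, z, method="asymp").statistic)

    def test_handles_ties_exactly(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=30).astype(float)
        z = rng.integers(0, 4, size=30).astype(float)
        _, stat = ks_global_test(x, z)
        grid = np.unique(np.concatenate([x, z]))
        brute = max(abs(ecdf_eval(z, t) - ecdf_eval(x, t)) for t in grid)
        assert stat == pytest.approx(np.sqrt(900 / 60) * brute)

    def test_type_one_error_close_to_alpha(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            ks_global_test(rng.normal(size=64), rng.normal(size=64), alpha=0.05)[0]
            for _ in range(1000))
        # the asymptotic quantile is slightly conservative at n = 64
        assert 0.01 <= rejections / 1000 <= 0.09
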