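import numpy as np
import pandas as pd
import pytest

from muacdose.growth import (
    GrowthTrendModel,
    SmoothCurve,
    interval_changes,
    intervals_frame,
    local_poly_smooth,
    normalized_difference_trend_test,
    resample_trend_analysis,
    velocity_regression,
)
from muacdose.qc import qc_cohort
from muacdose.synthetic import generate_cohort, preset_config
from muacdose.types import RunConfig

from conftest import make_card


class TestIntervalChanges:
    def test_two_week_interval_halved(self):
        """A +4 mm change over 14 days is a 2 mm/week velocity."""
        card = make_card(visits=[(0, 100, 5.0), (14, 104, 5.2)])
        (o,) = interval_changes(card)
        assert o.muac_velocity == pytest.approx(2.0)
        assert o.interval_days == 14
        assert o.prior_muac == 100

    def test_weight_gain_rate(self):
        card = make_card(visits=[(0, 100, 5.0), (7, 102, 5.35)])
        (o,) = interval_changes(card)
        assert o.weight_gain_rate == pytest.approx(350 / 5.0 / 7)  # 10 g/kg/day

    def test_no_change_zero_velocity(self):
        card = make_card(visits=[(0, 100, 5.0), (7, 100, 5.0)])
        (o,) = interval_changes(card)
        assert o.muac_velocity == 0.0 and o.weight_gain_rate == 0.0

    def test_pairs_with_missing_measurements_skipped(self):
        card = make_card(visits=[(0, 100, 5.0), (7, None, 5.2), (14, 104, 5.4)])
        obs = interval_changes(card)
        assert len(obs) == 0  # both intervals touch the MUAC-less visit

    def test_halving_intervals_and_changes_preserves_velocity(self):
        """Velocity normalization is scale-free in the visit spacing."""
        full = make_card(visits=[(0, 100, 5.0), (14, 104, 5.28)])
        half = make_card(visits=[(0, 100, 5.0), (7, 102, 5.14)])
        (a,) = interval_changes(full)
        (b,) = interval_changes(half)
        assert a.muac_velocity == pytest.approx(b.muac_velocity)
        assert a.weight_gain_rate == pytest.approx(b.weight_gain_rate)


class TestSmoother:
    grid = np.arange(100.0, 126.0)

    def test_reproduces_constants(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(100, 125, 200)
        y = np.full(200, 3.7)
        for kernel in ("epanechnikov", "uniform", "triangle", "gaussian"):
            c = local_poly_smooth(x, y, self.grid, kernel=kernel, bandwidth=4.0)
            ok = np.isfinite(c.estimate)
            assert ok.any()
            np.testing.assert_allclose(c.estimate[ok], 3.7, atol=1e-12)

    def test_degree_one_reproduces_lines(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(100, 125, 300)
        y = 1.5 - 0.04 * x
        c = local_poly_smooth(x, y, self.grid, bandwidth=3.0, degree=1)
        ok = np.isfinite(c.estimate)
        np.testing.assert_allclose(c.estimate[ok], 1.5 - 0.04 * self.grid[ok], atol=1e-10)

    def test_uniform_degree_zero_equals_windowed_mean_oracle(self):
        """Degree-0 uniform-kernel smoothing is exactly a windowed mean."""
        rng = np.random.default_rng(3)
        x = rng.uniform(95, 130, 20)
        y = rng.normal(2.0, 1.0, 20)
        h = 5.0
        c = local_poly_smooth(x, y, self.grid, kernel="uniform", bandwidth=h)
        for g, est in zip(self.grid, c.estimate):
            inside = np.abs(x - g) <= h
            if inside.any():
                assert est == pytest.approx(float(y[inside].mean()), abs=1e-12)
            else:
                assert np.isnan(est)

    def test_zero_weight_grid_points_missing(self):
        c = local_poly_smooth([100.0, 101.0], [1.0, 2.0], [100.0, 120.0], bandwidth=2.0)
        assert np.isfinite(c.estimate[0]) and np.isnan(c.estimate[1])

    def test_singular_design_falls_back_to_local_mean(self):
        x = np.full(10, 110.0)
        y = np.arange(10.0)
        c = local_poly_smooth(x, y, [110.0], bandwidth=2.0, degree=1)
        assert c.estimate[0] == pytest.approx(y.mean())

    def test_band_mean(self):
        c = SmoothCurve(grid=np.array([100.0, 101, 102, 103]), estimate=np.array([1.0, 2, 3, 4]), bandwidth=1)
        assert c.band_mean(100, 102) == pytest.approx(1.5)
        assert np.isnan(c.band_mean(200, 210))


class TestTrendTest:
    def _curve(self, vals):
        vals = np.asarray(vals, float)
        return SmoothCurve(grid=np.arange(100.0, 100.0 + len(vals)), estimate=vals, bandwidth=1)

    def test_affine_transform_gives_zero_slope(self):
        a = self._curve([2.0, 1.8, 1.5, 1.1, 1.0])
        b = self._curve([3.9, 3.5, 2.9, 2.1, 1.9])  # 1.9 + 2*(a - 1)
        t = normalized_difference_trend_test(a, b)
        assert t.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_difference_is_significant(self):
        a = self._curve(np.linspace(1, 0, 8))
        b = self._curve(np.linspace(0, 1, 8))
        t = normalized_difference_trend_test(a, b)
        assert t.p_value < 1e-6

    def test_slope_matches_hand_ols(self):
        """Five-point slope agrees with the closed-form OLS slope."""
        a = self._curve([0.0, 0.3, 0.2, 0.9, 1.0])
        b = self._curve([0.0, 0.1, 0.5, 0.4, 1.0])
        t = normalized_difference_trend_test(a, b)
        g = np.arange(100.0, 105.0)
        d = a.estimate - b.estimate  # both already span [0,1]
        slope = np.sum((g - g.mean()) * (d - d.mean())) / np.sum((g - g.mean()) ** 2)
        assert t.slope == pytest.approx(slope, abs=1e-12)

    def test_constant_curve_normalized_to_half(self):
        a = self._curve([1.0, 1.0, 1.0, 1.0])
        b = self._curve([0.0, 0.4, 0.6, 1.0])
        t = normalized_difference_trend_test(a, b)
        # diff = 0.5 - normB, so slope = -slope of normB
        assert t.slope == pytest.approx(-0.1 / 0.3, rel=0.5)

    def test_mismatched_grids_rejected(self):
        a = self._curve([1.0, 2.0, 3.0])
        b = SmoothCurve(grid=np.array([1.0, 2, 3]), estimate=np.zeros(3), bandwidth=1)
        with pytest.raises(ValueError, match="grid"):
            normalized_difference_trend_test(a, b)


class TestVelocityRegression:
    def test_exact_linear_slope(self):
        rng = np.random.default_rng(4)
        m = rng.integers(100, 126, 200).astype(float)
        df = pd.DataFrame({"prior_muac": m, "muac_velocity": 8.3 - 0.06 * m})
        r = velocity_regression(df)
        assert r.slope == pytest.approx(-0.06, abs=1e-12)

    def test_permutation_invariance(self, anchor_observations):
        obs = anchor_observations
        a = velocity_regression(obs)
        b = velocity_regression(obs.sample(frac=1.0, random_state=0))
        assert a.slope == pytest.approx(b.slope, rel=1e-12)

    def test_matches_hand_computed_slope(self):
        m = np.array([100.0, 103, 105, 108, 111, 114, 117, 120, 122, 124])
        v = np.array([2.1, 2.0, 1.7, 1.9, 1.5, 1.6, 1.2, 1.1, 1.15, 0.9])
        slope = np.sum((m - m.mean()) * (v - v.mean())) / np.sum((m - m.mean()) ** 2)
        r = velocity_regression(pd.DataFrame({"prior_muac": m, "muac_velocity": v}))
        assert r.slope == pytest.approx(slope, abs=1e-12)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"prior_muac": [110.0] * 5, "muac_velocity": [1.0] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            velocity_regression(df)


class TestResampling:
    def test_same_seed_reproducible(self, anchor_observations):
        kw = dict(per_country=300, replicates=5, muac_range=(100, 140), seed=21)
        a = resample_trend_analysis(anchor_observations, **kw)
        b = resample_trend_analysis(anchor_observations, **kw)
        np.testing.assert_array_equal(a.slopes, b.slopes)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_rescaled_deterministic_trends_have_zero_slope(self):
        """When weight gain is an affine rescaling of MUAC velocity the
        normalized difference vanishes identically."""
        cfg = preset_config(
            "linear_slope",
            n_per_country=40,
            seed=6,
            muac_noise_sd=0.0,
            weight_noise_sd=0.0,
            nonresponse_fraction=0.0,
            missed_visit_prob=0.0,
            quantize=False,
        )
        obs = intervals_frame(generate_cohort(cfg))
        r = resample_trend_analysis(obs, per_country=100, replicates=3, muac_range=(100, 125), seed=1)
        np.testing.assert_allclose(r.slopes, 0.0, atol=1e-9)

    def test_empty_stratum_named(self, anchor_observations):
        obs = anchor_observations[anchor_observations["country"] != "Yemen"].copy()
        obs.loc[obs.index[:1], "country"] = "Yemen"
        obs = obs[obs["country"].isin(["Yemen"])].iloc[:0]
        with pytest.raises(ValueError, match="no observations"):
            resample_trend_analysis(obs, per_country=10, replicates=1)

    def test_trend_calibration_under_true_null(self):
        """Both normalized trends share one shape in expectation, so at the
        5% level roughly 95% of independently generated cohorts should be
        non-significant. Cohorts are fresh per replicate: subsampling a
        single small cohort would instead detect that cohort's own sampling
        deviation from the generator."""
        root = np.random.default_rng(42)
        pvals = []
        for s in root.integers(0, 2**31 - 1, 100):
            cards = generate_cohort(preset_config("band_anchor", n_per_country=200, seed=int(s)))
            obs = qc_cohort(cards).observations
            r = resample_trend_analysis(
                obs, per_country=10**9, replicates=1, muac_range=(100, 140), seed=int(s) % 100000
            )
            pvals.append(r.p_values[0])
        frac = float(np.mean(np.asarray(pvals) > 0.05))
        assert 0.90 <= frac <= 0.99


class TestModelSurface:
    def test_fit_recovers_band_anchors(self, anchor_observations):
        cfg = RunConfig(rng_seed=2, trend_replicates=5, trend_per_country=500)
        res = GrowthTrendModel(anchor_observations, cfg).fit()
        assert res.muac_curve.band_mean(100, 110) == pytest.approx(2.0, abs=0.2)
        assert res.muac_curve.band_mean(120, 125) == pytest.approx(1.0, abs=0.2)
        assert res.weight_curve.band_mean(100, 110) == pytest.approx(3.9, abs=0.3)
        assert res.weight_curve.band_mean(120, 125) == pytest.approx(2.4, abs=0.3)
        assert "MUAC velocity slope" in res.summary()
        bm = res.band_means()
        assert list(bm.columns) == ["band_lo", "band_hi", "muac_velocity", "weight_gain_rate"]
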