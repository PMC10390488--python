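import numpy as np
import pytest
from scipy import stats

import luadsim as L


def expo_table(rng, n, median, follow_up=40.0):
    t = rng.exponential(median / np.log(2), size=n)
    return L.EventTable(np.minimum(t, follow_up), (t <= follow_up).astype(int))


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        ev = L.EventTable([3.0, 5.0, 8.0], [0, 0, 0])
        km = L.km_estimate(ev)
        assert km.times.size == 0
        assert np.all(km.evaluate([0.0, 4.0, 10.0]) == 1.0)

    def test_two_subject_hand_example(self):
        ev = L.EventTable([1.0, 4.0], [1, 0])
        km = L.km_estimate(ev)
        assert km.evaluate(1.0) == pytest.approx(0.5)

    def test_no_censoring_closed_form(self, rng):
        n = 37
        times = np.sort(rng.uniform(1, 30, size=n))
        km = L.km_estimate(L.EventTable(times, np.ones(n, int)))
        for k, t in enumerate(times, start=1):
            assert km.evaluate(t) == pytest.approx(1 - k / n, rel=1e-12)

    def test_matches_lifelines_on_censored_data(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(10, size=80)
        e = rng.random(80) < 0.7
        km = L.km_estimate(L.EventTable(t, e.astype(int)))
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0.1, t.max(), 57)
        np.testing.assert_allclose(
            km.evaluate(grid),
            kmf.predict(grid).to_numpy(),
            atol=1e-10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            L.EventTable([], [])


class TestInferTTP:
    def test_no_deaths_near_pfs(self):
        out = L.infer_ttp([2.0, 5.0, 7.0], [20.0, 30.0])
        np.testing.assert_array_equal(out, [2.0, 5.0, 7.0])

    def test_multiset_difference(self):
        out = L.infer_ttp([2.0, 3.0, 5.0], [3.0, 9.0], tol=0.0)
        np.testing.assert_array_equal(out, [2.0, 5.0])

    def test_each_death_removes_at_most_one(self):
        out = L.infer_ttp([4.0, 4.0], [4.0], tol=0.0)
        np.testing.assert_array_equal(out, [4.0])

    def test_tolerance_matching(self):
        out = L.infer_ttp([4.0, 8.0], [4.3], tol=0.5)
        np.testing.assert_array_equal(out, [8.0])

    def test_output_length_invariant(self, rng):
        pfs = list(rng.uniform(1, 20, size=30))
        osd = list(rng.choice(pfs, size=10, replace=False))
        out = L.infer_ttp(pfs, osd, tol=0.0)
        assert len(out) == len(pfs) - 10


class TestBootstrapPI:
    def test_single_resample_collapses(self, rng):
        ev = expo_table(rng, 100, 9.0)
        band = L.bootstrap_pi(ev, 50, B=1, seed=0)
        np.testing.assert_array_equal(band.lo, band.hi)

    def test_degenerate_outcomes_zero_width(self):
        ev = L.EventTable(np.full(50, 7.0), np.ones(50, int))
        band = L.bootstrap_pi(ev, 20, B=200, seed=0)
        assert np.all(band.hi - band.lo == 0.0)

    def test_band_width_shrinks_with_sample_size(self, rng):
        ev = expo_table(rng, 4000, 9.0)
        w = {}
        for n_real in (50, 200):
            band = L.bootstrap_pi(ev, n_real, B=400, seed=1)
            sel = (band.grid > 2) & (band.grid < 20)
            w[n_real] = np.mean(band.hi[sel] - band.lo[sel])
        assert w[200] < w[50]
        assert w[50] / w[200] == pytest.approx(2.0, rel=0.3)  # ~ 1/sqrt(n)

    def test_contains_median_resample(self, rng):
        ev = expo_table(rng, 1000, 9.0)
        band = L.bootstrap_pi(ev, 159, B=500, seed=2, level=0.5)
        km = L.km_estimate(ev)
        s = km.evaluate(band.grid)
        inside = (s >= band.lo - 1e-9) & (s <= band.hi + 1e-9)
        assert inside.mean() > 0.9

    def test_oversized_subsample_rejected(self, rng):
        ev = expo_table(rng, 30, 9.0)
        with pytest.raises(ValueError):
            L.bootstrap_pi(ev, 50, B=10, seed=0)


class TestRawCoverage:
    def test_full_band_gives_hundred(self, rng):
        obs = L.km_estimate(expo_table(rng, 50, 9.0))
        band = L.PredictionBand(np.array([0.0, 50.0]),
                                np.zeros(2), np.ones(2))
        assert L.raw_coverage(obs, band) == 100.0

    def test_curve_above_band_gives_zero(self, rng):
        obs = L.km_estimate(expo_table(rng, 50, 9.0))
        band = L.PredictionBand(np.array([0.0, 50.0]),
                                np.zeros(2), np.zeros(2) + 1e-12)
        assert L.raw_coverage(obs, band) == 0.0

    def test_constructed_half_coverage(self):
        obs = L.SurvivalCurve(times=np.array([1.0, 2.0, 3.0, 4.0]),
                              surv=np.array([0.9, 0.8, 0.4, 0.3]))
        band = L.PredictionBand(np.array([0.0]), np.array([0.7]), np.array([1.0]))
        assert L.raw_coverage(obs, band) == 50.0

    def test_disjoint_ranges_rejected(self):
        obs = L.SurvivalCurve(times=np.array([1.0, 2.0]), surv=np.array([0.9, 0.8]))
        band = L.PredictionBand(np.array([10.0, 20.0]), np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            L.raw_coverage(obs, band)


class TestLogrank:
    def test_identical_tables(self, rng):
        ev = expo_table(rng, 40, 9.0)
        stat, p = L.logrank(ev, ev)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        a = L.EventTable([1.0, 2.0], [1, 1])
        b = L.EventTable([3.0, 4.0], [1, 1])
        stat, p = L.logrank(a, b)
        # O1=2, E1=1/2+1/3, V=1/4+2/9 -> (7/6)^2/(17/36)
        assert stat == pytest.approx((7 / 6) ** 2 / (17 / 36), rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test
        for _ in range(5):
            a = expo_table(rng, 60, 9.0)
            b = expo_table(rng, 70, 12.0)
            stat, p = L.logrank(a, b)
            res = logrank_test(a.times, b.times, a.events, b.events)
            assert stat == pytest.approx(res.test_statistic, rel=1e-9)
            assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_no_events_warns_and_returns_one(self):
        a = L.EventTable([1.0, 2.0], [0, 0])
        with pytest.warns(UserWarning):
            stat, p = L.logrank(a, a)
        assert p == 1.0

    def test_null_rejection_rate(self, rng):
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            a = expo_table(rng, 60, 9.0)
            b = expo_table(rng, 60, 9.0)
            _, p = L.logrank(a, b)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.025)


class TestBootstrappedLogrank:
    def test_single_test_granularity(self, rng):
        vp = expo_table(rng, 500, 9.0)
        real = expo_table(rng, 100, 9.0)
        frac = L.bootstrapped_logrank(vp, real, n_tests=1, seed=0)
        assert frac in (0.0, 100.0)

    def test_null_mostly_negative(self, rng):
        vp = expo_table(rng, 1500, 9.0)
        real = expo_table(rng, 150, 9.0)
        frac = L.bootstrapped_logrank(vp, real, n_tests=300, seed=1)
        assert frac >= 80.0

    def test_strong_shift_mostly_positive(self, rng):
        vp = expo_table(rng, 1500, 9.0)
        real = expo_table(rng, 150, 4.5)
        frac = L.bootstrapped_logrank(vp, real, n_tests=300, seed=2)
        assert frac <= 5.0


class TestValidateAndReport:
    def test_zero_thresholds_always_pass(self, rng):
        vp = expo_table(rng, 800, 9.0)
        obs = expo_table(rng, 100, 5.0)
        cfg = L.ValidationConfig(n_bootstrap_pi=100, n_lr_tests=100,
                                 coverage_threshold_pct=0.0, lr_threshold_pct=0.0)
        report = L.validate(vp, obs, cfg, seed=0)
        assert report.passed

    def test_report_json_fields(self, rng):
        import json
        vp = expo_table(rng, 500, 9.0)
        obs = vp.subsample(80, rng)
        cfg = L.ValidationConfig(n_bootstrap_pi=100, n_lr_tests=100)
        report = L.validate(vp, obs, cfg, seed=3)
        d = json.loads(report.to_json())
        assert d["n_bootstrap_pi"] == 100 and d["n_lr_tests"] == 100
        assert d["passed"] == (d["passed_coverage"] and d["passed_lr"])
        assert 0 <= d["raw_coverage_pct"] <= 100

    def test_percentage_bounds_enforced(self):
        with pytest.raises(ValueError):
            L.ValidationReport(raw_coverage_pct=120.0, lr_negative_pct=50.0,
                               coverage_threshold_pct=80, lr_threshold_pct=80,
                               n_bootstrap_pi=10, n_lr_tests=10, seed=0)


class TestEventsFromCurve:
    def test_round_trip_from_km(self, rng):
        t = np.round(rng.exponential(9.0, size=60), 1) + 0.1
        e = (rng.random(60) < 0.8).astype(int)
        ev = L.EventTable(t, e)
        km = L.km_estimate(ev)
        # attach at-risk counts on the curve's own grid
        srt = np.sort(t)
        n_risk = t.size - np.searchsorted(srt, km.times, side="left")
        curve = L.SurvivalCurve(km.times, km.surv, n_risk.astype(float))
        rec = L.events_from_curve(curve)
        km2 = L.km_estimate(rec)
        np.testing.assert_allclose(km2.times, km.times)
        np.testing.assert_allclose(km2.surv, km.surv, atol=1e-9)
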