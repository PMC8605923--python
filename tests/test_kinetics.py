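import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stabval.kinetics import (
    LN_10_OVER_9, ArrheniusModel, DegradationSeries, adjusted_rate,
    fit_arrhenius, fit_first_order, load_degradation_csv, series_from_frame,
    shelf_life, stability_table, t90,
)
from stabval.synthetic import arrhenius_from_anchors, rate_at

TIMES = np.array([0.0, 24.0, 72.0, 120.0])


def make_series(k, times=TIMES, noise=None, condition="acid", temp=40.0,
                sample_id="STD"):
    rec = 100.0 * np.exp(-k * times)
    if noise is not None:
        rec = rec * noise
    return DegradationSeries(condition=condition, temperature=temp,
                            times=times, recovery=rec, sample_id=sample_id)


class TestDegradationSeries:
    def test_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            DegradationSeries("acid", 40.0, times=[24, 72], recovery=[90, 80])

    def test_nondecreasing(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            DegradationSeries("acid", 40.0, times=[0, 72, 24], recovery=[100, 90, 95])

    def test_below_absolute_zero(self):
        with pytest.raises(ValueError, match="absolute zero"):
            DegradationSeries("acid", -300.0, times=[0, 24], recovery=[100, 90])


class TestFitFirstOrder:
    def test_noiseless_exponential(self):
        fit = fit_first_order(make_series(0.01))
        assert fit.k0 == pytest.approx(0.01, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.excluded_points == []

    def test_constant_recovery(self):
        fit = fit_first_order(make_series(0.0))
        assert fit.k0 == 0.0

    def test_zero_recovery_excluded(self):
        s = DegradationSeries("base", 60.0, times=TIMES,
                              recovery=[100.0, 10.0, 0.0, 0.0])
        fit = fit_first_order(s)
        assert fit.excluded_points == [2, 3]
        assert fit.n_points_used == 2

    def test_truncated_series_error(self):
        s = DegradationSeries("base", 60.0, times=TIMES,
                              recovery=[100.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="truncated"):
            fit_first_order(s)

    def test_anchor_t0(self):
        # exact exponential: anchored and free fits agree
        fit = fit_first_order(make_series(0.02), anchor_t0=True)
        assert fit.k0 == pytest.approx(0.02, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log(100.0))
        assert fit.anchored

    def test_log_base_equivalence(self):
        rng = np.random.default_rng(3)
        s = make_series(0.005, noise=1 + rng.normal(0, 0.01, 4))
        fit_e = fit_first_order(s, log_base="e")
        fit_10 = fit_first_order(s, log_base="10")
        assert fit_10.k0 == pytest.approx(fit_e.k0, rel=1e-12)

    def test_parameter_recovery_simulation(self):
        # 500 replications at true k0 = 0.005, multiplicative RSD 1%
        rng = np.random.default_rng(42)
        true_k = 0.005
        estimates = []
        for _ in range(500):
            noise = 1 + rng.normal(0, 0.01, TIMES.size)
            estimates.append(fit_first_order(make_series(true_k, noise=noise)).k0)
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - true_k) < 2 * mc_se


class TestFitArrhenius:
    def test_two_point_exact(self):
        temps = [40.0, 60.0]
        rates = {t: math.exp(30.0 - 0.8 * 11605.0 / (t + 273.15)) for t in temps}
        model = fit_arrhenius(rates)
        assert model.e_param == pytest.approx(0.8, abs=1e-9)
        assert model.a_param == pytest.approx(30.0, abs=1e-6)
        assert model.b_const == pytest.approx(1.0 / 11605.0)

    def test_equal_rates_zero_energy(self):
        model = fit_arrhenius({40.0: 0.01, 60.0: 0.01})
        assert model.e_param == pytest.approx(0.0, abs=1e-12)

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        a_true, e_true = 28.0, 0.75
        rates = {t: rate_at(a_true, e_true, t) * math.exp(rng.normal(0, 0.05))
                 for t in (25.0, 40.0, 60.0)}
        model = fit_arrhenius(rates)

        # independent brute-force grid search minimizing SSE over (A, E)
        inv_t = np.array([1 / (t + 273.15) for t in sorted(rates)])
        logk = np.array([math.log(rates[t]) for t in sorted(rates)])
        a_grid = np.arange(20.0, 36.0, 0.01)
        e_grid = np.arange(0.4, 1.1, 0.001)
        pred = (a_grid[:, None, None]
                - e_grid[None, :, None] * 11605.0 * inv_t[None, None, :])
        sse = ((pred - logk[None, None, :]) ** 2).sum(axis=2)
        ia, ie = np.unravel_index(np.argmin(sse), sse.shape)
        # (A, E) are strongly correlated along the fit ridge: an E-grid step
        # of 0.001 eV moves the optimal A by ~0.001 * 11605 / T ~ 0.04
        assert model.e_param == pytest.approx(e_grid[ie], abs=0.0015)
        assert model.a_param == pytest.approx(a_grid[ia], abs=0.06)

    def test_single_temperature_error(self):
        with pytest.raises(ValueError, match="2 distinct temperatures"):
            fit_arrhenius({40.0: 0.01})

    def test_nonpositive_rate_error(self):
        with pytest.raises(ValueError, match="nonpositive rate"):
            fit_arrhenius({40.0: 0.01, 60.0: 0.0})


class TestAdjustedRate:
    def test_interpolation_identity(self):
        rates = {40.0: 0.01, 60.0: 0.08}
        model = fit_arrhenius(rates)
        for t, k in rates.items():
            ka, extrapolated = adjusted_rate(model, t)
            assert ka == pytest.approx(k, rel=1e-9)
            assert not extrapolated

    def test_zero_energy_constant(self):
        model = ArrheniusModel(a_param=-3.0, e_param=0.0,
                               fitted_temperatures=(300.0, 330.0), r2=1.0)
        for t in (4.0, 25.0, 60.0):
            ka, _ = adjusted_rate(model, t)
            assert ka == pytest.approx(math.exp(-3.0))

    def test_matches_generator_closed_form(self):
        a_true, e_true = arrhenius_from_anchors(0.01, 40.0, 0.08, 60.0)
        model = fit_arrhenius({t: rate_at(a_true, e_true, t)
                               for t in (40.0, 50.0, 60.0)})
        ka, extrapolated = adjusted_rate(model, 25.0)
        assert ka == pytest.approx(rate_at(a_true, e_true, 25.0), abs=1e-9)
        assert extrapolated

    def test_monotone_in_temperature(self):
        model = ArrheniusModel(a_param=20.0, e_param=0.7,
                               fitted_temperatures=(300.0, 330.0), r2=1.0)
        ks = [adjusted_rate(model, t)[0] for t in (4.0, 25.0, 40.0, 60.0)]
        assert ks == sorted(ks)


class TestT90:
    def test_reported_basic_hydrolysis_row(self):
        assert round(t90(0.04275), 2) == 2.46

    def test_reported_fast_row(self):
        assert round(t90(0.4795), 2) == 0.22

    def test_unit_identity(self):
        assert t90(LN_10_OVER_9) == pytest.approx(1.0)

    def test_c0_cancels(self):
        assert t90(0.01, c0=100.0) == t90(0.01, c0=3.5)

    def test_nonpositive_rate(self):
        with pytest.raises(ValueError):
            t90(0.0)

    @settings(max_examples=100, deadline=None)
    @given(ka=st.floats(1e-6, 1e3))
    def test_identity_property(self, ka):
        assert t90(ka) * ka == pytest.approx(LN_10_OVER_9, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31), k=st.floats(1e-4, 0.1))
    def test_log_base_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        s = make_series(k, noise=1 + rng.normal(0, 0.01, TIMES.size))
        k_e = fit_first_order(s, log_base="e").k0
        k_10 = fit_first_order(s, log_base="10").k0
        if k_e <= 0:
            return
        assert t90(k_e) == pytest.approx(t90(k_10), rel=1e-9)


class TestShelfLife:
    def test_estimate_identity(self):
        model = fit_arrhenius({40.0: 0.01, 60.0: 0.08})
        est = shelf_life(model, 25.0)
        assert est.t90_h * est.ka == pytest.approx(LN_10_OVER_9, rel=1e-12)
        assert est.extrapolated


class TestStabilityTable:
    def test_single_noiseless_series(self):
        table = stability_table([make_series(0.01)])
        row = table.iloc[0]
        assert row.ka_e3_per_h == pytest.approx(10.0)
        assert row.t90_h == pytest.approx(10.536, abs=0.001)
        assert row.r2 == pytest.approx(1.0)

    def test_truncated_series_footnoted(self):
        s = DegradationSeries("base", 60.0, times=TIMES,
                              recovery=[100.0, 10.0, 0.0, 0.0], sample_id="F2")
        table = stability_table([s])
        assert "truncated" in table.iloc[0].note
        assert "24" in table.iloc[0].note

    def test_unfittable_series_annotated_not_fatal(self):
        bad = DegradationSeries("base", 60.0, times=TIMES,
                                recovery=[100.0, 0.0, 0.0, 0.0], sample_id="F2")
        ok = make_series(0.01, sample_id="STD")
        with pytest.warns(UserWarning, match="skipping fit"):
            table = stability_table([bad, ok])
        assert len(table) == 2
        bad_row = table[table.sample_id == "F2"].iloc[0]
        assert np.isnan(bad_row.ka_per_h)
        assert "unfittable" in bad_row.note

    def test_identity_audit_four_temperatures(self):
        a, e = arrhenius_from_anchors(2e-3, 40.0, 2e-2, 60.0)
        series = [make_series(rate_at(a, e, t), temp=t, condition="temperature")
                  for t in (4.0, 25.0, 40.0, 60.0)]
        table = stability_table(series)
        assert len(table) == 4
        for row in table.itertuples():
            assert row.t90_h * row.ka_per_h == pytest.approx(LN_10_OVER_9, rel=1e-12)
            # noiseless: adjusted rate equals the generating rate
            assert row.ka_per_h == pytest.approx(
                rate_at(a, e, row.temperature_c), rel=1e-9)

    def test_single_temperature_uses_k0(self):
        table = stability_table([make_series(0.02, condition="uv", temp=25.0)])
        assert table.iloc[0].ka_per_h == pytest.approx(table.iloc[0].k0_per_h)

    def test_target_temperature_row(self):
        a, e = arrhenius_from_anchors(1e-2, 40.0, 8e-2, 60.0)
        series = [make_series(rate_at(a, e, t), temp=t) for t in (40.0, 60.0)]
        table = stability_table(series, target_temperatures=[25.0])
        target = table[table.note.str.contains("target")]
        assert len(target) == 1
        assert target.iloc[0].ka_per_h == pytest.approx(rate_at(a, e, 25.0), rel=1e-6)
        assert "extrapolated" in target.iloc[0].note


class TestCsvInterface:
    def test_round_trip_with_replicates(self, tmp_path):
        rows = []
        for rep in (1, 2, 3):
            for t, rec in zip(TIMES, [100.0, 90.0, 70.0, 55.0]):
                rows.append(f"STD,acid,40,{t},{rep},{rec + rep - 2}")
        path = tmp_path / "deg.csv"
        path.write_text("sample_id,condition,temperature_c,time_h,replicate,"
                        "recovery_pct\n" + "\n".join(rows) + "\n")
        series = load_degradation_csv(path)
        assert len(series) == 1
        s = series[0]
        assert s.n_replicates == 3
        assert np.allclose(s.recovery, [100.0, 90.0, 70.0, 55.0])
        assert np.allclose(s.recovery_sd, 1.0)

    def test_area_reference_schema(self, tmp_path):
        path = tmp_path / "deg.csv"
        path.write_text(
            "sample_id,condition,temperature_c,time_h,replicate,area,area_ref\n"
            "STD,acid,40,0,1,1000,1000\nSTD,acid,40,24,1,800,1000\n")
        s = load_degradation_csv(path)[0]
        assert np.allclose(s.recovery, [100.0, 80.0])

    def test_missing_columns(self, tmp_path):
        import pandas as pd
        with pytest.raises(ValueError, match="missing columns"):
            series_from_frame(pd.DataFrame({"sample_id": ["a"]}))


class TestParameterRecoveryProperty:
    def test_activation_energy_median_error(self):
        # 3-temperature synthetic studies, true E in [0.3, 1.2] eV, RSD <= 2%
        rng = np.random.default_rng(2024)
        rel_errors = []
        for _ in range(200):
            e_true = rng.uniform(0.3, 1.2)
            k60 = rng.uniform(0.01, 0.05)
            # anchor A so that k(60) = k60 for the drawn E
            a_true = math.log(k60) + e_true * 11605.0 / (60.0 + 273.15)
            rates = {}
            for temp in (25.0, 40.0, 60.0):
                k = rate_at(a_true, e_true, temp)
                noise = 1 + rng.normal(0, 0.02, TIMES.size)
                fit = fit_first_order(make_series(k, noise=noise, temp=temp))
                if fit.k0 > 0:
                    rates[temp] = fit.k0
            if len(rates) < 2:
                continue
            model = fit_arrhenius(rates)
            rel_errors.append(abs(model.e_param - e_true) / e_true)
        assert np.median(rel_errors) < 0.15
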