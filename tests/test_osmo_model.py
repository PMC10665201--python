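"""Unit and property tests for the non-ideal osmometry model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psibuffer.osmo_model import (
    DilutionSeries,
    IdealSoluteSpec,
    OsmoticModelParams,
    additive_prediction,
    deviation_from_additivity,
    dilution_buffering_index,
    fit_nonideal,
    ieff_temperature_profile,
    osmolality_to_pressure,
    predict_osmolality,
    vant_hoff_osmolality,
)
from psibuffer.synthetic import (
    CondensingMixtureSpec,
    SyntheticOsmoSpec,
    gen_buffered_dilution,
    gen_condensing_mixture,
    gen_osmometry_series,
)


class TestElementaryRelations:
    @pytest.mark.parametrize(
        "conc,i,expected",
        [(0.0, 2.0, 0.0), (100.0, 1.0, 100.0), (150.0, 2.0, 300.0)],
    )
    def test_vant_hoff_osmolality(self, conc, i, expected):
        assert vant_hoff_osmolality(conc, IdealSoluteSpec(vant_hoff_factor=i)) == expected

    def test_vant_hoff_rejects_negative_conc(self):
        with pytest.raises(ValueError):
            vant_hoff_osmolality(-1.0, IdealSoluteSpec())

    def test_pressure_conversion(self):
        # 1 mol/kg * rho_w * R * 298.15 K, by hand: 2.479e6 Pa
        assert osmolality_to_pressure(0.0, 298.15) == 0.0
        assert osmolality_to_pressure(1000.0, 298.15) == pytest.approx(2.479e6, rel=1e-3)
        assert osmolality_to_pressure(2000.0, 298.15) == pytest.approx(
            2 * osmolality_to_pressure(1000.0, 298.15)
        )

    def test_pressure_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            osmolality_to_pressure(100.0, 0.0)

    def test_predict_hand_value_and_limits(self):
        assert predict_osmolality((1.0, 0.002), 0.0) == 0.0
        assert predict_osmolality((1.0, 0.002), 400.0) == pytest.approx(2000.0)
        # I_eff = 0 reduces exactly to the linear van't Hoff form
        grid = np.linspace(0, 500, 11)
        np.testing.assert_array_equal(predict_osmolality((2.5, 0.0), grid), 2.5 * grid)

    def test_predict_pole_error(self):
        with pytest.raises(ValueError):
            predict_osmolality((1.0, 0.002), 500.0)

    @given(
        a=st.floats(0.5, 5.0),
        ieff=st.floats(0.0, 0.004),
        c=st.floats(1.0, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_predict_monotone_in_conc_and_ieff(self, a, ieff, c):
        v = predict_osmolality((a, ieff), c)
        assert predict_osmolality((a, ieff), c * 1.01) > v
        assert predict_osmolality((a, ieff + 1e-4), c) > v


class TestDilutionSeriesValidation:
    def test_rejects_decreasing_concentrations(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            DilutionSeries("x", 300.0, [1.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            DilutionSeries("x", 300.0, [1.0, 2.0], [1.0])

    def test_celsius_converted_to_kelvin(self):
        s = DilutionSeries("x", 27.0, [1.0, 2.0], [1.0, 2.0])
        assert s.temperature == pytest.approx(300.15)

    def test_baseline_correction_subtracts_buffer(self):
        s = DilutionSeries("x", 300.0, [1.0, 2.0], [11.0, 12.0], baseline_osmolality=10.0)
        np.testing.assert_allclose(s.baseline_corrected().osmolality, [1.0, 2.0])


class TestFitNonideal:
    def test_noise_free_recovery_exact(self):
        spec = SyntheticOsmoSpec(noise_sd_frac=0.0, n_replicates=1)
        params = fit_nonideal(gen_osmometry_series(spec))
        assert params.A == pytest.approx(spec.A_true, rel=1e-6)
        assert params.I_eff == pytest.approx(spec.I_eff_true, rel=1e-6)

    def test_linear_data_yields_zero_ieff_within_ci(self):
        spec = SyntheticOsmoSpec(I_eff_true=0.0, noise_sd_frac=0.0, n_replicates=1)
        params = fit_nonideal(gen_osmometry_series(spec))
        assert params.I_eff_ci95[0] <= params.I_eff <= params.I_eff_ci95[1]
        assert params.I_eff == pytest.approx(0.0, abs=1e-8)
        assert params.A == pytest.approx(1.0, rel=1e-6)

    def test_monte_carlo_recovery_and_coverage(self):
        """1% multiplicative noise, 3 curves x 8 concentrations, 200 sims:
        median relative errors < 5% and 95% CI coverage in [90%, 99%]."""
        n_sims = 200
        errs_a, errs_i, cov_a, cov_i = [], [], 0, 0
        for k in range(n_sims):
            spec = SyntheticOsmoSpec(seed=1000 + k)
            params = fit_nonideal(gen_osmometry_series(spec))
            errs_a.append(abs(params.A - spec.A_true) / spec.A_true)
            errs_i.append(abs(params.I_eff - spec.I_eff_true) / spec.I_eff_true)
            cov_a += params.A_ci95[0] <= spec.A_true <= params.A_ci95[1]
            cov_i += params.I_eff_ci95[0] <= spec.I_eff_true <= params.I_eff_ci95[1]
        assert np.median(errs_a) < 0.05
        assert np.median(errs_i) < 0.05
        assert 0.90 <= cov_a / n_sims <= 0.99
        assert 0.90 <= cov_i / n_sims <= 0.99

    def test_mixed_temperature_rejected(self):
        s1 = gen_osmometry_series(SyntheticOsmoSpec(seed=0), temperature=27.0)
        s2 = gen_osmometry_series(SyntheticOsmoSpec(seed=1), temperature=37.0)
        with pytest.raises(ValueError, match="temperature"):
            fit_nonideal(s1 + s2)

    def test_bootstrap_ci_brackets_point_estimate(self):
        series = gen_osmometry_series(SyntheticOsmoSpec(seed=7))
        params = fit_nonideal(series, ci_method="bootstrap", n_bootstrap=200, seed=3)
        assert params.I_eff_ci95[0] <= params.I_eff <= params.I_eff_ci95[1]
        repeat = fit_nonideal(series, ci_method="bootstrap", n_bootstrap=200, seed=3)
        assert repeat.I_eff_ci95 == params.I_eff_ci95  # seeded and reproducible

    def test_params_invariants(self):
        with pytest.raises(ValueError):
            OsmoticModelParams(A=-1.0, I_eff=0.0)
        with pytest.raises(ValueError):
            OsmoticModelParams(A=1.0, I_eff=-0.1)


class TestTemperatureProfile:
    def test_recovers_decreasing_ieff_trend(self):
        by_t = {
            t: gen_osmometry_series(
                SyntheticOsmoSpec(noise_sd_frac=0.0, n_replicates=1, ieff_slope=2e-5),
                temperature=t,
            )
            for t in [17.0, 22.0, 27.0, 32.0, 37.0]
        }
        profile = ieff_temperature_profile(by_t)
        temps = [t for t, _ in profile]
        ieffs = [p.I_eff for _, p in profile]
        assert temps == sorted(temps)
        assert all(np.diff(ieffs) < 0)  # interactions grow as temperature falls

    def test_single_temperature_matches_fit_nonideal(self):
        series = gen_osmometry_series(SyntheticOsmoSpec(seed=5))
        profile = ieff_temperature_profile({27.0: series})
        assert len(profile) == 1
        assert profile[0][1].I_eff == pytest.approx(fit_nonideal(series).I_eff)

    def test_failures_do_not_abort_other_temperatures(self):
        good = gen_osmometry_series(SyntheticOsmoSpec(seed=5))
        bad = [
            DilutionSeries("x", 17.0, [1.0, 2.0], [1.0, 2.0]),  # < 3 concentrations
        ]
        profile = ieff_temperature_profile({17.0: bad, 27.0: good})
        assert isinstance(profile[0][1], Exception)
        assert isinstance(profile[1][1], object) and profile[1][1].I_eff >= 0


def _ideal_series(name, slope, cmax=300.0, n=7, sem=None):
    c = np.linspace(0.0, cmax, n)
    return DilutionSeries(name, 300.0, c, slope * c, sem=None if sem is None else np.full(n, sem))


class TestAdditivity:
    def test_component_at_zero_is_identity(self):
        a = _ideal_series("a", 2.0)
        b = _ideal_series("b", 1.0)
        pred = additive_prediction(a, b, (1.0, 0.0), total_conc=np.linspace(0, 300, 5))
        np.testing.assert_allclose(pred.predicted, 2.0 * pred.concentrations)

    def test_two_ideal_solutes_linear_with_weighted_slope(self):
        a = _ideal_series("a", 2.0)
        b = _ideal_series("b", 1.0)
        pred = additive_prediction(a, b, (2.0, 1.0), total_conc=np.linspace(0, 300, 5))
        expected_slope = (2 / 3) * 2.0 + (1 / 3) * 1.0
        np.testing.assert_allclose(pred.predicted, expected_slope * pred.concentrations)

    def test_error_propagation_3_4_5(self):
        a = _ideal_series("a", 2.0, sem=3.0)
        b = _ideal_series("b", 1.0, sem=4.0)
        pred = additive_prediction(a, b, (1.0, 1.0), total_conc=np.array([100.0]))
        assert pred.predicted_sem[0] == pytest.approx(5.0)

    def test_no_silent_extrapolation(self):
        a = _ideal_series("a", 2.0, cmax=100.0)
        b = _ideal_series("b", 1.0, cmax=100.0)
        with pytest.raises(ValueError, match="outside the measured range"):
            additive_prediction(a, b, (1.0, 1.0), total_conc=np.array([500.0]))

    def test_observed_equals_predicted_gives_zero_deviation(self):
        a = _ideal_series("a", 2.0)
        b = _ideal_series("b", 1.0)
        grid = np.linspace(0.0, 300.0, 5)
        pred = additive_prediction(a, b, (2.0, 1.0), total_conc=grid)
        obs = DilutionSeries("obs", 300.0, grid, pred.predicted)
        res = deviation_from_additivity(pred, obs)
        np.testing.assert_allclose(res.percent_deviation[1:], 0.0, atol=1e-12)
        assert res.summary_deviation == pytest.approx(0.0, abs=1e-12)

    def test_condensing_mixture_positive_above_threshold(self):
        spec = CondensingMixtureSpec()
        grid = np.linspace(60.0, 600.0, 19)
        obs, macro, solute = gen_condensing_mixture(spec, grid)
        pred = additive_prediction(macro, solute, (2.0, 1.0), total_conc=grid)
        res = deviation_from_additivity(pred, obs)
        above = pred.predicted > spec.osm_c
        below = pred.predicted < spec.osm_c / 2
        assert res.summary_deviation > 0
        assert np.all(res.percent_deviation[above] > 1.0)
        assert np.all(np.abs(res.percent_deviation[below & (grid > 0)]) < 1.0)

    def test_ideal_mixture_with_noise_bounded_deviation(self, rng):
        sd = 2.0
        grid = np.linspace(0.0, 300.0, 7)
        a = _ideal_series("a", 2.0)
        b = _ideal_series("b", 1.0)
        pred = additive_prediction(a, b, (1.0, 1.0), total_conc=grid)
        devs = []
        for _ in range(100):
            noisy = pred.predicted + rng.normal(0, sd, size=grid.size)
            noisy[0] = 0.0
            obs = DilutionSeries("obs", 300.0, grid, noisy)
            devs.append(
                deviation_from_additivity(pred, obs, conc_floor=grid[1]).summary_deviation
            )
        mean_level = pred.predicted[1:].mean()
        assert abs(np.mean(devs)) < 3 * sd / mean_level * 100


class TestBufferingIndex:
    def test_linear_series_index_zero(self):
        d = np.linspace(0.05, 1.0, 10)
        res = dilution_buffering_index(d, 500.0 * d)
        assert res.buffering_index == pytest.approx(0.0, abs=1e-12)

    def test_buffered_extract_positive_index(self):
        d = np.linspace(0.05, 1.0, 12)
        spec = CondensingMixtureSpec(I_eff=0.0025, hydration_release_frac=1.0, steepness=0.02)
        _, osm = gen_buffered_dilution(spec, d)
        assert dilution_buffering_index(d, osm).buffering_index > 0.05

    def test_ideal_extract_generator_index_zero(self):
        d = np.linspace(0.05, 1.0, 12)
        spec = CondensingMixtureSpec(I_eff=0.0, hydration_release_frac=0.0)
        _, osm = gen_buffered_dilution(spec, d)
        assert dilution_buffering_index(d, osm).buffering_index == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        d = np.linspace(0.05, 1.0, 12)
        spec = CondensingMixtureSpec(I_eff=0.0025, hydration_release_frac=1.0, steepness=0.02)
        _, osm = gen_buffered_dilution(spec, d)
        i1 = dilution_buffering_index(d, osm).buffering_index
        i2 = dilution_buffering_index(d, 7.3 * osm).buffering_index
        assert i2 == pytest.approx(i1, rel=1e-12)

    def test_too_few_linear_points_raises_config_error(self):
        d = np.array([0.5, 0.7, 0.9, 1.0])
        with pytest.raises(ValueError, match="d_lin"):
            dilution_buffering_index(d, 500 * d, d_lin=0.3)
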