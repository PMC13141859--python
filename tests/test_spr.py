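import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ternscan import (
    InjectionSeries,
    KineticParams,
    binary_series,
    cooperativity,
    derive_constants,
    dilution_series,
    fit_kinetics,
    make_sensorgram_dataset,
    read_sensorgrams,
    simulate_sensorgram,
    ternary_series,
    write_sensorgrams,
)
from ternscan.spr import FitError


class TestDilutionSeries:
    def test_ten_point_two_fold_from_50mM_ends_near_98uM(self):
        series = dilution_series(50e-3, 2.0, 10)
        assert len(series) == 10
        assert series[-1] == pytest.approx(50e-3 / 2**9)
        assert series[-1] * 1e6 == pytest.approx(97.65625)

    def test_single_point(self):
        np.testing.assert_array_equal(dilution_series(1e-6, 2.0, 1), [1e-6])

    def test_five_point_series_ends_at_62_5_nM(self):
        series = dilution_series(1e-6, 2.0, 5)
        assert series[-1] == pytest.approx(62.5e-9)

    @pytest.mark.parametrize("top,fold,n", [(-1, 2, 3), (1e-6, 1.0, 3), (1e-6, 2, 0)])
    def test_invalid_parameters_rejected(self, top, fold, n):
        with pytest.raises(ValueError):
            dilution_series(top, fold, n)

    def test_paper_series_factories(self):
        binary = binary_series()
        assert len(binary.concentrations) == 10
        assert (binary.contact_time, binary.dissociation_time) == (120.0, 180.0)
        ternary = ternary_series()
        assert len(ternary.concentrations) == 5
        assert ternary.concentrations[0] == pytest.approx(1e-6)
        assert ternary.concentrations[-1] == pytest.approx(62.5e-9)
        assert (ternary.contact_time, ternary.dissociation_time) == (400.0, 600.0)


LS2 = KineticParams(k_on=1.47e5, k_off=0.0085, Rmax=100.0)


class TestSimulateSensorgram:
    def test_zero_concentration_gives_flat_zero(self):
        gram = simulate_sensorgram(LS2, 0.0, 400.0, 600.0)
        np.testing.assert_array_equal(gram.response, 0.0)

    def test_long_contact_plateaus_at_equilibrium_response(self):
        conc = 1e-6
        gram = simulate_sensorgram(LS2, conc, 50_000.0, 10.0)
        r_eq = LS2.Rmax * conc / (conc + LS2.K_D)
        assert gram.response[np.searchsorted(gram.time, 50_000.0) - 1] == pytest.approx(
            r_eq, rel=1e-6
        )

    def test_matches_independent_ode_integration(self):
        """Closed-form curve vs direct integration of
        dR/dt = k_on·C·(Rmax−R) − k_off·R with C switched off at t_contact."""
        conc, t_c, t_d = 0.5e-6, 400.0, 600.0
        gram = simulate_sensorgram(LS2, conc, t_c, t_d, dt=1.0)

        def rhs(t, r):
            c = conc if t <= t_c else 0.0
            return LS2.k_on * c * (LS2.Rmax - r[0]) - LS2.k_off * r[0]

        assoc = solve_ivp(
            rhs, (0, t_c), [0.0], t_eval=gram.time[gram.time <= t_c],
            rtol=1e-11, atol=1e-12, max_step=1.0,
        )
        dissoc = solve_ivp(
            rhs, (t_c, gram.time[-1]), [assoc.y[0, -1]],
            t_eval=gram.time[gram.time > t_c], rtol=1e-11, atol=1e-12, max_step=1.0,
        )
        oracle = np.concatenate([assoc.y[0], dissoc.y[0]])
        assert np.max(np.abs(gram.response - oracle)) < 1e-6

    def test_noise_free_phases_are_monotone_and_bounded(self):
        conc = 0.25e-6
        gram = simulate_sensorgram(LS2, conc, 400.0, 600.0)
        assoc = gram.response[gram.time <= 400.0]
        dissoc = gram.response[gram.time > 400.0]
        assert np.all(np.diff(assoc) >= 0)
        assert np.all(np.diff(dissoc) <= 0)
        assert assoc.max() <= LS2.Rmax * conc / (conc + LS2.K_D) + 1e-9

    def test_noise_reproducible_from_seed(self):
        a = simulate_sensorgram(LS2, 1e-6, 400.0, 600.0, noise_sd=2.0, seed=11)
        b = simulate_sensorgram(LS2, 1e-6, 400.0, 600.0, noise_sd=2.0, seed=11)
        np.testing.assert_array_equal(a.response, b.response)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_sensorgram(LS2, -1e-9, 400.0, 600.0)


class TestFitKinetics:
    def test_noise_free_self_consistency(self):
        grams, _ = make_sensorgram_dataset(LS2, ternary_series(), noise_sd=0.0, seed=0)
        fit = fit_kinetics(grams)
        assert fit.params.k_on == pytest.approx(LS2.k_on, rel=1e-4)
        assert fit.params.k_off == pytest.approx(LS2.k_off, rel=1e-4)
        assert fit.params.Rmax == pytest.approx(LS2.Rmax, rel=1e-4)

    def test_noisy_recovery_within_ten_percent(self):
        grams, _ = make_sensorgram_dataset(
            LS2, ternary_series(), noise_sd=0.02 * LS2.Rmax, seed=42
        )
        fit = fit_kinetics(grams)
        assert fit.params.k_on == pytest.approx(LS2.k_on, rel=0.10)
        assert fit.params.k_off == pytest.approx(LS2.k_off, rel=0.10)
        assert fit.stderr_k_on > 0 and fit.stderr_k_off > 0

    def test_narrow_series_warns(self):
        series = InjectionSeries(
            concentrations=(1e-7,), contact_time=400.0, dissociation_time=600.0
        )
        grams, _ = make_sensorgram_dataset(LS2, series, noise_sd=3.0, seed=1)
        with pytest.warns(UserWarning, match="4-fold"):
            fit_kinetics(grams)

    def test_flat_data_rejected(self):
        grams = [simulate_sensorgram(LS2, 0.0, 400.0, 600.0)]
        with pytest.raises(FitError):
            fit_kinetics(grams)


class TestDerivedConstants:
    def test_ls2_published_rates_give_58_nM_and_81_s(self):
        kd, t_half = derive_constants(KineticParams(1.47e5, 0.0085, 100.0))
        assert kd * 1e9 == pytest.approx(57.82, abs=0.01)
        assert round(kd * 1e9) == 58
        assert t_half == pytest.approx(81.55, abs=0.01)
        assert abs(t_half - 81.0) <= 1.0  # matches the printed 81 s within rounding

    def test_unit_rates(self):
        kd, t_half = derive_constants(KineticParams(1.0, 1.0, 1.0))
        assert kd == 1.0
        assert t_half == pytest.approx(np.log(2))

    def test_doubling_k_off_scaling_law(self):
        kd1, th1 = derive_constants(KineticParams(1e5, 0.01, 50.0))
        kd2, th2 = derive_constants(KineticParams(1e5, 0.02, 50.0))
        assert kd2 == pytest.approx(2 * kd1)
        assert th2 == pytest.approx(th1 / 2)


class TestCooperativity:
    def test_ls1_alpha_3_1_positive(self):
        result = cooperativity(1320e-9, 426e-9)
        assert result.alpha == pytest.approx(3.1, abs=0.05)
        assert result.classification == "positive"

    def test_ls2_alpha_31_2_positive(self):
        result = cooperativity(1810e-9, 58e-9)
        assert result.alpha == pytest.approx(31.2, abs=0.05)
        assert result.classification == "positive"

    def test_equal_kds_neutral(self):
        assert cooperativity(5e-7, 5e-7).classification == "neutral"

    def test_negative_cooperativity_label(self):
        assert cooperativity(1e-7, 5e-7).classification == "negative"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cooperativity(0.0, 1e-7)

    @settings(deadline=None, max_examples=30)
    @given(
        kd_b=st.floats(1e-9, 1e-5), kd_t=st.floats(1e-9, 1e-5),
        scale=st.floats(1e-3, 1e3),
    )
    def test_alpha_scale_invariant(self, kd_b, kd_t, scale):
        a1 = cooperativity(kd_b, kd_t).alpha
        a2 = cooperativity(kd_b * scale, kd_t * scale).alpha
        assert a2 == pytest.approx(a1, rel=1e-9)


class TestSensorgramIO:
    def test_round_trip(self, tmp_path):
        grams, _ = make_sensorgram_dataset(LS2, ternary_series(), noise_sd=1.0, seed=3)
        path = tmp_path / "sensorgrams.csv"
        write_sensorgrams(grams, path)
        back = read_sensorgrams(path)
        assert len(back) == len(grams)
        for orig, rt in zip(grams, back):
            np.testing.assert_allclose(rt.response, orig.response)
            assert rt.concentration == pytest.approx(orig.concentration)
            assert rt.t_contact == orig.t_contact

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_sensorgrams(path)

    def test_unparseable_field_reports_line_number(self, tmp_path):
        path = tmp_path / "bad2.csv"
        path.write_text(
            "time_s,response_RU,concentration_M,cycle_id\n"
            "0.0,1.0,1e-6,0\n"
            "1.0,oops,1e-6,0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_sensorgrams(path)
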