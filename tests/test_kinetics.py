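"""Kinetic fits: forward-then-invert oracles, derived constants, Patlak."""

import numpy as np
import pytest
from scipy import stats

import nafsim as nf
from nafsim.kinetics import FitConvergenceError

LN2 = np.log(2.0)

ASSOC_TIMES = np.array([0.0, 5.0, 15.0, 30.0, 60.0])
WASH_TIMES = np.array([0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])


class TestFitAssociation:
    def test_noiseless_curve_recovers_k_obs(self, printed_params):
        tac = nf.TimeActivityCurve(
            ASSOC_TIMES, 2.0 * nf.association_timecourse(printed_params, ASSOC_TIMES)
        )
        fit = nf.fit_association(tac, 1e-11, k_off_known=0.0027)
        assert fit.k_obs == pytest.approx(0.0477, rel=1e-6)
        assert fit.k_on == pytest.approx(4.5e9, rel=1e-6)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-6)

    def test_recovered_half_time_within_printed_uncertainty(self, printed_params):
        tac = nf.TimeActivityCurve(
            ASSOC_TIMES, nf.association_timecourse(printed_params, ASSOC_TIMES)
        )
        fit = nf.fit_association(tac, 1e-11)
        assert 14.3 - 1.9 <= fit.half_time_assoc <= 14.3 + 1.9

    def test_flat_zero_curve_raises(self):
        tac = nf.TimeActivityCurve(ASSOC_TIMES, np.zeros_like(ASSOC_TIMES))
        with pytest.raises(FitConvergenceError):
            nf.fit_association(tac, 1e-11)

    def test_k_obs_not_exceeding_k_off_raises(self, printed_params):
        tac = nf.TimeActivityCurve(
            ASSOC_TIMES, nf.association_timecourse(printed_params, ASSOC_TIMES)
        )
        with pytest.raises(FitConvergenceError, match="k_off"):
            nf.fit_association(tac, 1e-11, k_off_known=1.0)

    def test_too_few_points_rejected(self):
        tac = nf.TimeActivityCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 1.5]))
        with pytest.raises(ValueError, match="4 points"):
            nf.fit_association(tac, 1e-11)


class TestFitDissociation:
    def test_noiseless_washout_recovers_k_off(self, printed_params):
        tac = nf.TimeActivityCurve(
            WASH_TIMES, nf.dissociation_timecourse(printed_params, 1.0, WASH_TIMES)
        )
        fit = nf.fit_dissociation(tac)
        assert fit.k_off == pytest.approx(0.0027, rel=1e-6)
        assert 254 - 43 <= fit.half_time_dissoc <= 254 + 43

    def test_constant_curve_gives_zero_rate(self):
        tac = nf.TimeActivityCurve(WASH_TIMES, np.full_like(WASH_TIMES, 3.0))
        fit = nf.fit_dissociation(tac)
        assert fit.k_off == pytest.approx(0.0, abs=1e-8)


class TestDeriveKd:
    @pytest.mark.parametrize(
        "k_on, k_off, expected",
        [(4.5e9, 0.0027, 6.0e-13), (1e9, 1e-3, 1e-12), (7.7e8, 0.0, 0.0)],
    )
    def test_ratio(self, k_on, k_off, expected):
        assert nf.derive_kd(k_on, k_off) == pytest.approx(expected, rel=1e-12, abs=1e-30)

    def test_printed_constants_give_0p6_picomolar(self):
        assert nf.derive_kd(4.5e9, 0.0027) * 1e12 == pytest.approx(0.6, rel=1e-12)

    def test_nonpositive_k_on_rejected(self):
        with pytest.raises(ValueError, match="k_on"):
            nf.derive_kd(0.0, 0.1)


class TestConcentrationResponse:
    def test_calibration_line_recovered_exactly(self):
        concs = 10.0 ** np.arange(-12.0, -6.0)
        acts = 10.0 ** (0.92 * np.log10(concs) + 13.0)
        fit = nf.fit_concentration_response(concs, acts)
        assert fit.slope == pytest.approx(0.92, abs=1e-12)
        assert fit.intercept == pytest.approx(13.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_proportional_data_has_unit_slope(self):
        concs = np.array([1e-10, 1e-9, 1e-8])
        fit = nf.fit_concentration_response(concs, 5.0 * concs)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_has_zero_slope(self):
        concs = np.array([1e-10, 1e-9, 1e-8])
        fit = nf.fit_concentration_response(concs, np.full(3, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nf.fit_concentration_response([1e-10, 1e-9, 1e-8], [1.0, -1.0, 2.0])


class TestPatlak:
    def test_plaque_like_influx_recovered_within_printed_range(self):
        st = nf.simulate_dynamic_study(0.003, 0.3, nf.default_plasma_model())
        res = nf.patlak(st.tissue, st.plasma, frame_durations_min=st.frame_durations_min)
        assert 0.0005 <= res.ki <= 0.007
        assert res.ki == pytest.approx(0.003, rel=1e-3)

    def test_zero_influx_gives_flat_patlak_line(self):
        st = nf.simulate_dynamic_study(0.0, 0.45, nf.default_plasma_model())
        res = nf.patlak(st.tissue, st.plasma, frame_durations_min=st.frame_durations_min)
        assert res.ki == pytest.approx(0.0, abs=1e-12)
        assert res.v == pytest.approx(0.45, rel=1e-9)

    def test_trapezoid_error_shrinks_under_grid_refinement(self):
        # plain-TAC path: uniform schedules, finer frames → smaller Ki error
        plasma = nf.default_plasma_model()
        errors = []
        for frame_s in (120.0, 15.0):
            n = int(3120 / frame_s)
            st = nf.simulate_dynamic_study(0.05, 0.3, plasma, schedule_s=[frame_s] * n)
            res = nf.patlak(st.tissue, st.plasma)  # trapezoid, no durations
            errors.append(abs(res.ki - 0.05))
        assert errors[1] < errors[0]

    def test_too_few_points_after_cutoff_rejected(self):
        t = np.array([1.0, 2.0, 12.0, 20.0])
        plasma = nf.TimeActivityCurve(t, np.full(4, 1.0), "blood")
        tissue = nf.TimeActivityCurve(t, np.full(4, 0.5), "tissue")
        with pytest.raises(ValueError, match="3 usable"):
            nf.patlak(tissue, plasma)

    def test_nonpositive_plasma_rejected(self):
        t = np.arange(1.0, 8.0)
        plasma = nf.TimeActivityCurve(t, np.array([1, 1, 0, 1, 1, 1, 1.0]), "blood")
        tissue = nf.TimeActivityCurve(t, np.ones(7), "tissue")
        with pytest.raises(ValueError, match="positive"):
            nf.patlak(tissue, plasma)


class TestFitPlasmaBiexponential:
    def test_noiseless_parameters_recovered(self):
        truth = nf.PlasmaModel(a1=0.8, a2=0.2, lam1=0.3, lam2=0.01)
        t = np.linspace(0.5, 60.0, 25)
        model, diag = nf.fit_plasma_biexponential(
            nf.TimeActivityCurve(t, truth(t), "plasma")
        )
        assert model.a1 == pytest.approx(0.8, rel=1e-4)
        assert model.lam1 == pytest.approx(0.3, rel=1e-4)
        assert model.a2 == pytest.approx(0.2, rel=1e-4)
        assert model.lam2 == pytest.approx(0.01, rel=1e-4)
        assert not diag["degenerate"]

    def test_single_exponential_flagged_degenerate(self):
        t = np.linspace(0.5, 60.0, 25)
        tac = nf.TimeActivityCurve(t, 0.7 * np.exp(-0.05 * t), "plasma")
        _, diag = nf.fit_plasma_biexponential(tac)
        assert diag["degenerate"]

    def test_default_preset_refit_keeps_60min_fraction_in_range(self):
        truth = nf.default_plasma_model()
        t = np.linspace(0.5, 70.0, 36)
        model, _ = nf.fit_plasma_biexponential(
            nf.TimeActivityCurve(t, truth(t), "plasma")
        )
        assert 0.04 <= model(60.0) / model(0.0) <= 0.08


class TestInternalConsistency:
    def test_kd_and_half_times_consistent_with_rates(self, printed_params):
        tac = nf.TimeActivityCurve(
            ASSOC_TIMES, nf.association_timecourse(printed_params, ASSOC_TIMES)
        )
        fit = nf.fit_association(tac, 1e-11, k_off_known=0.0027)
        assert fit.kd_m * fit.k_on == pytest.approx(fit.k_off, rel=1e-12)
        assert fit.half_time_assoc * fit.k_obs == pytest.approx(LN2, rel=1e-12)
        assert fit.half_time_dissoc * fit.k_off == pytest.approx(LN2, rel=1e-12)

    def test_fitted_k_obs_is_affine_in_ligand_concentration(self):
        # k_obs = k_on·L + k_off: slope and intercept recovered over 4 levels
        concs = np.array([0.5e-11, 1e-11, 2e-11, 4e-11])
        kobs = []
        for L in concs:
            p = nf.KineticParameters(ligand_conc=L)
            tac = nf.TimeActivityCurve(
                ASSOC_TIMES, nf.association_timecourse(p, ASSOC_TIMES)
            )
            kobs.append(nf.fit_association(tac, L).k_obs)
        res = stats.linregress(concs, kobs)
        assert res.slope == pytest.approx(4.5e9, rel=1e-5)
        assert res.intercept == pytest.approx(0.0027, rel=1e-4)
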