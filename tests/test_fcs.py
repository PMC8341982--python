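"""FCS correlation, model fitting, corrections and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wntquant.fcs import (
    ALEXA488_D,
    AutocorrelationCurve,
    Calibration,
    FcsModelParams,
    FitConfig,
    IntensityTrace,
    StokesScalingInput,
    autocorrelate,
    calibrate,
    correct_particle_number,
    diffusion_coefficient,
    eval_model,
    fit_acf,
    qc_trace,
    stokes_scale,
    to_concentration,
)


def brute_force_g(counts: np.ndarray, lag_bins: int) -> float:
    """Definitional O(n) sum per lag, written independently of the library."""
    mean = sum(counts) / len(counts)
    acc = 0.0
    for t in range(len(counts) - lag_bins):
        acc += (counts[t] - mean) * (counts[t + lag_bins] - mean)
    return 1.0 + acc / (len(counts) - lag_bins) / mean**2


class TestAutocorrelate:
    def test_matches_brute_force_oracle(self, rng):
        counts = rng.poisson(4.0, 2500)
        acf = autocorrelate(IntensityTrace(counts=counts, bin_width=1e-4))
        lag_bins = np.rint(acf.lags / 1e-4).astype(int)
        for k, g in list(zip(lag_bins, acf.g))[::7]:
            assert abs(g - brute_force_g(counts.tolist(), int(k))) < 1e-10

    def test_matches_vectorized_oracle_at_ten_thousand_bins(self, rng):
        counts = rng.poisson(3.0, 10_000).astype(float)
        acf = autocorrelate(IntensityTrace(counts=counts, bin_width=2e-5))
        mean = counts.mean()
        d = counts - mean
        for k, g in zip(np.rint(acf.lags / 2e-5).astype(int), acf.g):
            expected = 1.0 + np.sum(d[:-k] * d[k:]) / (len(d) - k) / mean**2
            assert abs(g - expected) < 1e-10

    def test_constant_trace_has_unit_correlation(self):
        acf = autocorrelate(IntensityTrace(counts=np.full(2000, 9), bin_width=1e-4))
        np.testing.assert_allclose(acf.g, 1.0)

    def test_alternating_toy_trace_at_unit_lag(self):
        """[2,4,2,4,...]: g at one-bin lag is 1 - variance/mean^2 = 8/9."""
        counts = np.tile([2, 4], 600)
        acf = autocorrelate(IntensityTrace(counts=counts, bin_width=1e-3),
                            min_lag_bins=1)
        assert acf.g[0] == pytest.approx(1.0 - 1.0 / 9.0, abs=1e-3)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            autocorrelate(IntensityTrace(counts=np.ones(500), bin_width=1e-4))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            autocorrelate(IntensityTrace(counts=np.zeros(2000), bin_width=1e-4))


class TestEvalModel:
    def params(self, **kw):
        d = dict(g_inf=1.0, n_particles=50.0, f_trip=0.15, tau_trip_ms=0.01,
                 components=((0.6, 1.0), (0.4, 50.0)), sp=5.0)
        d.update(kw)
        return FcsModelParams(**d)

    def test_long_lag_limit_is_offset(self):
        p = self.params()
        assert eval_model(p, np.array([1e4]))[0] == pytest.approx(p.g_inf)

    def test_zero_lag_amplitude_is_inverse_particle_number(self):
        p = self.params(f_trip=0.0, components=((1.0, 2.0),))
        assert eval_model(p, np.array([1e-12]))[0] == pytest.approx(
            p.g_inf + 1.0 / p.n_particles)

    def test_against_independent_symbolic_evaluation(self):
        import sympy as sy
        p = self.params()
        tau = sy.Symbol("tau")
        trip = 1 + sy.Rational(15, 100) / (1 - sy.Rational(15, 100)) \
            * sy.exp(-tau / sy.Rational(1, 100))
        diff = (sy.Rational(6, 10) / ((1 + tau / 1) * sy.sqrt(1 + tau / 25))
                + sy.Rational(4, 10) / ((1 + tau / 50) * sy.sqrt(1 + tau / 1250)))
        expr = 1 + trip * diff / 50
        for lag_ms in (0.005, 0.1, 1.0, 20.0, 300.0):
            expected = float(expr.subs(tau, sy.Float(lag_ms, 30)))
            got = eval_model(p, np.array([lag_ms * 1e-3]))[0]
            assert got == pytest.approx(expected, rel=1e-10)

    @given(st.floats(min_value=-6, max_value=1))
    def test_monotone_decay_without_triplet(self, log_tau):
        p = self.params(f_trip=0.0)
        taus = 10.0 ** np.array([log_tau, log_tau + 0.1])
        g = eval_model(p, taus)
        assert g[0] >= g[1]

    def test_axial_variant_differs(self):
        p = self.params()
        lags = np.array([1e-3])
        assert eval_model(p, lags, axial="full")[0] < eval_model(p, lags)[0]


class TestFitAcf:
    def make_curve(self, p, rng, noise=0.01):
        lags = np.geomspace(1e-4, 1.0, 80)
        g = eval_model(p, lags)
        g = g + rng.normal(0.0, noise * (g - p.g_inf + 0.002))
        return AutocorrelationCurve(lags=lags, g=g)

    def test_two_component_recovery_over_replicates(self):
        """Known two-component curves + 1% noise: N and fractions back
        within 10% (median over 50 seeded replicates)."""
        true = FcsModelParams(g_inf=1.0, n_particles=80.0, f_trip=0.0,
                              tau_trip_ms=1e-3,
                              components=((0.65, 1.38), (0.35, 69.0)), sp=5.0)
        cfg = FitConfig(sp=5.0, fix_tau1_ms=1.38)
        ns, f2s = [], []
        for seed in range(50):
            acf = self.make_curve(true, np.random.default_rng(seed))
            fit = fit_acf(acf, cfg)
            ns.append(fit.params.n_particles)
            f2s.append(fit.params.components[1][0])
        assert abs(np.median(ns) / 80.0 - 1.0) < 0.10
        assert abs(np.median(f2s) - 0.35) < 0.035

    def test_single_component_data_yields_negligible_second_fraction(self, rng):
        true = FcsModelParams(g_inf=1.0, n_particles=60.0, f_trip=0.0,
                              tau_trip_ms=1e-3, components=((1.0, 1.38),), sp=5.0)
        acf = self.make_curve(true, rng, noise=0.005)
        fit = fit_acf(acf, FitConfig(sp=5.0, fix_tau1_ms=1.38))
        assert fit.params.components[1][0] < 0.05

    def test_structured_residuals_are_flagged_not_dropped(self, rng):
        """A curve from the wrong model family fits badly; the runs test
        flags it but a result is still returned."""
        lags = np.geomspace(1e-4, 1.0, 80)
        g = 1.0 + 0.02 * np.exp(-(np.log10(lags) + 2.0) ** 2)  # bump, not a decay
        fit = fit_acf(AutocorrelationCurve(lags=lags, g=g), FitConfig(sp=5.0, fix_tau1_ms=1.38))
        assert "residual_runs_test" in fit.exclusion_flags

    def test_too_few_points_rejected(self):
        lags = np.geomspace(1e-4, 1e-2, 10)
        with pytest.raises(ValueError, match="points"):
            fit_acf(AutocorrelationCurve(lags=lags, g=np.ones(10)),
                    FitConfig(sp=5.0))


class TestQc:
    def test_constant_trace_accepted_in_full(self, rng):
        counts = rng.poisson(10.0, 120_000)
        qc = qc_trace(IntensityTrace(counts=counts, bin_width=1e-3))
        assert qc.accepted
        a, b = qc.window
        assert b - a >= 115.0

    def test_strong_bleach_rejected_with_reason(self, rng):
        t = np.arange(120_000) * 1e-3
        lam = 10.0 * (1.0 - 0.5 * t / 120.0)  # 50% monotone bleach
        counts = rng.poisson(lam)
        qc = qc_trace(IntensityTrace(counts=counts, bin_width=1e-3))
        assert not qc.accepted
        assert qc.reason == "bleaching"

    def test_step_artifact_excluded_from_window(self, rng):
        lam = np.where(np.arange(120_000) < 40_000, 12.0, 6.0)  # cell movement
        counts = rng.poisson(lam)
        qc = qc_trace(IntensityTrace(counts=counts, bin_width=1e-3))
        assert qc.accepted
        a, b = qc.window
        assert a >= 39.0  # the long clean stretch after the step
        assert b - a >= 30.0


class TestCorrectionsAndCalibration:
    @pytest.mark.parametrize("n,auto_frac,ratio,expected", [
        (100.0, 0.0, 1.0, 100.0),
        (100.0, 0.1, 1.0, 81.0),
        (50.0, 0.05, 1.2, 54.15),
    ])
    def test_particle_number_correction(self, n, auto_frac, ratio, expected):
        out = correct_particle_number(n, i_total=1000.0,
                                      i_autofluorescence=auto_frac * 1000.0,
                                      i_start=ratio * 800.0, i_ana=800.0)
        assert out == pytest.approx(expected)

    def test_correction_preconditions(self):
        with pytest.raises(ValueError):
            correct_particle_number(10.0, i_total=5.0, i_autofluorescence=6.0,
                                    i_start=1.0, i_ana=1.0)

    def test_reference_dye_calibration(self):
        cal = calibrate(0.025, sp=5.0)
        assert cal.omega_xy == pytest.approx(math.sqrt(4 * 435 * 2.5e-5))
        assert cal.omega_xy == pytest.approx(0.2086, abs=2e-4)

    def test_volume_linear_in_structural_parameter(self):
        v1 = calibrate(0.025, sp=4.0).volume
        v2 = calibrate(0.025, sp=8.0).volume
        assert v2 == pytest.approx(2.0 * v1)

    def test_calibration_diffusion_round_trip(self):
        cal = calibrate(0.031, sp=6.0)
        assert diffusion_coefficient(0.031, cal.omega_xy) == pytest.approx(ALEXA488_D)

    def test_diffusion_inverse_in_tau(self):
        assert diffusion_coefficient(2.0, 0.3) == pytest.approx(
            diffusion_coefficient(1.0, 0.3) / 2.0)

    def test_concentration_zero_and_single_particle(self):
        cal = Calibration(omega_xy=0.25, sp=5.0, volume=1.0, d_ref=435.0)
        assert to_concentration(0.0, cal) == 0.0
        assert to_concentration(1.0, cal) == pytest.approx(1.66, abs=0.01)

    def test_reported_number_concentration_pair_fixes_the_volume(self):
        """80 molecules <-> 180 nM back-solves to the ~0.74 fl default
        fixture volume."""
        volume = 80.0 / (180e-9 * 6.02214076e23 * 1e-15)
        assert volume == pytest.approx(0.738, abs=0.002)
        cal = Calibration(omega_xy=0.2867, sp=5.0, volume=volume, d_ref=435.0)
        assert to_concentration(80.0, cal) == pytest.approx(180.0, rel=1e-6)

    def test_component_split_sums_to_total(self):
        cal = Calibration(omega_xy=0.25, sp=5.0, volume=0.5, d_ref=435.0)
        total, comps = to_concentration(60.0, cal, fractions=(0.65, 0.35))
        assert sum(comps) == pytest.approx(total)


class TestStokesScaling:
    def test_monomeric_fusion_prediction(self):
        d = stokes_scale(StokesScalingInput(d_ref=24.1, mass_ref=27.0,
                                            mass_target=115.0))
        assert round(d, 1) == 14.9

    def test_equal_masses_unchanged(self):
        assert stokes_scale(StokesScalingInput(10.0, 40.0, 40.0)) == 10.0

    def test_eightfold_mass_halves_the_coefficient(self):
        assert stokes_scale(StokesScalingInput(10.0, 5.0, 40.0)) == pytest.approx(5.0)
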