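"""Unit and property tests for the minimal WNT/CTNNB1 ODE model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wntquant.model import (
    DEFAULT_DC_TOTAL,
    DEFAULT_TCF_TOTAL,
    ModelState,
    RateParameters,
    SteadyStateError,
    WntSchedule,
    rhs,
    scan_parameter,
    simulate,
    steady_state,
)


def make_params(**kw) -> RateParameters:
    defaults = dict(b=0.423, K1=120.0, k3=0.423 / 62.5, k6k7=0.96,
                    K2=320.0, k5k4=1.7)
    defaults.update(kw)
    return RateParameters.from_ratios(**defaults)


class TestRhs:
    def test_matches_term_by_term_oracle(self, rng):
        """The vector field agrees with an independent per-term evaluation."""
        p = RateParameters(b=0.7, k1=0.4, k2=3.0, k3=0.05, k4=0.2, k5=0.3,
                           k6=0.11, k7=0.09, k8=0.02, k9=1.5, rate_scale=2.5)
        x1, x2, x3, x4, x5, x6, x7 = rng.uniform(1.0, 50.0, 7)
        st_ = ModelState(x1, x2, x3, x4, x5, x6, x7)
        for w in (0.0, 1.0):
            s = p.rate_scale
            b, k1, k2, k3, k4, k5, k6, k7, k8, k9 = [
                v * s for v in (p.b, p.k1, p.k2, p.k3, p.k4, p.k5,
                                p.k6, p.k7, p.k8, p.k9)]
            expected = [
                -k1 * x1 * x2 + k2 * x3 - k6 * x1 + k7 * x5 + b,
                -k1 * x1 * x2 + (k2 + k3) * x3 - w * (k4 * x2 - k5 * x4),
                k1 * x1 * x2 - (k2 + k3) * x3,
                w * (k4 * x2 - k5 * x4),
                k6 * x1 - k7 * x5 - k8 * x5 * x6 + k9 * x7,
                -k8 * x5 * x6 + k9 * x7,
                k8 * x5 * x6 - k9 * x7,
            ]
            np.testing.assert_allclose(rhs(st_, p, w), expected, rtol=1e-12)

    def test_zero_state_with_no_synthesis_is_absorbing(self):
        p = make_params(b=0.0)
        out = rhs(ModelState(0, 0, 0, 0, 0, 0, 0), p, 0)
        assert np.all(out == 0.0)

    def test_reported_off_state_is_near_the_model_equilibrium(self, reference_chain):
        """The tabulated WNT OFF concentrations lie within 1% of the exact
        fixed point of the derived parameter set (their printed rounding is
        too coarse for the stiff TCF-binding terms to vanish directly)."""
        eq = steady_state(reference_chain["off"], w=0,
                          dc_total=reference_chain["dc_total"],
                          tcf_total=reference_chain["tcf_total"],
                          method="algebraic")
        assert max(np.abs(rhs(eq, reference_chain["off"], 0))) < 1e-8
        reported = np.array([91, 82.4, 62.5, 0.0, 87, 81, 22.2])
        computed = eq.to_array()
        np.testing.assert_allclose(computed[[0, 1, 2, 4, 5]],
                                   reported[[0, 1, 2, 4, 5]], rtol=0.01)
        assert computed[3] == 0.0
        assert abs(computed[6] - reported[6]) / reported[6] < 0.02

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            ModelState(-1, 0, 0, 0, 0, 0, 0)


class TestSteadyState:
    def test_integration_agrees_with_algebraic_fixed_point(self, reference_chain, rng):
        for params, w in ((reference_chain["off"], 0), (reference_chain["on"], 1)):
            alg = steady_state(params, w, method="algebraic")
            num = steady_state(params, w, method="integrate", rng=rng)
            np.testing.assert_allclose(num.to_array(), alg.to_array(), rtol=1e-5)

    def test_independent_of_initial_guess(self, reference_chain):
        states = [
            steady_state(reference_chain["on"], 1, method="integrate",
                         rng=np.random.default_rng(s)).to_array()
            for s in range(3)
        ]
        for s in states[1:]:
            np.testing.assert_allclose(s, states[0], rtol=1e-6)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_time_rescaling_leaves_fixed_point_unchanged(self, factor):
        p = make_params()
        base = steady_state(p, 1, method="algebraic").to_array()
        scaled = steady_state(p.rescaled(factor), 1, method="algebraic").to_array()
        np.testing.assert_allclose(scaled, base, rtol=1e-10)

    def test_depends_on_ratios_only_when_binding_is_fast(self):
        """Doubling the absolute association magnitude k1 (ratios fixed)
        moves the steady state by less than 1%."""
        base = steady_state(make_params(), 1, method="algebraic").to_array()
        fast = steady_state(make_params(k1=0.1), 1, method="algebraic").to_array()
        assert np.max(np.abs(fast / base - 1.0)) < 0.01

    def test_infeasible_k3_raises(self):
        with pytest.raises(SteadyStateError):
            steady_state(make_params(k3=1e-4), 0, method="algebraic")

    def test_w1_without_reactivation_raises(self):
        with pytest.raises(SteadyStateError):
            steady_state(make_params(k5k4=None), 1, method="algebraic")


class TestSimulate:
    def test_off_equilibrium_is_a_fixed_point_of_the_flow(self, reference_chain):
        init = steady_state(reference_chain["off"], 0, method="algebraic")
        traj = simulate(reference_chain["off"], init, None,
                        np.linspace(0, 500, 51))
        np.testing.assert_allclose(
            traj.states, np.tile(init.to_array(), (len(traj.t), 1)), rtol=1e-6)

    def test_wnt_onset_reaches_reported_on_state(self, reference_chain):
        init = steady_state(reference_chain["off"], 0, method="algebraic")
        schedule = WntSchedule(onset=0.0, steep=150.0)
        traj = simulate(reference_chain["off"], init, schedule,
                        np.linspace(0, 2000, 201),
                        params_on=reference_chain["on"])
        final = traj.final
        target = steady_state(reference_chain["on"], 1, method="algebraic")
        np.testing.assert_allclose(final.to_array(), target.to_array(), rtol=5e-3)
        # reported WNT ON concentrations (nM)
        assert abs(final.x5 - 170) / 170 < 0.02
        assert abs(final.x7 - 86) / 86 < 0.02

    def test_conserved_pools_do_not_drift(self, reference_chain):
        init = steady_state(reference_chain["off"], 0, method="algebraic")
        traj = simulate(reference_chain["off"], init, WntSchedule(0.0, 150.0),
                        np.linspace(0, 1500, 301),
                        params_on=reference_chain["on"])
        dc_drift, tcf_drift = traj.conservation_drift()
        assert dc_drift < 1e-6
        assert tcf_drift < 1e-6

    def test_trajectory_time_rescaling_identity(self, reference_chain):
        """Multiplying all rates by R equals replaying the trajectory at R x
        speed (with the transition schedule compressed accordingly)."""
        p_off, p_on = reference_chain["off"], reference_chain["on"]
        init = steady_state(p_off, 0, method="algebraic")
        t = np.linspace(0, 800, 81)
        slow = simulate(p_off, init, WntSchedule(0.0, 100.0), t, params_on=p_on)
        fast = simulate(p_off.rescaled(2.0), init, WntSchedule(0.0, 50.0),
                        t / 2.0, params_on=p_on.rescaled(2.0))
        np.testing.assert_allclose(fast.states, slow.states, rtol=1e-5, atol=1e-6)

    def test_nuclear_pool_rises_faster_and_further_than_cytoplasmic(
            self, reference_chain):
        init = steady_state(reference_chain["off"], 0, method="algebraic")
        traj = simulate(reference_chain["off"], init, WntSchedule(0.0, 150.0),
                        np.linspace(0, 2000, 401),
                        params_on=reference_chain["on"])
        nuc_fold = traj.nuclear_total / traj.nuclear_total[0]
        cyt_fold = traj.cytoplasmic_total / traj.cytoplasmic_total[0]
        assert nuc_fold[-1] > cyt_fold[-1]
        assert np.all(nuc_fold[1:] >= cyt_fold[1:] - 1e-9)
        assert traj.nc_ratio[0] < 1.0 < traj.nc_ratio[-1]


class TestScan:
    def test_identity_scan_returns_baseline(self, reference_chain):
        p = reference_chain["off"]
        base = steady_state(p, 0, method="algebraic")
        scan = scan_parameter(p, "k3", [p.k3], w=0)
        np.testing.assert_allclose(scan.states[0].to_array(), base.to_array(),
                                   rtol=1e-12)

    def test_scan_totals_are_sums_of_components(self, reference_chain):
        scan = scan_parameter(reference_chain["off"], "k3",
                              np.linspace(0.004, 0.008, 5), w=0)
        df = scan.to_frame()
        np.testing.assert_allclose(df["cytoplasmic_total"], df["x1"] + df["x3"])
        np.testing.assert_allclose(df["nuclear_total"], df["x5"] + df["x7"])

    def test_scan_values_must_be_positive(self, reference_chain):
        with pytest.raises(ValueError):
            scan_parameter(reference_chain["off"], "k3", [-0.001], w=0)
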