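"""Rate-constant ratios from measured equilibrium concentrations.

At steady state the mass-action balances of the minimal model reduce to
closed forms in the measured pools:

* nuclear shuttling       k6/k7 = x5/x1
* CTNNB1 turnover         k3    = b/x3           (flux balance k3 x3 = b)
* free destruction complex x2   = K1 x3/x1       (small-b approximation)
* TCF binding             K2 = k9/k8 = x5 (TCF0 - x7)/x7

The destruction-complex inactivation ratio k5/k4 is not identifiable from
concentrations alone and is fitted so that the WNT ON steady state matches
the measured free cytoplasmic CTNNB1 (x1) and TCF-bound nuclear CTNNB1
(x7).  The global time-scale factor is fitted to the observed time at which
the nuclear pool completes its OFF->ON shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import (
    RateParameters,
    WntSchedule,
    simulate,
    steady_state,
)

__all__ = [
    "EquilibriumMeasurement",
    "DerivedRatios",
    "InfeasibleTargetError",
    "derive_ratios",
    "estimate_tcf_total",
    "fit_dc_inactivation",
    "fit_rate_factor",
]


class InfeasibleTargetError(ValueError):
    """The requested fit targets violate a conservation constraint."""


@dataclass(frozen=True)
class EquilibriumMeasurement:
    """Measured steady-state concentrations (nM) for one WNT condition.

    ``cb_free``/``nb_free``/``nb_tcf``/``cb_dc`` are the free cytoplasmic,
    free nuclear, TCF-bound nuclear and destruction-complex-bound pools of
    CTNNB1; ``tcf_total`` is total nuclear TCF.  ``k1_ratio`` (the CB-DC
    dissociation constant K1, nM) and the synthesis rate ``b`` (nM/min) come
    from the literature rather than from fluctuation measurements.
    """

    condition: str  # "WNT_OFF" or "WNT_ON"
    cb_free: float
    nb_free: float
    nb_tcf: float
    cb_dc: float
    tcf_total: float
    k1_ratio: float
    b: float

    def __post_init__(self):
        for name in ("cb_free", "nb_free", "nb_tcf", "cb_dc", "tcf_total",
                     "k1_ratio", "b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.nb_tcf > self.tcf_total:
            raise ValueError("bound TCF cannot exceed total TCF")
        if self.condition not in ("WNT_OFF", "WNT_ON"):
            raise ValueError("condition must be WNT_OFF or WNT_ON")


@dataclass(frozen=True)
class DerivedRatios:
    """Rate ratios determined by the equilibrium conditions (full precision).

    ``k5k4`` stays None here: it requires the model fit
    (:func:`fit_dc_inactivation`), not a closed form in measured pools.
    """

    k3: float            # 1/min
    k6k7: float          # dimensionless
    K2: float            # nM
    dc_free: float       # nM, x2 from the small-b approximation
    tcf_total: float     # nM
    k5k4: float | None = None

    def rounded(self) -> dict:
        """Values at reporting precision (as printed in the results tables)."""
        out = {
            "k3": round(self.k3, 4),
            "k6k7": round(self.k6k7, 2),
            "K2": round(self.K2) if self.K2 >= 100 else round(self.K2, 1),
            "dc_free": round(self.dc_free, 1),
            "tcf_total": round(self.tcf_total),
        }
        if self.k5k4 is not None:
            out["k5k4"] = round(self.k5k4, 1)
        return out


def derive_ratios(meas: EquilibriumMeasurement, exact_dc: bool = False,
                  k1: float | None = None) -> DerivedRatios:
    """Closed-form rate ratios from one condition's measured concentrations.

    ``exact_dc=True`` replaces the small-b approximation for the free
    destruction complex with the full balance x2 = (K1 x3 + b/k1)/x1, which
    requires an absolute association rate ``k1`` (1/(nM min), time-scaled).
    """
    for name in ("cb_free", "cb_dc", "nb_tcf"):
        if getattr(meas, name) <= 0:
            raise ValueError(f"measurement {name} must be positive to derive ratios")
    k6k7 = meas.nb_free / meas.cb_free
    k3 = meas.b / meas.cb_dc
    if exact_dc:
        if k1 is None or k1 <= 0:
            raise ValueError("exact_dc requires a positive absolute rate k1")
        dc_free = (meas.k1_ratio * meas.cb_dc + meas.b / k1) / meas.cb_free
    else:
        dc_free = meas.k1_ratio * meas.cb_dc / meas.cb_free
    K2 = meas.nb_free * (meas.tcf_total - meas.nb_tcf) / meas.nb_tcf
    return DerivedRatios(k3=k3, k6k7=k6k7, K2=K2, dc_free=dc_free,
                         tcf_total=meas.tcf_total)


def estimate_tcf_total(nb_tcf_on: float, residual_free_fraction: float) -> float:
    """Total nuclear TCF from the WNT ON bound pool plus the residual free pool.

    The bound pool after stimulation is taken as the committed TCF; a
    fraction of it (relative to the bound amount) remains free, so
    TCF0 = nb_tcf_on * (1 + residual_free_fraction).
    """
    if nb_tcf_on < 0:
        raise ValueError("nb_tcf_on must be >= 0")
    if not 0 <= residual_free_fraction <= 1:
        raise ValueError("residual_free_fraction must lie in [0, 1]")
    return nb_tcf_on * (1.0 + residual_free_fraction)


def fit_dc_inactivation(
    params: RateParameters,
    x1_target: float,
    x7_target: float,
    dc_total: float,
    tcf_total: float,
) -> float:
    """Fit the reactivation/inactivation ratio k5/k4 to the WNT ON equilibrium.

    Minimises the squared relative error of the steady-state (x1, x7)
    against the targets over log10(k5/k4) in [-3, 3].  Raises
    :class:`InfeasibleTargetError` when the targets cannot be reached: the
    turnover balance b/k3 must leave room in the destruction-complex pool,
    and targets equal to the WNT OFF fixed point would need k5/k4 -> inf
    (no inactivation at all).
    """
    x3 = params.b / params.k3
    if x3 >= dc_total:
        raise InfeasibleTargetError(
            "b/k3 exceeds the destruction-complex total; no WNT ON steady state")
    # x2 needed for the x1 target; must leave a positive inactivated pool
    x2_needed = (params.K1 + params.k3 / params.k1) * x3 / x1_target
    if x2_needed >= dc_total - x3:
        raise InfeasibleTargetError(
            "targets require a non-positive inactivated destruction-complex pool "
            "(they coincide with the WNT OFF equilibrium; k5/k4 is unbounded)")

    def cost(log_ratio: float) -> float:
        p = params.with_ratio("k5k4", 10.0 ** log_ratio)
        st = steady_state(p, w=1, dc_total=dc_total, tcf_total=tcf_total,
                          method="algebraic")
        return ((st.x1 - x1_target) / x1_target) ** 2 + \
               ((st.x7 - x7_target) / x7_target) ** 2

    res = minimize_scalar(cost, bounds=(-3.0, 3.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(10.0 ** res.x)


def fit_rate_factor(
    params_off: RateParameters,
    params_on: RateParameters,
    schedule: WntSchedule,
    t_target: float,
    convergence_fraction: float = 0.95,
    dc_total: float | None = None,
    tcf_total: float | None = None,
    bracket: tuple[float, float] = (0.5, 500.0),
) -> float:
    """Global time-scale factor at which the nuclear response lands on time.

    Finds ``rate_scale`` such that the total nuclear CTNNB1 pool first
    reaches ``convergence_fraction`` of its OFF -> ON shift at ``t_target``
    minutes after WNT onset.  The transition schedule is applied as given
    (its ``steep`` is in absolute minutes and does not rescale).
    """
    if t_target <= 0:
        raise ValueError("t_target must be positive")
    if not 0 < convergence_fraction < 1:
        raise ValueError("convergence_fraction must lie in (0, 1)")
    from .model import DEFAULT_DC_TOTAL, DEFAULT_TCF_TOTAL
    dc = DEFAULT_DC_TOTAL if dc_total is None else dc_total
    tcf = DEFAULT_TCF_TOTAL if tcf_total is None else tcf_total
    off = steady_state(params_off, w=0, dc_total=dc, tcf_total=tcf, method="algebraic")
    on = steady_state(params_on, w=1, dc_total=dc, tcf_total=tcf, method="algebraic")
    n_off, n_on = off.nuclear_total, on.nuclear_total
    level = n_off + convergence_fraction * (n_on - n_off)

    def time_to_level(scale: float) -> float:
        p0 = params_off.rescaled(scale / params_off.rate_scale)
        p1 = params_on.rescaled(scale / params_on.rate_scale)
        horizon = max(4.0 * t_target, schedule.onset + schedule.steep + t_target)
        for _ in range(8):  # extend until the shift completes
            grid = np.linspace(0.0, horizon, 2000)
            traj = simulate(p0, off, schedule, grid, params_on=p1)
            n = traj.nuclear_total
            above = np.nonzero(n >= level)[0]
            if above.size:
                break
            horizon *= 4.0
        else:
            return np.inf
        i = above[0]
        if i == 0:
            return traj.t[0]
        # linear interpolation to the crossing
        t0, t1 = traj.t[i - 1], traj.t[i]
        return t0 + (level - n[i - 1]) / (n[i] - n[i - 1]) * (t1 - t0)

    g = lambda scale: time_to_level(scale) - (schedule.onset + t_target)
    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    if not (np.isfinite(glo) and np.isfinite(ghi)) or glo * ghi > 0:
        raise ValueError(
            f"rate-scale root not bracketed on {bracket}: g={glo:.3g}, {ghi:.3g}")
    return float(brentq(g, lo, hi, xtol=1e-3, rtol=1e-6))
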