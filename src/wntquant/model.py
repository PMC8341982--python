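"""Minimal ODE model of WNT/CTNNB1 signaling.

Seven concentrations (nM) evolve under mass-action kinetics:

    x1  CB      free cytoplasmic CTNNB1
    x2  DC      free destruction complex
    x3  CB*-DC  destruction-complex-bound, phosphorylated CTNNB1
    x4  DC*     DVL-inactivated destruction complex
    x5  NB      free nuclear CTNNB1
    x6  TCF     free TCF/LEF
    x7  NB-TCF  TCF-bound nuclear CTNNB1

The reactions are: CB + DC <-> CB*-DC (k1, k2); CB*-DC -> DC + CB*
(k3, CB* is degraded and not tracked); DC <-> DC* (k4, k5, only active
when the WNT input w = 1); CB <-> NB shuttling (k6, k7); and
NB + TCF <-> NB-TCF (k8, k9).  Synthesis of CB occurs at constant rate b.

Two quantities are conserved along every trajectory: total destruction
complex x2 + x3 + x4 and total TCF x6 + x7.  Steady states depend only on
the rate *ratios* (K1 = k2/k1, k3, b, k6/k7, K2 = k9/k8, k5/k4) provided
k3/k1 is small against K1; a global multiplicative factor on all rates and
b (``rate_scale``) sets the time scale without moving the fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateParameters",
    "ModelState",
    "WntSchedule",
    "Trajectory",
    "ScanResult",
    "SolverError",
    "SteadyStateError",
    "rhs",
    "simulate",
    "steady_state",
    "scan_parameter",
    "DEFAULT_DC_TOTAL",
    "DEFAULT_TCF_TOTAL",
]

#: Conserved totals (nM) used throughout unless overridden: total destruction
#: complex 82.4 + 62.5 and total TCF in the nucleus.
DEFAULT_DC_TOTAL = 144.9
DEFAULT_TCF_TOTAL = 103.0

# Baseline absolute magnitudes (pre-scaling).  Only ratios are constrained by
# equilibrium data; these magnitudes are chosen so that k3/k1 << K1 (fixed
# points sit on the ratio-determined values) and equilibration lands on the
# observed few-hour time scale once rate_scale ~ 20 is applied.
BASELINE_K1 = 0.05  # nM^-1 min^-1
BASELINE_K7 = 0.03  # min^-1
BASELINE_K4 = 0.01  # min^-1
BASELINE_K8 = 0.01  # nM^-1 min^-1


class SolverError(RuntimeError):
    """ODE integration failed (step-size collapse); carries the failure time."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge within the configured horizon."""


@dataclass(frozen=True)
class RateParameters:
    """Kinetic constants of the minimal model.

    Units: b in nM/min; k1, k8 in 1/(nM min); k2-k7, k9 in 1/min.
    ``rate_scale`` multiplies every rate and b (a pure change of time unit);
    ``steep`` is the time in minutes after WNT onset at which the gradual
    OFF->ON transition of the shuttling/retention/inactivation ratios
    completes.
    """

    b: float
    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    rate_scale: float = 1.0
    steep: float = 150.0

    def __post_init__(self):
        for name in ("b", "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("k1", "k4", "k7", "k8"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be > 0")
        if self.steep < 0:
            raise ValueError("steep must be >= 0")

    # -- ratio views ------------------------------------------------------
    @property
    def K1(self) -> float:
        """Dissociation constant of CB*-DC, k2/k1 (nM)."""
        return self.k2 / self.k1

    @property
    def K2(self) -> float:
        """Dissociation constant of NB-TCF, k9/k8 (nM)."""
        return self.k9 / self.k8

    @property
    def k6k7(self) -> float:
        """Nuclear import/export ratio."""
        return self.k6 / self.k7

    @property
    def k5k4(self) -> float:
        """Destruction-complex reactivation/inactivation ratio (DC/DC* at
        equilibrium)."""
        return self.k5 / self.k4

    @classmethod
    def from_ratios(
        cls,
        *,
        b: float,
        K1: float,
        k3: float,
        k6k7: float,
        K2: float,
        k5k4: float | None = None,
        rate_scale: float = 1.0,
        steep: float = 150.0,
        k1: float = BASELINE_K1,
        k7: float = BASELINE_K7,
        k4: float = BASELINE_K4,
        k8: float = BASELINE_K8,
    ) -> "RateParameters":
        """Build absolute rates from the identifiable ratios.

        ``k5k4=None`` (the WNT OFF case, where inactivation is switched off
        by w=0) sets k5 = 0.
        """
        return cls(
            b=b,
            k1=k1,
            k2=K1 * k1,
            k3=k3,
            k4=k4,
            k5=(0.0 if k5k4 is None else k5k4 * k4),
            k6=k6k7 * k7,
            k7=k7,
            k8=k8,
            k9=K2 * k8,
            rate_scale=rate_scale,
            steep=steep,
        )

    def with_ratio(self, name: str, value: float) -> "RateParameters":
        """Return a copy with one ratio (or k3) replaced.

        ``name`` is one of ``k3``, ``k6k7`` (alias ``k6/k7``), ``k9k8``
        (aliases ``k9/k8``, ``K2``), ``k5k4`` (alias ``k5/k4``).  Ratios are
        changed by moving the numerator rate, keeping the denominator fixed.
        """
        key = name.replace("/", "")
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
        if key == "k3":
            return replace(self, k3=value)
        if key == "k6k7":
            return replace(self, k6=value * self.k7)
        if key in ("k9k8", "K2"):
            return replace(self, k9=value * self.k8)
        if key == "k5k4":
            return replace(self, k5=value * self.k4)
        raise KeyError(f"unknown scan parameter {name!r}")

    def rescaled(self, factor: float) -> "RateParameters":
        """Multiply the global time-scale factor (all rates and b) by ``factor``."""
        return replace(self, rate_scale=self.rate_scale * factor)

    def scaled_rates(self) -> np.ndarray:
        """(b, k1..k9) with rate_scale applied, as a flat array."""
        r = np.array([self.b, self.k1, self.k2, self.k3, self.k4,
                      self.k5, self.k6, self.k7, self.k8, self.k9])
        return r * self.rate_scale


@dataclass(frozen=True)
class ModelState:
    """The seven model concentrations in nM."""

    x1: float
    x2: float
    x3: float
    x4: float
    x5: float
    x6: float
    x7: float

    def __post_init__(self):
        for name, v in zip(self.field_names(), self.values()):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"state component {name} must be finite and >= 0, got {v}")

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return ("x1", "x2", "x3", "x4", "x5", "x6", "x7")

    def values(self) -> tuple[float, ...]:
        return (self.x1, self.x2, self.x3, self.x4, self.x5, self.x6, self.x7)

    def to_array(self) -> np.ndarray:
        return np.array(self.values(), dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ModelState":
        x = np.asarray(x, dtype=float)
        if x.shape != (7,):
            raise ValueError("state array must have length 7")
        # tiny negative overshoot from the solver is clipped to zero
        x = np.where((x < 0) & (x > -1e-9), 0.0, x)
        return cls(*x)

    # -- derived pools ----------------------------------------------------
    @property
    def cytoplasmic_total(self) -> float:
        """Total cytoplasmic CTNNB1, x1 + x3 (nM)."""
        return self.x1 + self.x3

    @property
    def nuclear_total(self) -> float:
        """Total nuclear CTNNB1, x5 + x7 (nM)."""
        return self.x5 + self.x7

    @property
    def nc_ratio(self) -> float:
        return self.nuclear_total / self.cytoplasmic_total

    @property
    def nuclear_bound_fraction(self) -> float:
        return self.x7 / self.nuclear_total

    @property
    def dc_total(self) -> float:
        return self.x2 + self.x3 + self.x4

    @property
    def tcf_total(self) -> float:
        return self.x6 + self.x7


@dataclass(frozen=True)
class WntSchedule:
    """WNT input and parameter-transition weight as functions of time.

    The binary input w switches 0 -> 1 at ``onset`` (minutes).  The
    interpolation weight s rises linearly from 0 at onset to 1 at
    ``onset + steep`` and stays at 1; the shuttling (k6/k7), retention
    (k9/k8) and destruction-complex inactivation ratios follow s from their
    WNT OFF to their WNT ON values.  ``steep = 0`` makes both switches
    instantaneous.
    """

    onset: float = 0.0
    steep: float = 150.0

    def __post_init__(self):
        if self.steep < 0:
            raise ValueError("steep must be >= 0")

    def w(self, t: float) -> float:
        return 1.0 if t >= self.onset else 0.0

    def s(self, t: float) -> float:
        if t < self.onset:
            return 0.0
        if self.steep == 0:
            return 1.0
        return float(min((t - self.onset) / self.steep, 1.0))


def _rhs_raw(x: np.ndarray, r: np.ndarray, w: float) -> np.ndarray:
    """Mass-action right-hand side; r = (b, k1..k9) already time-scaled."""
    b, k1, k2, k3, k4, k5, k6, k7, k8, k9 = r
    x1, x2, x3, x4, x5, x6, x7 = x
    bind = k1 * x1 * x2          # CB + DC association flux
    dvl = w * (k4 * x2 - k5 * x4)  # DC inactivation flux (WNT only)
    tcf = k8 * x5 * x6 - k9 * x7   # NB + TCF association flux
    shuttle = k6 * x1 - k7 * x5
    return np.array([
        -bind + k2 * x3 - shuttle + b,
        -bind + (k2 + k3) * x3 - dvl,
        bind - (k2 + k3) * x3,
        dvl,
        shuttle - tcf,
        -tcf,
        tcf,
    ])


def rhs(state: ModelState, params: RateParameters, w: float) -> np.ndarray:
    """Time derivatives (nM/min) of the seven concentrations.

    ``w`` is the binary WNT input; it multiplies the DVL-mediated
    destruction-complex inactivation terms.
    """
    if w not in (0, 1, 0.0, 1.0):
        raise ValueError("w must be 0 or 1")
    x = state.to_array()
    if np.any(x < 0):
        raise ValueError("state components must be non-negative")
    return _rhs_raw(x, params.scaled_rates(), float(w))


@dataclass
class Trajectory:
    """Result of :func:`simulate`: states over a time grid (minutes, nM)."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 7)

    def __getitem__(self, i: int) -> ModelState:
        return ModelState.from_array(np.clip(self.states[i], 0.0, None))

    @property
    def final(self) -> ModelState:
        return self[-1]

    @property
    def cytoplasmic_total(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 2]

    @property
    def nuclear_total(self) -> np.ndarray:
        return self.states[:, 4] + self.states[:, 6]

    @property
    def nc_ratio(self) -> np.ndarray:
        return self.nuclear_total / self.cytoplasmic_total

    def conservation_drift(self) -> tuple[float, float]:
        """Max relative drift of the two conserved pools over the trajectory."""
        dc = self.states[:, 1] + self.states[:, 2] + self.states[:, 3]
        tcf = self.states[:, 5] + self.states[:, 6]
        drift = lambda a: float(np.max(np.abs(a - a[0])) / a[0])
        return drift(dc), drift(tcf)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=ModelState.field_names())
        df.insert(0, "time_min", self.t)
        df["cytoplasmic_total"] = self.cytoplasmic_total
        df["nuclear_total"] = self.nuclear_total
        df["nc_ratio"] = self.nc_ratio
        return df


def _integrate_segment(f, t0, t1, x0, t_eval, rtol, atol):
    sol = solve_ivp(f, (t0, t1), x0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval if len(t_eval) else None)
    if not sol.success:
        raise SolverError(f"ODE solver failed: {sol.message}",
                          t=float(sol.t[-1]) if sol.t.size else t0)
    return sol


def simulate(
    params: RateParameters,
    init: ModelState,
    schedule: WntSchedule | None,
    t_grid: np.ndarray,
    params_on: RateParameters | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over ``t_grid`` (strictly increasing, minutes).

    With ``schedule=None`` the WNT input stays at 0 and parameters are
    constant.  With a schedule and ``params_on`` given, w switches at the
    scheduled onset while the ratios k6/k7 and k9/k8 interpolate linearly
    (weight s) from their values in ``params`` to their values in
    ``params_on``; destruction-complex inactivation ramps in by scaling k4
    from 0 to its ``params_on`` value (so k5/k4 descends from its
    effectively-off limit to the ON ratio).  k3, b, K1 and the denominator
    rates are taken from ``params_on`` after onset.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    x0 = init.to_array()
    if schedule is None:
        f = lambda t, x: _rhs_raw(x, params.scaled_rates(), 0.0)
        sol = _integrate_segment(f, t_grid[0], t_grid[-1], x0, t_grid, rtol, atol)
        return Trajectory(t=sol.t, states=sol.y.T)

    p_on = params_on if params_on is not None else params
    r_off = params.scaled_rates()
    r_on = p_on.scaled_rates()

    def rates_at(t: float) -> tuple[np.ndarray, float]:
        w = schedule.w(t)
        if w == 0.0:
            return r_off, 0.0
        s = schedule.s(t)
        r = r_on.copy()
        # numerator rates follow the interpolated ratios
        r[6] = ((1 - s) * params.k6k7 + s * p_on.k6k7) * r[7]      # k6
        r[9] = ((1 - s) * params.K2 + s * p_on.K2) * r[8]          # k9
        r[4] = s * r[4]                                            # k4 ramps in
        return r, 1.0

    def f(t, x):
        r, w = rates_at(t)
        return _rhs_raw(x, r, w)

    # integrate piecewise across the kinks of the schedule
    breaks = [t_grid[0], schedule.onset, schedule.onset + schedule.steep, t_grid[-1]]
    breaks = sorted({b for b in breaks if t_grid[0] <= b <= t_grid[-1]})
    collected: dict[float, np.ndarray] = {t_grid[0]: x0}
    x = x0
    for a, c in zip(breaks[:-1], breaks[1:]):
        wanted = t_grid[(t_grid > a) & (t_grid <= c)]
        t_eval = np.unique(np.append(wanted, c))
        sol = _integrate_segment(f, a, c, x, t_eval, rtol, atol)
        for tk, xk in zip(sol.t, sol.y.T):
            if tk in t_grid:
                collected[tk] = xk
        x = sol.y[:, -1]
    t = np.array(sorted(collected))
    y = np.vstack([collected[tk] for tk in t])
    return Trajectory(t=t, states=y)


def _initial_state(
    w: float,
    dc_total: float,
    tcf_total: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """A non-negative start on the conservation manifold.

    With an rng, the split of the conserved pools and the free CTNNB1 levels
    are randomised (steady states must not depend on this); otherwise a fixed
    mid-range guess is used.  With w = 0 the inactivated complex x4 is pinned
    to 0 because w = 0 freezes it at its initial value.
    """
    if rng is None:
        f3, f4, f7, x1, x5 = 0.4, 0.2, 0.2, 50.0, 50.0
    else:
        f3, f4, f7 = rng.uniform(0.05, 0.9, size=3)
        f4 *= (1 - f3)
        x1, x5 = rng.uniform(1.0, 300.0, size=2)
    if w == 0:
        f4 = 0.0
    x3 = f3 * dc_total
    x4 = f4 * dc_total
    x2 = dc_total - x3 - x4
    x7 = f7 * tcf_total
    return np.array([x1, x2, x3, x4, x5, tcf_total - x7, x7])


def steady_state(
    params: RateParameters,
    w: float,
    dc_total: float = DEFAULT_DC_TOTAL,
    tcf_total: float = DEFAULT_TCF_TOTAL,
    method: str = "integrate",
    init: ModelState | None = None,
    rng: np.random.Generator | None = None,
    deriv_tol: float = 1e-8,
    horizon: float = 1e5,
) -> ModelState:
    """Steady state for fixed WNT input and conserved totals.

    ``method="integrate"`` runs the stiff-capable adaptive solver until every
    |dxi/dt| < ``deriv_tol`` nM/min (or raises :class:`SteadyStateError` at
    the ``horizon``); ``method="algebraic"`` evaluates the closed-form fixed
    point (x3 = b/k3, the DC pool split by conservation and, under WNT, by
    k5/k4; x1 from the CB*-DC balance; x5 = (k6/k7) x1; x7 from the TCF
    binding isotherm).  Both depend only on rate ratios, not on rate_scale.
    """
    if w not in (0, 1, 0.0, 1.0):
        raise ValueError("w must be 0 or 1")
    if dc_total <= 0 or tcf_total <= 0:
        raise ValueError("conserved totals must be positive")
    r = params.scaled_rates()
    b, k1, k2, k3, k4, k5, k6, k7, k8, k9 = r

    if method == "algebraic":
        if k3 <= 0:
            raise SteadyStateError("k3 must be positive for a finite CB pool")
        x3 = b / k3
        if x3 >= dc_total:
            raise SteadyStateError(
                f"synthesis/degradation balance b/k3 = {x3:.3g} nM exceeds the "
                f"total destruction-complex pool {dc_total} nM")
        if w == 0:
            x4 = 0.0
            x2 = dc_total - x3
        else:
            if k5 <= 0:
                # all DC ends up inactivated; no finite fixed point with x2 > 0
                raise SteadyStateError("w=1 with k5=0 drives the free DC pool to zero")
            x2 = (dc_total - x3) / (1.0 + k4 / k5)
            x4 = dc_total - x3 - x2
        x1 = (k2 + k3) * x3 / (k1 * x2)
        x5 = (k6 / k7) * x1
        x7 = x5 * tcf_total / (x5 + k9 / k8)
        return ModelState(x1, x2, x3, x4, x5, tcf_total - x7, x7)

    if method != "integrate":
        raise ValueError("method must be 'integrate' or 'algebraic'")

    x = init.to_array() if init is not None else _initial_state(w, dc_total, tcf_total, rng)
    f = lambda t, y: _rhs_raw(y, r, float(w))
    # equilibration time scales inversely with rate_scale
    stretch = 2000.0 / params.rate_scale
    t = 0.0
    while t < horizon:
        sol = _integrate_segment(f, t, t + stretch, x, np.array([t + stretch]), 1e-8, 1e-10)
        x = sol.y[:, -1]
        t += stretch
        if np.max(np.abs(_rhs_raw(x, r, float(w)))) < deriv_tol:
            return ModelState.from_array(np.clip(x, 0.0, None))
    raise SteadyStateError(
        f"derivatives did not fall below {deriv_tol} nM/min within {horizon} min")


@dataclass
class ScanResult:
    """Steady states along a one-parameter scan."""

    name: str
    values: np.ndarray
    states: list[ModelState]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, s in zip(self.values, self.states):
            rows.append({
                self.name: v,
                **dict(zip(ModelState.field_names(), s.values())),
                "cytoplasmic_total": s.cytoplasmic_total,
                "nuclear_total": s.nuclear_total,
                "nc_ratio": s.nc_ratio,
                "nuclear_bound_fraction": s.nuclear_bound_fraction,
            })
        return pd.DataFrame(rows)


def scan_parameter(
    params: RateParameters,
    name: str,
    values: Sequence[float],
    w: float,
    dc_total: float = DEFAULT_DC_TOTAL,
    tcf_total: float = DEFAULT_TCF_TOTAL,
    method: str = "algebraic",
) -> ScanResult:
    """Steady state as a function of one rate parameter or ratio.

    ``name`` is ``k3``, ``k6k7``/``k6/k7`` or ``k9k8``/``k9/k8``; only the
    named quantity is replaced at each scan value.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("scan values must be positive")
    states = [
        steady_state(params.with_ratio(name, v), w, dc_total, tcf_total, method=method)
        for v in values
    ]
    return ScanResult(name=name.replace("/", ""), values=values, states=states)
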