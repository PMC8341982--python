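"""Fluorescence correlation spectroscopy: correlation, fitting, calibration.

The chain implemented here mirrors a confocal point-FCS workflow on photon
count traces: select a drift-free analysis window, estimate the intensity
autocorrelation G(tau) on a quasi-logarithmic lag grid, fit a
triplet x multi-component 3D-diffusion model, correct the fitted particle
number for autofluorescence and bleaching, and convert numbers and
diffusion times to concentrations and diffusion coefficients through a
reference-dye calibration of the detection volume.

Units: photon counts per bin; lag times in seconds on curve objects and in
milliseconds on model parameters (the convention of FCS fitting software);
radii in micrometres; diffusion coefficients in um^2/s; volumes in
femtolitres; concentrations in nanomolar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.stats import norm

__all__ = [
    "IntensityTrace",
    "AutocorrelationCurve",
    "FcsModelParams",
    "FitConfig",
    "FitResult",
    "QcResult",
    "Calibration",
    "ConcentrationResult",
    "StokesScalingInput",
    "autocorrelate",
    "eval_model",
    "fit_acf",
    "qc_trace",
    "correct_particle_number",
    "calibrate",
    "diffusion_coefficient",
    "to_concentration",
    "stokes_scale",
    "ALEXA488_D",
]

#: Diffusion coefficient of the Alexa488 reference dye in aqueous solution
#: at 22.5 degC (um^2/s), used to calibrate the detection volume.
ALEXA488_D = 435.0


@dataclass
class IntensityTrace:
    """Photon counts per time bin from a single-point measurement."""

    counts: np.ndarray
    bin_width: float  # seconds
    metadata: dict = field(default_factory=dict)
    analysis_window: tuple[float, float] | None = None  # seconds

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def window_counts(self) -> np.ndarray:
        """Counts restricted to the analysis window (whole trace if unset)."""
        if self.analysis_window is None:
            return self.counts
        a, b = self.analysis_window
        i = max(int(round(a / self.bin_width)), 0)
        j = min(int(round(b / self.bin_width)), self.n_bins)
        return self.counts[i:j]

    def to_csv(self, path) -> None:
        t = np.arange(self.n_bins) * self.bin_width
        pd.DataFrame({"time_s": t, "counts": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "IntensityTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("trace CSV needs at least two rows")
        return cls(counts=df["counts"].to_numpy(), bin_width=float(t[1] - t[0]),
                   metadata=metadata or {})


@dataclass
class AutocorrelationCurve:
    """Normalised intensity autocorrelation g(tau) on increasing lags (s)."""

    lags: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape or self.lags.ndim != 1:
            raise ValueError("lags and g must be matching 1-d arrays")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")

    @property
    def n_points(self) -> int:
        return int(self.lags.size)

    def to_csv(self, path) -> None:
        pd.DataFrame({"lag_s": self.lags, "g": self.g}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AutocorrelationCurve":
        df = pd.read_csv(path)
        return cls(lags=df["lag_s"].to_numpy(), g=df["g"].to_numpy())


def quasi_log_lags(n_bins: int, points_per_octave: int = 8,
                   min_lag: int = 2, max_lag: int | None = None) -> np.ndarray:
    """Integer lag indices, ~uniform in log2, from ``min_lag`` to n_bins/10."""
    if max_lag is None:
        max_lag = n_bins // 10
    if max_lag < min_lag:
        raise ValueError("trace too short for the requested lag range")
    n_oct = math.log2(max_lag / min_lag)
    grid = min_lag * 2.0 ** (np.arange(0, n_oct * points_per_octave + 1) / points_per_octave)
    lags = np.unique(np.round(grid).astype(int))
    return lags[(lags >= min_lag) & (lags <= max_lag)]


def autocorrelate(trace: IntensityTrace, points_per_octave: int = 8,
                  min_lag_bins: int = 2, max_lag_bins: int | None = None
                  ) -> AutocorrelationCurve:
    """Estimate g(tau) = 1 + <dI(t) dI(t+tau)> / <I>^2 over the analysis window.

    The estimator uses the window mean for dI and divides the lagged product
    sum by the number of contributing pairs, evaluated exactly (no
    coarse-graining), on a quasi-logarithmic integer lag grid.
    """
    counts = trace.window_counts().astype(float)
    n = counts.size
    if n < 1000:
        raise ValueError(f"analysis window has {n} bins; need >= 1000")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero mean intensity in the analysis window")
    lags = quasi_log_lags(n, points_per_octave, min_lag_bins, max_lag_bins)
    d = counts - mean
    g = np.empty(lags.size)
    for i, k in enumerate(lags):
        g[i] = 1.0 + (d[:-k] @ d[k:]) / (n - k) / mean**2
    return AutocorrelationCurve(lags=lags * trace.bin_width, g=g)


@dataclass(frozen=True)
class FcsModelParams:
    """Parameters of the triplet x multi-component diffusion model.

    ``components`` is a sequence of (fraction, tau_diff_ms) pairs whose
    fractions sum to one; ``sp`` is the structural parameter omega_z/omega_xy
    of the detection volume.
    """

    g_inf: float
    n_particles: float
    f_trip: float
    tau_trip_ms: float
    components: tuple[tuple[float, float], ...]
    sp: float

    def __post_init__(self):
        if not 0 <= self.f_trip < 1:
            raise ValueError("f_trip must lie in [0, 1)")
        if self.tau_trip_ms <= 0:
            raise ValueError("tau_trip_ms must be positive")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.sp <= 0:
            raise ValueError("sp must be positive")
        fr = sum(f for f, _ in self.components)
        if abs(fr - 1.0) > 1e-6:
            raise ValueError(f"component fractions must sum to 1, got {fr}")
        if any(tau <= 0 for _, tau in self.components):
            raise ValueError("diffusion times must be positive")


def eval_model(p: FcsModelParams, lags_s: np.ndarray,
               axial: str = "sqrt") -> np.ndarray:
    """Evaluate the triplet-diffusion model at lag times (seconds).

    G(tau) = G_inf + (1/N) (1 + F/(1-F) e^(-tau/tau_t))
             * sum_i F_i (1 + tau/tau_i)^-1 (1 + tau/(tau_i sp^2))^-1/2

    ``axial="sqrt"`` is the standard 3D form (one transverse factor, one
    axial square-root factor); ``axial="full"`` raises the axial factor to
    the power -1 instead, for sensitivity checks against the alternative
    reading of the model.
    """
    tau = np.asarray(lags_s, dtype=float) * 1e3  # model times in ms
    trip = 1.0
    if p.f_trip > 0:
        trip = 1.0 + p.f_trip / (1.0 - p.f_trip) * np.exp(-tau / p.tau_trip_ms)
    diff = np.zeros_like(tau)
    for frac, tau_i in p.components:
        transverse = 1.0 / (1.0 + tau / tau_i)
        ax = 1.0 + tau / (tau_i * p.sp**2)
        if axial == "sqrt":
            diff += frac * transverse / np.sqrt(ax)
        elif axial == "full":
            diff += frac * transverse / ax
        else:
            raise ValueError("axial must be 'sqrt' or 'full'")
    return p.g_inf + trip * diff / p.n_particles


@dataclass
class FitConfig:
    """Bounds and fixing choices for :func:`fit_acf`.

    Defaults follow the bounds used for two-component fits of CTNNB1
    traces: G_inf in [0.5, 1.5], N in [0.001, 500], tau_trip in
    [1e-6, 0.05] ms, tau_diff2 in [10, 150] ms, and the first diffusion
    component either fixed (``fix_tau1_ms``) to the monomer value derived
    from the calibration, or free within [0.5, 10] ms.
    """

    sp: float = 5.0
    n_components: int = 2
    fix_tau1_ms: float | None = None
    tau1_bounds_ms: tuple[float, float] = (0.5, 10.0)
    tau2_bounds_ms: tuple[float, float] = (10.0, 150.0)
    n_bounds: tuple[float, float] = (0.001, 500.0)
    g_inf_bounds: tuple[float, float] = (0.5, 1.5)
    with_triplet: bool = False
    tau_trip_bounds_ms: tuple[float, float] = (1e-6, 0.05)
    axial: str = "sqrt"
    weights: np.ndarray | None = None


@dataclass
class FitResult:
    params: FcsModelParams
    residuals: np.ndarray
    chi2: float
    red_chi2: float | None
    runs_test_p: float
    exclusion_flags: list[str]
    lmfit_result: object = None

    @property
    def flagged(self) -> bool:
        return bool(self.exclusion_flags)


def _runs_test_p(residuals: np.ndarray) -> float:
    """Two-sided p-value of the Wald-Wolfowitz runs test on residual signs.

    Misfits show long same-sign runs around the fitted curve; small p flags
    a structured residual distribution.
    """
    s = np.sign(residuals)
    s = s[s != 0]
    n_pos = int(np.sum(s > 0))
    n_neg = int(np.sum(s < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        return 0.0
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    mu = 1 + 2 * n_pos * n_neg / n
    var = 2 * n_pos * n_neg * (2 * n_pos * n_neg - n) / (n**2 * (n - 1))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def fit_acf(acf: AutocorrelationCurve, config: FitConfig) -> FitResult:
    """Bounded least-squares fit of the triplet-diffusion model to a curve.

    The structural parameter is fixed from the day's calibration.  Residual
    diagnostics (sign-runs test, reduced chi-square when per-lag weights are
    supplied) are returned as advisory exclusion flags, never applied
    silently.
    """
    if acf.n_points < 30:
        raise ValueError(f"curve has {acf.n_points} points; need >= 30 spanning the decay")
    if config.n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    p = lmfit.Parameters()
    amp0 = max(np.max(acf.g) - 1.0, 1e-4)
    p.add("g_inf", value=1.0, min=config.g_inf_bounds[0], max=config.g_inf_bounds[1])
    p.add("n_particles", value=min(max(1.0 / amp0, config.n_bounds[0]), config.n_bounds[1]),
          min=config.n_bounds[0], max=config.n_bounds[1])
    if config.fix_tau1_ms is not None:
        p.add("tau1", value=config.fix_tau1_ms, vary=False)
    else:
        lo, hi = config.tau1_bounds_ms
        p.add("tau1", value=math.sqrt(lo * hi), min=lo, max=hi)
    if config.n_components == 2:
        lo, hi = config.tau2_bounds_ms
        p.add("tau2", value=math.sqrt(lo * hi), min=lo, max=hi)
        p.add("f2", value=0.3, min=0.0, max=1.0)
    if config.with_triplet:
        lo, hi = config.tau_trip_bounds_ms
        p.add("f_trip", value=0.1, min=0.0, max=0.999)
        p.add("tau_trip", value=math.sqrt(lo * hi), min=lo, max=hi)

    def build(params: lmfit.Parameters) -> FcsModelParams:
        v = params.valuesdict()
        if config.n_components == 2:
            comps = ((1.0 - v["f2"], v["tau1"]), (v["f2"], v["tau2"]))
        else:
            comps = ((1.0, v["tau1"]),)
        return FcsModelParams(
            g_inf=v["g_inf"], n_particles=v["n_particles"],
            f_trip=v.get("f_trip", 0.0),
            tau_trip_ms=v.get("tau_trip", 1e-3) or 1e-3,
            components=comps, sp=config.sp)

    def resid(params):
        r = eval_model(build(params), acf.lags, axial=config.axial) - acf.g
        if config.weights is not None:
            r = r * config.weights
        return r

    mini = lmfit.minimize(resid, p, method="least_squares")
    if not mini.success:
        raise RuntimeError(f"ACF fit did not converge: {mini.message}")
    fitted = build(mini.params)
    residuals = eval_model(fitted, acf.lags, axial=config.axial) - acf.g
    chi2 = float(np.sum(resid(mini.params) ** 2))
    red_chi2 = float(mini.redchi) if config.weights is not None else None
    runs_p = _runs_test_p(residuals)

    flags = []
    if runs_p < 0.01:
        flags.append("residual_runs_test")
    if red_chi2 is not None and red_chi2 > 5:
        flags.append("reduced_chi2")
    for name, par in mini.params.items():
        if par.vary and par.min is not None and par.max is not None:
            span = par.max - par.min
            if span > 0 and (par.value - par.min < 1e-6 * span
                             or par.max - par.value < 1e-6 * span):
                flags.append(f"bound_active:{name}")
    return FitResult(params=fitted, residuals=residuals, chi2=chi2,
                     red_chi2=red_chi2, runs_test_p=runs_p,
                     exclusion_flags=flags, lmfit_result=mini)


@dataclass
class QcResult:
    accepted: bool
    window: tuple[float, float] | None  # seconds
    reason: str
    drift: float  # relative linear-trend change over the selected window


def qc_trace(trace: IntensityTrace, max_drift: float = 0.10,
             min_window_s: float = 30.0, segment_s: float = 1.0) -> QcResult:
    """Select the longest analysis window with bounded intensity drift.

    The trace is coarse-grained to ~``segment_s`` segments; over every
    candidate window the relative change of a linear trend
    (|slope| * span / mean) is evaluated and the longest window with change
    <= ``max_drift`` is returned.  Traces without a compliant window of at
    least ``min_window_s`` are rejected, labelled "bleaching" when the
    overall trend is monotone decreasing and "unstable" otherwise.
    """
    counts = trace.counts.astype(float)
    seg_bins = max(int(round(segment_s / trace.bin_width)), 1)
    n_seg = counts.size // seg_bins
    if n_seg < 2:
        return QcResult(False, None, "too_short", np.inf)
    means = counts[: n_seg * seg_bins].reshape(n_seg, seg_bins).mean(axis=1)
    t = (np.arange(n_seg) + 0.5) * seg_bins * trace.bin_width

    def window_drift(i: int, j: int) -> float:
        y = means[i:j]
        x = t[i:j]
        if y.mean() == 0:
            return np.inf
        slope = np.polyfit(x, y, 1)[0]
        return abs(slope) * (x[-1] - x[0]) / y.mean()

    best = None  # (length, start, end, drift)
    for i in range(n_seg - 1):
        for j in range(n_seg, i + 1, -1):
            if best is not None and (j - i) <= best[0]:
                break
            d = window_drift(i, j)
            if d <= max_drift:
                best = (j - i, i, j, d)
                break
    min_segments = max(int(math.ceil(min_window_s / (seg_bins * trace.bin_width))), 2)
    if best is not None and best[0] >= min_segments:
        _, i, j, d = best
        window = (i * seg_bins * trace.bin_width, j * seg_bins * trace.bin_width)
        return QcResult(True, window, "ok", d)
    overall_slope = np.polyfit(t, means, 1)[0]
    total_change = overall_slope * (t[-1] - t[0]) / means.mean()
    reason = "bleaching" if total_change < -max_drift else "unstable"
    return QcResult(False, None, reason, abs(total_change))


def correct_particle_number(n_apa: float, i_total: float,
                            i_autofluorescence: float,
                            i_start: float, i_ana: float) -> float:
    """Autofluorescence and bleaching correction of an apparent particle number.

    N_corr = N_apa (1 - I_auto/I_total)^2 (I_start/I_ana): the squared term
    removes the uncorrelated background contribution to the amplitude, the
    intensity ratio rescales for moderate bleaching between the start of the
    measurement and the analysed window.
    """
    if not i_total > i_autofluorescence >= 0:
        raise ValueError("need i_total > i_autofluorescence >= 0")
    if i_ana <= 0 or i_start < 0:
        raise ValueError("intensities must be positive")
    return n_apa * (1.0 - i_autofluorescence / i_total) ** 2 * (i_start / i_ana)


@dataclass(frozen=True)
class Calibration:
    """Detection-volume geometry anchored to a reference dye."""

    omega_xy: float  # um
    sp: float
    volume: float    # fl (= um^3), cylinder approximation 2 pi w^3 sp
    d_ref: float     # um^2/s

    def tau_diff_ms(self, d: float) -> float:
        """Expected diffusion time (ms) of a species with coefficient d (um^2/s)."""
        return self.omega_xy**2 / (4.0 * d) * 1e3


def calibrate(tau_diff_ref_ms: float, sp: float,
              d_ref: float = ALEXA488_D) -> Calibration:
    """Detection volume from the reference dye's fitted diffusion time.

    omega_xy = sqrt(4 D_ref tau_diff); the volume is approximated by a
    cylinder V = 2 pi omega_xy^3 sp.
    """
    if tau_diff_ref_ms <= 0 or sp <= 0 or d_ref <= 0:
        raise ValueError("tau_diff, sp and d_ref must be positive")
    omega = math.sqrt(4.0 * d_ref * tau_diff_ref_ms * 1e-3)
    return Calibration(omega_xy=omega, sp=sp,
                       volume=2.0 * math.pi * omega**3 * sp, d_ref=d_ref)


def diffusion_coefficient(tau_diff_ms: float, omega_xy: float) -> float:
    """D = omega_xy^2 / (4 tau_diff) in um^2/s (tau in ms, omega in um)."""
    if tau_diff_ms <= 0 or omega_xy <= 0:
        raise ValueError("tau_diff and omega_xy must be positive")
    return omega_xy**2 / (4.0 * tau_diff_ms * 1e-3)


@dataclass
class ConcentrationResult:
    n_apparent: float
    n_corrected: float
    concentration_total: float            # nM
    component_concentrations: tuple[float, ...]  # nM, ordered as the fit components
    diffusion_coefficients: tuple[float, ...]    # um^2/s


def to_concentration(n_corrected: float, cal: Calibration,
                     fractions: Sequence[float] | None = None) -> float | tuple:
    """Concentration in nM from a corrected particle number, C = N/(V N_A).

    With ``fractions`` given, returns (total, per-component tuple).
    """
    if cal.volume <= 0:
        raise ValueError("calibration volume must be positive")
    total = n_corrected / (cal.volume * 1e-15 * Avogadro) * 1e9
    if fractions is None:
        return total
    return total, tuple(f * total for f in fractions)


@dataclass(frozen=True)
class StokesScalingInput:
    """Inputs for the relative Einstein-Stokes scaling between two proteins.

    Temperature, viscosity and the Boltzmann constant cancel in the ratio
    form used here; only the cube root of the mass ratio enters (spherical
    molecules of equal density).
    """

    d_ref: float        # um^2/s of the reference protein
    mass_ref: float     # kDa
    mass_target: float  # kDa

    def __post_init__(self):
        if self.mass_ref <= 0 or self.mass_target <= 0 or self.d_ref <= 0:
            raise ValueError("masses and d_ref must be positive")


def stokes_scale(inp: StokesScalingInput) -> float:
    """Expected diffusion coefficient of the target protein (um^2/s).

    D_target = D_ref (m_ref/m_target)^(1/3); e.g. free SGFP2 at 24.1 um^2/s
    (27 kDa) predicts 14.9 um^2/s for the 115 kDa SGFP2-CTNNB1 fusion.
    """
    return inp.d_ref * (inp.mass_ref / inp.mass_target) ** (1.0 / 3.0)
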