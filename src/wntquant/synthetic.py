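"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's measurement regimes without any
external data:

* :func:`simulate_fcs_trace` — photon-count traces from point detection of
  Brownian particles (two diffusing species around 14.9 and 0.1-0.6
  um^2/s, 50-150 particles in a ~0.74 fl volume, optional dark-state
  blinking), for the FCS chain;
* :func:`simulate_nandb_stack` — photon-count frame stacks with
  monomer/oligomer brightness species, for N&B;
* :func:`simulate_equilibrium_measurements` — noisy replicates of the
  steady-state concentration measurements, for parameter-derivation
  recovery studies.

Every generator takes an explicit seed and is bit-reproducible; each
returns a ground-truth record alongside the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numba
import numpy as np

from .fcs import IntensityTrace
from .nandb import ImageStack
from .derive import EquilibriumMeasurement
from .model import ModelState

__all__ = [
    "SpeciesConfig",
    "FcsSimConfig",
    "NbSimConfig",
    "MeasurementNoiseConfig",
    "simulate_fcs_trace",
    "simulate_nandb_stack",
    "simulate_equilibrium_measurements",
]

# Default detection geometry: cylinder volume 2 pi w^3 sp ~ 0.74 fl, the
# effective volume back-solved from the observed 80 molecules <-> 180 nM
# correspondence.
DEFAULT_OMEGA_XY = 0.2867  # um
DEFAULT_SP = 5.0


@dataclass(frozen=True)
class SpeciesConfig:
    """One diffusing species: coefficient (um^2/s), number fraction and
    per-particle peak count rate (kHz)."""

    d: float
    fraction: float
    brightness_khz: float = 3.0

    def __post_init__(self):
        if self.d <= 0 or self.brightness_khz < 0 or not 0 <= self.fraction <= 1:
            raise ValueError("invalid species configuration")


@dataclass
class FcsSimConfig:
    """Configuration of the Brownian photon-trace simulator.

    ``n_particles`` is the average particle number in the FCS effective
    volume pi^(3/2) w^2 wz (what an unbiased amplitude fit reports as N).
    The simulation box is periodic, ``box_height`` >= 6 wz tall; particle
    positions advance by Gaussian jumps whose variance is 2 D dt per axis,
    taken with a per-species sub-stride so the RMS step stays below
    omega_xy/15 (stride 1 for the fast species at default binning —
    jump-process increments make the sampled correlation exact at integer
    lag multiples, so coarser strides for very slow species only save
    arithmetic).
    """

    # monomer at the Einstein-Stokes value; complex at the middle of the
    # measured 0.1-0.6 um^2/s range, which also keeps its diffusion time
    # well inside the [10, 150] ms fit bounds at the default geometry
    species: tuple[SpeciesConfig, ...] = (
        SpeciesConfig(d=14.9, fraction=0.65, brightness_khz=3.0),
        SpeciesConfig(d=0.3, fraction=0.35, brightness_khz=3.0),
    )
    n_particles: float = 80.0
    omega_xy: float = DEFAULT_OMEGA_XY
    sp: float = DEFAULT_SP
    triplet_fraction: float = 0.0
    tau_trip_ms: float = 0.005
    bin_width: float = 8e-5   # s
    duration: float = 10.0    # s
    background_khz: float = 0.0
    box_lateral: float | None = None  # um, default 6 omega_xy
    box_height: float | None = None   # um, default 6 omega_z
    seed: int = 0

    def __post_init__(self):
        total = sum(s.fraction for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1, got {total}")
        if self.n_particles <= 0 or self.bin_width <= 0 or self.duration <= 0:
            raise ValueError("n_particles, bin_width and duration must be positive")
        if not 0 <= self.triplet_fraction < 1:
            raise ValueError("triplet_fraction must lie in [0, 1)")

    @property
    def omega_z(self) -> float:
        return self.sp * self.omega_xy

    @property
    def effective_volume(self) -> float:
        """FCS effective volume pi^(3/2) w^2 wz in um^3 (= fl)."""
        return math.pi ** 1.5 * self.omega_xy**2 * self.omega_z

    @property
    def box(self) -> tuple[float, float, float]:
        """Periodic box (um): lateral default 6 omega_xy (smaller boxes let
        wrapped-around walkers produce spurious long-lag correlation),
        height at least 6 omega_z so the detection volume fits."""
        lx = self.box_lateral if self.box_lateral is not None else 6.0 * self.omega_xy
        lz = self.box_height if self.box_height is not None else 6.0 * self.omega_z
        if lz < 6.0 * self.omega_z - 1e-12:
            raise ValueError("box smaller than detection volume: height must be >= 6 omega_z")
        if lx < 3.0 * self.omega_xy - 1e-12:
            raise ValueError("box smaller than detection volume: lateral extent must be >= 3 omega_xy")
        return lx, lx, lz

    def tau_diff_ms(self, d: float) -> float:
        return self.omega_xy**2 / (4.0 * d) * 1e3


@numba.njit(cache=True, fastmath=True)
def _walk_chunk(pos, steps_xy, steps_z, rz, lam, lx, ly, lz, ax, az
                ):  # pragma: no cover - exercised via wrapper
    """Advance walkers by pre-drawn Gaussian steps and accumulate weights.

    ``pos`` (n_part, 3) is updated in place; ``lam`` (m,) receives the sum
    of detection weights per update step.  The axial coordinate advances
    only every ``rz`` updates (with correspondingly larger jumps): the
    axial weight factor varies on the much longer axial diffusion time, so
    its staircase approximation is negligible while the transverse motion
    keeps full time resolution.
    """
    n_part = pos.shape[0]
    m = steps_xy.shape[1]
    cx, cy, cz = lx / 2.0, ly / 2.0, lz / 2.0
    for p in range(n_part):
        x, y, z = pos[p, 0], pos[p, 1], pos[p, 2]
        wz = math.exp(-az * (z - cz) ** 2) if az * (z - cz) ** 2 < 30.0 else 0.0
        for t in range(m):
            x += steps_xy[p, t, 0]
            y += steps_xy[p, t, 1]
            if x < 0.0:
                x += lx
            elif x >= lx:
                x -= lx
            if y < 0.0:
                y += ly
            elif y >= ly:
                y -= ly
            if t % rz == 0:
                z += steps_z[p, t // rz]
                if z < 0.0:
                    z += lz
                elif z >= lz:
                    z -= lz
                qz = az * (z - cz) ** 2
                wz = math.exp(-qz) if qz < 30.0 else 0.0
            q = ax * ((x - cx) ** 2 + (y - cy) ** 2)
            if q < 20.0 and wz > 0.0:
                lam[t] += math.exp(-q) * wz
        pos[p, 0], pos[p, 1], pos[p, 2] = x, y, z


def _stride_for(d: float, bin_width: float, omega_xy: float) -> int:
    """Sub-stride keeping the RMS transverse jump below omega_xy/15."""
    target = (omega_xy / 15.0) ** 2
    return int(min(max(math.floor(target / (2.0 * d * bin_width)), 1), 64))


def _species_lambda(rng: np.random.Generator, n_part: int, n_bins: int,
                    bin_width: float, d: float, box: tuple[float, float, float],
                    omega_xy: float, omega_z: float,
                    chunk: int = 8192) -> np.ndarray:
    """Summed detection weights per bin for one species (no brightness).

    Positions advance with a sub-stride chosen so the RMS transverse jump
    stays below omega_xy/15 (stride 1 for fast species at default binning);
    the weight is held constant within a stride.  Gaussian jump increments
    make the sampled correlation exact at integer multiples of the update
    interval.
    """
    if n_part == 0:
        return np.zeros(n_bins)
    lx, ly, lz = box
    stride = _stride_for(d, bin_width, omega_xy)
    n_upd = -(-n_bins // stride)  # ceil
    dt_u = stride * bin_width
    sigma = math.sqrt(2.0 * d * dt_u)
    # axial updates every rz transverse updates: resolve the axial diffusion
    # time tau_z = omega_z^2/(4D) with >= 10 points
    tau_z = omega_z**2 / (4.0 * d)
    rz = int(min(max(math.floor(tau_z / (10.0 * dt_u)), 1), 256))
    sigma_z = math.sqrt(2.0 * d * rz * dt_u)

    pos = rng.uniform(0.0, 1.0, size=(n_part, 3))
    pos *= np.array([lx, ly, lz])
    lam = np.zeros(n_upd)
    done = 0
    while done < n_upd:
        m = min(chunk, n_upd - done)
        mz = -(-m // rz)
        steps_xy = rng.standard_normal((n_part, m, 2), dtype=np.float32)
        steps_xy *= np.float32(sigma)
        steps_z = rng.standard_normal((n_part, mz), dtype=np.float32)
        steps_z *= np.float32(sigma_z)
        _walk_chunk(pos, steps_xy, steps_z, rz, lam[done:done + m],
                    lx, ly, lz, 2.0 / omega_xy**2, 2.0 / omega_z**2)
        done += m
    return np.repeat(lam, stride)[:n_bins]


def _telegraph_duty(rng: np.random.Generator, n_part: int, n_bins: int,
                    bin_width: float, f_dark: float, tau_trip_s: float
                    ) -> np.ndarray:
    """Two-state blinking occupancy (0/1 per particle per bin).

    Stationary dark fraction ``f_dark``, relaxation time ``tau_trip_s``;
    valid as a per-bin telegraph when tau_trip is not far below the bin
    width.  Returns the bright-state indicator array (n_bins, n_part).
    """
    k_total = 1.0 / tau_trip_s
    p_dark = f_dark
    # per-bin transition probabilities from the two-state master equation
    decay = math.exp(-k_total * bin_width)
    state = (rng.uniform(size=n_part) >= p_dark).astype(np.int8)  # 1 = bright
    out = np.empty((n_bins, n_part), dtype=np.int8)
    u = rng.uniform(size=(n_bins, n_part))
    for t in range(n_bins):
        p_bright = (1 - p_dark) + (state - (1 - p_dark)) * decay
        state = (u[t] < p_bright).astype(np.int8)
        out[t] = state
    return out


def simulate_fcs_trace(cfg: FcsSimConfig) -> tuple[IntensityTrace, dict]:
    """Simulate one photon-count trace plus its ground-truth record.

    Per-bin photon counts are Poisson draws from the summed 3D-Gaussian
    detection weights of Brownian walkers in a periodic box, scaled by each
    species' peak count rate, plus an optional flat background.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bins = int(round(cfg.duration / cfg.bin_width))
    box = cfg.box
    v_box = box[0] * box[1] * box[2]
    conc = cfg.n_particles / cfg.effective_volume  # particles per um^3

    rate = np.zeros(n_bins)
    truth_species = []
    n_eff_actual = 0.0
    for sp in cfg.species:
        n_box = int(round(conc * sp.fraction * v_box))
        if cfg.triplet_fraction > 0 and n_box > 0:
            # per-particle weights are needed to apply blinking; this path is
            # intended for modest trace sizes
            lam = np.zeros(n_bins)
            duty = _telegraph_duty(rng, n_box, n_bins, cfg.bin_width,
                                   cfg.triplet_fraction, cfg.tau_trip_ms * 1e-3)
            per = _species_lambda_per_particle(rng, n_box, n_bins, cfg.bin_width,
                                               sp.d, box, cfg.omega_xy, cfg.omega_z)
            lam = (per * duty).sum(axis=1)
        else:
            lam = _species_lambda(rng, n_box, n_bins, cfg.bin_width, sp.d, box,
                                  cfg.omega_xy, cfg.omega_z)
        rate += sp.brightness_khz * 1e3 * cfg.bin_width * lam
        n_in_eff = n_box / v_box * cfg.effective_volume
        n_eff_actual += n_in_eff
        truth_species.append({
            "d": sp.d,
            "fraction": sp.fraction,
            "brightness_khz": sp.brightness_khz,
            "tau_diff_ms": cfg.tau_diff_ms(sp.d),
            "n_box": n_box,
            "n_effective": n_in_eff,
        })
    rate += cfg.background_khz * 1e3 * cfg.bin_width
    counts = rng.poisson(rate)

    truth = {
        "seed": cfg.seed,
        "n_particles_effective": n_eff_actual,
        "concentration_per_um3": conc,
        "omega_xy": cfg.omega_xy,
        "sp": cfg.sp,
        "effective_volume_fl": cfg.effective_volume,
        "triplet_fraction": cfg.triplet_fraction,
        "tau_trip_ms": cfg.tau_trip_ms,
        "species": truth_species,
    }
    trace = IntensityTrace(counts=counts, bin_width=cfg.bin_width,
                           metadata={"synthetic": True, "seed": cfg.seed})
    return trace, truth


def _species_lambda_per_particle(rng, n_part, n_bins, bin_width, d, box,
                                 omega_xy, omega_z) -> np.ndarray:
    """Per-particle detection weights, shape (n_bins, n_part)."""
    lx, ly, lz = box
    target = (omega_xy / 15.0) ** 2
    stride = int(min(max(math.floor(target / (2.0 * d * bin_width)), 1), 64))
    n_upd = -(-n_bins // stride)
    sigma = math.sqrt(2.0 * d * stride * bin_width)
    pos = rng.uniform(0.0, 1.0, size=(n_part, 3)) * np.array([lx, ly, lz])
    steps = rng.standard_normal((n_upd, n_part, 3)) * sigma
    steps[0] = 0.0
    path = (np.cumsum(steps, axis=0) + pos) % np.array([lx, ly, lz])
    q = 2.0 * ((path[:, :, 0] - lx / 2) ** 2 + (path[:, :, 1] - ly / 2) ** 2) / omega_xy**2
    q += 2.0 * (path[:, :, 2] - lz / 2) ** 2 / omega_z**2
    w = np.exp(-q)
    return np.repeat(w, stride, axis=0)[:n_bins]


@dataclass
class NbSimConfig:
    """Configuration of the frame-stack simulator.

    Emitters are placed in a slab of height 2 x 1.5 omega_z around the focal
    plane; ``density`` is the resulting areal density (particles per um^2 of
    imaged field).  ``oligomer_size`` multiplies the per-molecule brightness
    (a dimer carries twice the monomer count rate).  The default "fast" mode
    redraws positions independently every frame (diffusion much faster than
    the frame interval); "slow" mode propagates persistent walkers with
    coefficient ``d_slow``.
    """

    brightness_per_dwell: float = 1.0   # photons per dwell per molecule at peak
    oligomer_size: int = 1
    density: float = 25.0               # particles per um^2
    shape: tuple[int, int] = (64, 64)
    frames: int = 50
    pixel_dwell: float = 1e-4           # s
    pixel_size: float = 0.207           # um
    omega_xy: float = DEFAULT_OMEGA_XY
    sp: float = DEFAULT_SP
    background_per_dwell: float = 0.0
    mode: str = "fast"
    d_slow: float = 0.05                # um^2/s, slow mode only
    seed: int = 0

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.oligomer_size < 1:
            raise ValueError("oligomer_size must be >= 1")
        if self.frames < 2:
            raise ValueError("need at least 2 frames")
        if self.mode not in ("fast", "slow"):
            raise ValueError("mode must be 'fast' or 'slow'")

    @property
    def omega_z(self) -> float:
        return self.sp * self.omega_xy

    @property
    def slab_half_height(self) -> float:
        return 1.5 * self.omega_z


def simulate_nandb_stack(cfg: NbSimConfig) -> tuple[ImageStack, dict]:
    """Simulate a photon-count frame stack plus its ground-truth record.

    Each frame sums separable Gaussian point-spread contributions of all
    emitters into per-pixel Poisson rates.  In the fast-diffusion limit the
    emitter configuration decorrelates completely between frames.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    ly, lx = h * cfg.pixel_size, w * cfg.pixel_size
    zh = cfg.slab_half_height
    area = lx * ly
    b_particle = cfg.brightness_per_dwell * cfg.oligomer_size

    xg = (np.arange(w) + 0.5) * cfg.pixel_size
    yg = (np.arange(h) + 0.5) * cfg.pixel_size
    frames = np.empty((cfg.frames, h, w), dtype=np.int64)

    if cfg.mode == "slow":
        n_p = rng.poisson(cfg.density * area)
        xs = rng.uniform(0, lx, n_p)
        ys = rng.uniform(0, ly, n_p)
        zs = rng.uniform(-zh, zh, n_p)
        frame_interval = h * w * cfg.pixel_dwell  # raster time per frame
        sigma = math.sqrt(2.0 * cfg.d_slow * frame_interval)

    for k in range(cfg.frames):
        if cfg.mode == "fast":
            n_p = rng.poisson(cfg.density * area)
            xs = rng.uniform(0, lx, n_p)
            ys = rng.uniform(0, ly, n_p)
            zs = rng.uniform(-zh, zh, n_p)
        else:
            step = rng.standard_normal((3, n_p)) * sigma
            xs = (xs + step[0]) % lx
            ys = (ys + step[1]) % ly
            zs = ((zs + zh + step[2]) % (2 * zh)) - zh
        if n_p:
            wx = np.exp(-2.0 * (xs[:, None] - xg[None, :]) ** 2 / cfg.omega_xy**2)
            wy = np.exp(-2.0 * (ys[:, None] - yg[None, :]) ** 2 / cfg.omega_xy**2)
            wz = np.exp(-2.0 * zs**2 / cfg.omega_z**2)
            lam = np.einsum("ph,pw->hw", wy * (b_particle * wz)[:, None], wx)
        else:
            lam = np.zeros((h, w))
        frames[k] = rng.poisson(lam + cfg.background_per_dwell)

    conc = cfg.density / (2 * zh)  # per um^3
    v_eff = math.pi ** 1.5 * cfg.omega_xy**2 * cfg.omega_z
    truth = {
        "seed": cfg.seed,
        "concentration_per_um3": conc,
        "expected_apparent_number": conc * v_eff,
        "expected_apparent_brightness": b_particle * 2.0 ** -1.5,
        "oligomer_size": cfg.oligomer_size,
        "brightness_per_dwell": cfg.brightness_per_dwell,
        "mode": cfg.mode,
    }
    stack = ImageStack(frames=frames, pixel_dwell=cfg.pixel_dwell,
                       pixel_size=cfg.pixel_size,
                       metadata={"synthetic": True, "seed": cfg.seed})
    return stack, truth


@dataclass
class MeasurementNoiseConfig:
    """Noisy replicates of an equilibrium concentration measurement.

    Multiplicative log-normal noise (median-unbiased, sigma from the
    coefficient of variation) is applied to the four fluctuation-measured
    pools; the literature-derived quantities (b, K1, total TCF) are held
    fixed.
    """

    truth: EquilibriumMeasurement
    cv: float = 0.10
    replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def measurement_from_state(state: ModelState, condition: str,
                           k1_ratio: float, b: float) -> EquilibriumMeasurement:
    """Package a model steady state as an equilibrium measurement."""
    return EquilibriumMeasurement(
        condition=condition, cb_free=state.x1, nb_free=state.x5,
        nb_tcf=state.x7, cb_dc=state.x3, tcf_total=state.tcf_total,
        k1_ratio=k1_ratio, b=b)


def simulate_equilibrium_measurements(cfg: MeasurementNoiseConfig
                                      ) -> tuple[list[EquilibriumMeasurement], dict]:
    """Draw noisy measurement replicates around the configured truth."""
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log(1.0 + cfg.cv**2))
    out = []
    for _ in range(cfg.replicates):
        f = np.exp(sigma * rng.standard_normal(4))
        nb_tcf = min(cfg.truth.nb_tcf * f[2], cfg.truth.tcf_total)
        out.append(EquilibriumMeasurement(
            condition=cfg.truth.condition,
            cb_free=cfg.truth.cb_free * f[0],
            nb_free=cfg.truth.nb_free * f[1],
            nb_tcf=nb_tcf,
            cb_dc=cfg.truth.cb_dc * f[3],
            tcf_total=cfg.truth.tcf_total,
            k1_ratio=cfg.truth.k1_ratio,
            b=cfg.truth.b,
        ))
    truth = {"seed": cfg.seed, "cv": cfg.cv, "replicates": cfg.replicates,
             "truth": asdict(cfg.truth)}
    return out, truth
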