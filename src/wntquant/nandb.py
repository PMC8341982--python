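"""Number & Brightness analysis of photon-count image stacks.

A stack of frames acquired at the same positions samples, per pixel, the
fluctuating number of emitters in the detection volume.  With a photon
counting detector the per-pixel mean <I> and variance sigma^2 separate into
shot noise (variance = mean) and number fluctuations, giving the
shot-noise-subtracted estimators

    apparent brightness  epsilon = (sigma^2 - <I>) / <I>     (counts/dwell)
    apparent number      n       = <I>^2 / (sigma^2 - <I>)

Brightness is an intensive, per-particle property; it is reported relative
to a monomer control measured in the same compartment, so a dimer reads ~2.
Particle-number conventions differ between techniques: N&B software reports
the number inside the 3D-Gaussian PSF volume, which is gamma = 0.3536
(= 2^-3/2) times the apparent number above; dividing that reported number
by gamma recovers the FCS-comparable value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "GAMMA_3D_GAUSS",
    "ImageStack",
    "BrightnessMap",
    "RoiSummary",
    "pixel_stats",
    "brightness_number",
    "roi_summary",
    "exclusion_mask",
]

#: Geometric factor 2^(-3/2) relating the 3D-Gaussian-volume particle number
#: reported by N&B analysis to the apparent (FCS-comparable) number.
GAMMA_3D_GAUSS = 0.3536


@dataclass
class ImageStack:
    """Frames x height x width photon counts with acquisition geometry."""

    frames: np.ndarray
    pixel_dwell: float  # seconds per pixel
    pixel_size: float   # um
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-d array (frames, height, width)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_dwell <= 0 or self.pixel_size <= 0:
            raise ValueError("pixel_dwell and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path, pixel_dwell: float, pixel_size: float) -> "ImageStack":
        return cls(frames=tifffile.imread(path), pixel_dwell=pixel_dwell,
                   pixel_size=pixel_size)


def pixel_stats(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and unbiased (ddof=1) variance across frames."""
    frames = stack.frames.astype(float)
    return frames.mean(axis=0), frames.var(axis=0, ddof=1)


@dataclass
class BrightnessMap:
    """Per-pixel brightness/number estimates plus the no-signal mask.

    ``mask`` marks pixels excluded from summaries: zero-mean pixels and
    pixels whose variance does not exceed shot noise (no fluctuation
    signal); brightness and number are NaN there.
    """

    mean: np.ndarray
    variance: np.ndarray
    brightness: np.ndarray
    number: np.ndarray
    mask: np.ndarray  # True = excluded


def brightness_number(mean: np.ndarray, variance: np.ndarray,
                      mode: str = "photon_counting") -> BrightnessMap:
    """Apparent molecular brightness and particle number per pixel.

    Photon-counting mode subtracts shot noise: epsilon = (var - mean)/mean,
    n = mean^2/(var - mean).  Pixels with var <= mean carry no fluctuation
    signal and are masked.
    """
    if mode != "photon_counting":
        raise ValueError("only photon_counting mode is implemented")
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    excess = variance - mean
    mask = (mean <= 0) | (excess <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(mask, np.nan, excess / mean)
        n = np.where(mask, np.nan, mean**2 / excess)
    return BrightnessMap(mean=mean, variance=variance, brightness=eps,
                         number=n, mask=mask)


def exclusion_mask(bmap: BrightnessMap, roi: np.ndarray,
                   mad_factor: float = 3.0) -> np.ndarray:
    """Static/bright-structure exclusion inside an ROI.

    Pixels whose mean intensity exceeds the ROI median by more than
    ``mad_factor`` median absolute deviations are marked for exclusion
    (immobile bright structures inflate the variance and distort the
    brightness estimate).
    """
    roi = np.asarray(roi, dtype=bool)
    vals = bmap.mean[roi & ~bmap.mask]
    if vals.size == 0:
        return np.zeros_like(roi)
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        return np.zeros_like(roi)
    return roi & (bmap.mean > med + mad_factor * mad)


@dataclass
class RoiSummary:
    """Median brightness/number statistics over one ROI."""

    label: str
    median_brightness: float           # apparent counts/dwell
    normalized_brightness: float       # relative to the monomer control
    number_raw: float                  # 3D-Gaussian-volume convention
    number_gamma_corrected: float      # FCS-comparable (= raw / gamma)
    n_pixels: int

    def to_row(self) -> dict:
        return {
            "roi": self.label,
            "median_brightness": self.median_brightness,
            "normalized_brightness": self.normalized_brightness,
            "number_raw": self.number_raw,
            "number_gamma_corrected": self.number_gamma_corrected,
            "n_pixels": self.n_pixels,
        }


def roi_summary(bmap: BrightnessMap, roi: np.ndarray,
                monomer_reference: float, label: str = "roi",
                mad_factor: float | None = 3.0,
                gamma: float = GAMMA_3D_GAUSS) -> RoiSummary:
    """Summarise brightness and particle number over an ROI.

    The ROI median apparent brightness is normalised to the monomer control
    median measured in the same compartment.  ``number_raw`` is the median
    apparent number scaled by gamma (the PSF-volume convention N&B software
    reports); dividing by gamma recovers the FCS-comparable number.
    Bright static structures are excluded via :func:`exclusion_mask` unless
    ``mad_factor`` is None.
    """
    roi = np.asarray(roi, dtype=bool)
    if monomer_reference <= 0:
        raise ValueError("monomer_reference must be positive")
    excluded = bmap.mask.copy()
    if mad_factor is not None:
        excluded |= exclusion_mask(bmap, roi, mad_factor)
    use = roi & ~excluded
    if not np.any(use):
        raise ValueError(f"ROI {label!r} has no usable pixels after exclusions")
    med_eps = float(np.median(bmap.brightness[use]))
    med_n = float(np.median(bmap.number[use]))
    raw = gamma * med_n
    return RoiSummary(
        label=label,
        median_brightness=med_eps,
        normalized_brightness=med_eps / monomer_reference,
        number_raw=raw,
        number_gamma_corrected=raw / gamma,
        n_pixels=int(np.sum(use)),
    )
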