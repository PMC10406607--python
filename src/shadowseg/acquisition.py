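"""Photon-count image formation and dwell-time bookkeeping.

Images are formed as independent Poisson draws around the PSF-blurred
dye density; paired low/high-exposure volumes are produced by binomial
thinning of the photon stream, which is statistically identical to
setting aside the photons of the first 10 us of a 70 us voxel dwell.
The same thinning yields the 50:50 two-detector split and the
interleaved duplicate-split control used to separate restoration error
from true morphodynamics.

Stored 16-bit TIFF counts may be inverted (value = 65535 - counts), the
shadow-imaging convention where maximal extracellular signal appears
black.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .optics import EffectivePSF

_INVERT_MAX = 65535  # 16-bit inversion constant

#: photons per microsecond per unit dye density; chosen so a default
#: 70-us high-exposure volume reaches mean ECS counts in the
#: photon-counting STED range (~20-60 per voxel)
DEFAULT_BRIGHTNESS = 1.0
DEFAULT_BACKGROUND = 0.005  # photons per us (dark counts / stray light)


@dataclass
class PhotonImage:
    """Integer photon counts with acquisition metadata."""

    counts: np.ndarray  # non-negative int
    dwell_us: float
    voxel_size_nm: float = 50.0
    detectors_summed: bool = True
    inverted: bool = False
    brightness_scale: float = DEFAULT_BRIGHTNESS
    background_rate: float = DEFAULT_BACKGROUND
    seed: int = 0
    channel: str = "shadow"

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")


@dataclass
class PairedAcquisition:
    """Voxel-exact low/high exposure pair (low is a sub-interval of high)."""

    low: PhotonImage
    high: PhotonImage
    voxel_exact: bool = True


@dataclass
class LightBudget:
    dwell_low_us: float
    dwell_high_us: float

    @property
    def exposure_reduction(self) -> float:
        return 1.0 - self.dwell_low_us / self.dwell_high_us

    @property
    def acceleration(self) -> float:
        return self.dwell_high_us / self.dwell_low_us

    def report(self) -> dict:
        """Rounded percentages as printed in imaging protocols."""
        return {
            "dwell_low_us": self.dwell_low_us,
            "dwell_high_us": self.dwell_high_us,
            "exposure_reduction_percent": int(round(100 * self.exposure_reduction)),
            "acceleration_fold": round(self.acceleration, 1),
        }


def light_budget(dwell_low_us: float, dwell_high_us: float) -> LightBudget:
    """Photon-load reduction and acquisition speed-up of the low-exposure
    scheme at fixed laser powers (10/70 us -> 86% reduction, 7x faster)."""
    if dwell_low_us <= 0 or dwell_high_us <= 0:
        raise ValueError("dwell times must be positive")
    if dwell_low_us >= dwell_high_us:
        raise ValueError("low dwell must be shorter than high dwell")
    return LightBudget(dwell_low_us, dwell_high_us)


def _psf_kernel(psf: EffectivePSF | np.ndarray, voxel_nm: float) -> np.ndarray:
    if isinstance(psf, EffectivePSF):
        if abs(psf.voxel_size[0] - voxel_nm) > 1e-6 or \
                abs(psf.voxel_size[1] - voxel_nm) > 1e-6:
            psf = psf.resampled((voxel_nm,) * 3)
        kernel = psf.values
    else:
        kernel = np.asarray(psf, dtype=float)
    return kernel / kernel.sum()


def expected_rate(density: np.ndarray, psf: EffectivePSF | np.ndarray,
                  dwell_us: float,
                  brightness_scale: float = DEFAULT_BRIGHTNESS,
                  background_rate: float = DEFAULT_BACKGROUND,
                  voxel_size_nm: float = 50.0) -> np.ndarray:
    """Noise-free expected photon count per voxel (the Poisson mean)."""
    if dwell_us <= 0:
        raise ValueError("dwell time must be positive")
    if np.any(density < 0):
        raise ValueError("dye density must be non-negative")
    kernel = _psf_kernel(psf, voxel_size_nm)
    blurred = fftconvolve(density, kernel, mode="same")
    blurred = np.clip(blurred, 0.0, None)  # FFT ringing guard
    return dwell_us * (brightness_scale * blurred + background_rate)


def image_volume(density: np.ndarray, psf: EffectivePSF | np.ndarray,
                 dwell_us: float = 70.0,
                 brightness_scale: float = DEFAULT_BRIGHTNESS,
                 background_rate: float = DEFAULT_BACKGROUND,
                 seed: int = 0, voxel_size_nm: float = 50.0,
                 channel: str = "shadow") -> PhotonImage:
    """Image a dye-density volume: PSF blur, then Poisson photon counts."""
    lam = expected_rate(density, psf, dwell_us, brightness_scale,
                        background_rate, voxel_size_nm)
    rng = np.random.default_rng([seed, 11])
    counts = rng.poisson(lam).astype(np.int64)
    return PhotonImage(counts, dwell_us, voxel_size_nm,
                       brightness_scale=brightness_scale,
                       background_rate=background_rate, seed=seed,
                       channel=channel)


def split_dwell(high: PhotonImage, low_dwell_us: float = 10.0,
                seed: int | None = None) -> PairedAcquisition:
    """Set aside the photons of the first ``low_dwell_us`` of the high
    exposure: per voxel Binomial(counts, low/high) thinning.

    The low image is a true sub-interval of the high exposure, so the
    pair is voxel-exact and low <= high everywhere.
    """
    if high.inverted:
        raise ValueError("revert the count inversion before splitting")
    if low_dwell_us >= high.dwell_us or low_dwell_us <= 0:
        raise ValueError("low dwell must lie in (0, high dwell)")
    rng = np.random.default_rng([seed if seed is not None else high.seed, 13])
    low_counts = rng.binomial(high.counts, low_dwell_us / high.dwell_us)
    low = replace(high, counts=low_counts.astype(np.int64),
                  dwell_us=low_dwell_us)
    return PairedAcquisition(low=low, high=high)


def duplicate_split(acq: PhotonImage, dwell_each_us: float = 10.0,
                    seed: int | None = None
                    ) -> tuple[PhotonImage, PhotonImage]:
    """Two statistically independent measurements of the same scene.

    Sequential binomial thinning assigns each photon of the (long) dwell
    to the first or second interleaved interval; used as the static
    control when separating restoration inaccuracies from biological
    motion.
    """
    if acq.inverted:
        raise ValueError("revert the count inversion before splitting")
    if acq.dwell_us < 2 * dwell_each_us:
        raise ValueError("dwell too short for two interleaved measurements")
    rng = np.random.default_rng([seed if seed is not None else acq.seed, 17])
    p1 = dwell_each_us / acq.dwell_us
    first = rng.binomial(acq.counts, p1)
    remaining = acq.counts - first
    second = rng.binomial(remaining, dwell_each_us / (acq.dwell_us - dwell_each_us))
    mk = lambda c: replace(acq, counts=c.astype(np.int64),
                           dwell_us=dwell_each_us)
    return mk(first), mk(second)


def split_detectors(img: PhotonImage, seed: int | None = None
                    ) -> tuple[PhotonImage, PhotonImage]:
    """50:50 beam-splitter onto two photon-counting detectors."""
    rng = np.random.default_rng([seed if seed is not None else img.seed, 19])
    a = rng.binomial(img.counts, 0.5)
    det_a = replace(img, counts=a.astype(np.int64), detectors_summed=False)
    det_b = replace(img, counts=(img.counts - a).astype(np.int64),
                    detectors_summed=False)
    return det_a, det_b


def sum_detectors(det_a: PhotonImage, det_b: PhotonImage) -> PhotonImage:
    """Add both detection channels back up; photon-exact."""
    if det_a.counts.shape != det_b.counts.shape:
        raise ValueError("detector channels must share the same grid")
    return replace(det_a, counts=det_a.counts + det_b.counts,
                   detectors_summed=True)


def invert_counts(img: PhotonImage) -> PhotonImage:
    """16-bit count inversion (involution): stored = 65535 - stored."""
    if np.any(img.counts > _INVERT_MAX):
        raise OverflowError("counts exceed the 16-bit inversion range")
    return replace(img, counts=_INVERT_MAX - img.counts,
                   inverted=not img.inverted)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom else 0.0


def stitch_volumes(volumes: list[PhotonImage],
                   nominal_offsets_nm: list[tuple[float, float, float]],
                   search_radius: int = 4) -> PhotonImage:
    """Translation-stitch partially overlapping volumes.

    Integer-voxel offsets are refined by maximizing normalized cross-
    correlation in the overlap with the already-fused canvas; tiles are
    fused by linear blending with distance-to-edge weights.
    """
    if len(volumes) != len(nominal_offsets_nm):
        raise ValueError("one offset per volume required")
    vox = volumes[0].voxel_size_nm
    offsets = [np.round(np.asarray(o, dtype=float) / vox).astype(int)
               for o in nominal_offsets_nm]

    def edge_weight(shape):
        w = np.ones(shape)
        for ax, n in enumerate(shape):
            ramp = np.minimum(np.arange(n), np.arange(n)[::-1]) + 1.0
            sl = [None] * 3
            sl[ax] = slice(None)
            w = w * ramp[tuple(sl)]
        return w

    refined = [offsets[0]]
    # canvas bounds grow as tiles are added
    mins = offsets[0].copy()
    maxs = offsets[0] + volumes[0].counts.shape
    for i in range(1, len(volumes)):
        mins = np.minimum(mins, offsets[i])
        maxs = np.maximum(maxs, offsets[i] + volumes[i].counts.shape)
    mins -= search_radius
    maxs += search_radius
    shape = tuple(maxs - mins)
    acc = np.zeros(shape)
    wacc = np.zeros(shape)

    def paste(vol, off, weight):
        sl = tuple(slice(o, o + s) for o, s in zip(off - mins, vol.shape))
        acc[sl] += vol * weight
        wacc[sl] += weight

    first = volumes[0]
    paste(first.counts.astype(float), offsets[0],
          edge_weight(first.counts.shape))
    for i in range(1, len(volumes)):
        vol = volumes[i].counts.astype(float)
        best, best_off = None, None
        for dz in range(-search_radius, search_radius + 1):
            for dy in range(-search_radius, search_radius + 1):
                for dx in range(-search_radius, search_radius + 1):
                    off = offsets[i] + (dz, dy, dx)
                    sl = tuple(slice(o, o + s)
                               for o, s in zip(off - mins, vol.shape))
                    canvas = acc[sl]
                    weights = wacc[sl]
                    overlap = weights > 0
                    if overlap.sum() < 10 ** 3:
                        continue
                    score = _ncc(canvas[overlap] / weights[overlap],
                                 vol[overlap])
                    if best is None or score > best:
                        best, best_off = score, off
        if best_off is None:
            raise ValueError("tiles do not overlap sufficiently to stitch")
        refined.append(best_off)
        paste(vol, best_off, edge_weight(vol.shape))

    filled = wacc > 0
    fused = np.zeros(shape, dtype=np.int64)
    fused[filled] = np.round(acc[filled] / wacc[filled]).astype(np.int64)
    # crop to the filled bounding box
    nz = np.nonzero(filled)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    return replace(volumes[0], counts=fused[sl])
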