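"""Scalar focal-field optics for STED shadow imaging.

Simulates excitation and depletion focal intensity patterns from pupil
phase masks (flat, helical/vortex, top-hat) with a scalar Debye model:
the focal field in each z-plane is the 2D Fourier transform of the
apodized pupil with a per-plane defocus phase.  Depletion patterns are
combined incoherently (default 80/20 z-STED / 4pi(xy)-STED power split)
and turned into an effective imaging PSF via an exponential depletion
survival model with a single saturation knob ``zeta`` (peak depletion
intensity in units of the fluorophore saturation intensity).

Conventions
-----------
Arrays are ordered ``(z, y, x)``, sample counts are odd and the focal
point sits at the central voxel.  Pupil coordinates are dimensionless
with the aperture radius equal to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve


class InvalidMaskError(ValueError):
    """Phase-mask parameters outside their valid domain."""


class NotApplicableError(ValueError):
    """Operation undefined for this pattern (e.g. no on-axis zero)."""


@dataclass
class STEDConfig:
    """Optical configuration of the STED microscope."""

    excitation_wavelength: float = 640.0  # nm
    sted_wavelength: float = 775.0  # nm
    detection_wavelength: float = 685.0  # nm, bandpass center
    sted_power_total: float = 90.0  # mW
    power_ratio_z_to_xy: tuple[float, float] = (0.8, 0.2)
    saturation_scale: float | None = None  # zeta; None = calibrate
    pinhole_airy_units: float = 0.8
    numerical_aperture: float = 1.35
    refractive_index: float = 1.40  # silicone immersion

    def __post_init__(self) -> None:
        rz, rxy = self.power_ratio_z_to_xy
        if not (0.0 <= rz <= 1.0 and 0.0 <= rxy <= 1.0):
            raise ValueError("power ratio components must lie in [0, 1]")
        if abs(rz + rxy - 1.0) > 1e-9:
            raise ValueError("power ratio components must sum to 1")


@dataclass
class PhaseMask:
    """Pupil phase pattern: flat, helical (vortex) or top-hat.

    ``helicity`` m produces a total azimuthal phase ramp of 2*pi*m
    (m=2 is the "4pi-helical" mode with a shallower near-axis rise).
    The top-hat is a central disk phase-shifted by pi; at radius
    1/sqrt(2) the shifted and unshifted pupil areas are equal, which
    cancels the on-axis focal amplitude (z-STED).
    """

    kind: str = "flat"  # flat | helical | tophat
    helicity: int = 1
    tophat_radius: float = 1.0 / np.sqrt(2.0)
    zernike_terms: list[tuple[int, int, float]] = field(default_factory=list)

    def phase(self, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
        if self.kind == "flat":
            p = np.zeros_like(rho)
        elif self.kind == "helical":
            p = np.mod(self.helicity * phi, 2.0 * np.pi)
        elif self.kind == "tophat":
            if not (0.0 < self.tophat_radius < 1.0):
                raise InvalidMaskError(
                    f"tophat_radius must lie in (0, 1), got {self.tophat_radius}"
                )
            p = np.where(rho <= self.tophat_radius, np.pi, 0.0)
        else:
            raise InvalidMaskError(f"unknown mask kind {self.kind!r}")
        for n, l, coeff in self.zernike_terms:
            p = p + coeff * zernike(n, l, rho, phi)
        return p


@dataclass
class PupilField:
    """Sampled complex pupil: amplitude and phase on a square grid."""

    grid_half_extent: float
    samples_per_axis: int
    amplitude: np.ndarray
    phase: np.ndarray
    numerical_aperture: float
    wavelength: float
    refractive_index: float

    @property
    def complex_field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class FocalIntensity:
    """3D focal intensity on an odd-sized grid centred on the focus."""

    values: np.ndarray  # (z, y, x), >= 0
    voxel_size: tuple[float, float, float]  # nm per axis (z, y, x)

    @property
    def center_index(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.values.shape)

    @property
    def center_value(self) -> float:
        return float(self.values[self.center_index])

    def peak_normalized(self) -> "FocalIntensity":
        peak = self.values.max()
        return FocalIntensity(self.values / peak, self.voxel_size)

    def power_normalized(self) -> "FocalIntensity":
        total = self.values.sum()
        return FocalIntensity(self.values / total, self.voxel_size)


@dataclass
class EffectivePSF:
    """Effective STED imaging PSF with measured FWHMs (nm)."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    fwhm_lateral: float
    fwhm_axial: float

    def resampled(self, voxel_nm: tuple[float, float, float]) -> "EffectivePSF":
        """Trilinear resampling to another (typically coarser) voxel grid."""
        factors = [old / new for old, new in zip(self.voxel_size, voxel_nm)]
        out = ndimage.zoom(self.values, factors, order=1, grid_mode=False)
        # force odd shape so the peak stays at the centre voxel
        sl = tuple(slice(0, s - (1 - s % 2)) for s in out.shape)
        out = np.clip(out[sl], 0.0, None)
        return EffectivePSF(out / out.max(), tuple(voxel_nm),
                            self.fwhm_lateral, self.fwhm_axial)


def zernike(n: int, l: int, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Zernike polynomial Z_n^l, normalized to unit RMS over the unit disk."""
    m = abs(l)
    if (n - m) % 2 != 0 or m > n:
        raise ValueError(f"invalid Zernike indices (n={n}, l={l})")
    radial = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k) * factorial((n + m) // 2 - k)
                * factorial((n - m) // 2 - k)))
        radial = radial + c * rho ** (n - 2 * k)
    norm = np.sqrt(n + 1.0) if l == 0 else np.sqrt(2.0 * (n + 1.0))
    if l > 0:
        return norm * radial * np.cos(m * phi)
    if l < 0:
        return norm * radial * np.sin(m * phi)
    return norm * radial


def make_pupil(config: STEDConfig, mask: PhaseMask, samples: int = 128,
               wavelength: float | None = None,
               apodized: bool = False) -> PupilField:
    """Sample the pupil: uniform amplitude inside the aperture, mask phase.

    ``wavelength`` defaults to the STED wavelength (depletion patterns);
    pass the excitation or detection wavelength for those PSFs.  With
    ``apodized`` the aplanatic sqrt(cos(theta)) amplitude factor is
    applied (used for aberration-sensitivity studies; the uniform pupil
    keeps the equal-area top-hat cancellation exact).
    """
    if samples < 64:
        raise ValueError("pupil sampling requires samples >= 64")
    if wavelength is None:
        wavelength = config.sted_wavelength
    c = np.linspace(-1.0, 1.0, samples)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    rho = np.hypot(yy, xx)
    phi = np.arctan2(yy, xx)
    amplitude = (rho <= 1.0).astype(float)
    if apodized:
        sin_max = config.numerical_aperture / config.refractive_index
        cos_theta = np.sqrt(np.clip(1.0 - (sin_max * rho) ** 2, 0.0, None))
        amplitude = amplitude * cos_theta ** 0.5
    phase = np.where(amplitude > 0, mask.phase(rho, phi), 0.0)
    return PupilField(
        grid_half_extent=1.0,
        samples_per_axis=samples,
        amplitude=amplitude,
        phase=phase,
        numerical_aperture=config.numerical_aperture,
        wavelength=wavelength,
        refractive_index=config.refractive_index,
    )


def _odd_count(extent: float, voxel: float) -> int:
    n = max(int(round(extent / voxel)), 3)
    return n if n % 2 == 1 else n + 1


def focal_intensity(pupil: PupilField,
                    extent_nm: tuple[float, float, float] = (2400.0, 2400.0, 2400.0),
                    voxel_nm: tuple[float, float, float] = (25.0, 25.0, 25.0),
                    normalize: str = "peak") -> FocalIntensity:
    """Scalar Debye focal intensity |E|^2 around the focus.

    Per z-plane, a defocus phase exp(i*kz*z) is applied to the pupil and
    the lateral field is obtained as a (direct, separable) 2D Fourier
    transform evaluated on the requested grid.  The transform is scaled
    so that conjugate (FFT-matched) sampling conserves pupil power.

    Parameters
    ----------
    extent_nm, voxel_nm : (z, y, x) grid extent and sampling in nm.
    normalize : 'peak', 'total' or 'none'.
    """
    lam = pupil.wavelength
    if min(extent_nm) < 3.0 * lam:
        raise ValueError("extent must cover at least 3 wavelengths per axis")
    diffraction_fwhm = 0.51 * lam / pupil.numerical_aperture
    if max(voxel_nm[1], voxel_nm[2]) > 0.5 * diffraction_fwhm:
        warnings.warn(
            f"lateral voxel exceeds half the diffraction-limited FWHM "
            f"({diffraction_fwhm:.0f} nm); focal pattern may alias",
            stacklevel=2,
        )
    k0 = 2.0 * np.pi / lam
    kmax = pupil.numerical_aperture * k0  # transverse cutoff
    n = pupil.samples_per_axis
    kc = np.linspace(-kmax, kmax, n)  # rad/nm
    dk = kc[1] - kc[0]

    kyy, kxx = np.meshgrid(kc, kc, indexing="ij")
    kt2 = kyy ** 2 + kxx ** 2
    nk0 = pupil.refractive_index * k0
    kz = np.sqrt(np.maximum(nk0 ** 2 - kt2, 0.0))

    nz = _odd_count(extent_nm[0], voxel_nm[0])
    ny = _odd_count(extent_nm[1], voxel_nm[1])
    nx = _odd_count(extent_nm[2], voxel_nm[2])
    zc = (np.arange(nz) - nz // 2) * voxel_nm[0]
    yc = (np.arange(ny) - ny // 2) * voxel_nm[1]
    xc = (np.arange(nx) - nx // 2) * voxel_nm[2]

    # separable DFT kernels; scale (dk^2 / 2pi) makes the 2D transform
    # unitary in the continuous-FT sense
    my = np.exp(1j * np.outer(yc, kc))  # (ny, n)
    mx = np.exp(1j * np.outer(kc, xc))  # (n, nx)
    pupil_c = pupil.complex_field
    scale = dk * dk / (2.0 * np.pi)

    out = np.empty((nz, ny, nx))
    for iz, z in enumerate(zc):
        plane = pupil_c * np.exp(1j * (kz - nk0) * z)
        efield = scale * (my @ plane @ mx)
        out[iz] = np.abs(efield) ** 2

    fi = FocalIntensity(out, tuple(voxel_nm))
    if normalize == "peak":
        return fi.peak_normalized()
    if normalize == "total":
        return fi.power_normalized()
    return fi


def combine_sted_patterns(i_z: FocalIntensity, i_xy: FocalIntensity,
                          ratio: tuple[float, float] = (0.8, 0.2)) -> FocalIntensity:
    """Incoherent weighted sum of two depletion patterns.

    Each input is first normalized to unit total power, mirroring the
    experimental power split of the z-STED and xy-STED beams.
    """
    if i_z.values.shape != i_xy.values.shape:
        raise ValueError("depletion patterns must share the same grid")
    rz, rxy = ratio
    combined = (rz * i_z.power_normalized().values
                + rxy * i_xy.power_normalized().values)
    return FocalIntensity(combined, i_z.voxel_size)


def _profile_fwhm(profile: np.ndarray, step: float) -> float:
    """FWHM of a 1D profile by linear interpolation of half-max crossings."""
    peak_idx = int(np.argmax(profile))
    half = profile[peak_idx] / 2.0

    def crossing(direction: int) -> float:
        i = peak_idx
        while 0 < i < len(profile) - 1:
            j = i + direction
            if profile[j] < half:
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(i - peak_idx) + frac
            i = j
        return abs(i - peak_idx)

    return (crossing(-1) + crossing(+1)) * step


def measure_fwhm(psf_values: np.ndarray,
                 voxel_size: tuple[float, float, float]) -> tuple[float, float]:
    """(lateral, axial) FWHM in nm from axis profiles through the peak."""
    cz, cy, cx = np.unravel_index(np.argmax(psf_values), psf_values.shape)
    lat_x = _profile_fwhm(psf_values[cz, cy, :], voxel_size[2])
    lat_y = _profile_fwhm(psf_values[cz, :, cx], voxel_size[1])
    axial = _profile_fwhm(psf_values[:, cy, cx], voxel_size[0])
    return 0.5 * (lat_x + lat_y), axial


def _pinhole_filtered(det: FocalIntensity, radius_nm: float) -> np.ndarray:
    """Integrate the detection PSF over a hard pinhole disk per z-plane."""
    vy, vx = det.voxel_size[1], det.voxel_size[2]
    ry = int(np.ceil(radius_nm / vy))
    rx = int(np.ceil(radius_nm / vx))
    yy, xx = np.meshgrid((np.arange(2 * ry + 1) - ry) * vy,
                         (np.arange(2 * rx + 1) - rx) * vx, indexing="ij")
    disk = (yy ** 2 + xx ** 2 <= radius_nm ** 2).astype(float)
    disk /= disk.sum()
    out = np.empty_like(det.values)
    for iz in range(det.values.shape[0]):
        out[iz] = fftconvolve(det.values[iz], disk, mode="same")
    return np.clip(out, 0.0, None)


def detection_psf(config: STEDConfig, pupil_samples: int = 128,
                  extent_nm=(2400.0, 2400.0, 2400.0),
                  voxel_nm=(25.0, 25.0, 25.0)) -> FocalIntensity:
    """Confocal detection PSF: flat-mask focal intensity at the detection
    wavelength, integrated over the pinhole disk (hard disk model)."""
    pupil = make_pupil(config, PhaseMask("flat"), pupil_samples,
                       wavelength=config.detection_wavelength)
    det = focal_intensity(pupil, extent_nm, voxel_nm, normalize="peak")
    airy_radius = 0.61 * config.detection_wavelength / config.numerical_aperture
    filtered = _pinhole_filtered(det, config.pinhole_airy_units * airy_radius)
    return FocalIntensity(filtered / filtered.max(), det.voxel_size)


def effective_psf(exc: FocalIntensity, depletion: FocalIntensity,
                  zeta: float, detection: FocalIntensity) -> EffectivePSF:
    """Effective PSF under the exponential depletion survival model.

    h_eff = h_exc * exp(-ln2 * zeta * I_dep / I_dep,peak) * h_det.
    With zeta = 0 this reduces to the confocal (excitation x detection)
    PSF.  Resolution scales roughly as 1/sqrt(1 + c*zeta).
    """
    if zeta < 0:
        raise ValueError("saturation scale zeta must be >= 0")
    if exc.values.shape != depletion.values.shape:
        raise ValueError("excitation and depletion grids must match")
    dep = depletion.values / depletion.values.max()
    h = exc.values * np.exp(-np.log(2.0) * zeta * dep) * detection.values
    h = h / h.max()
    fwhm_lat, fwhm_ax = measure_fwhm(h, exc.voxel_size)
    return EffectivePSF(h, exc.voxel_size, fwhm_lat, fwhm_ax)


def near_axis_exponent(pattern: FocalIntensity, zero_tol: float = 1e-3,
                       n_angles: int = 90) -> float:
    """Power-law exponent of the focal-plane intensity rise near the axis.

    Fits log I vs log rho over rho in [0.2, 0.6] of the ring radius using
    azimuthally averaged profiles.  A vortex of helicity m rises as
    rho^(2m); the helicity-2 mode therefore rises more shallowly near its
    zero than the classical doughnut.
    """
    cz = pattern.values.shape[0] // 2
    plane = pattern.values[cz]
    peak = plane.max()
    cy, cx = plane.shape[0] // 2, plane.shape[1] // 2
    if plane[cy, cx] > zero_tol * peak:
        raise NotApplicableError("pattern has no on-axis zero in the focal plane")

    vy, vx = pattern.voxel_size[1], pattern.voxel_size[2]
    # azimuthally averaged radial profile to locate the ring crest
    max_r = min(cy * vy, cx * vx)
    radii = np.arange(1.0, max_r / min(vy, vx)) * min(vy, vx)
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)

    def azimuthal_mean(r_nm: np.ndarray) -> np.ndarray:
        ys = cy + np.outer(r_nm, np.sin(angles)) / vy
        xs = cx + np.outer(r_nm, np.cos(angles)) / vx
        vals = ndimage.map_coordinates(plane, [ys.ravel(), xs.ravel()], order=1)
        return vals.reshape(len(r_nm), n_angles).mean(axis=1)

    prof = azimuthal_mean(radii)
    ring_radius = radii[int(np.argmax(prof))]
    r_fit = np.geomspace(0.2 * ring_radius, 0.6 * ring_radius, 25)
    i_fit = azimuthal_mean(r_fit)
    # regress log I on [1, log rho, rho^2]: the quadratic envelope term
    # absorbs the ring roll-off so the log-slope coefficient estimates the
    # leading power of the near-axis rise
    u = r_fit / ring_radius
    design = np.column_stack([np.ones_like(u), np.log(u), u ** 2])
    coeffs, *_ = np.linalg.lstsq(design, np.log(i_fit), rcond=None)
    return float(coeffs[1])


def tophat_balanced_radius(config: STEDConfig, samples: int = 8001) -> float:
    """Top-hat radius cancelling the on-axis amplitude of the aplanatic
    (apodized) pupil; reduces to 1/sqrt(2) for a uniform pupil."""
    rho = np.linspace(0.0, 1.0, samples)
    sin_max = config.numerical_aperture / config.refractive_index
    apod = np.clip(1.0 - (sin_max * rho) ** 2, 0.0, None) ** 0.25
    weight = apod * rho
    cum = np.cumsum(weight)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(rho[idx])


def aberration_fill(config: STEDConfig, mask: PhaseMask,
                    spherical_coeff: float, pupil_samples: int = 128,
                    extent_nm=(2400.0, 2400.0, 2400.0),
                    voxel_nm=(25.0, 25.0, 25.0)) -> float:
    """Minimum-to-peak intensity ratio of a depletion pattern under primary
    spherical aberration (Zernike n=4, l=0, coefficient in rad RMS).

    Uses the apodized (aplanatic) pupil: on a uniform pupil a pure
    spherical term is an even function of rho^2 about the equal-area
    radius and leaves the top-hat zero mathematically intact, hiding the
    aberration sensitivity the apodized model exposes.  For top-hat masks
    the disk radius is rebalanced to the apodized amplitude so the
    unaberrated fill is ~0.  A non-zero fill degrades STED on/off
    contrast; the z-STED (top-hat) zero is the more sensitive one.
    """
    if mask.kind not in ("tophat", "helical"):
        raise InvalidMaskError("aberration_fill expects a tophat or helical mask")
    radius = mask.tophat_radius
    if mask.kind == "tophat":
        radius = tophat_balanced_radius(config)
    ab_mask = PhaseMask(mask.kind, mask.helicity, radius,
                        list(mask.zernike_terms) + [(4, 0, spherical_coeff)])
    pupil = make_pupil(config, ab_mask, pupil_samples, apodized=True)
    pattern = focal_intensity(pupil, extent_nm, voxel_nm, normalize="peak")
    return pattern.center_value / pattern.values.max()


def sted_depletion_pattern(config: STEDConfig, pupil_samples: int = 128,
                           extent_nm=(2400.0, 2400.0, 2400.0),
                           voxel_nm=(25.0, 25.0, 25.0),
                           xy_helicity: int = 2,
                           ratio: tuple[float, float] | None = None
                           ) -> FocalIntensity:
    """Combined z-STED (top-hat) + helical xy-STED depletion pattern at the
    configured power ratio (default 80/20, helicity-2 lateral mode)."""
    tophat = make_pupil(config, PhaseMask("tophat"), pupil_samples)
    helical = make_pupil(config, PhaseMask("helical", helicity=xy_helicity),
                         pupil_samples)
    i_z = focal_intensity(tophat, extent_nm, voxel_nm, normalize="none")
    i_xy = focal_intensity(helical, extent_nm, voxel_nm, normalize="none")
    return combine_sted_patterns(i_z, i_xy,
                                 ratio or config.power_ratio_z_to_xy)


def confocal_components(config: STEDConfig, pupil_samples: int = 128,
                        extent_nm=(2400.0, 2400.0, 2400.0),
                        voxel_nm=(25.0, 25.0, 25.0),
                        excitation_wavelength: float | None = None
                        ) -> tuple[FocalIntensity, FocalIntensity]:
    """(excitation, pinhole-filtered detection) focal intensities."""
    lam = excitation_wavelength or config.excitation_wavelength
    exc_pupil = make_pupil(config, PhaseMask("flat"), pupil_samples,
                           wavelength=lam)
    exc = focal_intensity(exc_pupil, extent_nm, voxel_nm, normalize="peak")
    det = detection_psf(config, pupil_samples, extent_nm, voxel_nm)
    return exc, det


def calibrate_zeta(config: STEDConfig, target_fwhm_nm: float = 130.0,
                   pupil_samples: int = 128,
                   extent_nm=(2400.0, 2400.0, 2400.0),
                   voxel_nm=(25.0, 25.0, 25.0),
                   zeta_grid: np.ndarray | None = None
                   ) -> tuple[float, EffectivePSF]:
    """Pick zeta so both lateral and axial effective-PSF FWHM approach an
    isotropic resolution target (default 130 nm).

    Returns the best zeta and its effective PSF.  The combined 80/20
    pattern shrinks both axes with a single saturation knob, so a common
    zeta can bring both FWHMs within ~10% of the target.
    """
    exc, det = confocal_components(config, pupil_samples, extent_nm, voxel_nm)
    dep = sted_depletion_pattern(config, pupil_samples, extent_nm, voxel_nm)
    if zeta_grid is None:
        zeta_grid = np.geomspace(0.5, 200.0, 25)

    def cost(zeta: float) -> tuple[float, EffectivePSF]:
        psf = effective_psf(exc, dep, zeta, det)
        dev = max(abs(psf.fwhm_lateral - target_fwhm_nm),
                  abs(psf.fwhm_axial - target_fwhm_nm)) / target_fwhm_nm
        return dev, psf

    best = min(((z,) + cost(z) for z in zeta_grid), key=lambda t: t[1])
    z0 = best[0]
    # local refinement around the best grid point
    for z in np.geomspace(z0 / 1.6, z0 * 1.6, 9):
        trial = (z,) + cost(z)
        if trial[1] < best[1]:
            best = trial
    return best[0], best[2]


def calibrate_isotropic(config: STEDConfig, target_fwhm_nm: float = 130.0,
                        pupil_samples: int = 128,
                        extent_nm=(2400.0, 2400.0, 2400.0),
                        voxel_nm=(25.0, 25.0, 25.0)
                        ) -> tuple[float, tuple[float, float], EffectivePSF]:
    """Calibrate zeta together with the z/xy depletion power split so the
    effective PSF is isotropic at the target resolution.

    The scalar focal-field model rises quartically with lateral offset but
    quadratically with defocus, so with a fixed power split a single zeta
    over-sharpens the axial direction before the lateral one reaches the
    target.  Experimentally the split is likewise an alignment-time knob;
    here both zeta and the split are fitted.  Returns
    ``(zeta, (ratio_z, ratio_xy), effective_psf)``.
    """
    exc, det = confocal_components(config, pupil_samples, extent_nm, voxel_nm)
    tophat = make_pupil(config, PhaseMask("tophat"), pupil_samples)
    helical = make_pupil(config, PhaseMask("helical", helicity=2), pupil_samples)
    i_z = focal_intensity(tophat, extent_nm, voxel_nm, "total")
    i_xy = focal_intensity(helical, extent_nm, voxel_nm, "total")

    def cost(rz: float, zeta: float) -> tuple[float, EffectivePSF]:
        dep = FocalIntensity(rz * i_z.values + (1 - rz) * i_xy.values,
                             i_z.voxel_size)
        psf = effective_psf(exc, dep, zeta, det)
        dev = max(abs(psf.fwhm_lateral - target_fwhm_nm),
                  abs(psf.fwhm_axial - target_fwhm_nm)) / target_fwhm_nm
        return dev, psf

    best = None
    for rz in np.linspace(0.15, 0.85, 8):
        for zeta in np.geomspace(2.0, 400.0, 14):
            trial = (zeta, rz) + cost(rz, zeta)
            if best is None or trial[2] < best[2]:
                best = trial
    # local refinement
    for rz in np.linspace(max(best[1] - 0.08, 0.02),
                          min(best[1] + 0.08, 0.98), 7):
        for zeta in np.geomspace(best[0] / 1.7, best[0] * 1.7, 9):
            trial = (zeta, rz) + cost(rz, zeta)
            if trial[2] < best[2]:
                best = trial
    zeta, rz, _, psf = best
    return zeta, (rz, 1.0 - rz), psf


def fit_resolution_scaling(fwhms: np.ndarray, zetas: np.ndarray) -> float:
    """Fit FWHM(zeta) = FWHM(0) * (1 + c*zeta)^p and return the exponent p.

    In the parabolic-minimum approximation of the depletion zero the
    exponent is -1/2 (square-root dependence of resolution on STED power).
    ``fwhms`` must include the zeta values given; the zero-depletion FWHM
    is taken from ``zetas == 0`` if present, else fitted.
    """
    fwhms = np.asarray(fwhms, dtype=float)
    zetas = np.asarray(zetas, dtype=float)

    def residual(c: float) -> tuple[float, float]:
        x = np.log1p(c * zetas)
        y = np.log(fwhms)
        p, intercept = np.polyfit(x, y, 1)
        res = float(np.sum((y - (p * x + intercept)) ** 2))
        return res, p

    cs = np.geomspace(1e-3, 10.0, 200)
    fits = [residual(c) for c in cs]
    return float(min(fits, key=lambda t: t[0])[1])
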