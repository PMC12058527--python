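"""Physical model layer for Fourier-transform Brillouin microscopy (FTBM).

FTBM measures the Brillouin spectrum of light scattered by thermally excited
acoustic phonons by sending the scattered light through a Michelson
interferometer and recording the detected intensity as a function of the
optical delay ``tau = OPL / c`` (OPL is the optical path-length difference,
i.e. twice the mirror displacement).  Because the Brillouin spectrum is
symmetric about the laser line, the interferogram factorizes into a fast
fringe at the laser frequency times a slowly varying *signed envelope*
``A(tau)`` that carries the full spectral information shifted to baseband.

This module houses:

* the domain types (optics, spectrum, photon budget, sampling schedule),
* the envelope model ``A(tau)`` with optional numerical-aperture broadening,
* the interferometer transfer function in detected photoelectrons,
* the sampling-design algebra (Nyquist sample count, symmetric-spectrum
  sample count, and their ratio -- the undersampling reduction factor), and
* schedule metrics (unambiguous frequency range and spectral resolution).

Conventions (fixed across the package): optical path lengths in nm, coarse
steps in mm, spectral quantities in GHz, intensities in photoelectrons,
``tau`` in seconds.  Schedules are always specified in OPL, never in mirror
displacement.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as C_M_PER_S

__all__ = [
    "InvalidParameterError",
    "ConfigurationError",
    "OpticalConfig",
    "BrillouinComponent",
    "BrillouinSpectrum",
    "PhotonBudget",
    "SamplingSchedule",
    "DesignParams",
    "EnvelopeSpec",
    "BROADENING_MODES",
    "brillouin_shift",
    "na_frequency_sigma_ghz",
    "envelope_model",
    "interferogram_model",
    "required_samples_standard",
    "required_samples_symmetric",
    "reduction_factor",
    "schedule_metrics",
    "opl_nm_to_tau_s",
    "illumination_power_per_pixel_uw",
    "illumination_energy_per_pixel_uj",
    "WATER_SOUND_SPEED_M_S",
    "WATER_REFRACTIVE_INDEX",
    "WATER_INTRINSIC_LINEWIDTH_GHZ",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigurationError(ValueError):
    """A configuration choice (e.g. an unknown mode string) is invalid."""


#: Longitudinal sound speed of water at room temperature, m/s.
WATER_SOUND_SPEED_M_S = 1490.0
#: Refractive index of water at ~780 nm.
WATER_REFRACTIVE_INDEX = 1.33
#: Default intrinsic (aperture-free) Brillouin FWHM of water at 780 nm / 90
#: degrees.  Chosen so that, combined with the Gaussian aperture broadening of
#: an effective NA of 0.47, the apparent linewidth is ~1.5 GHz, the value
#: observed for water in this scattering geometry.
WATER_INTRINSIC_LINEWIDTH_GHZ = 0.75

BROADENING_MODES = ("none", "gaussian-approx", "angle-integral")


def opl_nm_to_tau_s(opl_nm):
    """Convert an optical path length (nm) to an interferometric delay (s)."""
    return np.asarray(opl_nm, dtype=float) * 1e-9 / C_M_PER_S


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConfig:
    """Scattering and collection geometry of the instrument.

    Parameters
    ----------
    wavelength_nm
        Laser (vacuum) wavelength in nm.
    theta_deg
        Nominal scattering angle between illumination and collection axes,
        degrees.  90 for the orthogonal light-sheet geometry.
    na_eff
        Effective numerical aperture of the collection/illumination cone that
        broadens the Brillouin line (dimensionless, < refractive index).
    refractive_index
        Refractive index of the sample medium.
    """

    wavelength_nm: float
    theta_deg: float = 90.0
    na_eff: float = 0.0
    refractive_index: float = 1.33

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise InvalidParameterError("wavelength must be positive")
        if not 0.0 < self.theta_deg <= 180.0:
            raise InvalidParameterError("scattering angle must be in (0, 180]")
        if not 0.0 <= self.na_eff < self.refractive_index:
            raise InvalidParameterError("need 0 <= NA_eff < refractive index")
        if self.refractive_index <= 0:
            raise InvalidParameterError("refractive index must be positive")

    @property
    def omega_laser_rad_s(self) -> float:
        """Laser angular frequency ``2*pi*c/lambda`` in rad/s."""
        return 2.0 * math.pi * C_M_PER_S / (self.wavelength_nm * 1e-9)

    @property
    def laser_frequency_ghz(self) -> float:
        return C_M_PER_S / (self.wavelength_nm * 1e-9) / 1e9


@dataclass(frozen=True)
class BrillouinComponent:
    """One Stokes/anti-Stokes pair: shift, FWHM linewidth, amplitude.

    The amplitude is an expected photoelectron weight; components of a
    spectrum are combined proportionally to it.
    """

    shift_ghz: float
    linewidth_ghz: float
    amplitude: float = 1.0

    def __post_init__(self):
        if self.shift_ghz < 0:
            raise InvalidParameterError("Brillouin shift must be >= 0")
        if self.linewidth_ghz <= 0:
            raise InvalidParameterError("linewidth must be > 0")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class BrillouinSpectrum:
    """A symmetric Brillouin spectrum: a list of component pairs at ±shift."""

    components: tuple[BrillouinComponent, ...]

    def __init__(self, components):
        comps = tuple(
            c if isinstance(c, BrillouinComponent) else BrillouinComponent(*c)
            for c in components
        )
        if not comps:
            raise InvalidParameterError("spectrum needs at least one component")
        object.__setattr__(self, "components", comps)

    @classmethod
    def single(cls, shift_ghz, linewidth_ghz, amplitude=1.0) -> "BrillouinSpectrum":
        return cls([BrillouinComponent(shift_ghz, linewidth_ghz, amplitude)])

    @classmethod
    def water(cls, optics: OpticalConfig,
              sound_speed_m_s: float = WATER_SOUND_SPEED_M_S,
              linewidth_ghz: float = WATER_INTRINSIC_LINEWIDTH_GHZ,
              amplitude: float = 1.0) -> "BrillouinSpectrum":
        """Single-peak water spectrum with the shift set by the geometry."""
        shift = brillouin_shift(optics.refractive_index, sound_speed_m_s,
                                optics.wavelength_nm, optics.theta_deg)
        return cls.single(shift, linewidth_ghz, amplitude)


@dataclass(frozen=True)
class PhotonBudget:
    """Expected photoelectron counts per pixel per exposure at the
    interferometer input (detector gain fixed at 1 e-/count).

    ``n_elastic`` is the residual Rayleigh light *after* suppression by the
    atomic absorption cell; the suppression itself is not modelled.
    ``n_ase`` is broadband amplified spontaneous emission, assumed fully
    incoherent (it never contributes to the fringe).
    """

    n_brillouin: float
    n_elastic: float = 0.0
    n_ase: float = 0.0

    def __post_init__(self):
        for name in ("n_brillouin", "n_elastic", "n_ase"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.n_brillouin + self.n_elastic + self.n_ase


@dataclass(frozen=True)
class SamplingSchedule:
    """Fine/coarse OPL scan plan of the subsampled interferogram.

    ``n_fine`` positions spaced ``fine_step_nm`` sample the laser fringe
    locally at each of ``n_coarse`` positions spaced ``coarse_step_mm``.
    All values are optical path length (OPL = 2 * mirror displacement).
    """

    n_fine: int = 5
    fine_step_nm: float = 195.0
    n_coarse: int = 20
    coarse_step_mm: float = 10.0
    opl_origin_nm: float = 0.0

    def __post_init__(self):
        if self.n_fine < 3:
            raise InvalidParameterError("need at least 3 fine steps")
        if self.n_coarse < 2:
            raise InvalidParameterError("need at least 2 coarse steps")
        if self.fine_step_nm <= 0 or self.coarse_step_mm <= 0:
            raise InvalidParameterError("step sizes must be positive")

    @property
    def n_positions(self) -> int:
        return self.n_fine * self.n_coarse

    @property
    def total_opl_mm(self) -> float:
        return self.n_coarse * self.coarse_step_mm

    def fine_phase_step_rad(self, optics: OpticalConfig) -> float:
        """Laser-fringe phase advance per fine step, ``2*pi*delta/lambda``."""
        return 2.0 * math.pi * self.fine_step_nm / optics.wavelength_nm

    def validate_fine_step(self, optics: OpticalConfig) -> None:
        """The fine phase step must lie strictly inside (0, pi)."""
        step = self.fine_phase_step_rad(optics)
        if not 0.0 < step < math.pi:
            raise InvalidParameterError(
                f"fine phase step {step:.3f} rad must be in (0, pi); "
                f"adjust fine_step_nm for lambda={optics.wavelength_nm} nm")

    def positions_grid_nm(self) -> np.ndarray:
        """Nominal OPL positions, shape ``(n_coarse, n_fine)``, nm."""
        coarse = self.opl_origin_nm + np.arange(self.n_coarse) * self.coarse_step_mm * 1e6
        fine = np.arange(self.n_fine) * self.fine_step_nm
        return coarse[:, None] + fine[None, :]

    def positions_nm(self) -> np.ndarray:
        """Nominal OPL positions flattened in acquisition order, nm."""
        return self.positions_grid_nm().ravel()

    def coarse_opl_nm(self) -> np.ndarray:
        """Envelope abscissae: centre of each fine scan, nm."""
        centre = 0.5 * (self.n_fine - 1) * self.fine_step_nm
        return (self.opl_origin_nm + centre
                + np.arange(self.n_coarse) * self.coarse_step_mm * 1e6)

    def coarse_tau_s(self) -> np.ndarray:
        return opl_nm_to_tau_s(self.coarse_opl_nm())


@dataclass(frozen=True)
class DesignParams:
    """Spectrometer design targets for the sampling-design algebra.

    ``freq_range_ghz`` is the maximum unambiguous frequency (half the
    baseband bandwidth of the symmetric spectrum, ``(omega_max+Omega)/2pi``).
    """

    resolution_ghz: float
    freq_range_ghz: float
    lambda_min_nm: float

    def __post_init__(self):
        if min(self.resolution_ghz, self.freq_range_ghz, self.lambda_min_nm) <= 0:
            raise InvalidParameterError("design parameters must be positive")


@dataclass(frozen=True)
class EnvelopeSpec:
    """Spectrum + optics + broadening mode defining the envelope ``A(tau)``.

    ``broadening_mode``:

    * ``"none"`` -- pure Lorentzian pairs: exponential decay times cosine.
    * ``"gaussian-approx"`` -- multiplies each component by a Gaussian decay
      whose width is derived from the spread of scattering angles collected
      within the effective NA (Gaussian approximation of the aperture
      broadening).
    * ``"angle-integral"`` -- numerically averages the component fringe over
      the aperture's scattering-angle distribution (two circular apertures).
    """

    spectrum: BrillouinSpectrum
    optics: OpticalConfig
    broadening_mode: str = "none"

    def __post_init__(self):
        if self.broadening_mode not in BROADENING_MODES:
            raise ConfigurationError(
                f"unknown broadening_mode {self.broadening_mode!r}; "
                f"choose from {BROADENING_MODES}")


# ---------------------------------------------------------------------------
# Aperture (NA) broadening
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=32)
def _aperture_ratio_quadrature(na_eff: float, n_medium: float, theta_deg: float,
                               n_r: int = 6, n_phi: int = 8):
    """Deterministic quadrature of ``sin(theta'/2)/sin(theta/2)`` over the
    scattering angles theta' subtended by two uniformly filled circular
    apertures of half-angle ``asin(NA/n)`` around the nominal axes.

    Returns (ratios, weights) with weights summing to 1.
    """
    alpha = math.asin(na_eff / n_medium)
    theta = math.radians(theta_deg)
    # Pupil points: uniform over the disc of radius sin(alpha) in sine space.
    r = np.sqrt((np.arange(n_r) + 0.5) / n_r) * math.sin(alpha)
    phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
    sin_rho = np.repeat(r, n_phi)
    cos_rho = np.sqrt(1.0 - sin_rho**2)
    cphi = np.tile(np.cos(phi), n_r)
    sphi = np.tile(np.sin(phi), n_r)
    # Directions around +z (illumination).
    u = np.stack([sin_rho * cphi, sin_rho * sphi, cos_rho], axis=1)
    # Same cone rotated by theta about y (collection axis).
    ct, st = math.cos(theta), math.sin(theta)
    w = np.stack([sin_rho * cphi * ct + cos_rho * st,
                  sin_rho * sphi,
                  -sin_rho * cphi * st + cos_rho * ct], axis=1)
    cos_tp = np.clip(u @ w.T, -1.0, 1.0).ravel()
    ratios = np.sqrt(0.5 * (1.0 - cos_tp)) / math.sin(theta / 2.0)
    weights = np.full(ratios.shape, 1.0 / ratios.size)
    return ratios, weights


def na_frequency_sigma_ghz(optics: OpticalConfig, shift_ghz: float) -> float:
    """Standard deviation (GHz) of the apparent Brillouin shift caused by the
    spread of scattering angles within the effective NA.

    The shift scales as ``sin(theta'/2)``, so the broadening is the weighted
    std of that factor over the aperture distribution, times the nominal
    shift.  Zero NA gives zero broadening.
    """
    if optics.na_eff == 0.0:
        return 0.0
    ratios, wts = _aperture_ratio_quadrature(
        optics.na_eff, optics.refractive_index, optics.theta_deg)
    mean = float(np.sum(wts * ratios))
    var = float(np.sum(wts * (ratios - mean) ** 2))
    return shift_ghz * math.sqrt(var)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def brillouin_shift(n: float, v: float, wavelength_nm: float,
                    theta_deg: float = 90.0) -> float:
    """Brillouin shift ``2 n v sin(theta/2) / lambda`` in GHz.

    Parameters: refractive index ``n``, sound speed ``v`` (m/s), vacuum
    wavelength (nm), scattering angle (degrees).  Used to parameterize
    realistic synthetic spectra.
    """
    if n <= 0 or v <= 0 or wavelength_nm <= 0:
        raise InvalidParameterError("n, v and wavelength must be positive")
    if not 0.0 < theta_deg <= 180.0:
        raise InvalidParameterError("scattering angle must be in (0, 180]")
    return 2.0 * n * v * math.sin(math.radians(theta_deg) / 2.0) / (
        wavelength_nm * 1e-9) / 1e9


def _component_envelope(tau_s: np.ndarray, comp: BrillouinComponent,
                        spec: EnvelopeSpec) -> np.ndarray:
    nu = comp.shift_ghz * 1e9
    gamma = comp.linewidth_ghz * 1e9
    decay = np.exp(-math.pi * gamma * tau_s)
    if spec.broadening_mode == "none" or spec.optics.na_eff == 0.0:
        return decay * np.cos(2.0 * math.pi * nu * tau_s)
    if spec.broadening_mode == "gaussian-approx":
        sigma = na_frequency_sigma_ghz(spec.optics, comp.shift_ghz) * 1e9
        return (decay * np.cos(2.0 * math.pi * nu * tau_s)
                * np.exp(-2.0 * math.pi**2 * sigma**2 * tau_s**2))
    # angle-integral
    ratios, wts = _aperture_ratio_quadrature(
        spec.optics.na_eff, spec.optics.refractive_index, spec.optics.theta_deg)
    # Average the fringe over the aperture's shift distribution.
    phases = 2.0 * math.pi * nu * np.multiply.outer(tau_s, ratios)
    return decay * (np.cos(phases) @ wts)


def envelope_model(tau_s, spec: EnvelopeSpec) -> np.ndarray:
    """Signed interferogram envelope ``A(tau)``, normalized so ``A(0) = 1``.

    For a single Lorentzian component pair without aperture broadening this is
    ``exp(-pi*linewidth*tau) * cos(2*pi*shift*tau)``; multi-component spectra
    return the amplitude-weighted sum (which equals 1 at tau = 0 because every
    component does).  The envelope of a symmetric spectrum is even, so
    negative delays (reachable through stage jitter around the origin) are
    evaluated at ``|tau|``.
    """
    tau = np.asarray(tau_s, dtype=float)
    scalar = tau.ndim == 0
    tau = np.abs(np.atleast_1d(tau))
    weights = np.array([c.amplitude for c in spec.spectrum.components])
    if weights.sum() == 0:
        out = np.zeros_like(tau)
    else:
        acc = np.zeros_like(tau)
        for comp, w in zip(spec.spectrum.components, weights):
            if w > 0:
                acc += w * _component_envelope(tau, comp, spec)
        out = acc / weights.sum()
    return float(out[0]) if scalar else out


def interferogram_model(tau_s, budget: PhotonBudget, spec: EnvelopeSpec,
                        optics: OpticalConfig | None = None) -> np.ndarray:
    """Michelson transfer function in expected detected photoelectrons:

    ``N = (N_ASE + N_elas + N_Br + (N_elas + N_Br*A(tau)) * cos(w_L*tau)) / 2``

    ASE is incoherent and never enters the fringe term; the elastic line is
    spectrally narrow so its envelope is 1 over the scanned delays.
    """
    optics = optics or spec.optics
    tau = np.asarray(tau_s, dtype=float)
    a = envelope_model(tau, spec)
    fringe = np.cos(optics.omega_laser_rad_s * tau)
    n = 0.5 * (budget.n_ase + budget.n_elastic + budget.n_brillouin
               + (budget.n_elastic + budget.n_brillouin * a) * fringe)
    if np.any(np.asarray(n) < -1e-9 * max(budget.total, 1.0)):
        raise InvalidParameterError("negative expected count: invalid envelope")
    return n


def required_samples_standard(design: DesignParams) -> float:
    """Nyquist-Shannon sample count for the full interferogram,
    ``2c / (resolution * lambda_min)``."""
    return 2.0 * C_M_PER_S / (design.resolution_ghz * 1e9
                              * design.lambda_min_nm * 1e-9)


def required_samples_symmetric(n_fine: int, design: DesignParams) -> float:
    """Sample count when only the envelope must satisfy Nyquist:
    ``n_fine * 2 * freq_range / resolution``."""
    if n_fine < 3:
        raise InvalidParameterError("need n_fine >= 3")
    return n_fine * 2.0 * design.freq_range_ghz / design.resolution_ghz


def reduction_factor(n_fine: int, design: DesignParams,
                     optics: OpticalConfig | None = None) -> float:
    """Undersampling gain: ratio of the laser optical frequency to
    ``n_fine`` times the reconstructed frequency range.

    Exactly equals ``required_samples_standard / required_samples_symmetric``.
    """
    if n_fine < 3:
        raise InvalidParameterError("need n_fine >= 3")
    lam_nm = optics.wavelength_nm if optics is not None else design.lambda_min_nm
    nu_laser = C_M_PER_S / (lam_nm * 1e-9)
    return nu_laser / (n_fine * design.freq_range_ghz * 1e9)


def schedule_metrics(schedule: SamplingSchedule) -> tuple[float, float]:
    """(unambiguous frequency range, spectral resolution) in GHz.

    The coarse step sets the envelope Nyquist range ``c / (2*coarse_step)``;
    the total scanned OPL sets the resolution ``c / (n_coarse*coarse_step)``.
    """
    step_m = schedule.coarse_step_mm * 1e-3
    nu_max = C_M_PER_S / (2.0 * step_m) / 1e9
    resolution = C_M_PER_S / (schedule.n_coarse * step_m) / 1e9
    return nu_max, resolution


# ---------------------------------------------------------------------------
# Illumination dosage bookkeeping
# ---------------------------------------------------------------------------


def illumination_power_per_pixel_uw(total_power_mw: float, n_pixels: int) -> float:
    """Full-field power density: total power (mW) split over ``n_pixels``, in uW."""
    if total_power_mw < 0 or n_pixels <= 0:
        raise InvalidParameterError("power must be >= 0 and n_pixels > 0")
    return total_power_mw * 1e3 / n_pixels


def illumination_energy_per_pixel_uj(power_per_pixel_uw: float,
                                     n_positions: int,
                                     exposure_s: float) -> float:
    """Energy per pixel per full spectral acquisition, in uJ:
    power per pixel times the number of stage positions times exposure."""
    if power_per_pixel_uw < 0 or n_positions <= 0 or exposure_s <= 0:
        raise InvalidParameterError("invalid dosage inputs")
    return power_per_pixel_uw * n_positions * exposure_s
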