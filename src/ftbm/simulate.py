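"""Forward simulation: noisy sampled interferograms, reference channel and
synthetic phantoms.

Noise injection follows a fixed order at every scheduled position:
stage jitter -> multiplicative intensity noise -> Poisson shot noise ->
additive Gaussian read noise.  Identical (configuration, seed) pairs give
bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core import (
    BrillouinComponent,
    BrillouinSpectrum,
    EnvelopeSpec,
    InvalidParameterError,
    OpticalConfig,
    PhotonBudget,
    SamplingSchedule,
    envelope_model,
    interferogram_model,
    opl_nm_to_tau_s,
)

__all__ = [
    "NoiseModel",
    "SampledInterferogram",
    "PhantomGeometry",
    "SyntheticStack",
    "sample_interferogram",
    "make_reference_channel",
    "simulate_measurement",
    "make_phantom",
    "inclusion_fraction_map",
]

logger = logging.getLogger(__name__)

DEFAULT_AOM_OFFSET_MHZ = 250.0


@dataclass(frozen=True)
class NoiseModel:
    """Noise configuration for the simulator.

    read_noise_sd: camera read noise, photoelectrons (Gaussian, additive).
    stage_jitter_sd_nm: stage position error, nm OPL (Gaussian, one draw per
        scheduled position, perturbing fine and coarse moves alike).
    intensity_noise_sd: relative illumination fluctuation (Gaussian,
        multiplicative, drawn independently per sampled position, applied
        before the shot noise).
    shot_noise: Poisson photon statistics on/off.
    seed: RNG seed; the reproducibility contract is bit-identical output for
        identical (config, seed).
    """

    read_noise_sd: float = 0.0
    stage_jitter_sd_nm: float = 0.0
    intensity_noise_sd: float = 0.0
    shot_noise: bool = True
    seed: int | None = None

    def __post_init__(self):
        if min(self.read_noise_sd, self.stage_jitter_sd_nm,
               self.intensity_noise_sd) < 0:
            raise InvalidParameterError("noise s.d. values must be >= 0")

    @property
    def noiseless(self) -> bool:
        return (self.read_noise_sd == 0 and self.stage_jitter_sd_nm == 0
                and self.intensity_noise_sd == 0 and not self.shot_noise)


@dataclass
class SampledInterferogram:
    """Counts at each scheduled position (one pixel).

    ``positions_nm`` are the *nominal* OPL positions; the actual (jittered)
    positions are kept for diagnostics but are not available to the
    reconstruction (as in a real instrument).
    """

    positions_nm: np.ndarray
    counts: np.ndarray
    schedule: SamplingSchedule
    actual_positions_nm: np.ndarray | None = None
    pixel: tuple[int, int] | None = None

    def counts_grid(self) -> np.ndarray:
        """Counts reshaped to (n_coarse, n_fine)."""
        return self.counts.reshape(self.schedule.n_coarse, self.schedule.n_fine)

    def positions_grid_nm(self) -> np.ndarray:
        return self.positions_nm.reshape(self.schedule.n_coarse,
                                         self.schedule.n_fine)


def _resolve_rng(noise: NoiseModel | None, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = noise.seed if noise is not None else None
    return np.random.default_rng(seed)


def _jitter_positions(schedule: SamplingSchedule, noise: NoiseModel,
                      rng: np.random.Generator) -> np.ndarray:
    nominal = schedule.positions_nm()
    if noise.stage_jitter_sd_nm > 0:
        return nominal + rng.normal(0.0, noise.stage_jitter_sd_nm, nominal.shape)
    return nominal.copy()


def _apply_intensity_shot_read(expected: np.ndarray, noise: NoiseModel,
                               rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(expected, dtype=float)
    if noise.intensity_noise_sd > 0:
        out = out * (1.0 + rng.normal(0.0, noise.intensity_noise_sd, out.shape))
        n_neg = int(np.sum(out < 0))
        if n_neg:
            logger.warning("intensity noise drove %d expectations below zero; "
                           "clamped to 0", n_neg)
            out = np.clip(out, 0.0, None)
    if noise.shot_noise:
        out = rng.poisson(out).astype(float)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, out.shape)
    return out


def sample_interferogram(spectrum: BrillouinSpectrum, budget: PhotonBudget,
                         schedule: SamplingSchedule, noise: NoiseModel,
                         optics: OpticalConfig, *,
                         broadening_mode: str = "gaussian-approx",
                         rng: np.random.Generator | None = None,
                         actual_positions_nm: np.ndarray | None = None,
                         ) -> SampledInterferogram:
    """Simulate one noisy sampled interferogram for a single pixel.

    The expectation at each (jittered) position comes from the interferometer
    transfer function; noise is then applied in the fixed order intensity ->
    shot -> read.  Pass ``actual_positions_nm`` to reuse stage positions
    across channels acquired simultaneously (signal + reference share the
    stage).
    """
    schedule.validate_fine_step(optics)
    rng = _resolve_rng(noise, rng)
    nominal = schedule.positions_nm()
    if actual_positions_nm is None:
        actual = _jitter_positions(schedule, noise, rng)
    else:
        actual = np.asarray(actual_positions_nm, dtype=float)
        if actual.shape != nominal.shape:
            raise InvalidParameterError("actual positions shape mismatch")
    spec = EnvelopeSpec(spectrum, optics, broadening_mode)
    expected = interferogram_model(opl_nm_to_tau_s(actual), budget, spec, optics)
    counts = _apply_intensity_shot_read(expected, noise, rng)
    return SampledInterferogram(nominal, counts, schedule, actual)


def make_reference_channel(schedule: SamplingSchedule, optics: OpticalConfig,
                           level: float,
                           aom_offset_mhz: float = DEFAULT_AOM_OFFSET_MHZ, *,
                           noise: NoiseModel | None = None,
                           rng: np.random.Generator | None = None,
                           actual_positions_nm: np.ndarray | None = None,
                           ) -> SampledInterferogram:
    """Laser-line reference interferogram used for phase/sign assignment.

    The reference beam is frequency-shifted by the acousto-optic modulator,
    so its fringe runs at ``omega_L + 2*pi*aom_offset``; its envelope is
    constant (no Brillouin decay):
    ``level * (1 + cos((omega_L + 2*pi*f_aom) * tau)) / 2``.
    """
    if level <= 0:
        raise InvalidParameterError("reference level must be > 0")
    rng = _resolve_rng(noise, rng)
    nominal = schedule.positions_nm()
    if actual_positions_nm is None:
        actual = (_jitter_positions(schedule, noise, rng)
                  if noise is not None else nominal.copy())
    else:
        actual = np.asarray(actual_positions_nm, dtype=float)
    tau = opl_nm_to_tau_s(actual)
    omega = optics.omega_laser_rad_s + 2.0 * math.pi * aom_offset_mhz * 1e6
    expected = level * (1.0 + np.cos(omega * tau)) / 2.0
    counts = (expected if noise is None
              else _apply_intensity_shot_read(expected, noise, rng))
    return SampledInterferogram(nominal, counts, schedule, actual)


def simulate_measurement(spectrum: BrillouinSpectrum, budget: PhotonBudget,
                         schedule: SamplingSchedule, noise: NoiseModel,
                         optics: OpticalConfig, *,
                         broadening_mode: str = "gaussian-approx",
                         reference_level: float | None = None,
                         aom_offset_mhz: float = DEFAULT_AOM_OFFSET_MHZ,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[SampledInterferogram, SampledInterferogram | None]:
    """Simulate a signal interferogram and, optionally, a reference channel
    acquired simultaneously (shared stage positions, independent photon
    noise).  Draw order is fixed for reproducibility: jitter, signal noise,
    reference noise."""
    rng = _resolve_rng(noise, rng)
    actual = _jitter_positions(schedule, noise, rng)
    signal = sample_interferogram(spectrum, budget, schedule, noise, optics,
                                  broadening_mode=broadening_mode, rng=rng,
                                  actual_positions_nm=actual)
    reference = None
    if reference_level is not None:
        reference = make_reference_channel(schedule, optics, reference_level,
                                           aom_offset_mhz, noise=noise, rng=rng,
                                           actual_positions_nm=actual)
    return signal, reference


# ---------------------------------------------------------------------------
# Synthetic phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomGeometry:
    """Bead-in-gel phantom layout: spherical inclusions (default oil,
    2.15 GHz) in a homogeneous background (default agar, 3.53 GHz), with
    sharp or blurred edges.

    Intrinsic linewidth defaults (0.8 GHz oil, 1.0 GHz agar) are plausible
    configuration knobs, not measured values.
    """

    shape: tuple[int, int] = (32, 32)          # (ny, nx) pixels
    pixel_um: float = 0.5
    beads_um: tuple[tuple[float, float, float], ...] = ()  # (cx, cy, radius)
    background: BrillouinComponent = field(
        default_factory=lambda: BrillouinComponent(3.53, 1.0))
    inclusion: BrillouinComponent = field(
        default_factory=lambda: BrillouinComponent(2.15, 0.8))
    edge_blur_um: float = 0.0
    budget: PhotonBudget = field(default_factory=lambda: PhotonBudget(1000.0))

    def __post_init__(self):
        if self.edge_blur_um < 0:
            raise InvalidParameterError("edge blur must be >= 0")
        ny, nx = self.shape
        for cx, cy, r in self.beads_um:
            if r <= 0:
                raise InvalidParameterError("bead radius must be positive")
            if not (0 <= cx <= nx * self.pixel_um and 0 <= cy <= ny * self.pixel_um):
                raise InvalidParameterError("bead centre outside the image")


def inclusion_fraction_map(geometry: PhantomGeometry) -> np.ndarray:
    """Per-pixel amplitude fraction of the inclusion component.

    The fraction follows an erf profile of the signed distance to the nearest
    bead boundary (union of beads; inclusion wins on overlap), i.e. the
    normal CDF with the stated edge-blur s.d.; a zero blur gives a hard step.
    """
    ny, nx = geometry.shape
    x = (np.arange(nx) + 0.5) * geometry.pixel_um
    y = (np.arange(ny) + 0.5) * geometry.pixel_um
    xx, yy = np.meshgrid(x, y)
    if not geometry.beads_um:
        return np.zeros(geometry.shape)
    # Signed distance into the inclusion: positive inside a bead.
    signed = np.full(geometry.shape, -np.inf)
    for cx, cy, r in geometry.beads_um:
        d = r - np.hypot(xx - cx, yy - cy)
        signed = np.maximum(signed, d)
    if geometry.edge_blur_um == 0:
        return (signed > 0).astype(float)
    return 0.5 * (1.0 + erf(signed / (geometry.edge_blur_um * math.sqrt(2.0))))


@dataclass
class SyntheticStack:
    """Full-field frame stack (one 2D frame per scheduled position) plus the
    pixel-aligned ground truth used to generate it."""

    frames: np.ndarray                 # (n_positions, ny, nx)
    positions_nm: np.ndarray           # nominal, (n_positions,)
    schedule: SamplingSchedule
    optics: OpticalConfig
    noise: NoiseModel
    geometry: PhantomGeometry
    truth: dict[str, np.ndarray]       # shift/linewidth/amplitude/fraction maps
    broadening_mode: str = "gaussian-approx"
    reference_region: tuple[int, int, int, int] | None = None  # y0,y1,x0,x1
    reference_level: float | None = None
    seed: int | None = None


def make_phantom(geometry: PhantomGeometry, schedule: SamplingSchedule,
                 noise: NoiseModel, optics: OpticalConfig, *,
                 broadening_mode: str = "gaussian-approx",
                 reference_region: tuple[int, int, int, int] | None = None,
                 reference_level: float | None = None,
                 aom_offset_mhz: float = DEFAULT_AOM_OFFSET_MHZ,
                 rng: np.random.Generator | None = None) -> SyntheticStack:
    """Render a synthetic full-field stack of the phantom.

    Each pixel carries a two-component spectrum mixing the inclusion and
    background in proportion to the erf edge profile; every frame is the
    interferometer output at one scheduled position with the configured
    noise.  Stage jitter is common to all pixels of a frame (one stage);
    intensity, shot and read noise are per pixel.  An optional rectangular
    ``reference_region`` overwrites pixels with the laser reference channel,
    mirroring the D-shaped-mirror injection at the edge of the field.
    """
    schedule.validate_fine_step(optics)
    rng = _resolve_rng(noise, rng)
    frac = inclusion_fraction_map(geometry).ravel()
    ny, nx = geometry.shape
    n_px = ny * nx
    actual = _jitter_positions(schedule, noise, rng)
    tau = opl_nm_to_tau_s(actual)

    spec_incl = EnvelopeSpec(BrillouinSpectrum([geometry.inclusion]), optics,
                             broadening_mode)
    spec_bg = EnvelopeSpec(BrillouinSpectrum([geometry.background]), optics,
                           broadening_mode)
    a_incl = envelope_model(tau, spec_incl)          # (K,)
    a_bg = envelope_model(tau, spec_bg)
    fringe = np.cos(optics.omega_laser_rad_s * tau)
    b = geometry.budget
    # Expected counts, shape (K, n_px): Eq.-4 mixture linear in the fraction.
    mix = np.outer(a_incl, frac) + np.outer(a_bg, 1.0 - frac)
    expected = 0.5 * (b.total
                      + (b.n_elastic + b.n_brillouin * mix)
                      * fringe[:, None])
    if reference_region is not None:
        if reference_level is None or reference_level <= 0:
            raise InvalidParameterError(
                "reference_region requires a positive reference_level")
        y0, y1, x0, x1 = reference_region
        mask = np.zeros((ny, nx), dtype=bool)
        mask[y0:y1, x0:x1] = True
        omega = optics.omega_laser_rad_s + 2.0 * math.pi * aom_offset_mhz * 1e6
        ref_expected = reference_level * (1.0 + np.cos(omega * tau)) / 2.0
        expected[:, mask.ravel()] = ref_expected[:, None]
    counts = _apply_intensity_shot_read(expected, noise, rng)
    frames = counts.reshape(schedule.n_positions, ny, nx)

    frac2 = frac.reshape(ny, nx)
    truth = {
        "fraction": frac2,
        # Amplitude-weighted mixture values; exact for pure pixels.
        "shift_ghz": (frac2 * geometry.inclusion.shift_ghz
                      + (1 - frac2) * geometry.background.shift_ghz),
        "linewidth_ghz": (frac2 * geometry.inclusion.linewidth_ghz
                          + (1 - frac2) * geometry.background.linewidth_ghz),
        "amplitude": np.full((ny, nx), b.n_brillouin / 2.0),
    }
    return SyntheticStack(frames=frames, positions_nm=schedule.positions_nm(),
                          schedule=schedule, optics=optics, noise=noise,
                          geometry=geometry, truth=truth,
                          broadening_mode=broadening_mode,
                          reference_region=reference_region,
                          reference_level=reference_level, seed=noise.seed)
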