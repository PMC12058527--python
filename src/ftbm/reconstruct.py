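"""Inverse path of FTBM: local cosine fits, sign assignment, signed-envelope
assembly, zero-centred spectrum and shift/width estimation.

The pipeline mirrors the acquisition structure: at each coarse delay the
laser fringe is sampled with a few fine steps and fitted with a
fixed-frequency cosine, giving a local amplitude, phase and offset.  The
phase determines the sign of the envelope sample; the signed envelope is the
compressed representation of the symmetric spectrum, whose cosine transform
is the spectrum centred at zero.  Shift and linewidth are estimated either
by a nonlinear time-domain fit of the envelope model or by a Gaussian fit to
the frequency-domain peak.

A small statsmodels-flavoured facade (`InterferogramModel` ->
`ReconstructionResult` with `summary()`) wraps the per-interferogram
pipeline for interactive use; the functional operations below are the
implementation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .core import (
    BrillouinSpectrum,
    ConfigurationError,
    EnvelopeSpec,
    InvalidParameterError,
    OpticalConfig,
    SamplingSchedule,
    envelope_model,
    opl_nm_to_tau_s,
)
from .simulate import DEFAULT_AOM_OFFSET_MHZ, SampledInterferogram

__all__ = [
    "FitError",
    "LocalFit",
    "EnvelopeSamples",
    "Spectrum0",
    "ReconstructionResult",
    "local_cosine_fit",
    "signed_envelope",
    "envelope_spectrum",
    "fit_envelope_time_domain",
    "fit_spectrum_gaussian",
    "reconstruct_stack",
    "InterferogramModel",
]


class FitError(RuntimeError):
    """A fit could not be performed (e.g. rank-deficient design)."""


def _wrap(phase):
    """Wrap phases to (-pi, pi]."""
    return -np.mod(-np.asarray(phase) + math.pi, 2.0 * math.pi) + math.pi


# ---------------------------------------------------------------------------
# Local cosine fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalFit:
    """Result of one fixed-frequency cosine fit at a coarse position."""

    offset: float
    amplitude: float            # >= 0 before signing
    phase: float                # rad, wrapped to (-pi, pi]
    amplitude_sd: float
    residual_norm: float
    n_points: int
    coarse_index: int = 0
    reliable: bool = True       # amplitude above 3x its uncertainty


def _design_matrix(positions_nm: np.ndarray, wavelength_nm: float) -> np.ndarray:
    x = 2.0 * math.pi * positions_nm / wavelength_nm
    return np.column_stack([np.ones_like(x), np.cos(x), np.sin(x)])


def _beta_to_polar(beta, cov=None):
    """Convert linear coefficients (c0, p, q) of offset + p cos + q sin to
    (offset, amplitude, phase) with counts = offset + a*cos(x + phi)."""
    c0, p, q = beta
    a = math.hypot(p, q)
    phi = math.atan2(-q, p)
    if cov is None:
        return c0, a, phi, 0.0
    if a > 0:
        g = np.array([p / a, q / a])
        var_a = float(g @ cov[1:, 1:] @ g)
    else:
        var_a = float(0.5 * (cov[1, 1] + cov[2, 2]))
    return c0, a, phi, math.sqrt(max(var_a, 0.0))


def local_cosine_fit(counts, positions_nm, optics: OpticalConfig,
                     coarse_index: int = 0) -> LocalFit:
    """Least-squares fit of ``counts = offset + a*cos(2*pi*OPL/lambda + phi)``
    with the fringe frequency fixed by the laser wavelength.

    Solved in linearized form (offset, a*cos(phi), -a*sin(phi)); exact for
    noiseless cosine data.  The amplitude uncertainty is propagated from the
    residual scatter; fits whose amplitude falls below 3x that uncertainty
    are flagged unreliable (their phase carries no sign information).
    """
    counts = np.asarray(counts, dtype=float)
    positions_nm = np.asarray(positions_nm, dtype=float)
    if counts.shape != positions_nm.shape or counts.ndim != 1:
        raise InvalidParameterError("counts and positions must be equal-length 1-D")
    if counts.size < 3:
        raise FitError("need at least 3 samples for offset/amplitude/phase")
    X = _design_matrix(positions_nm, optics.wavelength_nm)
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("rank-deficient design: degenerate fine positions")
    beta, _, _, _ = np.linalg.lstsq(X, counts, rcond=None)
    resid = counts - X @ beta
    dof = counts.size - 3
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    c0, a, phi, a_sd = _beta_to_polar(beta, cov)
    reliable = a > max(3.0 * a_sd, 1e-12 * max(abs(c0), 1.0))
    return LocalFit(offset=c0, amplitude=a, phase=float(_wrap(phi)),
                    amplitude_sd=a_sd, residual_norm=float(np.linalg.norm(resid)),
                    n_points=counts.size, coarse_index=coarse_index,
                    reliable=bool(reliable))


def _local_fits_block(counts: np.ndarray, positions_grid_nm: np.ndarray,
                      wavelength_nm: float):
    """Vectorized local fits.

    counts: (n_coarse, n_fine, n_pixels); positions_grid_nm: (n_coarse, n_fine).
    Returns arrays (offset, amplitude, phase, amplitude_sd), each
    (n_coarse, n_pixels).
    """
    n_s, n_l, n_px = counts.shape
    offs = np.empty((n_s, n_px))
    amps = np.empty((n_s, n_px))
    phis = np.empty((n_s, n_px))
    sds = np.empty((n_s, n_px))
    dof = max(n_l - 3, 0)
    for n in range(n_s):
        X = _design_matrix(positions_grid_nm[n], wavelength_nm)
        pinv = np.linalg.pinv(X)
        beta = pinv @ counts[n]                       # (3, n_px)
        resid = counts[n] - X @ beta
        s2 = (resid**2).sum(axis=0) / dof if dof > 0 else np.zeros(n_px)
        xtx_inv = np.linalg.inv(X.T @ X)
        p, q = beta[1], beta[2]
        a = np.hypot(p, q)
        with np.errstate(invalid="ignore", divide="ignore"):
            gx = np.where(a > 0, p / np.where(a > 0, a, 1.0), 0.0)
            gy = np.where(a > 0, q / np.where(a > 0, a, 1.0), 0.0)
        var_a = s2 * (gx**2 * xtx_inv[1, 1] + 2 * gx * gy * xtx_inv[1, 2]
                      + gy**2 * xtx_inv[2, 2])
        var_a = np.where(a > 0, var_a,
                         s2 * 0.5 * (xtx_inv[1, 1] + xtx_inv[2, 2]))
        offs[n], amps[n] = beta[0], a
        phis[n] = _wrap(np.arctan2(-q, p))
        sds[n] = np.sqrt(np.clip(var_a, 0.0, None))
    return offs, amps, phis, sds


# ---------------------------------------------------------------------------
# Sign assignment and envelope assembly
# ---------------------------------------------------------------------------


@dataclass
class EnvelopeSamples:
    """Signed envelope samples on the coarse delay grid."""

    tau_s: np.ndarray
    amplitude: np.ndarray          # signed, photoelectrons
    amplitude_sd: np.ndarray
    signs: np.ndarray
    reliable: np.ndarray           # sign taken from the point's own phase

    def __post_init__(self):
        if np.any(np.diff(self.tau_s) <= 0):
            raise InvalidParameterError("tau grid must be strictly increasing")

    def normalized(self) -> np.ndarray:
        """Amplitudes scaled to the smallest-delay sample (the anchor)."""
        anchor = self.amplitude[0]
        if anchor == 0:
            raise InvalidParameterError("cannot normalize: zero anchor amplitude")
        return self.amplitude / anchor


def _phase_projection(phases, reliable, ref_phases=None):
    """Vectorized sign assignment; phases (n_s,) or (n_s, n_px).

    Returns ``(cos_psi, signs)`` where ``psi`` is the local phase relative
    to the fringe phase origin.  With a reference, the origin is the
    corrected reference phase per coarse step.  Without one, phases are
    compared against the first reliable sample, assuming a positive envelope
    there (the envelope is positive at small delay by construction).

    ``signs`` is sign(cos psi) with unreliable samples inheriting the sign
    of the nearest reliable lower-delay neighbour -- phase is meaningless at
    zero crossings, and sign continuity is the physical prior.  ``cos_psi``
    itself is used for the projection envelope estimator (see
    :func:`signed_envelope`).
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float).T).T
    reliable = np.atleast_2d(np.asarray(reliable, dtype=bool).T).T
    n_s, n_px = phases.shape
    if ref_phases is not None:
        ref = np.asarray(ref_phases, dtype=float)
        ref = ref[:, None] if ref.ndim == 1 else ref
        psi = _wrap(phases - ref)
    else:
        # Per-pixel anchor: phase of the first reliable sample.
        anchor_idx = np.argmax(reliable, axis=0)      # 0 if none reliable
        anchor = phases[anchor_idx, np.arange(n_px)]
        psi = _wrap(phases - anchor[None, :])
    cos_psi = np.cos(psi)
    signs = np.where(cos_psi >= 0.0, 1.0, -1.0)
    # Propagate the sign of the last reliable lower-delay neighbour.
    carried = signs[0].copy()
    for n in range(n_s):
        take_own = reliable[n]
        signs[n] = np.where(take_own, signs[n], carried)
        carried = np.where(take_own, signs[n], carried)
    return cos_psi, signs


def signed_envelope(fits, tau_s, reference=None,
                    aom_offset_mhz: float = DEFAULT_AOM_OFFSET_MHZ,
                    ) -> EnvelopeSamples:
    """Assemble the signed envelope from local fits.

    ``reference`` is the matching sequence of local fits of the laser
    reference channel; its phase, corrected for the deterministic AOM phase
    ramp ``2*pi*f_aom*tau``, defines the fringe phase origin.  Without a
    reference the sign is taken from phase continuity relative to the first
    reliable sample (degraded mode, correct when the envelope is positive at
    the smallest delay).

    The signed amplitude is the *projection* of the local fit onto the
    fringe-phase origin, ``a * cos(psi)``: identical to ``sign * a`` for
    noiseless data (psi is exactly 0 or pi) but linear in the fitted
    quadratures and therefore free of the magnitude folding bias near
    envelope zero crossings.
    """
    fits = list(fits)
    tau = np.asarray(tau_s, dtype=float)
    if len(fits) != tau.size:
        raise InvalidParameterError("need one local fit per coarse delay")
    amps = np.array([f.amplitude for f in fits])
    phases = np.array([f.phase for f in fits])
    sds = np.array([f.amplitude_sd for f in fits])
    reliable = np.array([f.reliable for f in fits], dtype=bool)
    ref_phases = None
    if reference is not None:
        reference = list(reference)
        if len(reference) != len(fits):
            raise InvalidParameterError("reference fits misaligned with signal")
        # Remove the AOM-offset phase ramp accumulated over the delay.
        ref_phases = (np.array([f.phase for f in reference])
                      - 2.0 * math.pi * aom_offset_mhz * 1e6 * tau)
    cos_psi, signs = _phase_projection(phases, reliable, ref_phases)
    return EnvelopeSamples(tau_s=tau, amplitude=cos_psi[:, 0] * amps,
                           amplitude_sd=sds, signs=signs[:, 0],
                           reliable=reliable)


# ---------------------------------------------------------------------------
# Zero-centred spectrum
# ---------------------------------------------------------------------------


@dataclass
class Spectrum0:
    """Zero-centred (baseband) half-spectrum of the symmetric input."""

    frequency_ghz: np.ndarray
    power: np.ndarray              # arbitrary units, proportional to counts
    resolution_ghz: float
    padding: int

    @property
    def nu_max_ghz(self) -> float:
        return float(self.frequency_ghz[-1])


def _cosine_transform(amplitude: np.ndarray, dtau: float, padding: int,
                      window: str | None):
    """Real-even transform along axis 0 with zero padding.

    For samples a_n at tau = n*dtau the transform is
    ``a_0 + 2*sum_n a_n cos(2*pi*nu*n*dtau)``, evaluated by FFT of the even
    extension of the zero-padded sequence.
    """
    a = np.asarray(amplitude, dtype=float)
    n = a.shape[0]
    if window is None:
        w = np.ones(n)
    elif window == "hann":
        w = np.hanning(2 * n - 1)[n - 1:]
    else:
        raise ConfigurationError(f"unknown window {window!r}")
    aw = a * (w if a.ndim == 1 else w[:, None])
    m = padding * n
    pad_shape = (m - n,) + aw.shape[1:]
    padded = np.concatenate([aw, np.zeros(pad_shape)], axis=0)
    even = np.concatenate([padded, padded[-2:0:-1]], axis=0)
    power = np.fft.rfft(even, axis=0).real
    freq_hz = np.fft.rfftfreq(2 * m - 2, d=dtau)
    return freq_hz / 1e9, power


def envelope_spectrum(env: EnvelopeSamples, padding: int = 8,
                      window: str | None = None) -> Spectrum0:
    """Cosine transform of the signed envelope: the optical spectrum centred
    at zero.  Requires a uniform coarse grid (no silent resampling); the
    frequency axis runs from 0 to ``c / (2 * coarse step)``.

    By default no apodization is applied (the physical envelope already
    decays); a Hann window is available for truncation-ringing control.
    """
    dtaus = np.diff(env.tau_s)
    dtau = float(np.mean(dtaus))
    if np.max(np.abs(dtaus - dtau)) > 1e-6 * dtau:
        raise InvalidParameterError(
            "non-uniform coarse delay grid; resample explicitly before "
            "transforming")
    if padding < 1:
        raise ConfigurationError("padding factor must be >= 1")
    freq_ghz, power = _cosine_transform(env.amplitude, dtau, padding, window)
    resolution_ghz = 1.0 / (env.tau_s.size * dtau) / 1e9
    return Spectrum0(frequency_ghz=freq_ghz, power=power,
                     resolution_ghz=resolution_ghz, padding=padding)


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    """Fitted Brillouin parameters with uncertainties and diagnostics.

    ``linewidth_ghz`` from the time-domain fit is the intrinsic FWHM (the
    aperture broadening is part of the model); from the frequency-domain
    Gaussian fit it is the *apparent* width including instrument resolution
    and aperture broadening.
    """

    shift_ghz: float
    linewidth_ghz: float
    amplitude: float
    method: str
    converged: bool
    shift_se_ghz: float = math.nan
    linewidth_se_ghz: float = math.nan
    amplitude_se: float = math.nan
    residual_norm: float = math.nan
    n_points: int = 0
    flags: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "FTBM reconstruction result",
            "=" * 44,
            f"method:            {self.method}",
            f"converged:         {self.converged}",
            f"n observations:    {self.n_points}",
            "-" * 44,
            f"Brillouin shift:   {self.shift_ghz:9.4f} GHz"
            f"  (s.e. {self.shift_se_ghz * 1e3:7.2f} MHz)",
            f"linewidth (FWHM):  {self.linewidth_ghz:9.4f} GHz"
            f"  (s.e. {self.linewidth_se_ghz * 1e3:7.2f} MHz)",
            f"amplitude:         {self.amplitude:9.2f} e-",
            f"residual norm:     {self.residual_norm:9.4g}",
        ]
        if self.flags:
            active = [k for k, v in self.flags.items() if v]
            lines.append(f"flags:             {', '.join(active) or 'none'}")
        return "\n".join(lines)


def _failed_result(method, n_points, flags):
    return ReconstructionResult(shift_ghz=math.nan, linewidth_ghz=math.nan,
                                amplitude=math.nan, method=method,
                                converged=False, n_points=n_points, flags=flags)


def _initial_linewidth_ghz(spec0: Spectrum0, nu0: float,
                           sigma_na_ghz: float) -> float:
    """Crude linewidth initial guess from the spectral peak width, corrected
    in quadrature for the transform resolution and aperture broadening."""
    f, p = spec0.frequency_ghz, spec0.power
    pk = np.argmin(np.abs(f - nu0))
    half = p[pk] / 2.0
    lo = pk
    while lo > 0 and p[lo] > half:
        lo -= 1
    hi = pk
    while hi < p.size - 1 and p[hi] > half:
        hi += 1
    fwhm_app = f[hi] - f[lo]
    gauss_fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_na_ghz
    est2 = fwhm_app**2 - spec0.resolution_ghz**2 - gauss_fwhm**2
    return min(max(math.sqrt(est2) if est2 > 0 else 0.5, 0.2), 5.0)


def fit_envelope_time_domain(env: EnvelopeSamples,
                             spec0: Spectrum0 | None = None,
                             optics: OpticalConfig | None = None, *,
                             broadening_mode: str = "gaussian-approx",
                             fit_offset: bool = False,
                             fit_origin: bool = False,
                             padding: int = 8,
                             max_iter: int = 200,
                             tol: float = 1e-8) -> ReconstructionResult:
    """Nonlinear least squares of the signed envelope samples against the
    envelope model ``amp * A(tau; shift, linewidth)``.

    The shift is initialized from the spectral peak and the linewidth from
    the peak width; parameters are bounded (shift in [0, nu_max], linewidth
    in (0, 2*nu_max]).  ``fit_offset`` adds a constant term for residual
    elastic (Rayleigh) light, whose narrow line contributes a non-decaying
    envelope.  ``fit_origin`` frees a small delay-origin offset bounded by
    half a coarse step.  Non-convergence falls back to the frequency-domain
    Gaussian fit, flagged.
    """
    if broadening_mode != "none" and optics is None:
        raise ConfigurationError("optics required for aperture broadening")
    tau = env.tau_s
    a_obs = env.amplitude
    n = tau.size
    if n < 4:
        raise InvalidParameterError("need at least 4 envelope points")
    scale = float(np.max(np.abs(a_obs)))
    if not np.isfinite(scale) or scale <= 0:
        return _failed_result("time-domain", n, {"degenerate_input": True})
    if spec0 is None:
        spec0 = envelope_spectrum(env, padding)
    dtau = float(np.mean(np.diff(tau)))
    nu_max = 1.0 / (2.0 * dtau) / 1e9

    from .core import na_frequency_sigma_ghz  # local import avoids cycle noise
    f, p = spec0.frequency_ghz, spec0.power
    search = f >= max(0.75 * spec0.resolution_ghz, 0.3)
    nu0 = float(f[search][np.argmax(p[search])]) if np.any(search) else nu_max / 2
    nu0 = min(max(nu0, 1e-3), nu_max - 1e-3)
    sigma_na = (na_frequency_sigma_ghz(optics, nu0)
                if broadening_mode == "gaussian-approx" and optics else 0.0)
    gamma0 = _initial_linewidth_ghz(spec0, nu0, sigma_na)

    def model(theta):
        amp, nu, gamma = theta[0], theta[1], theta[2]
        k = 3
        off = theta[k] if fit_offset else 0.0
        k += fit_offset
        dt0 = theta[k] if fit_origin else 0.0
        spec = EnvelopeSpec(BrillouinSpectrum.single(nu, gamma), optics
                            if optics is not None else _UNIT_OPTICS,
                            broadening_mode)
        return amp * envelope_model(tau + dt0, spec) + off

    def residuals(theta):
        return model(theta) - a_obs

    x0 = [scale, nu0, gamma0]
    lo = [0.0, 0.0, 1e-3]
    hi = [np.inf, nu_max, 2.0 * nu_max]
    if fit_offset:
        x0.append(0.0)
        lo.append(-np.inf)
        hi.append(np.inf)
    if fit_origin:
        x0.append(0.0)
        lo.append(-0.5 * dtau)
        hi.append(0.5 * dtau)
    try:
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            xtol=tol, ftol=tol, gtol=tol,
                            max_nfev=max_iter * (len(x0) + 1))
    except Exception:
        res = None
    if res is None or not res.success:
        fallback = fit_spectrum_gaussian(spec0)
        fallback.method = "time-domain"
        fallback.converged = False
        fallback.flags["frequency_domain_fallback"] = True
        return fallback

    amp, nu, gamma = res.x[0], res.x[1], res.x[2]
    dof = n - len(res.x)
    se = np.full(len(res.x), math.nan)
    if dof > 0 and res.jac is not None:
        s2 = 2.0 * res.cost / dof
        try:
            cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    flags = {
        "nyquist_proximity": nu > 0.95 * nu_max,
        "linewidth_at_bound": gamma > 0.98 * 2.0 * nu_max or gamma < 2e-3,
    }
    params = {"offset": res.x[3] if fit_offset else 0.0,
              "origin_delay_s": res.x[3 + fit_offset] if fit_origin else 0.0,
              "nu_max_ghz": nu_max}
    return ReconstructionResult(
        shift_ghz=float(nu), linewidth_ghz=float(gamma), amplitude=float(amp),
        method="time-domain", converged=True,
        shift_se_ghz=float(se[1]), linewidth_se_ghz=float(se[2]),
        amplitude_se=float(se[0]),
        residual_norm=float(math.sqrt(2.0 * res.cost)), n_points=n,
        flags=flags, params=params)


_UNIT_OPTICS = OpticalConfig(wavelength_nm=780.0)


def fit_spectrum_gaussian(spec0: Spectrum0, *,
                          exclude_below_ghz: float | None = None,
                          ) -> ReconstructionResult:
    """Single-Gaussian least squares around the dominant non-zero-frequency
    peak; returns the centre as the shift and the Gaussian FWHM as the
    *apparent* width (instrument resolution and aperture broadening are not
    removed)."""
    f, p = spec0.frequency_ghz, np.asarray(spec0.power, dtype=float)
    excl = (exclude_below_ghz if exclude_below_ghz is not None
            else max(0.75 * spec0.resolution_ghz, 0.3))
    mask = f >= excl
    if not np.any(mask):
        return _failed_result("frequency-domain", f.size, {"no_search_band": True})
    fi, pi = f[mask], p[mask]
    pk = int(np.argmax(pi))
    flags = {"edge_peak": pk in (0, pi.size - 1)}
    # Secondary-peak detection (multi-component pixels are delegated to the
    # two-Gaussian edge analysis; here we just flag them).
    interior = (pi[1:-1] > pi[:-2]) & (pi[1:-1] > pi[2:])
    loc = np.where(interior)[0] + 1
    others = loc[np.abs(fi[loc] - fi[pk]) > 2.5 * spec0.resolution_ghz]
    flags["multi_peak"] = bool(others.size and pi[others].max() > 0.5 * pi[pk])

    halfwidth = max(1.5 * spec0.resolution_ghz, 1.0)
    win = np.abs(fi - fi[pk]) <= halfwidth
    fw, pw = fi[win], pi[win]
    if fw.size < 4:
        return _failed_result("frequency-domain", f.size,
                              {**flags, "window_too_small": True})

    def gauss(x, a, mu, s):
        return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

    p0 = (float(pi[pk]), float(fi[pk]), max(spec0.resolution_ghz / 2.355, 0.3))
    try:
        popt, pcov = curve_fit(
            gauss, fw, pw, p0=p0,
            bounds=([0.0, excl, 0.05], [np.inf, f[-1], 10.0]), maxfev=2000)
    except Exception:
        return _failed_result("frequency-domain", f.size,
                              {**flags, "fit_failed": True})
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    fwhm_factor = 2.0 * math.sqrt(2.0 * math.log(2.0))
    return ReconstructionResult(
        shift_ghz=float(popt[1]), linewidth_ghz=float(fwhm_factor * popt[2]),
        amplitude=float(popt[0]), method="frequency-domain",
        converged=not flags["edge_peak"],
        shift_se_ghz=float(perr[1]),
        linewidth_se_ghz=float(fwhm_factor * perr[2]),
        amplitude_se=float(perr[0]),
        residual_norm=float(np.linalg.norm(gauss(fw, *popt) - pw)),
        n_points=int(fw.size), flags=flags, params={})


# ---------------------------------------------------------------------------
# Full-field stacks
# ---------------------------------------------------------------------------


def _bin_frames(frames: np.ndarray, k: int) -> np.ndarray:
    """Sum raw counts over k x k pixel blocks (before any fitting, preserving
    Poisson statistics); trailing rows/columns that do not fill a block are
    cropped."""
    if k == 1:
        return frames
    n, h, w = frames.shape
    h2, w2 = (h // k) * k, (w // k) * k
    f = frames[:, :h2, :w2]
    return f.reshape(n, h2 // k, k, w2 // k, k).sum(axis=(2, 4))


def reconstruct_stack(frames, positions_nm, schedule: SamplingSchedule,
                      optics: OpticalConfig, *,
                      binning: int = 1,
                      method: str = "time-domain",
                      reference_region: tuple[int, int, int, int] | None = None,
                      broadening_mode: str = "gaussian-approx",
                      aom_offset_mhz: float = DEFAULT_AOM_OFFSET_MHZ,
                      padding: int = 8,
                      fit_offset: bool = False,
                      return_spectra: bool = False) -> dict:
    """Per-pixel FTBM reconstruction of a full-field frame stack.

    Applies optional ``binning`` (summing counts) first, then the per-pixel
    pipeline: local cosine fits -> sign assignment (from the designated
    reference region, if any, else phase continuity) -> cosine transform ->
    the chosen parameter fit.  Returns shift/linewidth/amplitude maps plus a
    convergence mask; ``reference_region`` coordinates refer to the unbinned
    image and those pixels are masked out of the maps.
    """
    frames = np.asarray(frames, dtype=float)
    positions_nm = np.asarray(positions_nm, dtype=float)
    if frames.ndim != 3:
        raise InvalidParameterError("frames must be (n_positions, ny, nx)")
    if frames.shape[0] != schedule.n_positions:
        raise InvalidParameterError(
            f"frame count {frames.shape[0]} does not match schedule "
            f"({schedule.n_positions} positions)")
    if positions_nm.size != schedule.n_positions or not np.allclose(
            positions_nm, schedule.positions_nm(), atol=1e-3):
        raise InvalidParameterError("positions table inconsistent with schedule")
    if method not in ("time-domain", "frequency-domain"):
        raise ConfigurationError(f"unknown method {method!r}")

    ref_mask_binned = None
    if reference_region is not None:
        y0, y1, x0, x1 = reference_region
        full_mask = np.zeros(frames.shape[1:], dtype=bool)
        full_mask[y0:y1, x0:x1] = True
    frames_b = _bin_frames(frames, binning)
    n_pos, h, w = frames_b.shape
    if reference_region is not None:
        mb = full_mask[:(h * binning), :(w * binning)]
        ref_mask_binned = mb.reshape(h, binning, w, binning).any(axis=(1, 3))

    n_px = h * w
    counts = frames_b.reshape(schedule.n_coarse, schedule.n_fine, n_px)
    grid = schedule.positions_grid_nm()
    offs, amps, phis, sds = _local_fits_block(counts, grid, optics.wavelength_nm)
    reliable = amps > np.maximum(3.0 * sds, 1e-12 * np.maximum(np.abs(offs), 1.0))

    tau = schedule.coarse_tau_s()
    ref_phases = None
    if ref_mask_binned is not None and ref_mask_binned.any():
        ref_counts = counts[:, :, ref_mask_binned.ravel()].mean(axis=2)[..., None]
        _, _, rphi, _ = _local_fits_block(ref_counts, grid, optics.wavelength_nm)
        ref_phases = rphi[:, 0] - 2.0 * math.pi * aom_offset_mhz * 1e6 * tau
    cos_psi, signs = _phase_projection(phis, reliable, ref_phases)
    signed = cos_psi * amps

    dtau = float(np.mean(np.diff(tau)))
    freq_ghz, power = _cosine_transform(signed, dtau, padding, None)
    resolution_ghz = 1.0 / (schedule.n_coarse * dtau) / 1e9

    shift = np.full(n_px, np.nan)
    width = np.full(n_px, np.nan)
    amp = np.full(n_px, np.nan)
    ok = np.zeros(n_px, dtype=bool)
    resid = np.full(n_px, np.nan)
    skip = ref_mask_binned.ravel() if ref_mask_binned is not None else None
    for p in range(n_px):
        if skip is not None and skip[p]:
            continue
        spec0 = Spectrum0(freq_ghz, power[:, p], resolution_ghz, padding)
        if method == "time-domain":
            env = EnvelopeSamples(tau, signed[:, p], sds[:, p], signs[:, p],
                                  reliable[:, p])
            r = fit_envelope_time_domain(env, spec0, optics,
                                         broadening_mode=broadening_mode,
                                         fit_offset=fit_offset)
        else:
            r = fit_spectrum_gaussian(spec0)
        shift[p], width[p], amp[p] = r.shift_ghz, r.linewidth_ghz, r.amplitude
        ok[p] = r.converged
        resid[p] = r.residual_norm

    out = {
        "shift_ghz": shift.reshape(h, w),
        "linewidth_ghz": width.reshape(h, w),
        "amplitude": amp.reshape(h, w),
        "converged": ok.reshape(h, w),
        "residual": resid.reshape(h, w),
        "method": method,
        "binning": binning,
    }
    if return_spectra:
        out["frequency_ghz"] = freq_ghz
        out["spectra"] = power.reshape(power.shape[0], h, w)
    return out


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------


class InterferogramModel:
    """Single-pixel FTBM inverse problem, statsmodels style.

    Built from data (counts at scheduled OPL positions); ``fit()`` runs the
    local-fit / signed-envelope / spectrum pipeline and returns a
    :class:`ReconstructionResult` with estimates, standard errors and
    diagnostics.

    Examples
    --------
    >>> model = InterferogramModel.from_sampled(interferogram, optics)
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, counts, positions_nm, schedule: SamplingSchedule,
                 optics: OpticalConfig, *,
                 reference_counts=None,
                 broadening_mode: str = "gaussian-approx",
                 aom_offset_mhz: float = DEFAULT_AOM_OFFSET_MHZ):
        self.counts = np.asarray(counts, dtype=float)
        self.positions_nm = np.asarray(positions_nm, dtype=float)
        if self.counts.shape != self.positions_nm.shape:
            raise InvalidParameterError("counts/positions shape mismatch")
        if self.counts.size != schedule.n_positions:
            raise InvalidParameterError("counts do not match the schedule")
        self.schedule = schedule
        self.optics = optics
        self.reference_counts = (None if reference_counts is None
                                 else np.asarray(reference_counts, dtype=float))
        self.broadening_mode = broadening_mode
        self.aom_offset_mhz = aom_offset_mhz

    @classmethod
    def from_sampled(cls, interferogram: SampledInterferogram,
                     optics: OpticalConfig,
                     reference: SampledInterferogram | None = None,
                     **kwargs) -> "InterferogramModel":
        return cls(interferogram.counts, interferogram.positions_nm,
                   interferogram.schedule, optics,
                   reference_counts=None if reference is None else reference.counts,
                   **kwargs)

    def _fits_of(self, counts) -> list[LocalFit]:
        grid = self.schedule.positions_grid_nm()
        cg = counts.reshape(self.schedule.n_coarse, self.schedule.n_fine)
        return [local_cosine_fit(cg[n], grid[n], self.optics, coarse_index=n)
                for n in range(self.schedule.n_coarse)]

    def local_fits(self) -> list[LocalFit]:
        return self._fits_of(self.counts)

    def envelope(self) -> EnvelopeSamples:
        ref = (self._fits_of(self.reference_counts)
               if self.reference_counts is not None else None)
        return signed_envelope(self.local_fits(), self.schedule.coarse_tau_s(),
                               reference=ref,
                               aom_offset_mhz=self.aom_offset_mhz)

    def spectrum(self, padding: int = 8, window: str | None = None) -> Spectrum0:
        return envelope_spectrum(self.envelope(), padding, window)

    def fit(self, method: str = "time-domain", *, padding: int = 8,
            fit_offset: bool = False, fit_origin: bool = False,
            ) -> ReconstructionResult:
        env = self.envelope()
        spec0 = envelope_spectrum(env, padding)
        if method == "time-domain":
            return fit_envelope_time_domain(
                env, spec0, self.optics, broadening_mode=self.broadening_mode,
                fit_offset=fit_offset, fit_origin=fit_origin, padding=padding)
        if method == "frequency-domain":
            return fit_spectrum_gaussian(spec0)
        raise ConfigurationError(f"unknown method {method!r}")
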