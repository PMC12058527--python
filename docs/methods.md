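# Methods

## Model

A Michelson interferometer at delay `τ = OPL/c` (OPL is the optical path
difference, twice the mirror displacement; schedules are specified in OPL
throughout) turns the optical spectrum into an interferogram via the
Wiener–Khinchin relation.  For a spectrum symmetric about the laser line —
the Brillouin Stokes/anti-Stokes doublet — the interferogram is a carrier
fringe at the laser frequency `ω_L` times a real signed envelope:

```
2 N_detect(τ) = N_ASE + N_elas + N_Br + [N_elas + N_Br·A(τ)]·cos(ω_L τ)
```

All intensities are expected photoelectrons per pixel per exposure at the
interferometer input (detector gain fixed at 1); the overall factor ½ is
the Michelson splitting loss.  ASE (amplified spontaneous emission) is
broadband and incoherent, so it raises the offset but never the fringe.
The residual elastic (Rayleigh) line after suppression is spectrally
narrow, so its envelope is constant over the scanned delays; the
suppression itself (an atomic absorption cell, >80 dB) is not modelled —
users encode it directly in `N_elas`.

Each Lorentzian component pair (shift `ν_B`, FWHM `Δν_B`, amplitude weight)
contributes

```
A_c(τ) = exp(−π Δν_B τ) · cos(2π ν_B τ) · B_NA(τ)
```

and a multi-component spectrum is the amplitude-weighted mean, so `A(0)=1`
and `|A(τ)| ≤ 1` always.  The envelope of a symmetric spectrum is even;
negative delays (reachable through stage jitter around the OPL origin) are
evaluated at `|τ|`.

### Aperture (NA) broadening

Collecting over a finite aperture spreads the scattering angle θ′ and hence
the apparent shift, which scales as `sin(θ′/2)`.  The exact closed form of
this broadening is implementation-specific, so `B_NA` is selectable:

* `none` — no broadening (closed-form Lorentzian algebra applies exactly;
  used by the oracle tests).
* `gaussian-approx` (default) — Gaussian spectral broadening with standard
  deviation `σ_NA = ν_B · std[sin(θ′/2)]/sin(θ/2)`, i.e. a Gaussian decay
  factor `exp(−2π² σ_NA² τ²)` in time.  The std is computed once by a
  deterministic quadrature over two uniformly filled circular apertures of
  half-angle `asin(NA_eff/n)` around the nominal illumination and
  collection axes.
* `angle-integral` — the same quadrature used directly: the component
  fringe `cos(2π ν_B(θ′) τ)` is averaged over the aperture's θ′
  distribution.  The two broadening routes agree to within a few percent of
  the envelope over the delays of interest; the Gaussian form is the
  default because it admits an analytic model function in the fit.

At the default geometry (780 nm, θ = 90°, NA_eff = 0.47, n = 1.33) the
quadrature gives `σ_NA ≈ 0.448 GHz` at the water shift (3.593 GHz), a
Gaussian FWHM of ≈ 1.06 GHz.

### Default water spectrum

The water shift follows `ν_B = 2 n v sin(θ/2)/λ` with `v = 1490 m/s`,
`n = 1.33` → 3.593 GHz at the default geometry.  The *intrinsic* linewidth
default is 0.75 GHz: what is observed for water in this NA-broadened 90°
geometry is an apparent width of ~1.5 GHz, and 0.75 GHz Lorentzian combined
with the ≈1.06 GHz Gaussian aperture broadening gives a Voigt FWHM of
≈ 1.5 GHz.  The intrinsic value is a configuration knob, not a measured
quantity.

## Sampling design

* Full-interferogram (Nyquist) count: `N = 2c/(Δν·λ_min)` — ≈1.5×10⁶ at
  780 nm and 0.5 GHz resolution.
* Symmetric-spectrum count: only the envelope must satisfy Nyquist, giving
  `N = N_L · 2 ν_range/Δν` with `N_L ≥ 3` fine samples per coarse position
  (amplitude, phase and offset need three numbers).
* Reduction factor: `r = ν_L/(N_L·ν_range)`; exactly
  `N_standard/N_symmetric`, ≈1.8×10⁴ for `N_L = 3` and a 7 GHz range.
* Schedule metrics: a coarse OPL step δ gives an unambiguous range
  `c/(2δ)` and a resolution `c/(N_S·δ)` from the total scanned OPL.
  The speed of light is `scipy.constants.c` everywhere, so a 31 × 8 mm
  schedule reports 18.737 GHz / 1.209 GHz (commonly rounded to
  18.75 / 1.2).

## Simulator

Noise enters in a fixed order at each scheduled position: **stage jitter**
(Gaussian in OPL, one draw per position, shared by all pixels of a frame
and by simultaneously acquired channels) → **intensity noise**
(multiplicative Gaussian, drawn independently per sampled position;
negative expectations are clamped to zero and logged) → **shot noise**
(Poisson) → **read noise** (additive Gaussian; counts are non-negative
integers only while read noise is off).  Identical configuration and seed
give bit-identical output.

The reference channel is an unmodulated laser-line interferogram whose
fringe runs at `ω_L + 2π·f_AOM` (the acousto-optic modulator offset,
default 250 MHz); over 200 mm of OPL the offset accumulates only ~1.05 rad
of extra phase, which the reconstruction removes deterministically rather
than estimating it.

Phantoms are spherical inclusions (default oil, 2.15 GHz) in a homogeneous
background (default agar, 3.53 GHz).  Component amplitude fractions follow
a normal-CDF (erf) profile of the signed distance to the nearest bead
boundary with the configured blur s.d.; overlapping beads form a union with
the inclusion winning.  Intrinsic linewidth defaults (0.8 / 1.0 GHz) are
plausible knobs.  The per-pixel ground truth stored with every stack is the
amplitude-weighted mixture of the component parameters (exact for pure
pixels).  A stack can carry the laser reference in a designated rectangle
of the field, mirroring a D-shaped-mirror injection.

What the phantoms do **not** emulate: the optical point-spread function,
light-sheet thickness and illumination inhomogeneity, refraction artefacts,
and sample motion.  Passing tests therefore validate the spectral pipeline
and its photon-statistics scaling, not image formation in real tissue.

## Reconstruction

Two-stage inverse path, per pixel:

1. **Local cosine fit.**  At each coarse position the `N_L` fine samples are
   fitted with `offset + a·cos(2π·OPL/λ + φ)`, frequency fixed by the
   laser; solved linearly in `(offset, a cos φ, −a sin φ)`, exact on
   noiseless data.  The amplitude uncertainty is propagated from the
   residual scatter; amplitudes below 3× their uncertainty are flagged —
   their phase carries no sign information.
2. **Sign assignment / envelope.**  The fringe-phase origin comes from the
   reference channel (corrected for the deterministic AOM ramp
   `2π f_AOM τ`) or, without one, from the first reliable sample (assuming
   a positive envelope at the smallest delay — a degraded but
   self-contained mode).  The signed envelope sample is the *projection*
   `a·cos(ψ)` of the local fit onto that origin, not `sign(cos ψ)·a`: the
   two coincide exactly on noiseless data, but the projection is linear in
   the fitted quadratures and avoids the Rice magnitude-folding bias near
   envelope zero crossings, which otherwise biases the fitted shift by tens
   of MHz at kilophoton budgets.  The discrete sign sequence is still
   reported, with unreliable samples inheriting the nearest reliable
   lower-delay sign (continuity is the physical prior at zero crossings).
3. **Spectrum.**  The signed envelope on its uniform coarse grid is
   cosine-transformed (even extension, ×8 zero padding, no apodization by
   default since the envelope already decays; a Hann window is available).
   Non-uniform grids raise — no silent resampling.
4. **Parameter estimation.**  The default time-domain fit runs bounded
   nonlinear least squares of `amp·A(τ)` (plus an optional constant for
   residual elastic light, plus an optional OPL-origin offset bounded by
   half a coarse step) against the envelope samples: shift bounded to
   `[0, ν_max]`, linewidth to `(0, 2ν_max]`, tolerance 1e−8, ≤200
   iterations; the shift is initialized at the spectral peak and the
   linewidth from the peak width.  Standard errors come from the residual
   variance and the Jacobian.  Non-convergence falls back to the
   frequency-domain route, flagged.  The frequency-domain fit is a single
   Gaussian around the dominant non-zero-frequency peak; its width is the
   *apparent* width (resolution and aperture broadening included), and
   near-Nyquist or multi-peak spectra are flagged rather than unmixed.

Stacks are reconstructed by the same pipeline vectorized per pixel, with
optional k×k binning that **sums raw counts before any fitting**
(preserving Poisson statistics).  Components above the unambiguous range
alias to the mirror position `2ν_max − ν`.

## Performance protocol

Precision is the sample standard deviation (ddof = 1) of the fitted shift
or linewidth over replicate simulations — 100 replicates per condition by
default, matching the protocol behind the published scaling laws
(`N_L = 5` fine steps of 195 nm OPL, `N_S = 20` coarse steps of 10 mm,
water spectrum with aperture broadening).  Non-convergent replicates are
excluded and counted; a record with more than 10% exclusions is marked
failed.  For sweeps over the number of coarse steps, the coarse step is
rescaled to hold the total OPL at 200 mm and the per-step budget rescaled
to hold the total photons constant.

**Photon accounting.**  The stated "photoelectrons per sampling step" is,
by default, the fringe-averaged *detected* Brillouin count per step, so the
input budget is twice the stated number (the Michelson halves the mean).
The alternative reading — the detected expectation at OPL = 0 — is
available as `accounting="peak"`.  The default was chosen on information
grounds: a Cramér–Rao analysis of this two-stage protocol (local-fit
amplitude variance ≈ `2·offset/N_L`, Gaussian envelope fit) bounds the
shift precision at ≈10.7 MHz for 3,000 photoelectrons under peak
accounting, whereas the protocol's known precision figures (<10 MHz at
3,000 photoelectrons) require the per-step-mean reading, under which the
bound is ≈7.6 MHz.  `N_total = photons × N_S × N_L` is reported with every
record so either convention can be recovered.

The edge-resolution analysis follows the two-component route: spectra along
a line crossing a material boundary (optionally averaged over a
neighbourhood of adjacent positions) are decomposed into two fixed-centre
Gaussians; each normalized amplitude profile is fitted with an erf of
position and the FWHM `2√(2 ln 2)·σ` is reported per component.
Neighbourhood averaging convolves the edge with a boxcar and widens the
apparent FWHM — use `neighborhood=1` against construction oracles.

## Numerical choices and degenerate inputs

* Zero-amplitude envelopes return flagged, non-convergent results — no
  crash, no fabricated estimates.
* Rank-deficient fine-scan designs (degenerate positions) raise a fit
  error; the fine phase step is validated to lie strictly inside (0, π).
* The fine scan of 5 steps of λ/4 spans one inclusive fringe period, so the
  discrete fringe sum is not exactly zero (it leaves one half-fringe
  sample); exact discrete cancellation needs 4 steps of λ/4.
* Reported spectral metrics use the exact speed of light; printed values
  rounded to ~2 significant figures agree to that rounding.
* All randomness flows through a single numpy Generator per run; seeds are
  part of every configuration and every output's metadata.

## Known limitations

* Single-component spectra only in the default per-pixel fit; two-component
  analysis lives in the edge tools, and per-pixel multi-peak unmixing is
  out of scope.
* The exact analytic form of the instrument's NA-broadened envelope is
  approximated by the two selectable broadening modes; both are documented
  reconstructions, swappable if an exact form is supplied.
* No optical image formation (PSF, light-sheet geometry, refraction), no
  drift correction, no flat-field calibration, no Raman extension.
* The Monte-Carlo suite characterizes estimator precision under the stated
  noise model; experimental precision additionally depends on effects the
  simulator deliberately omits (see the phantom section).
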