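# ftbm — Fourier-transform Brillouin microscopy

Brillouin microscopy probes the viscoelastic properties of transparent
samples by measuring the tiny (GHz-scale) frequency shift and linewidth of
light scattered off thermally excited acoustic phonons.  A Fourier-transform
imaging spectrometer makes this a full-field measurement — one camera frame
per interferometer delay — but sampling a sub-GHz-resolution interferogram
at the Nyquist rate of the optical carrier would need on the order of 10⁶
stage positions.  Because the Brillouin spectrum is *symmetric* about the
laser line, the interferogram factorizes into a fast fringe at the laser
frequency times a slowly varying signed envelope `A(τ)` that carries the
full spectral information at baseband.  Sampling the fringe locally with a
handful of fine steps, and the envelope coarsely, cuts the required samples
by a factor of more than 10⁴.

`ftbm` is a tested software kit for this measurement scheme, aimed at
instrument builders and methods researchers.  It provides:

* **Forward model** — the Michelson transfer function in detected
  photoelectrons,

  `2 N_detect(τ) = N_ASE + N_elas + N_Br + [N_elas + N_Br·A(τ)]·cos(ω_L τ)`

  with `A(τ) = exp(−π Δν_B τ)·cos(2π ν_B τ)·B_NA(τ)` for each Lorentzian
  component pair (shift `ν_B`, FWHM `Δν_B`) and a selectable
  numerical-aperture broadening factor `B_NA`.
* **Sampling-design algebra** — the Nyquist sample count
  `N = 2c/(Δν·λ_min)`, the symmetric-spectrum count
  `N = N_L·2ν_range/Δν`, their ratio (the undersampling reduction factor),
  and schedule metrics (unambiguous range `c/2δ`, resolution `c/(N_S·δ)`).
* **Simulator** — noisy sampled interferograms (stage jitter → intensity
  noise → Poisson shot noise → read noise), a frequency-shifted laser
  reference channel, and synthetic oil-beads-in-agar phantoms rendered as
  full-field frame stacks with pixel-aligned ground truth.
* **Reconstruction** — fixed-frequency local cosine fits, phase-based sign
  assignment, signed-envelope assembly, zero-padded cosine transform, and
  shift/width estimation in the time domain (envelope model fit) or
  frequency domain (Gaussian peak fit), per pixel over stacks with optional
  binning.
* **Performance suite** — Monte-Carlo precision sweeps over photons, read
  noise, stage jitter, Rayleigh/ASE background, intensity noise and coarse
  step count; log–log scaling-law slopes; erf-based edge-resolution (FWHM)
  analysis; replicate precision maps.

## Worked example

Simulate one shot-noise-limited water interferogram (2,000 Brillouin
photoelectrons at the interferometer input, the 5 × 195 nm / 20 × 10 mm OPL
schedule) and fit it:

```python
import ftbm

optics = ftbm.default_water_optics()          # 780 nm, 90°, NA_eff 0.47
spectrum = ftbm.BrillouinSpectrum.water(optics)
schedule = ftbm.SamplingSchedule(n_fine=5, fine_step_nm=195.0,
                                 n_coarse=20, coarse_step_mm=10.0)
signal = ftbm.sample_interferogram(
    spectrum, ftbm.PhotonBudget(n_brillouin=2000),
    schedule, ftbm.NoiseModel(shot_noise=True, seed=0), optics)
result = ftbm.InterferogramModel.from_sampled(signal, optics).fit()
print(result.summary())
```

```
FTBM reconstruction result
============================================
method:            time-domain
converged:         True
n observations:    20
--------------------------------------------
Brillouin shift:      3.6014 GHz  (s.e.   15.00 MHz)
linewidth (FWHM):     0.7588 GHz  (s.e.   40.12 MHz)
amplitude:           1021.63 e-
residual norm:         95.65
flags:             none
```

The fitted shift is the water Brillouin shift at this geometry
(2·n·v·sin 45°/λ = 3.593 GHz) recovered to within its ~15 MHz standard
error; the linewidth is the intrinsic FWHM after the aperture broadening is
accounted for in the model; the amplitude is the envelope scale in
photoelectrons (half the input Brillouin budget).

The same pipeline runs from the shell:

```sh
ftbm design --wavelength 780 --resolution 0.5     # sampling-design numbers
ftbm simulate --photons 1000 --seed 1 --out interferogram.csv
ftbm phantom --size 32 32 --bead 8 8 4 --out stack/
ftbm reconstruct --in stack/ --out maps/
ftbm sweep --axis photons --values 1000,3000,10000 --out sweep.csv
```

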