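"""Tests for the FTBM inverse path: local fits, signing, spectra, and
shift/width estimation."""

import math

import numpy as np
import pytest
from scipy.constants import c as C

from ftbm.core import (
    BrillouinSpectrum,
    EnvelopeSpec,
    InvalidParameterError,
    PhotonBudget,
    SamplingSchedule,
    envelope_model,
    schedule_metrics,
)
from ftbm.reconstruct import (
    EnvelopeSamples,
    FitError,
    InterferogramModel,
    LocalFit,
    Spectrum0,
    envelope_spectrum,
    fit_envelope_time_domain,
    fit_spectrum_gaussian,
    local_cosine_fit,
    reconstruct_stack,
    signed_envelope,
)
from ftbm.simulate import (
    NoiseModel,
    PhantomGeometry,
    make_phantom,
    sample_interferogram,
    simulate_measurement,
)


def analytic_envelope_samples(shift, width, schedule, optics, mode="none",
                              scale=1.0):
    tau = schedule.coarse_tau_s()
    spec = EnvelopeSpec(BrillouinSpectrum.single(shift, width), optics, mode)
    a = scale * envelope_model(tau, spec)
    return EnvelopeSamples(tau, a, np.zeros_like(a),
                           np.sign(a) + (a == 0),
                           np.ones_like(a, dtype=bool))


class TestLocalCosineFit:
    def test_exact_on_noiseless_cosine(self, plain_optics):
        offset, a, phi = 100.0, 30.0, 0.7
        pos = np.arange(5) * 195.0  # pi/2 fringe phase steps at 780 nm
        x = 2 * math.pi * pos / plain_optics.wavelength_nm
        counts = offset + a * np.cos(x + phi)
        fit = local_cosine_fit(counts, pos, plain_optics)
        assert fit.offset == pytest.approx(offset, abs=1e-9)
        assert fit.amplitude == pytest.approx(a, abs=1e-9)
        assert fit.phase == pytest.approx(phi, abs=1e-12)
        assert fit.residual_norm < 1e-9
        assert fit.reliable

    def test_zero_amplitude_flagged(self, plain_optics):
        pos = np.arange(5) * 195.0
        fit = local_cosine_fit(np.full(5, 42.0), pos, plain_optics)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not fit.reliable

    def test_degenerate_positions_raise(self, plain_optics):
        with pytest.raises(FitError):
            local_cosine_fit(np.ones(5), np.zeros(5), plain_optics)

    def test_poisson_amplitude_estimator_nearly_unbiased(self, plain_optics):
        """With offset = amplitude = 500 and Poisson noise, the amplitude
        estimator bias stays below 5% of its own standard deviation."""
        offset = a = 500.0
        pos = np.arange(5) * 195.0
        x = 2 * math.pi * pos / plain_optics.wavelength_nm
        expected = offset + a * np.cos(x)
        rng = np.random.default_rng(11)
        draws = rng.poisson(expected, size=(4000, 5)).astype(float)
        amps = np.array([local_cosine_fit(d, pos, plain_optics).amplitude
                         for d in draws])
        # The magnitude |a| is slightly biased; at this SNR (~25) the bias
        # must be buried below 5% of the spread.
        assert abs(amps.mean() - a) < 0.05 * amps.std(ddof=1)


class TestSignedEnvelope:
    def test_constant_positive_envelope_all_plus(self, plain_optics):
        fits = [LocalFit(100, 50, 0.0, 1.0, 0.1, 5, i) for i in range(6)]
        tau = np.arange(6) * 1e-11
        env = signed_envelope(fits, tau)
        assert np.all(env.signs == 1)
        np.testing.assert_allclose(env.amplitude, 50.0)

    def test_reference_rotated_by_pi_flips_all_signs(self, plain_optics):
        fits = [LocalFit(100, 50, 0.0, 1.0, 0.1, 5, i) for i in range(6)]
        ref = [LocalFit(100, 50, math.pi, 1.0, 0.1, 5, i) for i in range(6)]
        tau = np.arange(6) * 1e-11
        env = signed_envelope(fits, tau, reference=ref, aom_offset_mhz=0.0)
        assert np.all(env.signs == -1)
        np.testing.assert_allclose(env.amplitude, -50.0)

    def test_signs_flip_at_analytic_zero_crossing(self, plain_optics,
                                                  kilophoton_budget):
        """Noiseless single-component envelope: the reconstructed signs flip
        exactly where the analytic envelope changes sign."""
        shift = 3.6
        sched = SamplingSchedule(n_fine=5, fine_step_nm=195.0, n_coarse=12,
                                 coarse_step_mm=10.0)
        spectrum = BrillouinSpectrum.single(shift, 0.5)
        si = sample_interferogram(spectrum, kilophoton_budget, sched,
                                  NoiseModel(shot_noise=False), plain_optics,
                                  broadening_mode="none")
        model = InterferogramModel.from_sampled(si, plain_optics,
                                                broadening_mode="none")
        env = model.envelope()
        truth = envelope_model(sched.coarse_tau_s(),
                               EnvelopeSpec(spectrum, plain_optics, "none"))
        keep = np.abs(truth) > 1e-3  # skip exact nodes where sign is undefined
        np.testing.assert_array_equal(np.sign(env.amplitude[keep]),
                                      np.sign(truth[keep]))

    def test_misaligned_reference_rejected(self):
        fits = [LocalFit(1, 1, 0.0, 0.0, 0.0, 5, i) for i in range(4)]
        with pytest.raises(InvalidParameterError):
            signed_envelope(fits, np.arange(4) * 1e-11, reference=fits[:2])


class TestEnvelopeSpectrum:
    def test_constant_envelope_peaks_at_zero(self):
        tau = np.arange(16) * 3e-11
        env = EnvelopeSamples(tau, np.ones(16), np.zeros(16), np.ones(16),
                              np.ones(16, dtype=bool))
        s = envelope_spectrum(env, padding=8)
        assert s.frequency_ghz[np.argmax(s.power)] == 0.0

    def test_matches_dense_fft_oracle(self, plain_optics, water_schedule):
        """The coarse cosine transform agrees with a dense FFT oracle of the
        same truncated analytic envelope."""
        env = analytic_envelope_samples(5.0, 1.0, water_schedule, plain_optics)
        s = envelope_spectrum(env, padding=8)
        # Dense oracle: same even extension, 64x finer sampling of the same
        # truncated envelope, evaluated by direct cosine sum on s's axis.
        dtau = np.mean(np.diff(env.tau_s))
        fine = np.arange(0, env.tau_s[-1] + dtau / 128, dtau / 64)
        spec = EnvelopeSpec(BrillouinSpectrum.single(5.0, 1.0), plain_optics,
                            "none")
        af = envelope_model(fine, spec)
        nu = s.frequency_ghz * 1e9
        oracle = (af[0] + 2 * np.cos(2 * math.pi * np.outer(nu, fine[1:]))
                  @ af[1:]) / 64.0
        a = s.power / np.max(s.power)
        b = oracle / np.max(oracle)
        assert np.max(np.abs(a - b)) < 0.05
        # Peak location within half a padded bin of the oracle's.
        bin_ghz = s.frequency_ghz[1] - s.frequency_ghz[0]
        assert abs(s.frequency_ghz[np.argmax(a)]
                   - s.frequency_ghz[np.argmax(b)]) <= bin_ghz / 2 + 1e-12

    def test_peak_within_half_bin_of_truth(self, plain_optics, water_schedule):
        env = analytic_envelope_samples(5.0, 1.0, water_schedule, plain_optics)
        s = envelope_spectrum(env, padding=8)
        bin_ghz = s.frequency_ghz[1] - s.frequency_ghz[0]
        peak = s.frequency_ghz[np.argmax(s.power)]
        assert abs(peak - 5.0) <= bin_ghz

    def test_aliasing_mirrors_above_nyquist(self, plain_optics,
                                            water_schedule):
        """A component above the unambiguous range folds back to the mirror
        position 2*nu_max - nu."""
        nu_max = schedule_metrics(water_schedule)[0]
        nu = nu_max + 2.0
        env = analytic_envelope_samples(nu, 1.0, water_schedule, plain_optics)
        s = envelope_spectrum(env, padding=8)
        r = fit_spectrum_gaussian(s)
        assert r.shift_ghz == pytest.approx(2 * nu_max - nu, abs=0.05)

    def test_nonuniform_grid_rejected(self):
        tau = np.array([0.0, 1.0, 2.0, 3.5]) * 1e-11
        env = EnvelopeSamples(tau, np.ones(4), np.zeros(4), np.ones(4),
                              np.ones(4, dtype=bool))
        with pytest.raises(InvalidParameterError):
            envelope_spectrum(env)


class TestTimeDomainFit:
    def test_noiseless_water_roundtrip(self, water_optics, water_schedule,
                                       water_spectrum):
        """Full pipeline on a noiseless simulated water interferogram
        recovers the generating shift and linewidth to < 0.1%."""
        si = sample_interferogram(water_spectrum, PhotonBudget(1000),
                                  water_schedule, NoiseModel(shot_noise=False),
                                  water_optics)
        res = InterferogramModel.from_sampled(si, water_optics).fit()
        truth = water_spectrum.components[0]
        assert res.converged
        assert res.shift_ghz == pytest.approx(truth.shift_ghz, rel=1e-3)
        assert res.linewidth_ghz == pytest.approx(truth.linewidth_ghz,
                                                  rel=1e-3)

    def test_zero_amplitude_flagged_not_crashing(self, water_optics,
                                                 water_schedule):
        tau = water_schedule.coarse_tau_s()
        env = EnvelopeSamples(tau, np.zeros_like(tau), np.zeros_like(tau),
                              np.ones_like(tau), np.zeros_like(tau, dtype=bool))
        res = fit_envelope_time_domain(env, optics=water_optics)
        assert not res.converged
        assert res.flags.get("degenerate_input")

    def test_elastic_offset_term(self, water_optics, water_schedule,
                                 water_spectrum):
        """Residual Rayleigh light adds a constant envelope term; the fit
        with the offset enabled still recovers the Brillouin parameters."""
        budget = PhotonBudget(1000, n_elastic=300)
        si = sample_interferogram(water_spectrum, budget, water_schedule,
                                  NoiseModel(shot_noise=False), water_optics)
        res = InterferogramModel.from_sampled(si, water_optics).fit(
            fit_offset=True)
        truth = water_spectrum.components[0]
        assert res.shift_ghz == pytest.approx(truth.shift_ghz, rel=1e-3)
        assert res.params["offset"] == pytest.approx(150.0, rel=0.02)

    def test_summary_renders(self, water_optics, water_schedule,
                             water_spectrum):
        si = sample_interferogram(water_spectrum, PhotonBudget(1000),
                                  water_schedule, NoiseModel(shot_noise=False),
                                  water_optics)
        text = InterferogramModel.from_sampled(si, water_optics).fit().summary()
        assert "Brillouin shift" in text and "GHz" in text
        assert "time-domain" in text


class TestFrequencyDomainFit:
    def test_self_fit_of_synthetic_gaussian(self):
        freq = np.linspace(0, 15, 601)
        power = 80.0 * np.exp(-0.5 * ((freq - 3.53) / 0.6) ** 2)
        s = Spectrum0(freq, power, resolution_ghz=1.2, padding=8)
        r = fit_spectrum_gaussian(s)
        assert r.shift_ghz == pytest.approx(3.53, abs=1e-6)
        assert r.linewidth_ghz == pytest.approx(2.355 * 0.6, rel=1e-4)

    def test_cross_method_agreement(self, water_optics, water_schedule,
                                    water_spectrum):
        """Time- and frequency-domain shifts agree within resolution/10 for a
        noiseless single-component input."""
        si = sample_interferogram(water_spectrum, PhotonBudget(1000),
                                  water_schedule, NoiseModel(shot_noise=False),
                                  water_optics)
        model = InterferogramModel.from_sampled(si, water_optics)
        td = model.fit("time-domain")
        fd = model.fit("frequency-domain")
        dv = schedule_metrics(water_schedule)[1]
        assert abs(td.shift_ghz - fd.shift_ghz) < dv / 10

    def test_two_equal_peaks_flagged_multi_peak(self, plain_optics,
                                                water_schedule):
        tau = water_schedule.coarse_tau_s()
        spec = EnvelopeSpec(BrillouinSpectrum([(2.15, 0.8, 1.0),
                                               (6.5, 1.0, 1.0)]),
                            plain_optics, "none")
        a = envelope_model(tau, spec)
        env = EnvelopeSamples(tau, a, np.zeros_like(a), np.ones_like(a),
                              np.ones_like(a, dtype=bool))
        r = fit_spectrum_gaussian(envelope_spectrum(env, 8))
        assert r.flags["multi_peak"]


class TestStackReconstruction:
    def test_single_pixel_stack_matches_direct_pipeline(
            self, water_optics, water_schedule, water_spectrum):
        si = sample_interferogram(water_spectrum, PhotonBudget(1000),
                                  water_schedule,
                                  NoiseModel(shot_noise=True, seed=3),
                                  water_optics)
        maps = reconstruct_stack(si.counts.reshape(-1, 1, 1), si.positions_nm,
                                 water_schedule, water_optics)
        direct = InterferogramModel.from_sampled(si, water_optics).fit()
        assert maps["shift_ghz"][0, 0] == pytest.approx(direct.shift_ghz,
                                                        abs=1e-9)
        assert maps["linewidth_ghz"][0, 0] == pytest.approx(
            direct.linewidth_ghz, abs=1e-9)

    def test_homogeneous_stack_matches_single_pixel_mc(
            self, water_optics, sim_schedule, water_spectrum):
        """Ergodicity: the spatial s.d. of a homogeneous shot-noise stack
        matches the single-pixel Monte-Carlo precision within 20%."""
        water_like = PhantomGeometry(
            shape=(16, 16), beads_um=(),
            background=water_spectrum.components[0],
            budget=PhotonBudget(2000.0))
        stack = make_phantom(water_like, sim_schedule,
                             NoiseModel(shot_noise=True, seed=17),
                             water_optics)
        maps = reconstruct_stack(stack.frames, stack.positions_nm,
                                 sim_schedule, water_optics)
        spatial_sd = np.std(maps["shift_ghz"][maps["converged"]], ddof=1)
        rng = np.random.default_rng(23)
        shifts = []
        for _ in range(100):
            si, _ = simulate_measurement(water_spectrum, PhotonBudget(2000.0),
                                         sim_schedule, NoiseModel(),
                                         water_optics, rng=rng)
            r = InterferogramModel.from_sampled(si, water_optics).fit()
            if r.converged:
                shifts.append(r.shift_ghz)
        mc_sd = np.std(shifts, ddof=1)
        assert spatial_sd == pytest.approx(mc_sd, rel=0.20)

    def test_binning_halves_shot_noise_spread(self, water_optics, sim_schedule,
                                              water_spectrum):
        """2x2 binning sums 4x the photons, halving the shift-map s.d."""
        water_like = PhantomGeometry(
            shape=(16, 16), beads_um=(),
            background=water_spectrum.components[0],
            budget=PhotonBudget(2000.0))
        stack = make_phantom(water_like, sim_schedule,
                             NoiseModel(shot_noise=True, seed=29),
                             water_optics)
        m1 = reconstruct_stack(stack.frames, stack.positions_nm, sim_schedule,
                               water_optics)
        m2 = reconstruct_stack(stack.frames, stack.positions_nm, sim_schedule,
                               water_optics, binning=2)
        sd1 = np.std(m1["shift_ghz"][m1["converged"]], ddof=1)
        sd2 = np.std(m2["shift_ghz"][m2["converged"]], ddof=1)
        assert sd1 / sd2 == pytest.approx(2.0, rel=0.25)

    def test_frame_count_mismatch_is_hard_error(self, water_optics,
                                                water_schedule):
        frames = np.zeros((10, 2, 2))
        with pytest.raises(InvalidParameterError):
            reconstruct_stack(frames, water_schedule.positions_nm()[:10],
                              water_schedule, water_optics)

    def test_positions_schedule_mismatch_is_hard_error(self, water_optics,
                                                       water_schedule):
        n = water_schedule.n_positions
        frames = np.zeros((n, 2, 2))
        bad = water_schedule.positions_nm() + 1000.0
        with pytest.raises(InvalidParameterError):
            reconstruct_stack(frames, bad, water_schedule, water_optics)

    def test_reference_region_signing(self, water_optics, sim_schedule,
                                      water_spectrum):
        """A stack carrying the laser reference in a corner reconstructs the
        sample pixels correctly using the reference phase."""
        geom = PhantomGeometry(shape=(6, 6), beads_um=(),
                               background=water_spectrum.components[0],
                               budget=PhotonBudget(2000.0))
        stack = make_phantom(geom, sim_schedule, NoiseModel(shot_noise=False),
                             water_optics, reference_region=(0, 2, 0, 2),
                             reference_level=4000.0)
        maps = reconstruct_stack(stack.frames, stack.positions_nm,
                                 sim_schedule, water_optics,
                                 reference_region=(0, 2, 0, 2))
        truth = water_spectrum.components[0].shift_ghz
        sample = maps["shift_ghz"][3:, 3:]
        assert np.all(np.isfinite(sample))
        np.testing.assert_allclose(sample, truth, rtol=1e-3)
        assert np.all(np.isnan(maps["shift_ghz"][0:2, 0:2]))
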