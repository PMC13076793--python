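import numpy as np
import pytest
from scipy.signal import find_peaks

from pamangio.forward import (
    AcquisitionSpec,
    OpticalSpec,
    TransducerSpec,
    simulate_confocal_stack,
    simulate_pa_ascan,
    simulate_pam_stack,
    simulate_pulse_echo,
    transducer_impulse_response,
)
from pamangio.phantom import PhantomSpec, make_calibration_target
from pamangio.recon import assemble_volume, extract_envelope


def spectrum(waveform, acq, n_fft=1 << 16):
    mag = np.abs(np.fft.rfft(waveform, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=acq.dt_us)
    return freqs, mag


class TestSpecs:
    def test_transducer_validation(self):
        with pytest.raises(ValueError):
            TransducerSpec(center_frequency_mhz=-1.0)
        with pytest.raises(ValueError):
            TransducerSpec(fractional_bandwidth=2.5)

    def test_optics_validation(self):
        with pytest.raises(ValueError):
            OpticalSpec(numerical_aperture=1.5)
        with pytest.raises(ValueError):
            OpticalSpec(pam_attenuation_per_um=-0.1)

    def test_depth_per_sample(self, quiet_acquisition):
        assert quiet_acquisition.depth_per_sample_um == pytest.approx(3.08)

    def test_nyquist_violation(self, transducer):
        bad = AcquisitionSpec(sampling_rate_msps=40.0)
        with pytest.raises(ValueError, match="Nyquist"):
            transducer_impulse_response(transducer, bad)

    def test_default_lateral_psf(self, optics):
        assert optics.lateral_psf_fwhm_um == pytest.approx(0.51 * 0.532 / 0.12)

    def test_psf_override(self):
        assert OpticalSpec(psf_fwhm_um=2.42).lateral_psf_fwhm_um == 2.42


class TestImpulseResponse:
    def test_minus6db_band_edges(self, transducer, quiet_acquisition):
        h = transducer_impulse_response(transducer, quiet_acquisition)
        freqs, mag = spectrum(h, quiet_acquisition)
        peak = mag.max()
        for edge in (19.0 * (1 - 0.69 / 2), 19.0 * (1 + 0.69 / 2)):
            val = np.interp(edge, freqs, mag)
            assert val == pytest.approx(0.5 * peak, rel=0.02)

    def test_envelope_fwhm_matches_axial_resolution(
        self, transducer, quiet_acquisition
    ):
        # time-envelope FWHM mapped to one-way depth reproduces ~103.4 µm
        h = transducer_impulse_response(transducer, quiet_acquisition)
        env = extract_envelope(h)
        above = env >= env.max() / 2
        fwhm_samples = above.sum()
        fwhm_um = fwhm_samples * quiet_acquisition.depth_per_sample_um
        assert fwhm_um == pytest.approx(103.4, rel=0.05)

    def test_doubling_bandwidth_halves_duration(self, quiet_acquisition):
        def duration(b):
            h = transducer_impulse_response(
                TransducerSpec(fractional_bandwidth=b), quiet_acquisition)
            env = extract_envelope(h)
            return (env >= env.max() / 2).sum()

        assert duration(0.8) == pytest.approx(duration(0.4) / 2, abs=2)

    def test_unit_peak_zero_phase(self, transducer, quiet_acquisition):
        h = transducer_impulse_response(transducer, quiet_acquisition)
        assert h.size % 2 == 1
        assert h[h.size // 2] == pytest.approx(1.0)
        np.testing.assert_allclose(h, h[::-1], atol=1e-12)


class TestAScan:
    def test_point_absorber_peak_position(self, optics, transducer,
                                          quiet_acquisition):
        z0, dz = 300.0, 1.0
        profile = np.zeros(500)
        profile[int(z0 / dz)] = 1.0
        rf = simulate_pa_ascan(profile, dz, optics, transducer,
                               quiet_acquisition)
        env = extract_envelope(rf)
        expected = round(z0 * 500.0 / 1540.0)
        assert abs(int(np.argmax(env)) - expected) <= 1

    def test_two_absorbers_resolvable_vs_merged(self, transducer,
                                                quiet_acquisition):
        opt = OpticalSpec(pam_attenuation_per_um=0.0)

        def count_peaks(separation_um):
            profile = np.zeros(1000)
            profile[300] = 1.0
            profile[300 + int(separation_um)] = 1.0
            rf = simulate_pa_ascan(profile, 1.0, opt, transducer,
                                   quiet_acquisition)
            env = extract_envelope(rf)
            peaks, _ = find_peaks(env, height=0.3 * env.max(),
                                  prominence=0.2 * env.max())
            return len(peaks)

        assert count_peaks(200.0) == 2  # above the ~103 µm axial resolution
        assert count_peaks(20.0) == 1   # below it: merged

    def test_attenuated_absorber_comb_exponential_decay(self, transducer,
                                                        quiet_acquisition):
        # isolated scatterers every 120 µm: their envelope peaks must decay
        # with the configured attenuation coefficient
        k = 2.0 / 431.0
        opt = OpticalSpec(pam_attenuation_per_um=k)
        profile = np.zeros(1600)
        depths = np.arange(200, 1500, 120)
        profile[depths] = 1.0
        rf = simulate_pa_ascan(profile, 1.0, opt, transducer,
                               quiet_acquisition)
        env = extract_envelope(rf)
        peaks = [env[int(round(z * 500 / 1540)) - 3:
                     int(round(z * 500 / 1540)) + 4].max() for z in depths]
        slope = np.polyfit(depths.astype(float), np.log(peaks), 1)[0]
        assert -slope == pytest.approx(k, rel=0.10)

    def test_linearity(self, optics, transducer, quiet_acquisition):
        profile = np.zeros(400)
        profile[100:110] = 1.0
        rf1 = simulate_pa_ascan(profile, 1.0, optics, transducer,
                                quiet_acquisition)
        rf3 = simulate_pa_ascan(3.0 * profile, 1.0, optics, transducer,
                                quiet_acquisition)
        np.testing.assert_allclose(rf3, 3.0 * rf1, rtol=1e-9, atol=1e-12)

    def test_shift_covariance(self, transducer, quiet_acquisition):
        opt = OpticalSpec(pam_attenuation_per_um=0.0)

        def peak(z0):
            profile = np.zeros(700)
            profile[int(z0)] = 1.0
            env = extract_envelope(
                simulate_pa_ascan(profile, 1.0, opt, transducer,
                                  quiet_acquisition))
            return int(np.argmax(env))

        shift_samples = peak(450.0) - peak(300.0)
        assert abs(shift_samples - round(150.0 * 500 / 1540)) <= 1

    def test_empty_profile_zero_trace(self, optics, transducer,
                                      quiet_acquisition):
        rf = simulate_pa_ascan(np.array([]), 1.0, optics, transducer,
                               quiet_acquisition, n_samples=64)
        assert rf.shape == (64,)
        assert not rf.any()

    def test_seeded_noise_reproducible(self, optics, transducer):
        acq = AcquisitionSpec(noise_sigma=0.05, rng_seed=7)
        profile = np.zeros(300)
        profile[100] = 1.0
        a = simulate_pa_ascan(profile, 1.0, optics, transducer, acq)
        b = simulate_pa_ascan(profile, 1.0, optics, transducer, acq)
        np.testing.assert_array_equal(a, b)


class TestPamStack:
    def test_zero_phantom_zero_frames(self, optics, transducer,
                                      quiet_acquisition):
        from pamangio.phantom import PhantomSpec, VascularPhantom

        spec = PhantomSpec(volume_size_um=(40.0, 40.0, 60.0))
        ph = VascularPhantom(np.zeros(spec.grid_shape, np.float32), [], spec)
        frames = simulate_pam_stack(ph, optics, transducer, quiet_acquisition)
        assert not frames.samples.any()

    def test_fiber_band_at_depth(self, optics, transducer, quiet_acquisition):
        target = make_calibration_target("fiber", (100.0, 40.0, 600.0),
                                         fiber_diameter_um=6.0,
                                         fiber_depth_um=300.0)
        frames = simulate_pam_stack(target, optics, transducer,
                                    quiet_acquisition)
        vol = assemble_volume(frames)
        col = vol.amplitude[vol.shape[0] // 2, 0, :]
        depth = np.argmax(col) * vol.voxel_pitch_um[2]
        assert depth == pytest.approx(300.0, abs=6.0)

    def test_energy_decay_depth_uniform(self, transducer, quiet_acquisition):
        from pamangio.phantom import PhantomSpec, VascularPhantom

        spec = PhantomSpec(volume_size_um=(40.0, 40.0, 600.0))
        ph = VascularPhantom(np.ones(spec.grid_shape, np.float32), [], spec)
        opt = OpticalSpec(pam_attenuation_per_um=2.0 / 431.0)
        frames = simulate_pam_stack(ph, opt, transducer, quiet_acquisition)
        env = extract_envelope(frames.samples[0, 0])
        interior = env[40:180]
        # smoothed maxima are non-increasing (allow tiny ripple)
        running_max = np.maximum.accumulate(interior[::-1])[::-1]
        assert np.all(interior <= running_max * (1 + 1e-9))

    def test_step_mismatch_error(self, optics, transducer):
        target = make_calibration_target("edge", (40.0, 20.0, 60.0),
                                         edge_position_um=20.0)
        acq = AcquisitionSpec(lateral_step_um=3.0, noise_sigma=0.0)
        with pytest.raises(ValueError, match="integer multiple"):
            simulate_pam_stack(target, optics, transducer, acq)


class TestConfocal:
    def test_no_attenuation_depth_independent(self, quiet_acquisition,
                                              small_phantom):
        opt = OpticalSpec(lscm_attenuation_per_um=0.0)
        vol = simulate_confocal_stack(small_phantom, opt, quiet_acquisition)
        sums = vol.amplitude.sum(axis=(0, 1))
        occupancy = (small_phantom.absorber > 0).sum(axis=(0, 1))
        # intensity per occupied voxel does not depend on depth
        good = occupancy > 50
        ratio = sums[good] / occupancy[good]
        assert np.ptp(ratio) / ratio.mean() < 0.2

    def test_steeper_than_pam(self, quiet_acquisition, small_phantom):
        opt = OpticalSpec()
        conf = simulate_confocal_stack(small_phantom, opt, quiet_acquisition)
        z = conf.depth_axis_um()
        pam_curve = np.exp(-opt.pam_attenuation_per_um * z)
        lscm_curve = np.exp(-opt.lscm_attenuation_per_um * z)
        assert np.all(lscm_curve <= pam_curve + 1e-12)


class TestPulseEcho:
    def test_spectral_peak_at_center_frequency(self, transducer,
                                               quiet_acquisition):
        echo = simulate_pulse_echo(transducer, quiet_acquisition)
        freqs = np.fft.rfftfreq(1 << 16, d=quiet_acquisition.dt_us)
        mag = np.abs(np.fft.rfft(echo, n=1 << 16))
        assert freqs[np.argmax(mag)] == pytest.approx(19.0, abs=0.1)

    def test_two_way_bandwidth_narrower_by_sqrt2(self, transducer,
                                                 quiet_acquisition):
        from pamangio.characterize import estimate_bandwidth

        one = transducer_impulse_response(transducer, quiet_acquisition)
        echo = simulate_pulse_echo(transducer, quiet_acquisition)
        _, b_one = estimate_bandwidth(one, quiet_acquisition)
        _, b_two = estimate_bandwidth(echo, quiet_acquisition)
        assert b_two / b_one == pytest.approx(1.0 / np.sqrt(2.0), rel=0.02)
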