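"""Signal and spike analysis: filter chain, spectra, CSD, phase locking,
asymmetry, STTC, stationarity."""

import numpy as np
import pytest
from scipy import signal as sps

from ca1forge import analysis as ana


def sine(freq, duration_s=10.0, fs=2000.0, amp=1.0, phase=0.0):
    t = np.arange(0, duration_s, 1.0 / fs)
    return t, amp * np.sin(2 * np.pi * freq * t + phase)


class TestSplitBands:
    def test_theta_passband_preserves_8hz(self):
        _, x = sine(8.0)
        bands = ana.split_bands(x)
        ratio = bands["theta"].std() / (x.std() / np.sqrt(5))
        # downsampling preserves variance of an 8 Hz tone
        assert bands["theta"].std() >= 0.95 * bands["lfp_ds"].std()

    def test_theta_band_rejects_50hz(self):
        _, x = sine(50.0)
        bands = ana.split_bands(x)
        # compare away from filtfilt edge transients
        n = len(bands["lfp_ds"])
        core = slice(n // 4, 3 * n // 4)
        assert bands["theta"][core].std() \
            <= 0.01 * bands["lfp_ds"][core].std()

    def test_dc_offset_removed(self):
        _, x = sine(8.0)
        bands = ana.split_bands(x + 5.0)
        assert abs(bands["lfp_ds"].mean()) < 0.01

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ana.split_bands(np.zeros(10))

    def test_zero_phase_impulse_response_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = ana.zero_phase_filter(x, "lowpass", 100.0, 2000.0)
        np.testing.assert_allclose(y, y[::-1], atol=1e-12)
        # group delay ~ 0: impulse response peak stays at the center
        assert abs(int(np.argmax(np.abs(y))) - 2000) <= 1


class TestMultitaperPsd:
    def test_tone_peak_within_half_resolution(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20.0, 1 / 400.0)
        x = np.sin(2 * np.pi * 8.0 * t) + 0.1 * rng.standard_normal(
            len(t))
        freqs, psd = ana.multitaper_psd(x, fs=400.0, resolution_hz=1.5)
        assert abs(ana.peak_frequency(freqs, psd) - 8.0) <= 0.75

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400 * 30)
        freqs, psd = ana.multitaper_psd(x, fs=400.0)
        sel = (freqs > 5) & (freqs < 195)
        slope = np.polyfit(freqs[sel], psd[sel], 1)[0]
        # flat: relative trend over the band within 10% of the mean level
        assert abs(slope) * 190 < 0.1 * psd[sel].mean()

    def test_parseval_total_power_matches_variance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(400 * 20)
        freqs, psd = ana.multitaper_psd(x, fs=400.0)
        total = np.trapezoid(psd, freqs)
        assert abs(total - x.var()) / x.var() < 0.05

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ana.multitaper_psd(np.zeros(100), fs=400.0,
                               resolution_hz=1.5)


class TestWaveletSpectrogram:
    def test_pure_tone_ridge_at_tone_frequency(self):
        t = np.arange(0, 5.0, 1 / 400.0)
        x = np.sin(2 * np.pi * 40.0 * t)
        freqs, power = ana.wavelet_spectrogram(x)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        ridge = freqs[np.argmax(power[:, core], axis=0)]
        assert np.all(np.abs(ridge - 40.0) < 1.0)

    def test_chirp_ridge_increases(self):
        t = np.arange(0, 10.0, 1 / 400.0)
        x = sps.chirp(t, f0=5.0, f1=20.0, t1=10.0)
        freqs, power = ana.wavelet_spectrogram(x, fmax=40.0)
        core = slice(len(t) // 5, 4 * len(t) // 5)
        ridge = freqs[np.argmax(power[:, core], axis=0)]
        smooth = np.convolve(ridge, np.ones(101) / 101, mode="valid")
        assert np.all(np.diff(smooth) > -0.05)
        assert smooth[-1] > smooth[0] + 5.0

    def test_zero_signal_floored(self):
        _, power = ana.wavelet_spectrogram(np.zeros(1000))
        assert np.all(power == -300.0)


class TestCsd:
    def test_quadratic_profile_constant_csd(self):
        depths = np.linspace(0, 400, 9)
        profile = 0.001 * depths**2
        traces = np.outer(profile, np.ones(100))
        csd = ana.csd_1d(traces, depths)
        expected = -0.3 * 2 * 0.001
        np.testing.assert_allclose(csd, expected, rtol=1e-6)

    def test_linear_profile_zero_csd(self):
        depths = np.linspace(0, 400, 9)
        traces = np.outer(0.01 * depths, np.ones(50))
        csd = ana.csd_1d(traces, depths)
        np.testing.assert_allclose(csd, 0.0, atol=1e-12)

    def test_dipole_localized_to_generating_depths(self):
        depths = np.linspace(0, 400, 17)
        src, snk = 100.0, 300.0
        # forward model: potential from two point sources along depth
        v = (1.0 / np.maximum(np.abs(depths - src), 12.0)
             - 1.0 / np.maximum(np.abs(depths - snk), 12.0))
        traces = np.outer(v, np.ones(10))
        csd = ana.csd_1d(traces, depths)
        spacing = depths[1] - depths[0]
        # positive CSD marks the current source, negative the sink
        assert abs(depths[np.argmax(csd[:, 0])] - src) <= spacing
        assert abs(depths[np.argmin(csd[:, 0])] - snk) <= spacing

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            ana.csd_1d(np.zeros((2, 10)), [0.0, 1.0])


class TestPhaseLocking:
    def test_spikes_at_fixed_phase_recovered(self):
        fs = 400.0
        f = 8.0
        t = np.arange(0, 10.0, 1 / fs)
        theta = np.sin(2 * np.pi * f * t)
        # trough of sin at phase 3pi/2 of the argument; spikes placed 90
        # degrees after the trough
        trough_times = (0.75 + np.arange(5, 70)) / f * 1000.0
        spike_times = trough_times + 0.25 / f * 1000.0 * 0.5
        res = ana.phase_locking(spike_times, theta, fs=fs)
        assert res is not None
        assert res.vector_norm > 0.99
        assert abs(res.mean_angle_deg - 45.0) < 5.0

    def test_rayleigh_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_cells = 1000
        for _ in range(n_cells):
            angles = rng.uniform(0, 2 * np.pi, 50)
            _, p = ana.rayleigh_test(angles)
            rejections += p < 0.05
        rate = rejections / n_cells
        assert abs(rate - 0.05) <= 0.02

    def test_rayleigh_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        for kappa in (0.0, 0.5, 2.0):
            angles = rng.vonmises(1.0, kappa, 200) % (2 * np.pi)
            _, p = ana.rayleigh_test(angles)
            _, p_ref = pingouin.circ_rayleigh(angles)
            assert abs(p - p_ref) < 1e-3

    def test_von_mises_mean_recovered(self):
        rng = np.random.default_rng(5)
        true_mean = np.radians(200.0)
        angles = rng.vonmises(true_mean, 2.0, 500) % (2 * np.pi)
        c, s = np.cos(angles).sum(), np.sin(angles).sum()
        est = np.degrees(np.arctan2(s, c)) % 360
        assert abs(est - 200.0) < 5.0

    def test_too_few_spikes_excluded(self):
        theta = np.sin(2 * np.pi * 8.0 * np.arange(0, 2.0, 1 / 400.0))
        assert ana.phase_locking(np.array([10.0, 20.0]), theta) is None


class TestAsymmetryIndex:
    def test_pure_sine_symmetric(self):
        t = np.arange(0, 20.0, 1 / 400.0)
        x = np.sin(2 * np.pi * 6.0 * t)
        out = ana.asymmetry_index(x)
        assert out is not None
        _, mean = out
        assert abs(mean) < 0.05

    def test_sawtooth_one_to_three_ratio(self):
        # low fundamental keeps enough harmonics below the 80 Hz edge for
        # the waveform to stay close to an ideal sawtooth
        t = np.arange(0, 30.0, 1 / 400.0)
        x = sps.sawtooth(2 * np.pi * 3.0 * t, width=0.25)
        out = ana.asymmetry_index(x)
        assert out is not None
        _, mean = out
        assert abs(mean - np.log(1.0 / 3.0)) < 0.1

    def test_inverted_sawtooth_flips_sign(self):
        t = np.arange(0, 20.0, 1 / 400.0)
        x = sps.sawtooth(2 * np.pi * 6.0 * t, width=0.25)
        _, m1 = ana.asymmetry_index(x)
        _, m2 = ana.asymmetry_index(-x[::-1])
        # time reversal of the inverted wave has mirrored rise/decay
        assert np.sign(m1) == np.sign(m2)
        _, m3 = ana.asymmetry_index(sps.sawtooth(
            2 * np.pi * 6.0 * t, width=0.75))
        assert np.sign(m3) == -np.sign(m1)

    def test_no_cycles_flagged(self):
        assert ana.asymmetry_index(np.zeros(4000) + 1e-15) is None


def brute_force_sttc(a, b, dt, t_start, t_stop):
    grid = np.linspace(t_start, t_stop, 200_001)

    def tiled(train):
        hit = np.zeros(len(grid), dtype=bool)
        for s in train:
            hit |= np.abs(grid - s) <= dt
        return hit.mean()

    def prop(train, other):
        return np.mean([np.min(np.abs(other - s)) <= dt for s in train])

    ta, tb = tiled(a), tiled(b)
    pa, pb = prop(a, b), prop(b, a)
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


class TestSttc:
    def test_identical_trains_unity(self):
        train = np.sort(np.random.default_rng(6).uniform(0, 1000, 50))
        assert ana.sttc(train, train, t_stop=1010.0) > 0.999

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(20):
            a = np.sort(rng.uniform(0, 100_000, 500))
            b = np.sort(rng.uniform(0, 100_000, 500))
            vals.append(ana.sttc(a, b, t_stop=100_000.0))
        assert np.mean(np.abs(np.array(vals)) < 0.05) >= 0.95

    def test_matches_brute_force_on_small_trains(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = np.sort(rng.uniform(0, 2000, 20))
            b = np.sort(rng.uniform(0, 2000, 20))
            got = ana.sttc(a, b, dt_ms=10.0, t_start=0.0, t_stop=2000.0)
            ref = brute_force_sttc(a, b, 10.0, 0.0, 2000.0)
            assert abs(got - ref) < 0.01

    def test_symmetric_and_shift_invariant(self):
        rng = np.random.default_rng(9)
        a = np.sort(rng.uniform(0, 5000, 40))
        b = np.sort(rng.uniform(0, 5000, 60))
        s1 = ana.sttc(a, b, t_stop=5000.0)
        s2 = ana.sttc(b, a, t_stop=5000.0)
        assert np.isclose(s1, s2)
        shift = 500.0
        s3 = ana.sttc(a + shift, b + shift, t_start=shift,
                      t_stop=5000.0 + shift)
        assert np.isclose(s1, s3)

    def test_empty_train_flagged(self):
        with pytest.raises(ValueError):
            ana.sttc([], [1.0, 2.0])


class TestCorrelogramAndGain:
    def test_identical_trains_peak_at_zero_lag(self):
        train = np.sort(np.random.default_rng(10).uniform(0, 10_000, 200))
        lags, hist = ana.spike_correlogram(train, train)
        assert lags[np.argmax(hist)] == 0.0

    def test_copy_network_gain_unity(self):
        spikes = {0: np.arange(10.0), 1: np.arange(5.0)}
        gains = ana.io_gain(spikes, dict(spikes))
        assert gains["all"] == 1.0

    def test_gain_linear_in_output_count(self):
        inp = {0: np.arange(10.0)}
        g1 = ana.io_gain(inp, {0: np.arange(10.0)})["all"]
        g2 = ana.io_gain(inp, {0: np.arange(20.0)})["all"]
        assert np.isclose(g2, 2 * g1)


class TestAdf:
    def test_white_noise_stationary(self):
        x = np.random.default_rng(11).standard_normal(2000)
        stationary, _, p = ana.adf_check(x)
        assert stationary

    def test_random_walk_mostly_nonstationary(self):
        rng = np.random.default_rng(12)
        nonstat = 0
        n_seeds = 100
        for _ in range(n_seeds):
            walk = np.cumsum(rng.standard_normal(500))
            stationary, _, _ = ana.adf_check(walk, detrend=False)
            nonstat += not stationary
        assert nonstat >= 0.9 * n_seeds

    def test_linear_trend_removed_before_test(self):
        rng = np.random.default_rng(13)
        x = 0.05 * np.arange(2000) + rng.standard_normal(2000)
        stationary, _, _ = ana.adf_check(x, detrend=True)
        assert stationary

    def test_constant_signal_trivially_stationary(self):
        stationary, _, _ = ana.adf_check(np.ones(500))
        assert stationary
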