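"""FFT/STFT/CWT back-ends and instantaneous frequency-domain features."""

import numpy as np
import pytest

from standscore.spectral_features import (TimeFrequencyMap, cwt_scalogram,
                                          default_cwt_freqs, fft_psd,
                                          fft_summary_features,
                                          instantaneous_features,
                                          morlet_cwt, stft_spectrogram)
from standscore.time_features import total_power

FS = 2000.0


def tone(freq, dur=4.0, fs=FS, amp=1.0):
    t = np.arange(0, dur, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


from oracles import imdf_oracle, imnf_oracle


class TestFftPsd:
    def test_pure_tone_dominant_frequency(self):
        freqs, psd = fft_psd(tone(50.0), FS)
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(psd)] - 50.0) <= df / 2

    def test_two_equal_tones_mean_frequency(self):
        x = tone(40.0) + tone(120.0)
        feats = fft_summary_features(x, FS)
        df = FS / len(x)
        assert abs(feats["fft_mean_freq"] - 80.0) <= df

    def test_white_noise_median_near_half_nyquist(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2**18)
        feats = fft_summary_features(x, FS)
        assert abs(feats["fft_median_freq"] - FS / 4) / (FS / 4) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parseval_total_power(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(5000)
        _, psd = fft_psd(x, FS)
        assert abs(psd.sum() - total_power(x)) <= 1e-6 * total_power(x)


class TestStft:
    def test_stationary_tone_ridge_fixed(self):
        tf = stft_spectrogram(tone(100.0), FS)
        ridge = tf.freqs[np.argmax(tf.power, axis=0)]
        assert np.all(np.abs(ridge - 100.0) < 5.0)

    def test_step_change_switches_within_one_window(self):
        x = np.concatenate([tone(40.0, 2.0), tone(120.0, 2.0)])
        tf = stft_spectrogram(x, FS, window_s=0.3)
        ridge = tf.freqs[np.argmax(tf.power, axis=0)]
        switch_times = tf.times[np.abs(ridge - 120.0) < 10.0]
        assert switch_times.min() > 2.0 - 0.3
        assert switch_times.min() < 2.0 + 0.3

    def test_zero_signal_zero_map(self):
        tf = stft_spectrogram(np.zeros(4000), FS)
        assert np.all(tf.power == 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            stft_spectrogram(np.zeros(100), FS, window_s=0.3)


class TestCwt:
    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp
        dur = 4.0
        t = np.arange(0, dur, 1 / FS)
        x = chirp(t, f0=20.0, f1=200.0, t1=dur, method="linear")
        freqs = default_cwt_freqs(FS, 10, 400, 120)
        tf = cwt_scalogram(x, FS, freqs, time_stride=8)
        mask = tf.valid_time_mask
        ridge = tf.freqs[np.argmax(tf.power[:, mask], axis=0)]
        f_true = 20.0 + (200.0 - 20.0) * tf.times[mask] / dur
        rel_err = np.abs(ridge - f_true) / f_true
        assert np.median(rel_err) < 0.05

    def test_power_scales_quadratically(self):
        x = tone(60.0, 2.0)
        freqs = default_cwt_freqs(FS, 10, 400, 40)
        p1 = cwt_scalogram(x, FS, freqs).power
        p3 = cwt_scalogram(3 * x, FS, freqs).power
        np.testing.assert_allclose(p3, 9 * p1, rtol=1e-7,
                                   atol=1e-9 * p1.max())

    def test_kernel_train_cwt_vs_fft_contrast(self):
        # 25 Hz pulse train convolved with a 140 Hz evoked kernel: the FFT
        # peak sits on a stimulation harmonic (comb spectrum), while the
        # time-averaged scalogram peaks at the kernel's own frequency —
        # the wavelet exposes evoked-response content that is not locked
        # to the stimulation rate
        from standscore.simulate import EvokedKernel, evoked_kernel_waveform
        fs = 2000.0
        n = int(10 * fs)
        x = np.zeros(n)
        x[(np.arange(0.01, 10.0, 1 / 25.0) * fs).astype(int)] = 1.0
        g = evoked_kernel_waveform(EvokedKernel(140.0, duration_s=0.04), fs)
        x = np.convolve(x, g, mode="same")
        freqs = default_cwt_freqs(fs, 10, 300, 100)
        tf = cwt_scalogram(x, fs, freqs, time_stride=8)
        avg = tf.power[:, tf.valid_time_mask].mean(axis=1)
        peak = tf.freqs[np.argmax(avg)]
        assert 125.0 <= peak <= 155.0
        f, psd = fft_psd(x, fs)
        fft_peak = f[np.argmax(psd)]
        df = f[1] - f[0]
        assert abs(fft_peak / 25.0 - round(fft_peak / 25.0)) * 25.0 <= df

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cwt_scalogram(np.zeros(1000), FS, np.array([100.0, 1100.0]))

    def test_matches_pywavelets_oracle(self):
        """Dual-route check: our frequency-domain Morlet CWT against
        PyWavelets' cmor wavelet with the equivalent parameterization."""
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(4)
        fs, n = 500.0, 3000
        x = rng.standard_normal(n)
        # cap at 120 Hz: below that the discretized pywt wavelet is a
        # faithful reference (at very small scales its sampled wavelet
        # diverges slightly from the analytic form)
        freqs = np.linspace(20, 120, 12)
        ours = np.abs(morlet_cwt(x, fs, freqs)) ** 2
        # omega0 = 6 <-> cmor bandwidth fb = 2, center fc = 6 / (2 pi)
        wavelet = "cmor2.0-0.9549296585513721"
        scales = pywt.central_frequency(wavelet) * fs / freqs
        ref, _ = pywt.cwt(x, scales, wavelet, method="conv")
        ref = np.abs(ref) ** 2
        interior = slice(300, n - 300)
        for i in range(len(freqs)):
            r = np.corrcoef(ours[i, interior], ref[i, interior])[0, 1]
            # pywt discretizes the wavelet (integrated, interpolated,
            # truncated at +-8), so agreement is high but not exact
            assert r > 0.985
        # structural agreement: both transforms put the ridge of a tone on
        # the same frequency row
        x_tone = np.sin(2 * np.pi * 60.0 * np.arange(n) / fs)
        ours_t = np.abs(morlet_cwt(x_tone, fs, freqs)) ** 2
        ref_t, _ = pywt.cwt(x_tone, scales, wavelet, method="conv")
        ridge_ours = np.argmax(ours_t[:, interior].mean(axis=1))
        ridge_ref = np.argmax((np.abs(ref_t) ** 2)[:, interior].mean(axis=1))
        assert ridge_ours == ridge_ref

    def test_grid_density_robustness(self):
        rng = np.random.default_rng(9)
        x = tone(80.0, 4.0) + 0.3 * rng.standard_normal(int(4 * FS))
        vals = []
        for bins in (90, 120, 150):   # +-25% around the default density
            tf = cwt_scalogram(x, FS, default_cwt_freqs(FS, 4, 500, bins),
                               time_stride=8)
            vals.append(instantaneous_features(tf).imdf_mean)
        assert max(vals) / min(vals) < 1.08


class TestInstantaneousFeatures:
    def _map(self, power, freqs=None, times=None):
        power = np.asarray(power, dtype=float)
        freqs = np.arange(1.0, power.shape[0] + 1) if freqs is None else freqs
        times = np.arange(power.shape[1], dtype=float) if times is None else times
        return TimeFrequencyMap(power=power, freqs=np.asarray(freqs, float),
                                times=times, method="CWT")

    def test_single_line_spectrum(self):
        freqs = np.array([10.0, 40.0, 120.0])
        power = np.zeros((3, 5))
        power[1] = 7.0
        sf = instantaneous_features(self._map(power, freqs))
        assert sf.imdf_mean == 40.0 and sf.imdf_sd == 0.0
        assert sf.fmax_mean == 40.0 and sf.imnf_mean == 40.0

    def test_two_equal_lines_median_between(self):
        freqs = np.array([40.0, 80.0, 120.0])
        power = np.zeros((3, 4))
        power[0] = 1.0
        power[2] = 1.0
        sf = instantaneous_features(self._map(power, freqs))
        assert 40.0 <= sf.imdf_mean <= 120.0
        assert sf.imnf_mean == 80.0

    def test_alternating_frames_population_sd(self):
        freqs = np.array([40.0, 120.0])
        power = np.zeros((2, 10))
        power[0, ::2] = 1.0
        power[1, 1::2] = 1.0
        sf = instantaneous_features(self._map(power, freqs))
        assert sf.imdf_mean == pytest.approx(80.0)
        assert sf.imdf_sd == pytest.approx(40.0)

    def test_matches_oracles_on_random_maps(self, rng):
        for _ in range(100):
            nf = int(rng.integers(2, 12))
            nt = int(rng.integers(2, 12))
            freqs = np.sort(rng.uniform(1, 500, nf))
            while len(np.unique(freqs)) < nf:
                freqs = np.sort(rng.uniform(1, 500, nf))
            power = rng.uniform(0, 1, (nf, nt))
            power[rng.uniform(size=power.shape) < 0.3] = 0.0
            tf = self._map(power, freqs)
            totals = power.sum(axis=0)
            keep = totals > 0
            if not keep.any():
                continue
            sf = instantaneous_features(tf)
            imnf = [imnf_oracle(freqs, power[:, j])
                    for j in range(nt) if keep[j]]
            imdf = [imdf_oracle(freqs, power[:, j])
                    for j in range(nt) if keep[j]]
            assert sf.imnf_mean == pytest.approx(np.mean(imnf), abs=1e-12)
            assert sf.imdf_mean == pytest.approx(np.mean(imdf), abs=1e-12)
            assert sf.imdf_sd == pytest.approx(np.std(imdf), abs=1e-12)

    def test_all_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_features(self._map(np.zeros((3, 4))))

    def test_pmax_cv_definition(self):
        power = np.zeros((2, 3))
        power[0] = [1.0, 2.0, 3.0]
        sf = instantaneous_features(self._map(power))
        assert sf.pmax_cv == pytest.approx(sf.pmax_sd / sf.pmax_mean)


class TestTfMapPersistence:
    def test_hdf5_round_trip(self, tmp_path):
        from standscore.spectral_features import load_tfmap, save_tfmap
        tf = cwt_scalogram(tone(60.0, 1.0), FS,
                           default_cwt_freqs(FS, 10, 200, 20))
        path = tmp_path / "map.h5"
        save_tfmap(path, tf)
        back = load_tfmap(path)
        np.testing.assert_array_equal(back.power, tf.power)
        assert back.method == "CWT"
        assert back.edge_exclude_s == tf.edge_exclude_s
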