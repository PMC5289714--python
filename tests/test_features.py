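"""Feature extraction: DWT, STFT, EMD, Welch PSD, coherence, P300."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegresp import (EEGRecording, band_coefficients, coherence,
                     dominant_frequency, dwt_block_length, dwt_decompose,
                     emd_features, emd_sift, p300_extract, stft_features,
                     stft_frame_count, welch_psd)
from eegresp.features import is_imf


def _sine(freq, seconds, fs):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestDWT:
    def test_perfect_reconstruction(self):
        x = np.random.default_rng(0).standard_normal(4096)
        dec = dwt_decompose(x, fs=140.0)
        err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
        assert err < 1e-8

    def test_energy_conservation_on_long_signal(self):
        x = np.random.default_rng(1).standard_normal(2 ** 15)
        dec = dwt_decompose(x, fs=140.0)
        e_coef = sum(float(np.sum(b ** 2)) for b in dec.coeff_blocks)
        assert abs(e_coef / np.sum(x ** 2) - 1) < 0.01

    def test_theta_sinusoid_energy_concentrates_in_theta_block(self):
        x = _sine(6.0, 20.0, 140.0)
        dec = dwt_decompose(x, fs=140.0)
        energies = {lab: float(np.sum(b ** 2))
                    for b, (lab, *_r) in zip(dec.coeff_blocks, dec.band_map)}
        assert energies["D4"] / sum(energies.values()) >= 0.8
        assert dict((lab, band) for lab, band, _l, _h in dec.band_map)["D4"] == "theta"

    @pytest.mark.parametrize("n,level", [(8400, 1), (8400, 5), (16800, 3)])
    def test_block_length_recurrence_matches_transform(self, n, level):
        x = np.zeros(n)
        dec = dwt_decompose(x, fs=140.0, levels=level)
        # detail block of the deepest level has index 1 in wavedec order
        assert len(dec.coeff_blocks[1]) == dwt_block_length(n, level)

    def test_level1_detail_length_8400(self):
        assert dwt_block_length(8400, 1) == 4203

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            dwt_decompose(np.zeros(200), fs=140.0, levels=5)


@pytest.fixture(scope="module")
def dec():
    return dwt_decompose(np.random.default_rng(2).standard_normal(8400),
                         fs=140.0)


class TestBandCoefficients:

    def test_all_bands_is_complete(self, dec):
        v, _ = band_coefficients(dec, ("delta", "theta", "alpha", "beta", "gamma"))
        assert len(v) == sum(len(b) for b in dec.coeff_blocks)

    def test_delta_theta_count_from_recurrence(self, dec):
        v, meta = band_coefficients(dec, ("delta", "theta"))
        expect = (dwt_block_length(8400, 5)      # A5
                  + dwt_block_length(8400, 5)    # D5
                  + dwt_block_length(8400, 4))   # D4
        assert len(v) == expect
        assert {m["band"] for m in meta} == {"delta", "theta"}

    def test_empty_band_set(self, dec):
        v, meta = band_coefficients(dec, ())
        assert len(v) == 0 and meta == []

    def test_unknown_band(self, dec):
        with pytest.raises(KeyError):
            band_coefficients(dec, ("sigma",))


class TestSTFT:
    def test_frame_count_formula_120s(self):
        fs = 256.0
        v, meta = stft_features(np.zeros(int(120 * fs)), fs)
        frames = {m["frame"] for m in meta}
        assert len(frames) == 237 == stft_frame_count(int(120 * fs), int(2 * fs),
                                                      int(0.5 * fs))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(600, 20000), window=st.integers(64, 512),
           hop=st.integers(16, 256))
    def test_frame_count_property(self, n, window, hop):
        x = np.zeros(n)
        if n < window:
            return
        fs = 100.0
        v, meta = stft_features(x, fs, window_s=window / fs, hop_s=hop / fs,
                                nfft=4096)
        assert 1 + max(m["frame"] for m in meta) == (n - window) // hop + 1

    def test_peak_frequency_per_frame(self):
        fs = 256.0
        x = _sine(5.0, 20.0, fs)
        win, nfft = int(2 * fs), 4096
        taper = np.hamming(win)
        for start in (0, int(5 * fs)):
            spec = np.abs(np.fft.rfft(x[start:start + win] * taper, nfft))
            peak = np.fft.rfftfreq(nfft, 1 / fs)[np.argmax(spec)]
            assert abs(peak - 5.0) <= fs / nfft

    def test_zero_signal_hits_floor_without_nan(self):
        v, _ = stft_features(np.zeros(2048), 256.0)
        assert np.isfinite(v).all() and (v == v[0]).all()

    def test_nfft_smaller_than_window(self):
        with pytest.raises(ValueError):
            stft_features(np.zeros(4096), 256.0, nfft=256)


class TestEMD:
    FS = 256.0

    def test_two_tone_separation(self):
        t = np.arange(int(8 * self.FS)) / self.FS
        imfset = emd_sift(np.sin(2 * np.pi * 3 * t) + np.sin(2 * np.pi * 30 * t))
        assert abs(dominant_frequency(imfset.imfs[0], self.FS) - 30.0) < 1.0
        assert abs(dominant_frequency(imfset.imfs[1], self.FS) - 3.0) < 1.0

    def test_monotone_ramp_yields_no_imfs(self):
        imfset = emd_sift(np.linspace(0.0, 1.0, 1000))
        assert imfset.imfs == []
        np.testing.assert_array_equal(imfset.residue, np.linspace(0.0, 1.0, 1000))

    def test_additivity(self):
        x = np.random.default_rng(3).standard_normal(2000)
        imfset = emd_sift(x)
        err = np.linalg.norm(imfset.reconstruct() - x) / np.linalg.norm(x)
        assert err < 1e-6

    def test_imf_conditions_hold(self):
        t = np.arange(int(8 * self.FS)) / self.FS
        imfset = emd_sift(np.sin(2 * np.pi * 3 * t) + np.sin(2 * np.pi * 30 * t))
        for imf in imfset.imfs[:2]:
            assert is_imf(imf)

    def test_k_tone_imf_count(self):
        """A well-separated 3-tone mixture resolves into 3 leading IMFs on
        at least 90 % of random phase draws."""
        rng = np.random.default_rng(4)
        t = np.arange(int(8 * self.FS)) / self.FS
        hits = 0
        for _ in range(10):
            phases = rng.uniform(0, 2 * np.pi, 3)
            x = sum(np.sin(2 * np.pi * f * t + p)
                    for f, p in zip((2.0, 8.0, 32.0), phases))
            imfset = emd_sift(x)
            energies = [np.sum(i ** 2) for i in imfset.imfs]
            doms = [dominant_frequency(i, self.FS) for i, e in
                    zip(imfset.imfs, energies) if e > 0.01 * max(energies)]
            hits += (len(doms) >= 3
                     and abs(doms[0] - 32) < 2 and abs(doms[1] - 8) < 1
                     and abs(doms[2] - 2) < 1)
        assert hits >= 9

    @pytest.mark.parametrize("freqs,n_expected", [
        ((6.0,), 1), ((40.0,), 0), ((3.0, 6.0), 2)])
    def test_band_selection(self, freqs, n_expected):
        t = np.arange(int(8 * self.FS)) / self.FS
        x = sum(np.sin(2 * np.pi * f * t) for f in freqs)
        imfset = emd_sift(x)
        with pytest.warns() if n_expected == 0 else _nullcontext():
            v, meta = emd_features(imfset, self.FS)
        assert len({m["imf"] for m in meta}) == n_expected


def _nullcontext():
    import contextlib
    return contextlib.nullcontext()


class TestWelch:
    def test_white_noise_integrated_psd_matches_variance(self):
        fs = 128.0
        x = np.random.default_rng(5).standard_normal(int(120 * fs)) * 2.0
        freqs, psd = welch_psd(x, fs)
        total = np.trapezoid(psd, freqs)
        assert abs(total / 4.0 - 1) < 0.1

    def test_sinusoid_band_power(self):
        fs = 128.0
        x = 3.0 * _sine(10.0, 60.0, fs)
        freqs, psd = welch_psd(x, fs)
        sel = (freqs >= 8) & (freqs <= 12)
        assert abs(np.trapezoid(psd[sel], freqs[sel]) / (9 / 2) - 1) < 0.1

    def test_zero_signal(self):
        _, psd = welch_psd(np.zeros(1024), 128.0)
        assert (psd == 0).all()


@pytest.fixture(scope="module")
def noise():
    rng = np.random.default_rng(6)
    n = int(62 * 256)
    return rng.standard_normal(n), rng.standard_normal(n)


class TestCoherence:
    FS = 256.0

    def test_self_coherence_is_one(self, noise):
        c = coherence(noise[0], noise[0], self.FS)
        np.testing.assert_allclose(c.C_xy, 1.0, atol=1e-9)

    def test_independent_noise_low_coherence(self, noise):
        c = coherence(*noise, fs=self.FS)
        assert c.C_xy.mean() < 0.15

    def test_delay_preserves_coherence(self, noise):
        d = int(0.05 * self.FS)
        c = coherence(noise[0][:-d], noise[0][d:], self.FS)
        assert c.C_xy.mean() > 0.9

    def test_bounds_symmetry_and_scale_invariance(self, noise):
        x, y = noise[0], 0.5 * noise[0] + noise[1]
        c1 = coherence(x, y, self.FS)
        c2 = coherence(y, x, self.FS)
        c3 = coherence(7.5 * x, 7.5 * y, self.FS)
        assert ((c1.C_xy >= 0) & (c1.C_xy <= 1)).all()
        np.testing.assert_allclose(c1.C_xy, c2.C_xy, atol=1e-9)
        np.testing.assert_allclose(c1.C_xy, c3.C_xy, rtol=1e-9)
        assert c1.freqs[0] == 2.0 and c1.freqs[-1] == 30.0 and len(c1.freqs) == 29

    def test_single_segment_raises(self):
        with pytest.raises(ValueError):
            coherence(np.zeros(512), np.zeros(512), self.FS)


class TestP300:
    FS = 256.0

    def _erp(self, amplitude=5.0, latency_s=0.4, noise=1.0, n_targets=41, seed=0):
        rng = np.random.default_rng(seed)
        soa = int(1.5 * self.FS)
        n = soa * (n_targets + 5)
        data = noise * rng.standard_normal((2, n))
        width = int(0.3 * self.FS) | 1      # odd length: single peak sample
        peak = int(latency_s * self.FS)
        tmpl = amplitude * np.hanning(width)
        events = []
        for k in range(n_targets):
            onset = soa * k + soa // 2
            events.append((onset, "Target"))
            start = onset + peak - width // 2
            data[:, start:start + width] += tmpl
        return EEGRecording("S01", "R", "F", "ERP", ("Cz", "Pz"), self.FS, data,
                            event_log=events)

    def test_planted_peak_recovery_under_noise(self):
        feats = p300_extract(self._erp())
        for f in feats:
            assert abs(f.p300_latency - 400.0) <= 20.0
            assert abs(f.p300_amplitude - 5.0) <= 1.0
            assert f.n_trials_averaged == 41

    def test_noise_free_template_exact(self):
        feats = p300_extract(self._erp(noise=0.0, n_targets=5))
        for f in feats:
            assert abs(f.p300_latency - 400.0) <= 1000.0 / self.FS
            assert abs(f.p300_amplitude - 5.0) < 1e-9

    def test_extraction_is_linear_in_amplitude(self):
        one = p300_extract(self._erp(noise=0.0, n_targets=5))[0]
        two = p300_extract(self._erp(amplitude=10.0, noise=0.0, n_targets=5))[0]
        assert abs(two.p300_amplitude - 2 * one.p300_amplitude) < 1e-9
        assert two.p300_latency == one.p300_latency

    def test_no_target_events(self):
        rec = self._erp(n_targets=1)
        rec = rec.copy_with(event_log=[(10, "Standard")])
        with pytest.raises(ValueError):
            p300_extract(rec)
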