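"""Per-recording feature families.

Implements the time-frequency decompositions that feed the classifier:

* 5-level ``db4`` discrete wavelet transform; the delta (0.5-4 Hz) and theta
  (4-8.5 Hz) coefficient blocks are the primary feature set,
* short-time Fourier transform log band powers (Hamming window, 2 s window,
  0.5 s hop, 4096-point FFT),
* empirical mode decomposition by cubic-spline envelope sifting, with the
  delta/theta intrinsic mode functions as features,
* Welch averaged-periodogram PSD and pairwise magnitude-squared coherence
  C_xy(f) = |S_xy(f)|^2 / (S_x(f) S_y(f)) on a 2-30 Hz grid,
* P300 amplitude/latency from target-locked ERP averages (300-700 ms window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .synthetic_cohort import EEGRecording

#: canonical band edges (Hz) used to name dyadic DWT blocks and STFT bins
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.5),
    "alpha": (8.5, 17.5),
    "beta": (17.5, 35.0),
    "gamma": (35.0, 70.0),
}


def _band_of(center_hz: float) -> str:
    if center_hz < 4.0:
        return "delta"
    if center_hz < 8.5:
        return "theta"
    if center_hz < 17.5:
        return "alpha"
    if center_hz < 35.0:
        return "beta"
    return "gamma"


# ---------------------------------------------------------------------------
# discrete wavelet transform
# ---------------------------------------------------------------------------

@dataclass
class WaveletDecomposition:
    """db4 filter-bank decomposition with blocks [A_L, D_L, ..., D_1]."""

    wavelet_name: str
    levels: int
    fs: float
    n_samples: int
    coeff_blocks: list[np.ndarray]
    band_map: list[tuple[str, str, float, float]]  # (block label, band, lo, hi)

    def reconstruct(self) -> np.ndarray:
        x = pywt.waverec(self.coeff_blocks, self.wavelet_name, mode="symmetric")
        return x[: self.n_samples]

    def block(self, label: str) -> np.ndarray:
        for blk, (lab, *_rest) in zip(self.coeff_blocks, self.band_map):
            if lab == label:
                return blk
        raise KeyError(label)


def dwt_block_length(n: int, level: int, filter_length: int = 8) -> int:
    """Coefficient length after ``level`` halvings with symmetric extension.

    Follows the recurrence l_k = floor((l_{k-1} - 1) / 2) + filter_length / 2.
    """
    for _ in range(level):
        n = (n - 1) // 2 + filter_length // 2
    return n


def dwt_decompose(x: np.ndarray, fs: float, wavelet: str = "db4",
                  levels: int = 5) -> WaveletDecomposition:
    """Multi-level DWT with symmetric boundary extension.

    Block frequency ranges follow the dyadic halving of [0, fs/2]; each block
    is named after the canonical band containing its centre frequency, so at
    the 140 Hz analysis rate the final approximation and D5 together cover the
    printed delta band (0-4.375 Hz) and D4 is theta (4.375-8.75 Hz).
    """
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(wavelet)
    if x.size <= w.dec_len * 2 ** levels:
        raise ValueError(
            f"signal of length {x.size} too short for {levels} levels "
            f"(need > {w.dec_len * 2 ** levels})")
    blocks = pywt.wavedec(x, wavelet, mode="symmetric", level=levels)
    band_map = []
    hi = fs / 2 ** (levels + 1)
    band_map.append((f"A{levels}", _band_of(hi / 2), 0.0, hi))
    for k in range(levels, 0, -1):
        lo, hi = fs / 2 ** (k + 1), fs / 2 ** k
        band_map.append((f"D{k}", _band_of((lo + hi) / 2), lo, hi))
    return WaveletDecomposition(wavelet, levels, fs, x.size, list(blocks), band_map)


def band_coefficients(dec: WaveletDecomposition,
                      bands=("delta", "theta")) -> tuple[np.ndarray, list[dict]]:
    """Concatenate the coefficient blocks mapped to the requested bands.

    Returns the feature vector and per-coefficient metadata dicts
    ``{"band", "block", "index"}``.  Blocks outside ``bands`` (alpha, beta,
    gamma by default) are discarded.
    """
    known = {b for _, b, _, _ in dec.band_map}
    unknown = set(bands) - {"delta", "theta", "alpha", "beta", "gamma"}
    if unknown:
        raise KeyError(f"unknown band name(s): {sorted(unknown)}")
    missing = set(bands) - known
    if missing:
        raise KeyError(f"band(s) {sorted(missing)} not present in this decomposition")
    feats, meta = [], []
    for blk, (label, band, _lo, _hi) in zip(dec.coeff_blocks, dec.band_map):
        if band in bands:
            feats.append(blk)
            meta.extend({"band": band, "block": label, "index": i}
                        for i in range(len(blk)))
    if not feats:
        return np.empty(0), []
    return np.concatenate(feats), meta


# ---------------------------------------------------------------------------
# short-time Fourier transform
# ---------------------------------------------------------------------------

def stft_features(x: np.ndarray, fs: float, window_s: float = 2.0,
                  hop_s: float = 0.5, nfft: int = 4096,
                  bands=("delta", "theta"),
                  log_floor: float = 1e-12) -> tuple[np.ndarray, list[dict]]:
    """Log band power per STFT frame, restricted to the requested bands.

    Hamming-windowed frames of ``window_s`` seconds every ``hop_s`` seconds;
    frame count is floor((n - window) / hop) + 1.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if x.size < win:
        raise ValueError("signal shorter than the STFT window")
    if nfft < win:
        raise ValueError(f"nfft={nfft} smaller than the window ({win} samples)")
    n_frames = (x.size - win) // hop + 1
    taper = np.hamming(win)
    starts = np.arange(n_frames) * hop
    frames = np.stack([x[s:s + win] * taper for s in starts])
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    feats, meta = [], []
    for band in bands:
        lo, hi = BAND_EDGES[band]
        sel = (freqs >= lo) & (freqs < hi)
        bp = np.log10(power[:, sel].sum(axis=1) + log_floor)
        feats.append(bp)
        meta.extend({"band": band, "frame": f} for f in range(n_frames))
    return np.concatenate(feats), meta


def stft_frame_count(n: int, window: int, hop: int) -> int:
    return (n - window) // hop + 1


# ---------------------------------------------------------------------------
# empirical mode decomposition
# ---------------------------------------------------------------------------

@dataclass
class IMFSet:
    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int]

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residue if self.imfs else self.residue


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.where((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))[0]
    minima = np.where((np.hstack([d, 1]) > 0) & (np.hstack([-1, d]) < 0))[0]
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    # mirror two extrema beyond each boundary so the spline does not diverge
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    k = min(2, len(t))
    tl, vl = -t[:k][::-1], v[:k][::-1]
    tr, vr = 2 * (n - 1) - t[-k:][::-1], v[-k:][::-1]
    tt = np.concatenate([tl, t, tr])
    vv = np.concatenate([vl, v, vr])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], vv[keep])(np.arange(n))


def is_imf(x: np.ndarray, mean_tol: float = 0.05) -> bool:
    """Check the two IMF conditions: extrema/zero-crossing counts differing by
    at most one, and a mean negligible against the RMS."""
    maxima, minima = _local_extrema(x)
    n_ext = maxima.size + minima.size
    rms = np.sqrt(np.mean(x * x))
    if rms == 0:
        return False
    return (abs(n_ext - _zero_crossings(x)) <= 1
            and abs(x.mean()) / rms < mean_tol)


def emd_sift(x: np.ndarray, max_imfs: int = 10, sd_threshold: float = 0.2,
             max_siftings: int = 100) -> IMFSet:
    """Empirical mode decomposition by envelope-mean sifting.

    Each sifting pass interpolates the maxima and minima with cubic splines,
    subtracts the envelope mean, and stops once the normalised squared
    difference between consecutive iterates falls below ``sd_threshold`` and
    the candidate satisfies the IMF conditions.  Decomposition ends when the
    residue has fewer than two maxima or two minima (monotone-like).
    """
    x = np.asarray(x, dtype=float)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        n_sift = 0
        for _ in range(max_siftings):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            mean_env = 0.5 * (_envelope(maxima, h) + _envelope(minima, h))
            h_new = h - mean_env
            denom = np.sum(h * h)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            n_sift += 1
            if sd < sd_threshold and is_imf(h):
                break
        imfs.append(h)
        counts.append(n_sift)
        residue = residue - h
    return IMFSet(imfs, residue, counts)


def dominant_frequency(x: np.ndarray, fs: float, window_s: float = 2.0) -> float:
    """Frequency of the Welch PSD peak."""
    freqs, psd = welch_psd(x, fs, window_s=min(window_s, x.size / fs))
    return float(freqs[np.argmax(psd)])


def emd_features(imfset: IMFSet, fs: float, bands=("delta", "theta"),
                 rel_energy_floor: float = 0.01) -> tuple[np.ndarray, list[dict]]:
    """Samples of the IMFs whose dominant frequency falls in ``bands``.

    IMFs carrying less than ``rel_energy_floor`` of the strongest IMF's
    energy are ignored: sifting leaves low-energy boundary artifacts whose
    dominant frequency is spuriously low.
    """
    if not imfset.imfs:
        raise ValueError("IMF set is empty")
    lo = min(BAND_EDGES[b][0] for b in bands)
    hi = max(BAND_EDGES[b][1] for b in bands)
    energies = [float(np.sum(imf ** 2)) for imf in imfset.imfs]
    e_floor = rel_energy_floor * max(energies)
    feats, meta = [], []
    for k, imf in enumerate(imfset.imfs):
        if energies[k] < e_floor:
            continue
        # full-length periodogram: drift-like sifting artifacts then resolve
        # below the delta edge instead of aliasing onto it
        f0 = dominant_frequency(imf, fs, window_s=imf.size / fs)
        if lo <= f0 < hi:
            feats.append(imf)
            meta.extend({"imf": k, "index": i, "band": _band_of(f0)}
                        for i in range(imf.size))
    if not feats:
        warnings.warn("no IMF with dominant frequency in the requested bands")
        return np.empty(0), []
    return np.concatenate(feats), meta


# ---------------------------------------------------------------------------
# Welch PSD and magnitude-squared coherence
# ---------------------------------------------------------------------------

def welch_psd(x: np.ndarray, fs: float,
              window_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch averaged periodogram (Hann window, 50 % segment overlap)."""
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError("signal shorter than one Welch segment")
    return sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float],
               window_s: float = 2.0) -> float:
    """Integrated Welch PSD over [lo, hi] Hz."""
    freqs, psd = welch_psd(x, fs, window_s)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))


@dataclass
class CoherenceSpectrum:
    pair: tuple[str, str]
    freqs: np.ndarray
    C_xy: np.ndarray
    S_x: np.ndarray
    S_y: np.ndarray
    S_xy: np.ndarray


def coherence(x: np.ndarray, y: np.ndarray, fs: float, window_s: float = 2.0,
              fmin: float = 2.0, fmax: float = 30.0, df: float = 1.0,
              pair: tuple[str, str] = ("x", "y")) -> CoherenceSpectrum:
    """Magnitude-squared coherence |S_xy|^2 / (S_x S_y) on a fixed Hz grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    nper = int(round(window_s * fs))
    n_seg = (x.size - nper) // (nper // 2) + 1 if x.size >= nper else 0
    if n_seg < 2:
        raise ValueError(
            "coherence needs >= 2 averaging segments (a single segment is "
            "identically 1)")
    freqs, sxy = sps.csd(x, y, fs=fs, nperseg=nper, noverlap=nper // 2)
    _, sx = sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)
    _, sy = sps.welch(y, fs=fs, nperseg=nper, noverlap=nper // 2)
    cxy = np.abs(sxy) ** 2 / (sx * sy)
    grid = np.arange(fmin, fmax + df / 2, df)
    idx = np.array([np.argmin(np.abs(freqs - f)) for f in grid])
    return CoherenceSpectrum(pair, grid, cxy[idx], sx[idx], sy[idx], sxy[idx])


def recording_coherence(rec: EEGRecording, **kwargs) -> list[CoherenceSpectrum]:
    """Coherence for every unordered channel pair (171 pairs for 19 channels)."""
    out = []
    for a, b in combinations(range(rec.n_channels), 2):
        out.append(coherence(rec.data[a], rec.data[b], rec.fs,
                             pair=(rec.channel_labels[a], rec.channel_labels[b]),
                             **kwargs))
    return out


# ---------------------------------------------------------------------------
# P300
# ---------------------------------------------------------------------------

@dataclass
class ERPFeatures:
    channel: str
    p300_amplitude: float          # microvolt
    p300_latency: float            # milliseconds after stimulus onset
    n_trials_averaged: int
    search_window: tuple[float, float] = (300.0, 700.0)


def p300_extract(erp: EEGRecording, stimulus: str = "Target",
                 window_ms: tuple[float, float] = (300.0, 700.0),
                 baseline_ms: float = 100.0) -> list[ERPFeatures]:
    """Average target-locked epochs and locate the positive P300 peak.

    Epochs are baseline-corrected by the mean of the ``baseline_ms`` interval
    preceding stimulus onset; the amplitude is the maximum (positive-going
    peak) of the average inside the search window, the latency its time.
    """
    if erp.event_log is None:
        raise ValueError("recording has no event log")
    fs = erp.fs
    pre = int(round(baseline_ms / 1000 * fs))
    post = int(round(window_ms[1] / 1000 * fs)) + 1
    onsets = [i for i, s in erp.event_log
              if s == stimulus and i - pre >= 0 and i + post <= erp.n_samples]
    if not onsets:
        raise ValueError(f"no {stimulus!r} event with a full epoch window")
    epochs = np.stack([erp.data[:, i - pre:i + post] for i in onsets])  # trials x ch x t
    epochs = epochs - epochs[:, :, :pre].mean(axis=2, keepdims=True)
    avg = epochs.mean(axis=0)
    t_ms = np.arange(-pre, post) / fs * 1000
    sel = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    out = []
    for ci, ch in enumerate(erp.channel_labels):
        seg = avg[ci, sel]
        k = int(np.argmax(seg))
        out.append(ERPFeatures(ch, float(seg[k]), float(t_ms[sel][k]),
                               len(onsets), window_ms))
    return out
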