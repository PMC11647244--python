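"""Signal analysis: FFT peak statistics, STFT, coherence, wave speed,
correlation networks, Lempel-Ziv complexity, and the trial-based
induced/evoked high-frequency power analysis used for grating sessions.

All routines operate on 1-D recordings sampled at the model rate
(1000 Hz by default) or on collections of per-node signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SpectralPeaks",
    "fft_peaks",
    "stft",
    "wave_speed",
    "coherence",
    "CorrelationNetwork",
    "correlation_network",
    "lzc",
    "lz76_phrases",
    "HFPowerResult",
    "grating_analysis",
    "demodulation_spectrum",
]


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectralPeaks:
    """Detected spectral peaks of one recording.

    Peaks are local maxima of the magnitude spectrum above
    ``threshold_factor`` times the median magnitude (the noise floor);
    ``half_widths_hz`` is each peak's width at half power (-3 dB),
    measured by linear interpolation.
    """

    freqs_hz: np.ndarray
    magnitude: np.ndarray
    peak_freqs_hz: np.ndarray
    peak_heights: np.ndarray
    half_widths_hz: np.ndarray
    noise_floor: float
    threshold_factor: float
    window: str

    def __len__(self):
        return len(self.peak_freqs_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.peak_freqs_hz,
                "power": self.peak_heights**2,
                "half_width_hz": self.half_widths_hz,
            }
        )


def _half_width(freqs: np.ndarray, mag: np.ndarray, i: int) -> float:
    """Width of the peak at index i at half power (-3 dB, i.e. magnitude
    ``peak / sqrt(2)``), by linear interpolation — the standard spectral
    linewidth; for a Hann taper on a record of length T it equals 1.44/T."""
    half = mag[i] / np.sqrt(2.0)
    lo = i
    while lo > 0 and mag[lo - 1] < mag[lo]:
        lo -= 1
    hi = i
    while hi < len(mag) - 1 and mag[hi + 1] < mag[hi]:
        hi += 1
    left = freqs[lo]
    for j in range(i, lo, -1):
        if mag[j - 1] <= half <= mag[j]:
            frac = (mag[j] - half) / (mag[j] - mag[j - 1])
            left = freqs[j] - frac * (freqs[j] - freqs[j - 1])
            break
    right = freqs[hi]
    for j in range(i, hi):
        if mag[j + 1] <= half <= mag[j]:
            frac = (mag[j] - half) / (mag[j] - mag[j + 1])
            right = freqs[j] + frac * (freqs[j + 1] - freqs[j])
            break
    return right - left


def fft_peaks(
    recording: np.ndarray,
    fs_hz: float = 1000.0,
    threshold_factor: float = 5.0,
    window: str = "hann",
    pad_factor: int = 4,
    fmin_hz: float = 1.0,
) -> SpectralPeaks:
    """Magnitude-spectrum peaks above ``threshold_factor`` x median floor.

    The recording is tapered (Hann by default), zero-padded by
    ``pad_factor`` for finer interpolation, and local maxima above the
    median-magnitude noise floor are returned with FWHM estimates. An
    all-zero signal yields an empty peak set.
    """
    x = np.asarray(recording, dtype=float)
    if x.size < 8:
        raise ValueError("recording too short")
    x = x - x.mean()
    w = sps.get_window(window, len(x))
    n = pad_factor * len(x)
    mag = np.abs(np.fft.rfft(x * w, n=n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    floor = float(np.median(mag))
    if floor == 0.0:
        return SpectralPeaks(freqs, mag, np.array([]), np.array([]), np.array([]), 0.0, threshold_factor, window)
    # minimum peak separation: half the mainlobe of the taper
    dist = max(1, int(0.5 * pad_factor))
    idx, _ = sps.find_peaks(mag, height=threshold_factor * floor, distance=dist)
    idx = idx[freqs[idx] >= fmin_hz]
    widths = np.array([_half_width(freqs, mag, i) for i in idx])
    return SpectralPeaks(freqs, mag, freqs[idx], mag[idx], widths, floor, threshold_factor, window)


def stft(
    recording: np.ndarray,
    fs_hz: float = 1000.0,
    nperseg: int = 128,
    overlap: float = 0.75,
    window: str = "hann",
):
    """Short-time Fourier transform magnitude. Returns (freqs, times, |S|)."""
    x = np.asarray(recording, dtype=float)
    if nperseg > len(x):
        raise ValueError("window longer than the signal")
    hop = max(1, int(round(nperseg * (1.0 - overlap))))
    st = sps.ShortTimeFFT(sps.get_window(window, nperseg), hop=hop, fs=fs_hz, scale_to="magnitude")
    S = st.stft(x)
    t = st.t(len(x))
    return st.f, t, np.abs(S)


# ---------------------------------------------------------------------------
# wave speed


def wave_speed(
    probe_recording: np.ndarray,
    distance_mm: float,
    source_amplitude: float,
    threshold_fraction: float = 0.01,
    dt_ms: float = 1.0,
) -> float:
    """Propagation speed (mm/ms) from the first threshold crossing.

    Arrival is the first step where ``|recording|`` exceeds
    ``threshold_fraction * source_amplitude``. Raises ``TimeoutError``
    when the wave never arrives within the record.
    """
    x = np.abs(np.asarray(probe_recording, dtype=float))
    thresh = threshold_fraction * source_amplitude
    above = np.nonzero(x > thresh)[0]
    if len(above) == 0:
        raise TimeoutError("wavefront did not reach the probe within the run")
    arrival_ms = (above[0] + 1) * dt_ms
    return distance_mm / arrival_ms


# ---------------------------------------------------------------------------
# coherence


def coherence(
    rec_a: np.ndarray,
    rec_b: np.ndarray,
    fs_hz: float = 1000.0,
    nperseg: int = 256,
    noverlap: int | None = 0,
):
    """Welch magnitude-squared coherence. Returns (freqs, coherence)."""
    a = np.asarray(rec_a, float)
    b = np.asarray(rec_b, float)
    if a.shape != b.shape:
        raise ValueError("recordings must have equal length")
    if len(a) < 2 * nperseg:
        raise ValueError("need at least two windows for coherence")
    return sps.coherence(a, b, fs=fs_hz, nperseg=nperseg, noverlap=noverlap)


# ---------------------------------------------------------------------------
# correlation networks


@dataclass
class CorrelationNetwork:
    """Thresholded positive-correlation graph over sampled node signals."""

    r: np.ndarray
    rho_plus: float
    degrees: np.ndarray
    locations: list

    def degree_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(k values, P(k)) over the sampled nodes."""
        kmax = int(self.degrees.max()) if len(self.degrees) else 0
        counts = np.bincount(self.degrees, minlength=kmax + 1)
        return np.arange(kmax + 1), counts / counts.sum()

    def tail_weight(self, quantile: float = 0.9) -> float:
        """Mean degree above the given quantile, normalized by the mean
        degree — a simple heaviness-of-tail summary."""
        d = np.sort(self.degrees)
        cut = d[int(quantile * (len(d) - 1))]
        tail = d[d >= cut]
        return float(tail.mean() / max(d.mean(), 1e-12))


def correlation_network(
    signals: np.ndarray,
    rho_plus: float = 0.07,
    locations=None,
) -> CorrelationNetwork:
    """Pearson correlation matrix of per-node signals, thresholded at
    ``rho_plus``; ``signals`` has shape (n_nodes, n_steps). A node with
    zero variance has no defined correlation and raises ValueError."""
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 signals")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance signal(s) at rows {np.nonzero(sd == 0)[0].tolist()}")
    r = np.corrcoef(X)
    adj = (r >= rho_plus) & ~np.eye(len(r), dtype=bool)
    degrees = adj.sum(axis=1)
    return CorrelationNetwork(r, rho_plus, degrees, list(locations) if locations is not None else [])


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity


def lz76_phrases(bits) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing of a
    binary sequence (Kaspar-Schuster counting)."""
    if isinstance(bits, str):
        s = bits
    else:
        s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        # grow the phrase while s[i:i+L] is reproducible from an earlier
        # starting position (overlap with the phrase itself is allowed);
        # the first non-reproducible extension closes the phrase
        L = 1
        while i + L <= n and s.find(s[i : i + L]) < i:
            L += 1
        c += 1
        i += L
    return c


def lzc(recording: np.ndarray, normalized: bool = False) -> float:
    """Lempel-Ziv complexity of the median-binarized recording.

    Values above the median map to 1. A constant signal degenerates to
    the all-zero string (complexity of the trivial sequence is returned).
    ``normalized=True`` reports ``c * log2(n) / n`` for cross-length
    comparison.
    """
    x = np.asarray(recording, dtype=float)
    if x.size < 2:
        raise ValueError("recording too short")
    bits = x > np.median(x)
    c = lz76_phrases(bits)
    if normalized:
        n = len(bits)
        return c * np.log2(n) / n
    return float(c)


# ---------------------------------------------------------------------------
# induced / evoked high-frequency power (grating protocol)


@dataclass
class HFPowerResult:
    """Trial-based time-frequency analysis of a session recording.

    ``induced`` averages single-trial power (non-phase-locked content
    survives); ``evoked`` is the power of the trial-averaged signal
    (phase-locked content only). ``hf_envelope_*`` average the
    baseline-corrected power over 250-450 Hz; ``demod_*`` are the
    frequency-demodulation spectra of that envelope in the pre- and
    post-stimulus windows.
    """

    freqs_hz: np.ndarray
    times_s: np.ndarray
    induced: np.ndarray
    evoked: np.ndarray
    induced_raw: np.ndarray
    evoked_raw: np.ndarray
    hf_envelope_induced: np.ndarray
    hf_envelope_evoked: np.ndarray
    demod_freqs_hz: np.ndarray
    demod_pre_induced: np.ndarray
    demod_post_induced: np.ndarray
    demod_pre_evoked: np.ndarray
    demod_post_evoked: np.ndarray
    evoked_sem: np.ndarray | None = None


def _sliding_power(x: np.ndarray, fs: float, freqs: np.ndarray, win_ms: int) -> np.ndarray:
    """Hann-tapered sliding-window power at each frequency, hop 1 sample.

    Implemented as complex demodulation: convolving ``x * exp(-i 2 pi f t)``
    with a Hann taper equals the windowed Fourier coefficient at ``f``.
    Returns power[(len(x) - win + 1), len(freqs)] at window centres.
    """
    win = int(win_ms * fs / 1000.0)
    taper = np.hanning(win)
    t = np.arange(len(x)) / fs
    out = np.empty((len(x) - win + 1, len(freqs)))
    for i, f in enumerate(freqs):
        z = x * np.exp(-2j * np.pi * f * t)
        coef = sps.fftconvolve(z, taper[::-1], mode="valid")
        out[:, i] = np.abs(coef) ** 2
    return out


def demodulation_spectrum(
    envelope: np.ndarray, fs_hz: float = 1000.0, pad_to_s: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """FFT magnitude of a slow power envelope (Hann window, zero-padded)."""
    x = np.asarray(envelope, dtype=float)
    x = (x - x.mean()) * np.hanning(len(x))
    n = int(pad_to_s * fs_hz)
    mag = np.abs(np.fft.rfft(x, n=max(n, len(x))))
    freqs = np.fft.rfftfreq(max(n, len(x)), 1.0 / fs_hz)
    return freqs, mag


def grating_analysis(
    session: np.ndarray,
    trial_onsets: np.ndarray,
    fs_hz: float = 1000.0,
    freqs_hz: np.ndarray | None = None,
    win_ms: int = 50,
    baseline_s: tuple[float, float] = (-0.25, -0.1),
    pre_s: tuple[float, float] = (-0.6, -0.1),
    post_s: tuple[float, float] = (-0.1, 0.4),
    hf_band_hz: tuple[float, float] = (250.0, 450.0),
    analysis_span_s: tuple[float, float] = (-0.8, 0.9),
    evoked_block: int = 10,
) -> HFPowerResult:
    """Induced and evoked time-frequency power around grating onsets.

    Single Hann taper, 50 ms windows sliding in 1 ms steps, target
    frequencies 20-500 Hz in 20 Hz steps. Power is baseline-corrected as
    relative change against the per-frequency mean over ``baseline_s``.
    The high-frequency envelope (mean over 250-450 Hz) is frequency
    demodulated separately in the ``pre_s`` and ``post_s`` windows.
    Evoked variability (SEM) is estimated over ``evoked_block``-trial
    averages.
    """
    session = np.asarray(session, dtype=float)
    onsets = np.asarray(trial_onsets, dtype=int)
    if len(onsets) < 10:
        raise ValueError("need at least 10 trials")
    if freqs_hz is None:
        freqs_hz = np.arange(20.0, 500.1, 20.0)
    win = int(win_ms * fs_hz / 1000.0)
    lo = int(analysis_span_s[0] * fs_hz)
    hi = int(analysis_span_s[1] * fs_hz)
    seg_len = hi - lo
    if onsets[0] + lo - win // 2 < 0 or onsets[-1] + hi + win // 2 > len(session):
        raise ValueError("trial windows exceed the session")
    # cut trials with margin so every window centre in the span is valid
    margin = win // 2
    trials = np.stack([session[o + lo - margin : o + hi + margin] for o in onsets])
    n_trials = len(trials)
    power = np.empty((n_trials, seg_len + (2 * margin - win + 1), len(freqs_hz)))
    for j in range(n_trials):
        power[j] = _sliding_power(trials[j], fs_hz, freqs_hz, win_ms)
    n_centres = power.shape[1]
    times_s = (lo - margin + win // 2 + np.arange(n_centres)) / fs_hz
    induced_raw = power.mean(axis=0)
    mean_trial = trials.mean(axis=0)
    evoked_raw = _sliding_power(mean_trial, fs_hz, freqs_hz, win_ms)

    def _baseline_correct(P):
        bl = (times_s >= baseline_s[0]) & (times_s <= baseline_s[1])
        base = P[bl].mean(axis=0, keepdims=True)
        return (P - base) / np.where(base > 0, base, 1.0)

    induced = _baseline_correct(induced_raw)
    evoked = _baseline_correct(evoked_raw)
    band = (freqs_hz >= hf_band_hz[0]) & (freqs_hz <= hf_band_hz[1])
    env_ind = induced[:, band].mean(axis=1)
    env_evo = evoked[:, band].mean(axis=1)

    def _window(env, span):
        m = (times_s >= span[0]) & (times_s <= span[1])
        return env[m]

    dfreqs, dpre_i = demodulation_spectrum(_window(env_ind, pre_s), fs_hz)
    _, dpost_i = demodulation_spectrum(_window(env_ind, post_s), fs_hz)
    _, dpre_e = demodulation_spectrum(_window(env_evo, pre_s), fs_hz)
    _, dpost_e = demodulation_spectrum(_window(env_evo, post_s), fs_hz)

    evoked_sem = None
    if n_trials >= 2 * evoked_block:
        blocks = []
        for s in range(0, n_trials - evoked_block + 1, evoked_block):
            bm = trials[s : s + evoked_block].mean(axis=0)
            P = _baseline_correct(_sliding_power(bm, fs_hz, freqs_hz, win_ms))
            blocks.append(P[:, band].mean(axis=1))
        blocks = np.stack(blocks)
        evoked_sem = blocks.std(axis=0, ddof=1) / np.sqrt(len(blocks))

    return HFPowerResult(
        freqs_hz,
        times_s,
        induced,
        evoked,
        induced_raw,
        evoked_raw,
        env_ind,
        env_evo,
        dfreqs,
        dpre_i,
        dpost_i,
        dpre_e,
        dpost_e,
        evoked_sem,
    )
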