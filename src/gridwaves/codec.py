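"""Wave-interference encoding and exact decoding of stimuli.

Encoding is simply running the model: a stimulus ``v(x, t)`` added to the
activations produces an interference pattern ``A(x, t)``. Because every
spatial Fourier mode evolves independently through a known linear map
(:mod:`gridwaves.modes`), the map can be inverted:

* a *static* image ``I(x)`` presented with a known exposure profile
  ``f(t)`` can be recovered from a single snapshot ``A(x, tbar)`` by
  dividing each mode by its scalar response ``s_k(tbar)``;
* a *general* stimulus can be recovered from the full history ``A(x, t)``
  by running the per-mode state recursion backwards (exact per-step
  deconvolution).

Both inversions are exact up to floating-point conditioning. Modes whose
response scalar falls below ``COND_FLOOR`` times the largest response are
zeroed and reported instead of being amplified into noise; this is the
machine-precision failure mode of very late snapshots under damping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT, resample, resample_poly
from scipy.signal.windows import hann

from .model import GridState, ModelParams, Simulation, Stimulus
from .modes import evolve_analytic, laplacian_eigenvalues, mode_eigenvalues, mode_map, propagator_entries
from .stimuli import PointStimulus

__all__ = [
    "SeparableStimulus",
    "DecodedImage",
    "IllConditionedDecodeError",
    "encode",
    "mode_response",
    "decode_static_image",
    "decode_dynamic",
    "decode_dynamic_decimated",
    "AudioRoundtripResult",
    "audio_roundtrip",
    "load_image_grey",
    "save_field_png",
    "load_wav_1khz",
    "save_wav",
    "pearson",
]

#: relative conditioning floor for per-mode inversion
COND_FLOOR = 1e-12


class IllConditionedDecodeError(RuntimeError):
    def __init__(self, modes):
        self.modes = modes
        super().__init__(f"{len(modes)} modes are ill-conditioned; decode would amplify noise")


class SeparableStimulus(Stimulus):
    """Static image times an exposure profile: ``v(x, t) = I(x) f(t)``.

    ``exposure`` is a 1-D array; ``exposure[i]`` multiplies the image at
    step ``onset_step + i``. The default single-sample exposure is a
    one-step flash.
    """

    def __init__(self, image: np.ndarray, exposure=(1.0,), onset_step: int = 1):
        self.image = np.asarray(image, dtype=float)
        self.exposure = np.asarray(exposure, dtype=float)
        self.onset_step = int(onset_step)

    def field_at(self, t, shape):
        i = t - self.onset_step
        if 0 <= i < len(self.exposure) and self.exposure[i] != 0.0:
            return self.exposure[i] * self.image
        return None


@dataclass
class DecodedImage:
    I_hat: np.ndarray
    snapshot_time: int
    fidelity: float | None = None
    n_ill_conditioned: int = 0


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 0.0


def encode(
    stimulus: Stimulus,
    shape: tuple[int, int],
    params: ModelParams,
    n_steps: int,
    method: str = "simulate",
    snapshot_times=None,
):
    """Run the model on a stimulus and return the interference pattern.

    ``method="simulate"`` steps the lattice (any topology) and returns the
    dense history ``A[(0..n_steps), x, y]``; ``method="analytic"`` uses the
    closed-form mode solution (torus only) and returns frames for
    ``snapshot_times`` (default: all steps).
    """
    if method == "analytic":
        return evolve_analytic(GridState.zeros(shape), params, n_steps, stimulus, times=snapshot_times)
    sim = Simulation(shape, params)
    res = sim.run(
        GridState.zeros(shape),
        n_steps,
        stimulus=stimulus,
        record_history=snapshot_times is None,
        snapshot_times=snapshot_times,
    )
    if snapshot_times is None:
        return res.history
    return np.array([res.snapshots[int(t)] for t in snapshot_times])


def mode_response(params: ModelParams, shape, exposure, onset_step: int, tbar: int) -> np.ndarray:
    """Per-mode scalar response ``s_k(tbar)`` to the exposure profile:
    ``s_k = sum_i exposure[i] * [M^(tbar - onset - i + 1)]_00``."""
    mu = laplacian_eigenvalues(shape, params.neighborhood)
    M = mode_map(mu, params)
    z1, z2 = mode_eigenvalues(mu, params)
    s = np.zeros(mu.shape, dtype=complex)
    for i, w in enumerate(np.atleast_1d(exposure)):
        n = tbar - (onset_step + i) + 1
        if w == 0.0 or n < 1:
            continue
        s += w * propagator_entries(M, z1, z2, n)[0]
    return s


def decode_static_image(
    snapshot: np.ndarray,
    exposure,
    params: ModelParams,
    tbar: int,
    onset_step: int = 1,
    reference: np.ndarray | None = None,
    on_ill_conditioned: str = "zero",
) -> DecodedImage:
    """Recover a static image from one activation snapshot at time ``tbar``.

    Each spatial mode is divided by its known scalar response
    ``s_k(tbar)``; modes with ``|s_k| < COND_FLOOR * max|s|`` are zeroed
    (``on_ill_conditioned="zero"``) or raise
    :class:`IllConditionedDecodeError` (``"raise"``).
    """
    snapshot = np.asarray(snapshot, dtype=float)
    s = mode_response(params, snapshot.shape, exposure, onset_step, tbar)
    mag = np.abs(s)
    bad = mag < COND_FLOOR * mag.max() if mag.max() > 0 else np.ones_like(mag, dtype=bool)
    if bad.any() and on_ill_conditioned == "raise":
        raise IllConditionedDecodeError(list(zip(*np.nonzero(bad))))
    Ak = np.fft.fft2(snapshot)
    Ik = np.where(bad, 0.0, Ak / np.where(bad, 1.0, s))
    I_hat = np.fft.ifft2(Ik).real
    fid = pearson(I_hat, reference) if reference is not None else None
    return DecodedImage(I_hat, tbar, fid, int(bad.sum()))


def decode_dynamic(
    history: np.ndarray,
    params: ModelParams,
    pad_factor: int = 4,
) -> np.ndarray:
    """Recover the stimulus ``v(x, t)`` from the dense output history.

    ``history`` holds ``A(x, t)`` for ``t = 0 .. T`` starting from rest
    (the ``t = 0`` frame is all zeros). Each spatial mode is deconvolved
    in the frequency domain: ``v_k(omega) = A_k(omega) / H_k(omega)``
    with ``H_k`` the DFT of the per-mode impulse response, zero-padded by
    ``pad_factor`` to suppress circular wrap-around. Frequencies where
    ``|H_k| < COND_FLOOR * max|H_k|`` are floored to zero rather than
    amplified. Returns ``v[(1..T), x, y]`` aligned with the injection
    convention of :meth:`gridwaves.model.Simulation.run`.

    The deconvolution treats the record as the whole response, so the
    recovered late steps are accurate once the response to the stimulus
    has decayed within the recorded window (record beyond the stimulus
    for about ``1/(f+g)`` steps under light damping).
    """
    history = np.asarray(history, dtype=float)
    T = history.shape[0] - 1
    shape = history.shape[1:]
    N = 1 << int(np.ceil(np.log2(max(2, pad_factor * T))))
    mu = laplacian_eigenvalues(shape, params.neighborhood)
    M = mode_map(mu, params)
    z1, z2 = mode_eigenvalues(mu, params)
    # impulse response h[m] = [M^(m+1)]_00 (injection affects A the same step)
    m00 = M[..., 0, 0].ravel()
    zz1, zz2 = z1.ravel(), z2.ravel()
    dz = zz1 - zz2
    degenerate = np.abs(dz) <= 1e-12 * (np.abs(zz1) + np.abs(zz2) + 1e-30)
    dz = np.where(degenerate, 1.0, dz)
    n = np.arange(1, N + 1)[:, None]
    p1 = zz1[None, :] ** n
    p2 = zz2[None, :] ** n
    h = (p1 * (m00 - zz2) - p2 * (m00 - zz1)) / dz
    if degenerate.any():
        zd = zz1[None, :]
        h_deg = zd ** (n - 1) * (n * (m00 - zd) + zd)
        h = np.where(degenerate[None, :], h_deg, h)
    H = np.fft.fft(h, axis=0)
    Ak = np.fft.fft2(history[1:], axes=(1, 2)).reshape(T, -1)
    Aw = np.fft.fft(Ak, n=N, axis=0)
    mag = np.abs(H)
    floor = COND_FLOOR * mag.max(axis=0, keepdims=True)
    bad = mag < floor
    Vw = np.where(bad, 0.0, Aw / np.where(bad, 1.0, H))
    vk = np.fft.ifft(Vw, axis=0)[:T]
    return np.fft.ifft2(vk.reshape((T,) + shape), axes=(1, 2)).real


def decode_dynamic_decimated(
    history_coarse: np.ndarray,
    stride: int,
    params: ModelParams,
    **kw,
) -> np.ndarray:
    """Decode from a history known only every ``stride``-th step.

    The coarse frames are sinc-interpolated (Fourier resampling) back to
    the full step grid before exact deconvolution, so the recovered
    stimulus is band-limited to the coarse Nyquist band — stimuli with
    content above ``fs / (2 * stride)`` cannot be recovered from the
    subsampled output.
    """
    n_coarse = history_coarse.shape[0]
    full = resample(history_coarse, (n_coarse - 1) * stride + 1, axis=0)
    return decode_dynamic(full, params, **kw)


@dataclass
class AudioRoundtripResult:
    input_wave: np.ndarray
    recordings: dict
    spectrogram_correlation: dict
    input_spectrogram: np.ndarray
    recording_spectrograms: dict
    freqs_hz: np.ndarray


def _stft_mag(x: np.ndarray, fs: float = 1000.0, nperseg: int = 128) -> tuple[np.ndarray, np.ndarray]:
    stft = ShortTimeFFT(hann(nperseg, sym=False), hop=nperseg // 4, fs=fs, scale_to="magnitude")
    S = np.abs(stft.stft(x))
    return stft.f, S


def audio_roundtrip(
    waveform: np.ndarray,
    fs_in: float,
    shape: tuple[int, int] = (150, 150),
    params: ModelParams | None = None,
    inject_node: tuple[int, int] = (0, 0),
    record_nodes=((50, 0), (0, 50), (50, 50)),
    n_steps: int | None = None,
    amplitude: float = 1.0,
    stft_nperseg: int = 128,
    record_radius_mm: float = 1.0,
) -> AudioRoundtripResult:
    """Inject an audio waveform at one node and compare spectrograms.

    The waveform is anti-alias resampled to the model rate (1000 Hz),
    injected at ``inject_node``, and recorded at the ``record_nodes`` by
    LFP-scale disc electrodes (2 mm diameter by default; single-column
    recordings under-represent the lowest fundamentals relative to the
    lattice's own high-frequency ringing). Each recording's Hann-window
    STFT (window 128 at 1000 Hz -> 0-500 Hz band) is correlated with the
    input spectrogram.
    """
    from .electrodes import Electrode
    from .states import get_preset

    if params is None:
        params = get_preset("waking", size=max(shape)).params
    wave = np.asarray(waveform, dtype=float)
    if wave.size == 0:
        raise ValueError("empty waveform")
    fs_model = params.fs_hz
    if fs_in != fs_model:
        frac = _as_fraction(fs_model / fs_in)
        wave = resample_poly(wave, frac[0], frac[1])
    if n_steps is None:
        n_steps = len(wave)
    wave = wave[:n_steps]
    stim = PointStimulus(inject_node, amplitude * wave, onset_step=1)
    electrodes = [Electrode(tuple(n), record_radius_mm, id=f"n{n[0]}_{n[1]}") for n in record_nodes]
    sim = Simulation(shape, params)
    res = sim.run(GridState.zeros(shape), n_steps, stimulus=stim, electrodes=electrodes)
    f, S_in = _stft_mag(wave, fs_model, stft_nperseg)
    corr, specs = {}, {}
    for eid, rec in res.recordings.items():
        _, S = _stft_mag(rec, fs_model, stft_nperseg)
        specs[eid] = S
        corr[eid] = pearson(np.log10(S_in + 1e-12), np.log10(S + 1e-12))
    return AudioRoundtripResult(wave, res.recordings, corr, S_in, specs, f)


def _as_fraction(x: float, max_den: int = 10000) -> tuple[int, int]:
    from fractions import Fraction

    fr = Fraction(x).limit_denominator(max_den)
    return fr.numerator, fr.denominator


# ---------------------------------------------------------------------------
# image / audio file ingestion

LUMA = (0.2126, 0.7152, 0.0722)


def load_image_grey(
    path,
    shape: tuple[int, int],
    amplitude_range: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Read a raster image, convert to grey by luminance weights, resample
    to the grid with nearest-neighbour sampling and rescale linearly into
    ``amplitude_range``."""
    from PIL import Image

    img = np.asarray(Image.open(path), dtype=float)
    if img.ndim == 3:
        img = img[..., 0] * LUMA[0] + img[..., 1] * LUMA[1] + img[..., 2] * LUMA[2]
    ix = np.minimum((np.arange(shape[0]) + 0.5) * img.shape[0] // shape[0], img.shape[0] - 1)
    iy = np.minimum((np.arange(shape[1]) + 0.5) * img.shape[1] // shape[1], img.shape[1] - 1)
    img = img[ix.astype(int)][:, iy.astype(int)]
    lo, hi = float(img.min()), float(img.max())
    a, b = amplitude_range
    if hi > lo:
        img = a + (img - lo) * (b - a) / (hi - lo)
    else:
        img = np.full_like(img, a)
    return img


def save_field_png(path, field: np.ndarray) -> None:
    from PIL import Image

    f = np.asarray(field, dtype=float)
    lo, hi = f.min(), f.max()
    scaled = np.zeros_like(f) if hi <= lo else (f - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)


def load_wav_1khz(path) -> np.ndarray:
    """Read a PCM WAV and resample to the 1000 Hz model rate."""
    fs, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(raw.dtype, np.integer) and np.abs(data).max() > 0:
        data = data / np.abs(data).max()
    if fs != 1000:
        num, den = _as_fraction(1000.0 / fs)
        data = resample_poly(data, num, den)
    return data


def save_wav(path, x: np.ndarray, fs: int = 1000) -> None:
    x = np.asarray(x, dtype=float)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    wavfile.write(path, fs, (x * 32767).astype(np.int16))
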