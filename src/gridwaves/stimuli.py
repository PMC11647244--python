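"""Stimulus generators: pulse trains, sinusoids, noise, gratings,
complex bursts, synthetic songs and random grey images.

Every generator is deterministic given its spec and seed; nothing here
needs external data. Pulse trains with a non-integer period (sampling
rate / fundamental) are scheduled by accumulated-phase bookkeeping so the
average rate is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Stimulus, SumStimulus

__all__ = [
    "PointStimulus",
    "DenseStimulus",
    "FieldStimulus",
    "PulseTrainSpec",
    "GratingSpec",
    "ComplexBurstSpec",
    "make_pulse_train",
    "make_multi_pulse_train",
    "make_sinusoid",
    "make_noise",
    "make_grating",
    "make_states_input",
    "make_synthetic_song",
    "make_random_image",
]


class PointStimulus(Stimulus):
    """A time series injected at a single node."""

    def __init__(self, node: tuple[int, int], series: np.ndarray, onset_step: int = 1):
        self.node = tuple(node)
        self.series = np.asarray(series, dtype=float)
        self.onset_step = int(onset_step)

    def field_at(self, t, shape):
        i = t - self.onset_step
        if 0 <= i < len(self.series) and self.series[i] != 0.0:
            v = np.zeros(shape)
            v[self.node] = self.series[i]
            return v
        return None


class DenseStimulus(Stimulus):
    """Explicit ``v[(t - onset), x, y]`` array."""

    def __init__(self, v: np.ndarray, onset_step: int = 1):
        self.v = np.asarray(v, dtype=float)
        self.onset_step = int(onset_step)

    def field_at(self, t, shape):
        i = t - self.onset_step
        if 0 <= i < self.v.shape[0]:
            return self.v[i]
        return None


class FieldStimulus(Stimulus):
    """A fixed spatial field applied on a schedule ``on(t) -> bool/float``."""

    def __init__(self, field_xy: np.ndarray, profile, onset_step: int = 1):
        self.field_xy = np.asarray(field_xy, dtype=float)
        self.profile = profile
        self.onset_step = int(onset_step)

    def field_at(self, t, shape):
        w = float(self.profile(t - self.onset_step))
        if w == 0.0:
            return None
        return w * self.field_xy


@dataclass(frozen=True)
class PulseTrainSpec:
    """Periodic 1-step rectangular pulses at a single node."""

    fundamental_hz: float
    amplitude: float = 1.0
    node: tuple[int, int] = (0, 0)
    onset_step: int = 1
    duration_steps: int = 3000
    pulse_width_steps: int = 1
    fs_hz: float = 1000.0

    def __post_init__(self):
        if self.fundamental_hz > self.fs_hz / 2.0:
            raise ValueError("fundamental exceeds the Nyquist frequency")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental must be > 0")


def pulse_train_series(spec: PulseTrainSpec) -> np.ndarray:
    """The 0/amplitude series realizing the train with exact average rate."""
    series = np.zeros(spec.duration_steps)
    period = spec.fs_hz / spec.fundamental_hz
    # pulse k starts at k * period; exactly floor(duration / period) pulses
    # fit in [0, duration), guarded against float round-off at the boundary
    n_pulses = int(np.ceil(spec.duration_steps / period - 1e-9))
    starts = np.floor(np.arange(n_pulses) * period + 1e-9).astype(int)
    for i in starts:
        series[i : i + spec.pulse_width_steps] += spec.amplitude
    return series[: spec.duration_steps]


def make_pulse_train(spec: PulseTrainSpec) -> PointStimulus:
    return PointStimulus(spec.node, pulse_train_series(spec), spec.onset_step)


def make_multi_pulse_train(
    fundamentals_hz,
    node=(0, 0),
    amplitude: float = 1.0,
    duration_steps: int = 3000,
    onset_step: int = 1,
) -> PointStimulus:
    """Superimposed pulse trains at several fundamentals, one node."""
    series = np.zeros(duration_steps)
    for f0 in fundamentals_hz:
        series += pulse_train_series(
            PulseTrainSpec(f0, amplitude, node, onset_step, duration_steps)
        )
    return PointStimulus(node, series, onset_step)


def make_sinusoid(
    f0_hz: float,
    node=(0, 0),
    amplitude: float = 1.0,
    duration_steps: int = 3000,
    onset_step: int = 1,
    fs_hz: float = 1000.0,
) -> PointStimulus:
    if f0_hz > fs_hz / 2.0:
        raise ValueError("frequency exceeds the Nyquist frequency")
    t = np.arange(duration_steps)
    return PointStimulus(node, amplitude * np.sin(2.0 * np.pi * f0_hz * t / fs_hz), onset_step)


class NoiseStimulus(Stimulus):
    """Spatiotemporal white noise over the whole grid ("chaotic" drive).

    Fields are generated on the fly from a counter-based stream so long
    runs do not need the dense array in memory; deterministic in the seed.
    """

    def __init__(self, sigma: float, seed: int, onset_step: int = 1, duration_steps: int | None = None):
        self.sigma = float(sigma)
        self.seed = int(seed)
        self.onset_step = int(onset_step)
        self.duration_steps = duration_steps

    def field_at(self, t, shape):
        i = t - self.onset_step
        if i < 0 or (self.duration_steps is not None and i >= self.duration_steps):
            return None
        rng = np.random.default_rng((self.seed, i))
        return self.sigma * rng.standard_normal(shape)


def make_noise(seed: int, sigma: float = 1.0, onset_step: int = 1, duration_steps: int | None = None) -> NoiseStimulus:
    return NoiseStimulus(sigma, seed, onset_step, duration_steps)


@dataclass(frozen=True)
class GratingSpec:
    """Static circular grating: 8 alternating parallel stripes in a disc.

    Four stripes drive at +10 mV and four at -9 mV, clipped to a disc of
    10 mm radius; the field is injected every step of a 1 s on-period,
    flanked by 1 s of silence before and after, for 100 trials (300 s).
    """

    radius_mm: float = 10.0
    n_stripes: int = 8
    value_pos_mv: float = 10.0
    value_neg_mv: float = -9.0
    on_ms: int = 1000
    pre_ms: int = 1000
    post_ms: int = 1000
    n_trials: int = 100
    center: tuple[int, int] = (75, 75)
    orientation_deg: float = 0.0
    column_pitch_mm: float = 0.5

    @property
    def trial_ms(self) -> int:
        return self.pre_ms + self.on_ms + self.post_ms

    @property
    def session_steps(self) -> int:
        return self.trial_ms * self.n_trials


def grating_field(spec: GratingSpec, shape: tuple[int, int]) -> np.ndarray:
    """The static stripe field (mV per node)."""
    nx, ny = shape
    r_cols = spec.radius_mm / spec.column_pitch_mm
    cx, cy = spec.center
    if cx + r_cols > nx - 1 or cx - r_cols < 0 or cy + r_cols > ny - 1 or cy - r_cols < 0:
        raise ValueError("grating disc exceeds the grid")
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    disc = x * x + y * y <= r_cols * r_cols
    ang = np.deg2rad(spec.orientation_deg)
    u = x * np.cos(ang) + y * np.sin(ang)  # coordinate across the stripes
    stripe_w = 2.0 * r_cols / spec.n_stripes
    idx = np.floor((u + r_cols) / stripe_w).astype(int).clip(0, spec.n_stripes - 1)
    vals = np.where(idx % 2 == 0, spec.value_pos_mv, spec.value_neg_mv)
    return np.where(disc, vals, 0.0)


class GratingStimulus(Stimulus):
    """Trial-tiled static grating (constant drive during each on-period)."""

    def __init__(self, spec: GratingSpec, shape: tuple[int, int], onset_step: int = 1):
        self.spec = spec
        self.field_xy = grating_field(spec, shape)
        self.onset_step = int(onset_step)

    def trial_onsets(self) -> np.ndarray:
        """Step index of stimulus onset (start of the on-period) per trial."""
        s = self.spec
        return self.onset_step + s.pre_ms + np.arange(s.n_trials) * s.trial_ms

    def field_at(self, t, shape):
        s = self.spec
        i = t - self.onset_step
        if i < 0 or i >= s.session_steps:
            return None
        phase = i % s.trial_ms
        if s.pre_ms <= phase < s.pre_ms + s.on_ms:
            return self.field_xy
        return None


def make_grating(spec: GratingSpec, shape: tuple[int, int], onset_step: int = 1) -> GratingStimulus:
    return GratingStimulus(spec, shape, onset_step)


@dataclass(frozen=True)
class ComplexBurstSpec:
    """Short high-frequency bursts riding on a low-frequency wave.

    ``n_stimuli`` bursts with random onsets and random locations; the
    standard drive for comparing simulated brain states.
    """

    hf_carrier_hz: float = 300.0
    hf_burst_ms: int = 50
    lf_wave_hz: float = 5.0
    n_stimuli: int = 50
    amplitude: float = 1.0
    duration_steps: int = 3000
    seed: int = 0


def make_states_input(spec: ComplexBurstSpec, shape: tuple[int, int]) -> Stimulus:
    """The complex burst stimulus realized as a sum of point inputs."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.hf_burst_ms)
    parts = []
    for _ in range(spec.n_stimuli):
        node = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        onset = int(rng.integers(1, max(2, spec.duration_steps - spec.hf_burst_ms)))
        burst = spec.amplitude * np.sin(2.0 * np.pi * spec.hf_carrier_hz * t / 1000.0)
        envelope = 0.5 * (1.0 + np.sin(2.0 * np.pi * spec.lf_wave_hz * t / 1000.0))
        parts.append(PointStimulus(node, burst * envelope, onset))
    return SumStimulus(parts)


def make_synthetic_song(
    seed: int = 0,
    sr_hz: int = 44100,
    duration_s: float = 3.0,
    n_notes: int = 12,
) -> np.ndarray:
    """A synthetic "song": a sequence of harmonic tone stacks plus two
    chirps, all fundamentals below 500 Hz. Stands in for copyrighted
    audio in the encode/record/compare protocol; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n = int(sr_hz * duration_s)
    t = np.arange(n) / sr_hz
    x = np.zeros(n)
    # fixed log-spaced fundamentals guarantee >= n_notes distinct lines < 500 Hz
    fundamentals = np.geomspace(60.0, 460.0, n_notes)
    note_len = n // n_notes
    order = rng.permutation(n_notes)
    for slot, which in enumerate(order):
        f0 = fundamentals[which]
        seg = slice(slot * note_len, (slot + 1) * note_len)
        tt = t[seg] - t[seg.start]
        env = np.sin(np.pi * np.arange(len(tt)) / len(tt)) ** 2
        tone = np.sin(2 * np.pi * f0 * tt)
        for h, w in ((2, 0.4), (3, 0.2)):
            if f0 * h < 500.0:
                tone += w * np.sin(2 * np.pi * f0 * h * tt)
        x[seg] += env * tone
    for f_lo, f_hi in ((80.0, 400.0), (450.0, 120.0)):
        sweep = f_lo + (f_hi - f_lo) * t / duration_s
        phase = 2 * np.pi * np.cumsum(sweep) / sr_hz
        x += 0.3 * np.sin(phase)
    return x / np.abs(x).max()


def make_random_image(seed: int, shape: tuple[int, int]) -> np.ndarray:
    """Random grey-value field in [0, 1]."""
    return np.random.default_rng(seed).random(shape)
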