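"""Named parameter regimes reproducing simulated (patho)physiological states.

The waking state uses the printed grating-protocol parameters
(c2 = 2.6655, f = 0.01, g = 0.0001) on a 150x150 grid with the 8-neighbour
stencil, for which the stability bound is c2_max = (2+f)(2+g)/1.5 = 2.680:
waking coupling sits 0.55 % below the bound ("approaches its maximum").
The remaining states are defined relative to waking:

waking        printed parameters; near-maximal coupling, broadband HF
sws           coupling halved -> low-frequency resonance (slow-wave-like)
anesthesia    dampings raised (f x10, g x100) -> generally damped network
alzheimer     waking + random lesion mask (default 4 % of columns)
schizophrenia waking + random symmetric per-edge coupling jitter, with c2
              rescaled so the largest jittered coupling stays below the
              stability bound (uncorrelated "synaptic" impairment)
seizure       coupling 5 % above the stability bound -> runaway resonance

The SWS/anesthesia/disease multipliers are package choices (the originals
are not printed); they are flagged as approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GridState, LesionMask, ModelParams, Simulation, make_jitter_weights
from .modes import dispersion, stability_max_coupling
from .stimuli import ComplexBurstSpec, make_states_input
from .analysis import fft_peaks, lzc

__all__ = [
    "StatePreset",
    "PRESET_NAMES",
    "WAKING_C2",
    "WAKING_F",
    "WAKING_G",
    "get_preset",
    "build_simulation",
    "compare_states",
    "resonance_vs_size",
]

WAKING_C2 = 2.6655
WAKING_F = 0.01
WAKING_G = 0.0001

PRESET_NAMES = ("waking", "sws", "anesthesia", "alzheimer", "schizophrenia", "seizure")

SWS_C2_FACTOR = 0.5
ANESTHESIA_F_FACTOR = 10.0
ANESTHESIA_G_FACTOR = 100.0
ALZHEIMER_LESION_FRACTION = 0.04
SCHIZOPHRENIA_JITTER = 0.2
SEIZURE_OVERDRIVE = 1.05


@dataclass(frozen=True)
class StatePreset:
    name: str
    params: ModelParams
    shape: tuple[int, int]
    lesion_fraction: float = 0.0
    coupling_jitter: float = 0.0
    seed: int = 0


def get_preset(name: str, size: int = 150, seed: int = 0) -> StatePreset:
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    shape = (size, size)
    base = ModelParams(
        c2=WAKING_C2,
        f=WAKING_F,
        g=WAKING_G,
        neighborhood="moore-8",
        boundary="torus",
        renormalize=False,
    )
    if name == "waking":
        return StatePreset(name, base, shape, seed=seed)
    if name == "sws":
        return StatePreset(name, base.replace(c2=SWS_C2_FACTOR * WAKING_C2), shape, seed=seed)
    if name == "anesthesia":
        return StatePreset(
            name,
            base.replace(f=ANESTHESIA_F_FACTOR * WAKING_F, g=ANESTHESIA_G_FACTOR * WAKING_G),
            shape,
            seed=seed,
        )
    if name == "alzheimer":
        return StatePreset(name, base, shape, lesion_fraction=ALZHEIMER_LESION_FRACTION, seed=seed)
    if name == "schizophrenia":
        # the largest jittered edge coupling is (1 + j) * c2; rescale to
        # keep it below the waking coupling (itself just below the bound)
        c2 = WAKING_C2 / (1.0 + SCHIZOPHRENIA_JITTER)
        return StatePreset(name, base.replace(c2=c2), shape, coupling_jitter=SCHIZOPHRENIA_JITTER, seed=seed)
    # seizure: deliberately unstable
    c2max = stability_max_coupling(WAKING_F, WAKING_G, "moore-8")
    return StatePreset(name, base.replace(c2=SEIZURE_OVERDRIVE * c2max), shape, seed=seed)


def build_simulation(preset: StatePreset) -> Simulation:
    lesion = None
    weights = None
    if preset.lesion_fraction > 0:
        lesion = LesionMask.random(preset.shape, preset.lesion_fraction, preset.seed)
    if preset.coupling_jitter > 0:
        weights = make_jitter_weights(
            preset.shape, preset.params.neighborhood, preset.coupling_jitter, preset.seed
        )
    return Simulation(preset.shape, preset.params, lesion=lesion, edge_weights=weights)


def compare_states(
    names=("waking", "sws", "anesthesia"),
    size: int = 100,
    n_steps: int = 3000,
    burst_spec: ComplexBurstSpec | None = None,
    record_node: tuple[int, int] | None = None,
    electrode_radius_mm: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the same complex-burst input through several presets and
    tabulate complexity and spectral summaries (one row per preset).

    The stimulus is seed-shared so every state sees identical input. The
    default probe is EEG-scale (20 mm diameter): complexity comparisons
    between states are made on the integrated mesoscale signal, where
    incoherent unit-level jitter averages out.
    """
    from .electrodes import Electrode

    if burst_spec is None:
        burst_spec = ComplexBurstSpec(duration_steps=n_steps, seed=seed)
    if record_node is None:
        record_node = (size // 2, size // 2)
    rows = []
    for name in names:
        preset = get_preset(name, size=size, seed=seed)
        stim = make_states_input(burst_spec, preset.shape)
        sim = build_simulation(preset)
        electrode = Electrode(record_node, electrode_radius_mm, id="probe")
        res = sim.run(GridState.zeros(preset.shape), n_steps, stimulus=stim, electrodes=[electrode])
        rec = res.recordings["probe"]
        peaks = fft_peaks(rec)
        dom = peaks.peak_freqs_hz[np.argmax(peaks.peak_heights)] if len(peaks) else np.nan
        rows.append(
            {
                "state": name,
                "lzc": lzc(rec),
                "lzc_normalized": lzc(rec, normalized=True),
                "n_peaks": len(peaks),
                "dominant_freq_hz": dom,
            }
        )
    return pd.DataFrame(rows)


def resonance_vs_size(
    sizes=(3, 7, 34, 151),
    n_steps: int = 3000,
    n_impulses: int = 10,
    seed: int = 0,
    params: ModelParams | None = None,
) -> dict[int, int]:
    """Count resolvable resonance peaks of the self-organized response to
    random peak input, per model size.

    A peak counts when it rises above 1 % of the strongest line and is
    separated by at least 1 Hz — a relative criterion, because the mode
    spectrum of a large grid is dense and a median-floor criterion would
    drown in it. Larger grids support more distinct mode frequencies, so
    the count grows with size.
    """
    import scipy.signal as sps

    from .electrodes import unit_electrode
    from .stimuli import PointStimulus
    from .model import SumStimulus

    if params is None:
        params = ModelParams(c2=1.9, f=0.001, g=0.0001, boundary="torus", neighborhood="von-neumann-4")

    def _count(rec, fs=1000.0, rel=1e-2, sep_hz=1.0, pad=4):
        x = rec - rec.mean()
        n = pad * len(x)
        mag = np.abs(np.fft.rfft(x * sps.get_window("hann", len(x)), n=n))
        df = fs / n
        if mag.max() == 0:
            return 0
        idx, _ = sps.find_peaks(mag, height=rel * mag.max(), distance=max(1, int(sep_hz / df)))
        return len(idx)

    out = {}
    for size in sizes:
        rng = np.random.default_rng(seed)
        shape = (size, size)
        parts = []
        for _ in range(n_impulses):
            node = (int(rng.integers(size)), int(rng.integers(size)))
            onset = int(rng.integers(1, n_steps // 3))
            series = np.array([rng.uniform(0.5, 1.0)])
            parts.append(PointStimulus(node, series, onset))
        sim = Simulation(shape, params)
        probe = unit_electrode((size // 2, size // 3 if size > 2 else 0), id="probe")
        res = sim.run(GridState.zeros(shape), n_steps, stimulus=SumStimulus(parts), electrodes=[probe])
        out[size] = _count(res.recordings["probe"])
    return out


def preset_dispersion(preset: StatePreset):
    """Dispersion table of a preset (torus modes)."""
    return dispersion(preset.params, preset.shape)
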