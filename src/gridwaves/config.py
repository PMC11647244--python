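"""Run configuration: a YAML file fully determines a simulation.

Schema (all keys optional unless noted):

.. code-block:: yaml

    grid: {nx: 150, ny: 150}
    params: {c2: 2.6655, f: 0.01, g: 0.0001,
             neighborhood: moore-8, boundary: torus, renormalize: false}
    preset: waking            # overrides params/grid when given
    n_steps: 3000             # required unless a grating stimulus sets it
    seed: 0
    stimulus:                 # one of the generator kinds
      kind: pulse-train | multi-pulse-train | sinusoid | noise | grating |
            complex-bursts | none
      ...generator fields...
    electrodes:
      - {center: [75, 75], radius_mm: 0.25, id: probe, aggregate: mean}
    lesion: {fraction: 0.04}
    jitter: {magnitude: 0.2}
    output: {recordings_csv: out.csv, history_h5: out.h5}

Every stochastic element derives its seed from the top-level ``seed``.
The config hash (sha256 of the canonical YAML dump) is written into all
outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import electrodes as el
from . import stimuli as st
from .model import GridState, LesionMask, ModelParams, Simulation, make_jitter_weights
from .states import PRESET_NAMES, build_simulation, get_preset

__all__ = ["RunConfig", "load_config", "config_hash", "execute", "logger"]

logger = logging.getLogger("gridwaves")


class GridCfg(BaseModel):
    nx: int = Field(150, ge=1)
    ny: int = Field(150, ge=1)


class ParamsCfg(BaseModel):
    c2: float = Field(1.0, gt=0)
    f: float = Field(0.0, ge=0)
    g: float = Field(0.0, ge=0)
    neighborhood: str = "von-neumann-4"
    boundary: str = "clamped"
    renormalize: bool = True
    column_pitch_mm: float = 0.5
    dt_ms: float = 1.0


class StimulusCfg(BaseModel):
    kind: str = "none"
    node: tuple[int, int] = (0, 0)
    fundamental_hz: float | None = None
    fundamentals_hz: list[float] | None = None
    amplitude: float = 1.0
    sigma: float = 1.0
    duration_steps: int | None = None
    onset_step: int = 1
    grating: dict[str, Any] | None = None
    bursts: dict[str, Any] | None = None

    @field_validator("kind")
    @classmethod
    def _known(cls, v):
        kinds = ("none", "pulse-train", "multi-pulse-train", "sinusoid", "noise", "grating", "complex-bursts")
        if v not in kinds:
            raise ValueError(f"stimulus kind must be one of {kinds}")
        return v


class ElectrodeCfg(BaseModel):
    center: tuple[int, int]
    radius_mm: float = el.UNIT_RADIUS_MM
    id: str = ""
    aggregate: str = "mean"


class LesionCfg(BaseModel):
    fraction: float = Field(0.0, ge=0.0, le=1.0)


class JitterCfg(BaseModel):
    magnitude: float = Field(0.0, ge=0.0, lt=1.0)


class OutputCfg(BaseModel):
    recordings_csv: str | None = None
    history_h5: str | None = None


class RunConfig(BaseModel):
    grid: GridCfg = GridCfg()
    params: ParamsCfg = ParamsCfg()
    preset: str | None = None
    n_steps: int | None = None
    seed: int = 0
    stimulus: StimulusCfg = StimulusCfg()
    electrodes: list[ElectrodeCfg] = []
    lesion: LesionCfg = LesionCfg()
    jitter: JitterCfg = JitterCfg()
    output: OutputCfg = OutputCfg()

    @field_validator("preset")
    @classmethod
    def _preset_known(cls, v):
        if v is not None and v not in PRESET_NAMES:
            raise ValueError(f"unknown preset {v!r}")
        return v


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_stimulus(cfg: RunConfig, shape):
    s = cfg.stimulus
    dur = s.duration_steps or cfg.n_steps or 3000
    if s.kind == "none":
        return None, None
    if s.kind == "pulse-train":
        return st.make_pulse_train(
            st.PulseTrainSpec(s.fundamental_hz, s.amplitude, tuple(s.node), s.onset_step, dur)
        ), None
    if s.kind == "multi-pulse-train":
        return st.make_multi_pulse_train(s.fundamentals_hz, tuple(s.node), s.amplitude, dur, s.onset_step), None
    if s.kind == "sinusoid":
        return st.make_sinusoid(s.fundamental_hz, tuple(s.node), s.amplitude, dur, s.onset_step), None
    if s.kind == "noise":
        return st.make_noise(cfg.seed, s.sigma, s.onset_step, dur), None
    if s.kind == "grating":
        spec = st.GratingSpec(**(s.grating or {}))
        stim = st.make_grating(spec, shape, s.onset_step)
        return stim, stim.trial_onsets()
    if s.kind == "complex-bursts":
        spec = st.ComplexBurstSpec(**{"seed": cfg.seed, "duration_steps": dur, **(s.bursts or {})})
        return st.make_states_input(spec, shape), None
    raise AssertionError(s.kind)


def execute(cfg: RunConfig):
    """Run a configured simulation; returns (RunResult, metadata dict)."""
    if cfg.preset is not None:
        preset = get_preset(cfg.preset, size=cfg.grid.nx, seed=cfg.seed)
        sim = build_simulation(preset)
        shape, params = preset.shape, preset.params
    else:
        shape = (cfg.grid.nx, cfg.grid.ny)
        params = ModelParams(**cfg.params.model_dump())
        lesion = (
            LesionMask.random(shape, cfg.lesion.fraction, cfg.seed) if cfg.lesion.fraction > 0 else None
        )
        weights = (
            make_jitter_weights(shape, params.neighborhood, cfg.jitter.magnitude, cfg.seed)
            if cfg.jitter.magnitude > 0
            else None
        )
        sim = Simulation(shape, params, lesion=lesion, edge_weights=weights)
    stim, trial_onsets = _build_stimulus(cfg, shape)
    n_steps = cfg.n_steps
    if n_steps is None:
        if cfg.stimulus.kind == "grating":
            n_steps = int(st.GratingSpec(**(cfg.stimulus.grating or {})).session_steps)
        else:
            raise ValueError("n_steps is required")
    electrodes = [
        el.Electrode(tuple(e.center), e.radius_mm, e.id, e.aggregate) for e in cfg.electrodes
    ]
    meta = {
        "config_hash": config_hash(cfg),
        "shape": list(shape),
        "params": {
            "c2": params.c2,
            "f": params.f,
            "g": params.g,
            "neighborhood": params.neighborhood,
            "boundary": params.boundary,
            "renormalize": params.renormalize,
        },
        "n_steps": n_steps,
        "seed": cfg.seed,
    }
    logger.info("run %s", meta)
    res = sim.run(
        GridState.zeros(shape),
        n_steps,
        stimulus=stim,
        electrodes=electrodes,
        record_history=cfg.output.history_h5 is not None,
    )
    if trial_onsets is not None:
        meta["trial_onsets"] = np.asarray(trial_onsets).tolist()
    _write_outputs(cfg, res, meta)
    return res, meta


def _write_outputs(cfg: RunConfig, res, meta) -> None:
    if cfg.output.recordings_csv:
        frame = res.recordings_frame()
        with open(cfg.output.recordings_csv, "w") as fh:
            fh.write(f"# config_hash={meta['config_hash']}\n")
            frame.to_csv(fh, index=False, lineterminator="\n")
    if cfg.output.history_h5:
        import h5py

        with h5py.File(cfg.output.history_h5, "w") as h5:
            ds = h5.create_dataset("A", data=res.history)
            for k, v in meta["params"].items():
                ds.attrs[k] = v
            ds.attrs["config_hash"] = meta["config_hash"]
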