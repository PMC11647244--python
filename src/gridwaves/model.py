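"""Lattice state and the discrete update rule.

The substrate is a square grid of virtual oscillators ("columns"). Each node
carries an activation ``A`` and a lateral-feedback variable ``Delta`` which is
the running time-integral of the grid Laplacian of ``A``. One update step
(1 ms of model time) is:

1. ``lap = mean over neighbours of (A_neighbour - A_node)``   (grid Laplacian)
2. ``Delta <- (Delta + c2 * lap) / (1 + f)``
3. ``A     <- (A + Delta) / (1 + g)``

With ``c2 = 1`` and ``f = g = 0`` this is the bare twice-integrated-Laplacian
rule; ``c2`` scales the lateral coupling, ``f`` damps the feedback and ``g``
damps the activation. The update is linear, so stimuli superpose exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "GridState",
    "LesionMask",
    "Stimulus",
    "Lattice",
    "Simulation",
    "RunResult",
    "InstabilityError",
    "DegenerateTopologyError",
]

NEIGHBOR_OFFSETS = {
    "von-neumann-4": ((1, 0), (-1, 0), (0, 1), (0, -1)),
    "moore-8": ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)),
}

#: Amplitudes beyond this are treated as numerically diverged even before
#: float64 overflow produces non-finite values.
OVERFLOW_LIMIT = 1e120


class InstabilityError(RuntimeError):
    """Trajectory left the stable regime (non-finite or overflowing values)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"simulation became unstable at step {step}")


class DegenerateTopologyError(ValueError):
    """Grid too small to have any lateral neighbours."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the lattice update rule.

    c2
        Lateral feedback coupling (> 0). Multiplies the grid Laplacian
        contribution; interpreted as excitatory transmission efficacy.
    f, g
        Dampings (>= 0) of the lateral feedback and of the activation.
        The derived per-step suppressions are ``delta1 = f/(1+f)`` and
        ``delta2 = g/(1+g)``; for small damping the impulse-energy decay
        timescale is about ``1/(f+g)`` steps.
    neighborhood
        ``"von-neumann-4"`` (default) or ``"moore-8"``.
    boundary
        ``"clamped"`` (default): edge nodes simply have fewer neighbours.
        ``"torus"``: periodic wrap; required by the analytic engine.
    renormalize
        If True (default) a node averages over its *actual* live neighbour
        count. If False the divisor is the full stencil size (4 or 8) and
        missing or lesioned neighbours contribute zero activation. The
        fixed-divisor rule bounds the Laplacian spectrum by the full-torus
        extreme for every lesion pattern (eigenvalue interlacing), so runs
        close to the stability limit stay stable under lesioning.
    column_pitch_mm, dt_ms
        Physical calibration: one column = 0.5 mm, one step = 1 ms
        (sampling rate 1000 Hz).
    """

    c2: float = 1.0
    f: float = 0.0
    g: float = 0.0
    neighborhood: str = "von-neumann-4"
    boundary: str = "clamped"
    renormalize: bool = True
    column_pitch_mm: float = 0.5
    dt_ms: float = 1.0

    def __post_init__(self):
        if self.c2 <= 0:
            raise ValueError(f"c2 must be > 0, got {self.c2}")
        if self.f < 0 or self.g < 0:
            raise ValueError("dampings f and g must be >= 0")
        if self.neighborhood not in NEIGHBOR_OFFSETS:
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.boundary not in ("clamped", "torus"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def delta1(self) -> float:
        return self.f / (1.0 + self.f)

    @property
    def delta2(self) -> float:
        return self.g / (1.0 + self.g)

    @property
    def d(self) -> float:
        """Combined damping factor (1+f)(1+g)."""
        return (1.0 + self.f) * (1.0 + self.g)

    @property
    def stencil_size(self) -> int:
        return len(NEIGHBOR_OFFSETS[self.neighborhood])

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class GridState:
    """Activation and lateral-feedback fields on the lattice."""

    A: np.ndarray
    Delta: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=float)
        if self.A.shape != self.Delta.shape:
            raise ValueError("A and Delta must have identical shape")
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "GridState":
        return cls(np.zeros(shape), np.zeros(shape), 0)

    @classmethod
    def random(cls, shape: tuple[int, int], seed: int, amplitude: float = 1.0) -> "GridState":
        rng = np.random.default_rng(seed)
        return cls(amplitude * rng.standard_normal(shape), np.zeros(shape), 0)

    def copy(self) -> "GridState":
        return GridState(self.A.copy(), self.Delta.copy(), self.t)


@dataclass(frozen=True)
class LesionMask:
    """Boolean field of inactivated nodes."""

    inactive: np.ndarray
    fraction: float
    seed: int | None = None

    @classmethod
    def random(cls, shape: tuple[int, int], fraction: float, seed: int) -> "LesionMask":
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        n = shape[0] * shape[1]
        n_off = int(round(fraction * n))
        rng = np.random.default_rng(seed)
        flat = np.zeros(n, dtype=bool)
        flat[rng.choice(n, size=n_off, replace=False)] = True
        return cls(flat.reshape(shape), fraction, seed)

    @classmethod
    def none(cls, shape: tuple[int, int]) -> "LesionMask":
        return cls(np.zeros(shape, dtype=bool), 0.0, None)


class Stimulus:
    """Base class: a time-and-space input ``v(x, t)``.

    ``field_at(t)`` returns the field injected *before* the step that
    advances the state from ``t - 1`` to ``t`` (None means no input).
    Subclasses live in :mod:`gridwaves.stimuli` and :mod:`gridwaves.codec`.
    """

    onset_step: int = 1

    def field_at(self, t: int, shape: tuple[int, int]) -> np.ndarray | None:
        raise NotImplementedError

    def __add__(self, other: "Stimulus") -> "SumStimulus":
        return SumStimulus([self, other])


class SumStimulus(Stimulus):
    def __init__(self, parts: Sequence[Stimulus]):
        self.parts = list(parts)

    def field_at(self, t, shape):
        out = None
        for p in self.parts:
            v = p.field_at(t, shape)
            if v is not None:
                out = v.copy() if out is None else out + v
        return out


class Lattice:
    """Precomputed neighbour bookkeeping for one grid shape.

    Holds the live-node mask, per-node divisor and optional symmetric
    per-edge coupling weights, and evaluates the grid Laplacian.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        params: ModelParams,
        lesion: LesionMask | None = None,
        edge_weights: Mapping[tuple[int, int], np.ndarray] | None = None,
    ):
        nx, ny = shape
        if params.boundary == "clamped" and max(nx, ny) < 2:
            raise DegenerateTopologyError("clamped grid needs at least 2 nodes in some dimension")
        if params.boundary == "torus" and min(nx, ny) < 3:
            raise ValueError("torus grids need at least 3 nodes per dimension")
        self.shape = shape
        self.params = params
        self.offsets = NEIGHBOR_OFFSETS[params.neighborhood]
        self.live = np.ones(shape, dtype=bool) if lesion is None else ~lesion.inactive
        if not self.live.any():
            raise ValueError("lesion leaves no live nodes")
        self.livef = self.live.astype(float)
        if edge_weights is not None:
            self.weights = {o: np.asarray(edge_weights[o], dtype=float) for o in self.offsets}
            self._check_weight_symmetry()
        else:
            self.weights = None
        # live-neighbour counts: unweighted (the divisor k) and weighted
        # (the coefficient of the -A term when couplings are jittered)
        k_uw = np.zeros(shape)
        k_w = np.zeros(shape)
        for o in self.offsets:
            n_live = self._shift(self.livef, o)
            k_uw += n_live
            k_w += n_live * self.weights[o] if self.weights is not None else n_live
        self.k_live = k_uw
        if params.renormalize:
            self.divisor = np.where(k_uw > 0, k_uw, 1.0)
            self.center_coeff = np.where(k_uw > 0, k_w, 0.0)
        else:
            K = float(params.stencil_size)
            self.divisor = K
            # missing/dead neighbours contribute (0 - A)/K with unit weight
            self.center_coeff = k_w + (K - k_uw)

    def _check_weight_symmetry(self):
        for o in self.offsets:
            no = (-o[0], -o[1])
            exists = self._shift(np.ones(self.shape), o) > 0
            mirrored = self._shift(self.weights[no], o)
            if not np.allclose(self.weights[o][exists], mirrored[exists]):
                raise ValueError("edge weights must be symmetric: W_o(x) == W_{-o}(x+o)")

    def _shift(self, X: np.ndarray, o: tuple[int, int]) -> np.ndarray:
        """Value of X at the neighbour x+o, with the boundary rule applied."""
        if self.params.boundary == "torus":
            return np.roll(X, shift=(-o[0], -o[1]), axis=(0, 1))
        out = np.zeros_like(X)
        nx, ny = X.shape
        sx = slice(max(o[0], 0), nx + min(o[0], 0))
        dx = slice(max(-o[0], 0), nx + min(-o[0], 0))
        sy = slice(max(o[1], 0), ny + min(o[1], 0))
        dy = slice(max(-o[1], 0), ny + min(-o[1], 0))
        out[dx, dy] = X[sx, sy]
        return out

    def laplacian(self, A: np.ndarray) -> np.ndarray:
        """Mean activation difference over neighbours (the grid Laplacian)."""
        Am = A * self.livef
        S = np.zeros(self.shape)
        for o in self.offsets:
            term = self._shift(Am, o)
            if self.weights is not None:
                term = term * self.weights[o]
            S += term
        lap = (S - self.center_coeff * Am) / self.divisor
        return lap * self.livef


@dataclass
class RunResult:
    """Outputs of :meth:`Simulation.run`."""

    recordings: dict
    snapshots: dict
    history: np.ndarray | None
    final: GridState
    time_ms: np.ndarray | None = None

    def recordings_frame(self):
        """Long-format DataFrame (time_ms, electrode_id, value)."""
        import pandas as pd

        rows = []
        for eid, values in self.recordings.items():
            t = np.arange(1, len(values) + 1, dtype=float)
            rows.append(pd.DataFrame({"time_ms": t, "electrode_id": eid, "value": values}))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["time_ms", "electrode_id", "value"]
        )


class Simulation:
    """The modulated update rule bound to a lattice.

    Parameters are fixed at construction; :meth:`step` advances a
    :class:`GridState` by one step, :meth:`run` iterates with stimulus
    injection, electrode sampling and instability detection.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        params: ModelParams,
        lesion: LesionMask | None = None,
        edge_weights: Mapping[tuple[int, int], np.ndarray] | None = None,
    ):
        self.shape = shape
        self.params = params
        self.lesion = lesion
        self.lattice = Lattice(shape, params, lesion, edge_weights)

    def inject(self, state: GridState, v: np.ndarray) -> GridState:
        """Add a stimulus field to the activations (before a step)."""
        v = np.asarray(v, dtype=float)
        if v.shape != state.shape:
            raise ValueError(f"stimulus shape {v.shape} != grid shape {state.shape}")
        A = state.A + v * self.lattice.livef
        return GridState(A, state.Delta.copy(), state.t)

    def step(self, state: GridState) -> GridState:
        """One update: Laplacian, feedback integration + damping, activation."""
        p = self.params
        lap = self.lattice.laplacian(state.A)
        Delta = (state.Delta + p.c2 * lap) / (1.0 + p.f)
        A = (state.A + Delta) / (1.0 + p.g)
        if self.lesion is not None:
            A = A * self.lattice.livef
            Delta = Delta * self.lattice.livef
        new = GridState(A, Delta, state.t + 1)
        m = np.abs(A).max()
        if not np.isfinite(m) or m > OVERFLOW_LIMIT:
            raise InstabilityError(new.t)
        return new

    def run(
        self,
        initial: GridState,
        n_steps: int,
        stimulus: Stimulus | None = None,
        electrodes: Sequence | None = None,
        record_history: bool = False,
        snapshot_times: Iterable[int] | None = None,
    ) -> RunResult:
        """Advance ``n_steps`` steps from ``initial``.

        Stimulus fields for step ``t`` (``t = initial.t+1 .. initial.t+n_steps``)
        are injected before that step; electrodes sample the activation after
        each step. ``record_history`` stores the dense ``A`` history
        (``n_steps+1`` frames including the initial state).
        """
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        state = initial.copy()
        if self.lesion is not None:
            state.A *= self.lattice.livef
            state.Delta *= self.lattice.livef
        snap_want = set(int(t) for t in snapshot_times) if snapshot_times else set()
        recordings = {e.id: np.empty(n_steps) for e in (electrodes or [])}
        history = None
        if record_history:
            history = np.empty((n_steps + 1,) + self.shape)
            history[0] = state.A
        snapshots = {}
        if state.t in snap_want:
            snapshots[state.t] = state.A.copy()
        for i in range(n_steps):
            t = state.t + 1
            if stimulus is not None:
                v = stimulus.field_at(t, self.shape)
                if v is not None:
                    state = self.inject(state, v)
            state = self.step(state)
            for e in electrodes or []:
                recordings[e.id][i] = e.sample(state.A)
            if record_history:
                history[i + 1] = state.A
            if t in snap_want:
                snapshots[t] = state.A.copy()
        time_ms = np.arange(1, n_steps + 1, dtype=float) * self.params.dt_ms
        return RunResult(recordings, snapshots, history, state, time_ms)


def make_jitter_weights(
    shape: tuple[int, int],
    neighborhood: str,
    magnitude: float,
    seed: int,
) -> dict[tuple[int, int], np.ndarray]:
    """Symmetric multiplicative per-edge coupling factors, uniform in
    ``[1 - magnitude, 1 + magnitude]``. Models uncorrelated ("impaired")
    synaptic transmission between neighbouring columns."""
    if not 0.0 <= magnitude < 1.0:
        raise ValueError("jitter magnitude must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    offsets = NEIGHBOR_OFFSETS[neighborhood]
    weights: dict[tuple[int, int], np.ndarray] = {}
    # deterministic positive half: offsets lexicographically > (0, 0)
    half = [o for o in offsets if o > (0, 0)]
    for o in half:
        w = 1.0 + magnitude * (2.0 * rng.random(shape) - 1.0)
        weights[o] = w
        # W_{-o}(x) = W_o(x - o): roll forward by o
        weights[(-o[0], -o[1])] = np.roll(w, shift=(o[0], o[1]), axis=(0, 1))
    return weights
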