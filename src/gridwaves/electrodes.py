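"""Virtual electrodes: disc-shaped spatial averages of the activation field.

Electrode scale is set by the disc radius (with the 0.5 mm column pitch):
0.25 mm covers exactly one column (unit electrode), 1 mm a 2 mm-diameter
LFP-like patch, 10 mm a 20 mm EEG-like patch, 2.5 mm the EEG electrode of
the grating protocol. A node is covered when its centre lies strictly
inside the radius (half-open disc). By default the electrode reports the
spatial MEAN over covered nodes so amplitudes are size-invariant; ``"sum"``
aggregation (amplitude grows with electrode area) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "Electrode",
    "unit_electrode",
    "lfp_electrode",
    "eeg_electrode",
    "mea_array",
    "coherence_pairs",
    "grating_layout",
    "UNIT_RADIUS_MM",
    "LFP_RADIUS_MM",
    "EEG_RADIUS_MM",
    "GRATING_EEG_RADIUS_MM",
]

UNIT_RADIUS_MM = 0.25
LFP_RADIUS_MM = 1.0
EEG_RADIUS_MM = 10.0
GRATING_EEG_RADIUS_MM = 2.5


@dataclass
class Electrode:
    """A disc electrode at ``center`` (column coordinates)."""

    center: tuple[int, int]
    radius_mm: float = UNIT_RADIUS_MM
    id: str = ""
    aggregate: str = "mean"
    column_pitch_mm: float = 0.5
    _cache: dict = dc_field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.id:
            self.id = f"e{self.center[0]}_{self.center[1]}_r{self.radius_mm:g}"
        if self.aggregate not in ("mean", "sum"):
            raise ValueError("aggregate must be 'mean' or 'sum'")

    def covered(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays of covered nodes (cached per grid shape)."""
        key = tuple(shape)
        if key not in self._cache:
            nx, ny = shape
            cx, cy = self.center
            if not (0 <= cx < nx and 0 <= cy < ny):
                raise ValueError(f"electrode centre {self.center} is off the {shape} grid")
            r = self.radius_mm / self.column_pitch_mm
            x = np.arange(nx)[:, None] - cx
            y = np.arange(ny)[None, :] - cy
            ix, iy = np.nonzero(x * x + y * y < r * r)
            if len(ix) == 0:
                raise ValueError("electrode covers no node")
            self._cache[key] = (ix, iy)
        return self._cache[key]

    def sample(self, A: np.ndarray) -> float:
        ix, iy = self.covered(A.shape)
        v = A[ix, iy]
        return float(v.mean() if self.aggregate == "mean" else v.sum())


def unit_electrode(center, id: str = "", **kw) -> Electrode:
    return Electrode(tuple(center), UNIT_RADIUS_MM, id, **kw)


def lfp_electrode(center, id: str = "", **kw) -> Electrode:
    return Electrode(tuple(center), LFP_RADIUS_MM, id, **kw)


def eeg_electrode(center, id: str = "", radius_mm: float = EEG_RADIUS_MM, **kw) -> Electrode:
    return Electrode(tuple(center), radius_mm, id, **kw)


def mea_array(
    origin: tuple[int, int],
    n_rows: int,
    n_cols: int,
    spacing_cols: int,
    radius_mm: float = UNIT_RADIUS_MM,
) -> list[Electrode]:
    """Rectangular multi-electrode array; ids ``meaR_C``."""
    out = []
    for r in range(n_rows):
        for c in range(n_cols):
            center = (origin[0] + r * spacing_cols, origin[1] + c * spacing_cols)
            out.append(Electrode(center, radius_mm, f"mea{r}_{c}"))
    _check_unique_ids(out)
    return out


def coherence_pairs(
    reference: tuple[int, int],
    distances_mm=(0.5, 2.0, 4.0, 8.0, 16.0, 32.0),
    radius_mm: float = UNIT_RADIUS_MM,
    axis: int = 0,
    column_pitch_mm: float = 0.5,
) -> list[tuple[Electrode, Electrode]]:
    """Electrode pairs separated by the standard distances along one axis."""
    pairs = []
    ref = Electrode(tuple(reference), radius_mm, "ref")
    for d in distances_mm:
        off = int(round(d / column_pitch_mm))
        center = list(reference)
        center[axis] += off
        pairs.append((ref, Electrode(tuple(center), radius_mm, f"d{d:g}mm")))
    return pairs


def grating_layout(
    stimulus_center: tuple[int, int],
    distances_mm=(0.0, 12.5, 40.0),
    radius_mm: float = GRATING_EEG_RADIUS_MM,
    axis: int = 0,
    column_pitch_mm: float = 0.5,
) -> list[Electrode]:
    """EEG electrodes at increasing distance from the grating centre."""
    out = []
    for d in distances_mm:
        center = list(stimulus_center)
        center[axis] += int(round(d / column_pitch_mm))
        out.append(Electrode(tuple(center), radius_mm, f"d{d:g}mm"))
    _check_unique_ids(out)
    return out


def _check_unique_ids(electrodes) -> None:
    ids = [e.id for e in electrodes]
    if len(set(ids)) != len(ids):
        raise ValueError("electrode ids must be unique")
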