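import numpy as np
import pytest

from gridwaves.model import GridState, ModelParams, Simulation


@pytest.fixture
def torus_params():
    """Mildly damped torus parameters used by several oracle tests."""
    return ModelParams(c2=1.3, f=0.01, g=0.003, neighborhood="moore-8", boundary="torus")


@pytest.fixture
def small_random_state():
    return GridState.random((16, 16), seed=3)


def naive_step(A, Delta, c2, f, g, neighborhood, boundary):
    """Literal per-node transcription of the five update steps.

    Independent of the vectorized implementation: plain Python loops over
    nodes and neighbours.
    """
    nx, ny = A.shape
    offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if neighborhood == "moore-8":
        offsets += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    lap = np.zeros_like(A)
    for i in range(nx):
        for j in range(ny):
            acc, k = 0.0, 0
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if boundary == "torus":
                    ii, jj = ii % nx, jj % ny
                elif not (0 <= ii < nx and 0 <= jj < ny):
                    continue
                acc += A[ii, jj] - A[i, j]
                k += 1
            lap[i, j] = acc / k if k else 0.0
    Delta_new = (Delta + c2 * lap) / (1.0 + f)
    A_new = (A + Delta_new) / (1.0 + g)
    return A_new, Delta_new
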