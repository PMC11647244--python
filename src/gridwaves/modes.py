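"""Exact normal-mode solution of the lattice model on a torus.

Because the update rule is linear and, on a torus, translation invariant,
the spatial Fourier modes of the lattice evolve independently. Each mode
``k`` carries a two-component state ``(A_k, Delta_k)`` advanced by a 2x2
transfer map whose entries depend only on the Laplacian eigenvalue
``mu_k`` and the parameters ``(c2, f, g)``:

    Delta_k <- (Delta_k + c2 * mu_k * A_k) / (1 + f)
    A_k     <- (A_k + Delta_k) / (1 + g)

Eigen-decomposing the map gives a damped oscillation per mode,

    A_k(t) = exp(-lambda_k t) * (p_k cos(omega_k t) + q_k sin(omega_k t)),

which is the closed-form solution used as the internal oracle for the
stepping simulation and as the mathematical basis of the codec.

Mode conventions: standard DFT indexing (``numpy.fft.fft2``), wavenumber
``theta = 2 pi k / n`` per axis; the Laplacian eigenvalue of the
neighbour-mean-minus-centre operator is

    von-neumann-4: mu = (cos tx + cos ty)/2 - 1            in [-2, 0]
    moore-8:       mu = (2cos tx + 2cos ty + 4cos tx cos ty)/8 - 1   in [-1.5, 0]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GridState, ModelParams, Stimulus

__all__ = [
    "laplacian_eigenvalues",
    "mu_min",
    "mode_map",
    "mode_eigenvalues",
    "DispersionTable",
    "dispersion",
    "stability_max_coupling",
    "spectral_radius",
    "propagator_entries",
    "impulse_response",
    "evolve_analytic",
]


def laplacian_eigenvalues(shape: tuple[int, int], neighborhood: str = "von-neumann-4") -> np.ndarray:
    """Eigenvalue ``mu_k`` of the grid Laplacian for every torus mode."""
    nx, ny = shape
    tx = 2.0 * np.pi * np.fft.fftfreq(nx)[:, None]
    ty = 2.0 * np.pi * np.fft.fftfreq(ny)[None, :]
    cx, cy = np.cos(tx), np.cos(ty)
    if neighborhood == "von-neumann-4":
        return (cx + cy) / 2.0 - 1.0
    if neighborhood == "moore-8":
        return (2.0 * cx + 2.0 * cy + 4.0 * cx * cy) / 8.0 - 1.0
    raise ValueError(f"unknown neighborhood {neighborhood!r}")


def mu_min(neighborhood: str, shape: tuple[int, int] | None = None) -> float:
    """Most negative Laplacian eigenvalue (exact over a given grid, or the
    lattice-wide extreme when no shape is given)."""
    if shape is not None:
        return float(laplacian_eigenvalues(shape, neighborhood).min())
    return {"von-neumann-4": -2.0, "moore-8": -1.5}[neighborhood]


def mode_map(mu: float | np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-mode 2x2 transfer map acting on ``(A_k, Delta_k)``.

    Broadcasts over ``mu``; the map axes are the trailing two dimensions.
    """
    mu = np.asarray(mu, dtype=float)
    b = 1.0 / (1.0 + params.f)
    a = params.c2 * mu * b
    M = np.empty(mu.shape + (2, 2))
    M[..., 0, 0] = (1.0 + a) / (1.0 + params.g)
    M[..., 0, 1] = b / (1.0 + params.g)
    M[..., 1, 0] = params.c2 * mu * b
    M[..., 1, 1] = b
    return M


def mode_eigenvalues(mu, params: ModelParams):
    """Eigenvalues ``(z1, z2)`` of the per-mode transfer map (complex)."""
    mu = np.asarray(mu, dtype=float)
    b = 1.0 / (1.0 + params.f)
    a = params.c2 * mu * b
    T = (1.0 + a) / (1.0 + params.g) + b
    D = b / (1.0 + params.g)
    disc = np.asarray(T * T - 4.0 * D, dtype=complex)
    root = np.sqrt(disc)
    return (T + root) / 2.0, (T - root) / 2.0


@dataclass
class DispersionTable:
    """Damping rate and angular frequency for every torus mode.

    ``omega`` is the oscillation angle per step (``freq_hz = omega/(2 pi) * fs``).
    Overdamped modes (real eigenvalues) carry ``omega = 0`` for positive
    roots or ``omega = pi`` for negative roots (sign-alternating, i.e.
    oscillation at the Nyquist frequency) and two distinct decay rates.
    """

    kx: np.ndarray
    ky: np.ndarray
    mu: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    lam: np.ndarray
    omega: np.ndarray
    overdamped: np.ndarray
    fs_hz: float

    @property
    def freq_hz(self) -> np.ndarray:
        return self.omega / (2.0 * np.pi) * self.fs_hz

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "kx_index": self.kx.ravel(),
                "ky_index": self.ky.ravel(),
                "mu": self.mu.ravel(),
                "lambda": self.lam.ravel(),
                "omega_rad_per_step": self.omega.ravel(),
                "freq_hz": self.freq_hz.ravel(),
                "overdamped": self.overdamped.ravel(),
            }
        )


def dispersion(params: ModelParams, shape: tuple[int, int]) -> DispersionTable:
    """Full per-mode table of ``(lambda_k, omega_k)`` on the torus."""
    nx, ny = shape
    mu = laplacian_eigenvalues(shape, params.neighborhood)
    z1, z2 = mode_eigenvalues(mu, params)
    overdamped = np.isclose(z1.imag, 0.0) & np.isclose(z2.imag, 0.0) & ~np.isclose(z1, z2)
    mag = np.maximum(np.abs(z1), np.abs(z2))
    lam = -np.log(np.maximum(mag, 1e-300))
    omega = np.abs(np.angle(z1))
    kx = np.broadcast_to(np.fft.fftfreq(nx, 1.0 / nx).astype(int)[:, None], mu.shape)
    ky = np.broadcast_to(np.fft.fftfreq(ny, 1.0 / ny).astype(int)[None, :], mu.shape)
    return DispersionTable(kx.copy(), ky.copy(), mu, z1, z2, lam, omega, overdamped, params.fs_hz)


def stability_max_coupling(
    f: float,
    g: float,
    neighborhood: str = "von-neumann-4",
    shape: tuple[int, int] | None = None,
) -> float:
    """Largest coupling ``c2`` with spectral radius <= 1 over all modes.

    For the mode map the Jury conditions reduce to
    ``c2 * |mu_min| <= (2 + f)(2 + g)``, hence the closed form
    ``c2_max = (2 + f)(2 + g) / |mu_min|`` (= 2 for the undamped
    4-neighbour torus, 8/3 for the undamped 8-neighbour torus).
    """
    if f < 0 or g < 0:
        raise ValueError("dampings must be >= 0")
    m = abs(mu_min(neighborhood, shape))
    if m == 0:
        return np.inf
    return (2.0 + f) * (2.0 + g) / m


def spectral_radius(params: ModelParams, shape: tuple[int, int]) -> float:
    """Max |eigenvalue| of the transfer map over all torus modes."""
    z1, z2 = mode_eigenvalues(laplacian_eigenvalues(shape, params.neighborhood), params)
    return float(np.maximum(np.abs(z1), np.abs(z2)).max())


def _mode_arrays(shape, params):
    mu = laplacian_eigenvalues(shape, params.neighborhood)
    M = mode_map(mu, params)
    z1, z2 = mode_eigenvalues(mu, params)
    return mu, M, z1, z2


def propagator_entries(M: np.ndarray, z1: np.ndarray, z2: np.ndarray, n: int):
    """Top row ``([M^n]_00, [M^n]_01)`` of the n-th power of the mode map.

    Uses the spectral-projector form
    ``M^n = (z1^n (M - z2 I) - z2^n (M - z1 I)) / (z1 - z2)``
    with the confluent (repeated-root) limit where ``z1 ~ z2``.
    """
    if n == 0:
        one = np.ones_like(z1)
        return one, np.zeros_like(z1)
    m00 = M[..., 0, 0]
    m01 = M[..., 0, 1]
    dz = z1 - z2
    degenerate = np.abs(dz) <= 1e-12 * (np.abs(z1) + np.abs(z2) + 1e-30)
    dz_safe = np.where(degenerate, 1.0, dz)
    p1n, p2n = z1**n, z2**n
    h00 = (p1n * (m00 - z2) - p2n * (m00 - z1)) / dz_safe
    h01 = m01 * (p1n - p2n) / dz_safe
    if np.any(degenerate):
        z = z1
        zn1 = z ** (n - 1)
        h00 = np.where(degenerate, zn1 * (n * (m00 - z) + z), h00)
        h01 = np.where(degenerate, m01 * n * zn1, h01)
    return h00, h01


def impulse_response(mu, params: ModelParams, n_steps: int) -> np.ndarray:
    """Per-mode activation response ``h[n]`` at ``n`` steps after a unit
    injection into ``A_k`` (injection happens before the first step, so
    ``h[0] = 1`` is the pre-step value and ``h[n] = [M^n]_00``)."""
    mu = np.asarray(mu, dtype=float)
    M = mode_map(mu, params)
    z1, z2 = mode_eigenvalues(mu, params)
    out = np.empty((n_steps + 1,) + mu.shape, dtype=complex)
    for n in range(n_steps + 1):
        out[n] = propagator_entries(M, z1, z2, n)[0]
    return out


def evolve_analytic(
    initial: GridState,
    params: ModelParams,
    n_steps: int,
    stimulus: Stimulus | None = None,
    times: list[int] | None = None,
) -> np.ndarray:
    """Closed-form trajectory ``A(x, t)`` on the torus.

    Matches :meth:`gridwaves.model.Simulation.run` step for step: the
    stimulus field for step ``t`` is added to the activation before that
    step. Returns an array of frames for the requested ``times``
    (default: every step ``1..n_steps``).

    This is an O(modes) closed-form evaluation per output frame plus an
    O(support) sum over stimulus injection times, evaluated independently
    per Fourier mode — no time stepping is involved.
    """
    if params.boundary != "torus":
        raise ValueError("the analytic solution requires a torus")
    shape = initial.shape
    mu, M, z1, z2 = _mode_arrays(shape, params)
    Ak0 = np.fft.fft2(initial.A)
    Dk0 = np.fft.fft2(initial.Delta)
    if times is None:
        times = list(range(1, n_steps + 1))
    # collect stimulus injections (step index, Fourier field)
    injections: list[tuple[int, np.ndarray]] = []
    if stimulus is not None:
        for tau in range(1, n_steps + 1):
            v = stimulus.field_at(tau, shape)
            if v is not None:
                injections.append((tau, np.fft.fft2(v)))
    out = np.empty((len(times),) + shape)
    for i, t in enumerate(times):
        if t < 0:
            raise ValueError("times must be >= 0")
        h00, h01 = propagator_entries(M, z1, z2, t)
        Ak = h00 * Ak0 + h01 * Dk0
        for tau, vk in injections:
            if tau <= t:
                hh, _ = propagator_entries(M, z1, z2, t - tau + 1)
                Ak = Ak + hh * vk
        out[i] = np.fft.ifft2(Ak).real
    return out


def max_group_speed(params: ModelParams, n_k: int = 2001) -> float:
    """Largest group velocity d(omega)/d|k| over axis modes, in mm/ms.

    This is the ballistic front speed of a disturbance travelling along a
    grid axis; measured first-arrival speeds should match it. Computed
    numerically from the axis dispersion omega(k).
    """
    k = np.linspace(0.0, np.pi, n_k)
    if params.neighborhood == "von-neumann-4":
        mu = (np.cos(k) + 1.0) / 2.0 - 1.0
    else:
        mu = (6.0 * np.cos(k) + 2.0) / 8.0 - 1.0
    # undamped dispersion (damping shifts omega only near the overdamped
    # transition, where a group velocity is not meaningful)
    omega = np.arccos(np.clip(1.0 + params.c2 * mu / 2.0, -1.0, 1.0))
    dk = k[1] - k[0]
    vg = np.abs(np.diff(omega)) / dk  # columns per step
    return float(vg.max()) * params.column_pitch_mm / params.dt_ms
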