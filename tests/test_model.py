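import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridwaves.model import (
    DegenerateTopologyError,
    GridState,
    InstabilityError,
    LesionMask,
    ModelParams,
    Simulation,
    make_jitter_weights,
)

from conftest import naive_step


class TestLaplacian:
    def test_uniform_field_has_zero_laplacian(self):
        sim = Simulation((6, 6), ModelParams())
        lap = sim.lattice.laplacian(np.full((6, 6), 3.7))
        assert np.allclose(lap, 0.0)

    def test_two_node_chain(self):
        """Manual application of the neighbour-mean rule on a 1D pair."""
        sim = Simulation((2, 1), ModelParams())
        lap = sim.lattice.laplacian(np.array([[1.0], [0.0]]))
        assert np.allclose(lap.ravel(), [-1.0, 1.0])

    def test_single_fourier_mode_is_eigenvector_on_torus(self):
        """Dense-matrix oracle: the normalized adjacency-minus-identity
        operator applied to a pure cosine mode scales it by mu_k."""
        n = 8
        params = ModelParams(boundary="torus")
        sim = Simulation((n, n), params)
        # dense operator oracle
        N = n * n
        L = np.zeros((N, N))
        for i in range(n):
            for j in range(n):
                a = i * n + j
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    b = ((i + di) % n) * n + (j + dj) % n
                    L[a, b] += 1.0 / 4.0
                L[a, a] -= 1.0
        kx, ky = 2, 3
        x = np.arange(n)
        mode = np.cos(2 * np.pi * (kx * x[:, None] + ky * x[None, :]) / n)
        expected = (L @ mode.ravel()).reshape(n, n)
        assert np.allclose(sim.lattice.laplacian(mode), expected, atol=1e-12)
        mu = (np.cos(2 * np.pi * kx / n) + np.cos(2 * np.pi * ky / n)) / 2.0 - 1.0
        assert np.allclose(sim.lattice.laplacian(mode), mu * mode, atol=1e-12)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(DegenerateTopologyError):
            Simulation((1, 1), ModelParams())


class TestStep:
    def test_two_node_chain_period_four(self):
        """Worked trajectory: A cycles (0,1),(0,1),(1,0),(1,0) and repeats."""
        sim = Simulation((2, 1), ModelParams(c2=1.0))
        st_ = GridState(np.array([[1.0], [0.0]]), np.zeros((2, 1)))
        seen = []
        for _ in range(8):
            st_ = sim.step(st_)
            seen.append(tuple(st_.A.ravel()))
        assert seen[:4] == [(0, 1), (0, 1), (1, 0), (1, 0)]
        assert seen[4:] == seen[:4]

    def test_uniform_state_is_fixed_point(self):
        sim = Simulation((5, 5), ModelParams())
        st_ = GridState(np.full((5, 5), 2.0), np.zeros((5, 5)))
        out = sim.step(st_)
        assert np.allclose(out.A, 2.0) and np.allclose(out.Delta, 0.0)

    @pytest.mark.parametrize("neighborhood", ["von-neumann-4", "moore-8"])
    @pytest.mark.parametrize("boundary", ["clamped", "torus"])
    def test_matches_naive_loop_oracle(self, neighborhood, boundary):
        rng = np.random.default_rng(0)
        params = ModelParams(c2=1.7, f=0.05, g=0.01, neighborhood=neighborhood, boundary=boundary)
        sim = Simulation((8, 8), params)
        A = rng.standard_normal((8, 8))
        D = rng.standard_normal((8, 8))
        st_ = GridState(A.copy(), D.copy())
        for _ in range(5):
            st_ = sim.step(st_)
            A, D = naive_step(A, D, 1.7, 0.05, 0.01, neighborhood, boundary)
            assert np.allclose(st_.A, A, atol=1e-13)
            assert np.allclose(st_.Delta, D, atol=1e-13)

    def test_modulated_reduces_to_bare_rule(self):
        """c2=1, f=g=0 reproduces the unmodulated update bit for bit on
        integer inputs."""
        params = ModelParams(c2=1.0, f=0.0, g=0.0, boundary="torus", neighborhood="von-neumann-4")
        sim = Simulation((4, 4), params)
        A = np.arange(16.0).reshape(4, 4) * 4  # multiples of k=4: exact division
        st_ = GridState(A, np.zeros((4, 4)))
        out = sim.step(st_)
        lap = sim.lattice.laplacian(A)
        assert np.array_equal(out.Delta, lap)
        assert np.array_equal(out.A, A + lap)

    def test_instability_error_carries_step_index(self):
        params = ModelParams(c2=3.0, boundary="torus")  # above the bound
        sim = Simulation((8, 8), params)
        st_ = GridState.zeros((8, 8))
        st_.A[0, 0] = 1.0
        with pytest.raises(InstabilityError) as exc:
            sim.run(st_, 3000)
        assert exc.value.step > 0


class TestInjectAndRun:
    def test_inject_zero_is_identity(self):
        sim = Simulation((4, 4), ModelParams())
        st_ = GridState.random((4, 4), seed=1)
        out = sim.inject(st_, np.zeros((4, 4)))
        assert np.array_equal(out.A, st_.A) and np.array_equal(out.Delta, st_.Delta)

    def test_inject_additivity(self):
        sim = Simulation((4, 4), ModelParams())
        st_ = GridState.random((4, 4), seed=1)
        rng = np.random.default_rng(2)
        v1, v2 = rng.standard_normal((2, 4, 4))
        a = sim.inject(sim.inject(st_, v1), v2)
        b = sim.inject(st_, v1 + v2)
        assert np.allclose(a.A, b.A)

    def test_inject_shape_mismatch(self):
        sim = Simulation((4, 4), ModelParams())
        with pytest.raises(ValueError):
            sim.inject(GridState.zeros((4, 4)), np.zeros((3, 4)))

    def test_zero_everything_stays_zero(self, torus_params):
        sim = Simulation((8, 8), torus_params)
        res = sim.run(GridState.zeros((8, 8)), 50, record_history=True)
        assert np.all(res.history == 0.0)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.5, 4.0))
    def test_response_linear_in_stimulus(self, seed, scale):
        """Superposition: scaling the input scales every A(x, t)."""
        from gridwaves.stimuli import DenseStimulus

        params = ModelParams(c2=1.3, f=0.01, g=0.003, neighborhood="moore-8", boundary="torus")
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((5, 8, 8))
        sim = Simulation((8, 8), params)
        r1 = sim.run(GridState.zeros((8, 8)), 30, stimulus=DenseStimulus(v), record_history=True)
        r2 = sim.run(GridState.zeros((8, 8)), 30, stimulus=DenseStimulus(scale * v), record_history=True)
        assert np.allclose(r2.history, scale * r1.history, atol=1e-10 * scale)

    def test_activation_sum_conserved_on_undamped_torus(self):
        params = ModelParams(c2=1.4, boundary="torus")
        sim = Simulation((10, 10), params)
        st_ = GridState.random((10, 10), seed=4)
        total0 = st_.A.sum()
        res = sim.run(st_, 200, record_history=True)
        totals = res.history.sum(axis=(1, 2))
        assert np.allclose(totals, total0, rtol=1e-12)

    def test_impulse_energy_decay_timescale(self):
        """With f = g = 0.001 the squared-activation decay time fitted over
        a long window is ~1/(f+g) = 500 steps."""
        params = ModelParams(c2=1.0, f=0.001, g=0.001, boundary="torus")
        sim = Simulation((24, 24), params)
        st_ = GridState.zeros((24, 24))
        st_.A[5, 5] = 1.0
        res = sim.run(st_, 3000, record_history=True)
        energy = (res.history**2).sum(axis=(1, 2))
        # fit log-linear decay between steps 500 and 2500
        t = np.arange(500, 2500)
        slope = np.polyfit(t, np.log(energy[500:2500]), 1)[0]
        tau = -1.0 / slope
        assert 400 < tau < 600


class TestLesions:
    def test_zero_fraction_identical_trajectory(self, torus_params):
        from gridwaves.stimuli import make_noise

        shape = (12, 12)
        stim = make_noise(seed=0, sigma=1.0)
        plain = Simulation(shape, torus_params)
        lesioned = Simulation(shape, torus_params, lesion=LesionMask.none(shape))
        r1 = plain.run(GridState.zeros(shape), 40, stimulus=stim, record_history=True)
        r2 = lesioned.run(GridState.zeros(shape), 40, stimulus=stim, record_history=True)
        assert np.array_equal(r1.history, r2.history)

    def test_fully_isolated_node_decays_geometrically(self):
        """Under renormalized averaging an isolated node has no lateral
        input left, so its activation decays by exactly 1/(1+g)."""
        g = 0.02
        shape = (5, 5)
        inactive = np.zeros(shape, dtype=bool)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            inactive[2 + di, 2 + dj] = True
        mask = LesionMask(inactive, inactive.mean())
        params = ModelParams(c2=1.0, g=g, renormalize=True)
        sim = Simulation(shape, params, lesion=mask)
        st_ = GridState.zeros(shape)
        st_.A[2, 2] = 1.0
        res = sim.run(st_, 10, record_history=True)
        expected = (1.0 + g) ** -np.arange(11)
        assert np.allclose(res.history[:, 2, 2], expected, rtol=1e-12)

    def test_lesioned_nodes_stay_silent(self, torus_params):
        from gridwaves.stimuli import make_noise

        shape = (12, 12)
        mask = LesionMask.random(shape, 0.2, seed=9)
        sim = Simulation(shape, torus_params, lesion=mask)
        res = sim.run(GridState.random(shape, seed=2), 40, stimulus=make_noise(0), record_history=True)
        assert np.all(res.history[1:][:, mask.inactive] == 0.0)

    def test_all_lesioned_rejected(self):
        with pytest.raises(ValueError):
            Simulation((4, 4), ModelParams(), lesion=LesionMask(np.ones((4, 4), bool), 1.0))

    def test_mask_fraction_is_exact(self):
        mask = LesionMask.random((50, 50), 0.04, seed=1)
        assert mask.inactive.sum() == 100


class TestJitter:
    def test_weights_are_symmetric_and_bounded(self):
        w = make_jitter_weights((10, 10), "moore-8", 0.3, seed=0)
        for o, arr in w.items():
            assert np.all(arr >= 0.7) and np.all(arr <= 1.3)
            # W_o(x) must equal W_{-o}(x + o)
            mirrored = np.roll(w[(-o[0], -o[1])], shift=(-o[0], -o[1]), axis=(0, 1))
            assert np.allclose(arr, mirrored)

    def test_zero_magnitude_equals_plain_lattice(self, torus_params):
        shape = (8, 8)
        w = make_jitter_weights(shape, torus_params.neighborhood, 0.0, seed=0)
        a = Simulation(shape, torus_params, edge_weights=w)
        b = Simulation(shape, torus_params)
        A = np.random.default_rng(0).standard_normal(shape)
        assert np.allclose(a.lattice.laplacian(A), b.lattice.laplacian(A))

    def test_jittered_run_bounded_below_stability(self, torus_params):
        shape = (12, 12)
        w = make_jitter_weights(shape, torus_params.neighborhood, 0.2, seed=3)
        sim = Simulation(shape, torus_params, edge_weights=w)
        st_ = GridState.random(shape, seed=0, amplitude=0.1)
        res = sim.run(st_, 500, record_history=True)
        assert np.isfinite(res.history).all()
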