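"""Implicit-Euler / FFT integrator on the torus grid."""

import numpy as np
import pytest

from turingfit import (
    GridSpec,
    KineticModel,
    SimulationConfig,
    gierer_meinhardt,
    gm_equilibrium,
    initial_condition,
    laplacian_symbol,
    simulate,
    step_size_bound,
)
from turingfit.simulate import apply_laplacian, implicit_step, _implicit_solve, _rfft_symbol


def dense_torus_laplacian(n):
    """Dense 5-point torus Laplacian (neighbor sum minus 4, unit weights)."""
    m = n * n
    L = np.zeros((m, m))
    for i in range(n):
        for j in range(n):
            v = i * n + j
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                w = ((i + di) % n) * n + (j + dj) % n
                L[v, w] += 1.0
            L[v, v] -= 4.0
    return L


def zero_kinetics(n_species=2):
    return KineticModel(
        n_species=n_species,
        reaction=lambda u, p=None: np.zeros_like(u),
        jacobian=lambda u, p=None: np.zeros(u.shape + (n_species,)),
        diffusion_diag=tuple([1.0] * n_species),
        scale=1.0,
    )


class TestSymbol:
    def test_constant_mode_is_one(self):
        assert laplacian_symbol(8, 0.3, 5.0)[0, 0] == pytest.approx(1.0)

    def test_nyquist_mode_is_maximum(self):
        sym = laplacian_symbol(8, 0.2, 3.0)
        assert sym[4, 4] == pytest.approx(1.0 + 8 * 0.2 * 3.0)
        assert sym.max() == sym[4, 4]
        assert np.all(sym >= 1.0)

    def test_symbol_equals_dense_eigenvalues(self):
        """On a 4x4 torus the symbol grid is the spectrum of I - h d L."""
        h, d = 0.2, 1.7
        sym = np.sort(laplacian_symbol(4, h, d).ravel())
        dense = np.eye(16) - h * d * dense_torus_laplacian(4)
        np.testing.assert_allclose(sym, np.sort(np.linalg.eigvalsh(dense)), atol=1e-10)

    def test_torus_lambda_max_is_eight(self):
        """Largest Laplacian eigenvalue used in the step bound, dense oracle."""
        eigs = np.linalg.eigvalsh(-dense_torus_laplacian(8))
        assert eigs.max() == pytest.approx(8.0, abs=1e-9)


class TestImplicitStep:
    def test_pure_diffusion_conserves_mass(self, rng):
        """Row sums of L vanish, so each species' mean is exact per step."""
        model = zero_kinetics()
        v = rng.uniform(0.5, 1.5, size=(8, 8, 2))
        means = v.mean(axis=(0, 1))
        for _ in range(1000):
            v = implicit_step(v, model, h=0.2, eps_inner=1e-3, max_inner=50)
        np.testing.assert_allclose(v.mean(axis=(0, 1)), means, atol=1e-10)

    def test_zero_diffusion_zero_reaction_is_identity(self, rng):
        model = KineticModel(
            n_species=2,
            reaction=lambda u, p=None: np.zeros_like(u),
            jacobian=None,
            diffusion_diag=(0.0, 0.0),
            scale=1.0,
        )
        v = rng.uniform(0.5, 1.5, size=(8, 8, 2))
        out = implicit_step(v, model, h=0.2, eps_inner=1e-3, max_inner=50)
        np.testing.assert_allclose(out, v, atol=1e-14)

    def test_fft_solve_equals_dense_solve(self, rng):
        """One linear solve via FFT vs dense LU on an 8x8 grid."""
        n, h, d = 8, 0.2, 2.5
        rhs = rng.normal(size=(n, n))
        via_fft = _implicit_solve(rhs, _rfft_symbol(n, h, d))
        dense = np.eye(n * n) - h * d * dense_torus_laplacian(n)
        via_lu = np.linalg.solve(dense, rhs.ravel()).reshape(n, n)
        np.testing.assert_allclose(via_fft, via_lu, atol=1e-9)

    def test_apply_laplacian_matches_dense(self, rng):
        f = rng.normal(size=(6, 6))
        expected = (dense_torus_laplacian(6) @ f.ravel()).reshape(6, 6)
        np.testing.assert_allclose(apply_laplacian(f), expected, atol=1e-12)


class TestInitialCondition:
    def test_support_and_determinism(self):
        u_star = np.array([1.02, 1.0404])
        f1 = initial_condition(u_star, GridSpec(16), seed=3)
        f2 = initial_condition(u_star, GridSpec(16), seed=3)
        assert np.array_equal(f1, f2)
        for i in range(2):
            assert f1[..., i].min() >= 0.9 * u_star[i]
            assert f1[..., i].max() <= 1.1 * u_star[i]

    def test_sample_mean_near_equilibrium(self):
        """Mean of U[0.9 u*, 1.1 u*] is u*; check within 3 standard errors."""
        u_star = np.array([2.0, 4.0])
        f = initial_condition(u_star, GridSpec(128), seed=11)
        se = 0.1 * u_star / np.sqrt(3 * 128 * 128)
        for i in range(2):
            assert abs(f[..., i].mean() - u_star[i]) < 3 * se[i]


class TestSimulate:
    def test_homogeneous_equilibrium_is_fixed_point(self):
        """Starting exactly at u* the field stays there and converges fast."""
        model = gierer_meinhardt(0.02, 1.0, 0.5, 100.0, 0.25)
        eq = gm_equilibrium(0.02, 1.0, 0.5)
        init = np.broadcast_to(eq.u_star, (16, 16, 2)).copy()
        pattern = simulate(model, GridSpec(16), SimulationConfig(t_final=300.0),
                           init_field=init)
        assert pattern.converged
        assert pattern.t_end <= 100.0 + 1e-9
        np.testing.assert_allclose(pattern.field, init, atol=1e-8)

    def test_turing_parameters_produce_pattern(self, pattern64):
        """The c-sweep regime yields a strongly nonhomogeneous steady state."""
        assert pattern64.amplitude > 0.5 * pattern64.field[..., 0].mean()
        assert np.all(np.isfinite(pattern64.field))
        assert np.all(pattern64.field > 0)

    def test_stable_parameters_produce_homogeneous_field(self):
        """Without a Turing instability the noise decays to the equilibrium."""
        model = gierer_meinhardt(0.02, 1.0, 1.2, 100.0, 0.5)
        eq = gm_equilibrium(0.02, 1.0, 1.2)
        pattern = simulate(model, GridSpec(32), SimulationConfig(seed=2, t_final=500.0),
                           u_star=eq.u_star)
        assert pattern.amplitude < 0.05 * pattern.field[..., 0].mean()

    def test_shift_equivariance(self):
        """Cyclically shifting the initial field shifts the final field."""
        model = gierer_meinhardt(0.02, 1.0, 0.5, 100.0, 0.25)
        eq = gm_equilibrium(0.02, 1.0, 0.5)
        init = initial_condition(eq.u_star, GridSpec(32), seed=9)
        cfg = SimulationConfig(t_final=20.0, check_interval=1000.0)
        base = simulate(model, GridSpec(32), cfg, init_field=init)
        shifted = simulate(model, GridSpec(32), cfg,
                           init_field=np.roll(init, (3, -5), axis=(0, 1)))
        np.testing.assert_allclose(
            shifted.field, np.roll(base.field, (3, -5), axis=(0, 1)), atol=1e-8
        )

    def test_steady_residual_criterion_honoured(self):
        """A converged run satisfies the inf-norm residual bound."""
        from turingfit.simulate import _steady_residual

        model = gierer_meinhardt(0.02, 1.0, 0.5, 100.0, 0.25)
        eq = gm_equilibrium(0.02, 1.0, 0.5)
        init = np.broadcast_to(eq.u_star, (16, 16, 2)).copy()
        pattern = simulate(model, GridSpec(16), SimulationConfig(t_final=300.0),
                           init_field=init)
        assert pattern.converged
        assert _steady_residual(pattern.field, model) <= 1e-6


class TestStepBound:
    def test_limit_of_vanishing_lipschitz(self):
        model = zero_kinetics()
        assert step_size_bound(model, 1e-12) == pytest.approx(1.0 / 8.0, rel=1e-6)

    def test_contraction_root(self):
        # max diffusion 1, L_f = 1: solve h/(1 - 8h) = 1 -> h = 1/9
        model = zero_kinetics()
        assert step_size_bound(model, 1.0) == pytest.approx(1.0 / 9.0)

    def test_scales_with_diffusion(self):
        model = gierer_meinhardt(0.02, 1.0, 0.5, 100.0, 0.25)  # max d = 25
        assert step_size_bound(model, 1.0) == pytest.approx(1.0 / 201.0)
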