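import numpy as np
import pytest

from cellforce.forward_solver import (
    ControlField,
    MassTarget,
    ginzburg_landau_energy,
    laplacian_matrix,
    laplacian_neumann,
    solve_forward,
    stable_substeps,
    step,
    _solve_implicit,
)
from cellforce.geometry import membrane_contour
from cellforce.model_core import DimensionlessParams, GridSpec, tanh_profile


def disk(grid, center=(0.5, 0.5), radius=0.3, eps=0.04):
    x, y = grid.mesh()
    return tanh_profile(radius - np.hypot(x - center[0], y - center[1]), eps)


def zero_level_radius(state, grid, center=(0.5, 0.5)):
    pts = membrane_contour(state, grid).polylines[0]
    return np.mean(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]))


class TestLaplacian:
    def test_constant_maps_to_zero_everywhere(self, grid32):
        out = laplacian_neumann(np.full(grid32.shape, 3.7), grid32)
        assert np.abs(out).max() == 0.0

    def test_linear_field_zero_in_interior(self, grid32):
        x, _ = grid32.mesh()
        out = laplacian_neumann(x, grid32)
        assert np.abs(out[1:-1, 1:-1]).max() < 1e-10

    def test_quadratic_exact_in_interior(self, grid32):
        x, _ = grid32.mesh()
        out = laplacian_neumann(x**2, grid32)
        assert np.allclose(out[1:-1, 1:-1], 2.0, atol=1e-9)

    def test_shape_mismatch_rejected(self, grid32):
        with pytest.raises(ValueError):
            laplacian_neumann(np.zeros((5, 5)), grid32)

    def test_matrix_matches_stencil(self, rng):
        grid = GridSpec(n=12)
        f = rng.standard_normal(grid.shape)
        via_matrix = (laplacian_matrix(grid) @ f.ravel()).reshape(grid.shape)
        assert np.allclose(via_matrix, laplacian_neumann(f, grid), atol=1e-9)

    @pytest.mark.parametrize("transpose", [False, True])
    def test_spectral_solve_matches_sparse_operator(self, rng, transpose):
        """The DCT-I solve must invert exactly the assembled stencil (and its
        transpose, which the adjoint sweep relies on)."""
        grid = GridSpec(n=16)
        a = 0.013
        A = np.eye(grid.n**2) - a * laplacian_matrix(grid).toarray()
        b = rng.standard_normal(grid.shape)
        x = _solve_implicit(b, grid, a, transpose=transpose)
        op = A.T if transpose else A
        assert np.abs(op @ x.ravel() - b.ravel()).max() < 1e-11


class TestStep:
    def test_uniform_minima_are_stationary(self, grid32, params_small):
        for val in (1.0, 0.0, -1.0):
            phi = np.full(grid32.shape, val)
            out, lam = step(phi, np.zeros(grid32.shape), val, params_small, 0.01, grid32)
            assert np.allclose(out, val, atol=1e-13)
            assert lam == pytest.approx(0.0, abs=1e-12)

    def test_multiplier_closed_form_for_uniform_mass_shift(self, grid32, params_small):
        """Pushing a uniform state's mass by dm needs lambda = eps tau dm / dt."""
        dt, dm = 0.01, 0.003
        phi = np.ones(grid32.shape)
        out, lam = step(phi, np.zeros(grid32.shape), 1.0 + dm, params_small, dt, grid32)
        expected = params_small.eps_bar * params_small.tau_bar * dm / dt
        assert lam == pytest.approx(expected, rel=1e-12)
        assert out.mean() == pytest.approx(1.0 + dm, abs=1e-14)

    def test_rejects_nonpositive_dt(self, grid32, params_small):
        with pytest.raises(ValueError):
            step(np.zeros(grid32.shape), np.zeros(grid32.shape), 0.0, params_small, -0.1, grid32)


class TestSolveForward:
    def test_uniform_fixed_point(self, grid32, params_small):
        eta = np.zeros((8,) + grid32.shape)
        traj = solve_forward(np.ones(grid32.shape), eta, np.ones(8), params_small, 0.01, grid32)
        assert np.allclose(traj.states[-1], 1.0, atol=1e-12)
        assert np.allclose(traj.lambdas, 0.0, atol=1e-11)

    def test_mass_tracking_is_exact(self, grid64, rng):
        params = DimensionlessParams(eps_bar=0.06, tau_bar=2.0, delta_bar=1.0)
        phi0 = disk(grid64, radius=0.25, eps=0.06)
        eta = 2.0 * rng.standard_normal((20,) + grid64.shape)
        mass = MassTarget.linear(float(phi0.mean()), float(phi0.mean()) + 0.05, 20)
        traj = solve_forward(phi0, eta, mass, params, 0.002, grid64)
        devs = np.abs(traj.states[1:].mean(axis=(1, 2)) - mass.values)
        assert devs.max() < 1e-10

    def test_no_cell_state_is_stationary(self, grid32, params_small):
        eta = np.zeros((5,) + grid32.shape)
        traj = solve_forward(-np.ones(grid32.shape), eta, None, params_small, 0.01, grid32)
        assert np.allclose(traj.states[-1], -1.0, atol=1e-12)

    def test_mirror_symmetry_preserved(self, grid64, rng):
        """Symmetric initial data + symmetric forcing stay symmetric."""
        params = DimensionlessParams(eps_bar=0.06, tau_bar=2.0, delta_bar=1.0)
        phi0 = disk(grid64, center=(0.5, 0.4), radius=0.22, eps=0.06)
        raw = rng.standard_normal((10,) + grid64.shape)
        eta = raw + raw[:, :, ::-1]  # mirror about the vertical centreline
        traj = solve_forward(phi0, eta, np.full(10, phi0.mean()), params, 0.002, grid64)
        assert np.abs(traj.states[-1] - traj.states[-1][:, ::-1]).max() < 1e-12

    def test_energy_decreases_unforced(self, grid64):
        params = DimensionlessParams(eps_bar=0.08, tau_bar=1.0, delta_bar=1.0)
        # strictly inside the stability region of the explicit potential term
        dt = 0.5 * params.eps_bar**2 / params.delta_bar
        phi0 = disk(grid64, center=(0.45, 0.55), radius=0.25, eps=0.08)
        eta = np.zeros((50,) + grid64.shape)
        traj = solve_forward(phi0, eta, None, params, dt, grid64)
        energies = [ginzburg_landau_energy(s, params, grid64) for s in traj.states]
        assert np.all(np.diff(energies) <= 1e-12)

    def test_curvature_flow_matches_shrinking_circle_law(self):
        """Scaled-down mean-curvature benchmark in the sharp-interface regime.

        The diffuse model tracks R^2 = R0^2 - 2 (delta/tau) t to within 2%
        while the radius stays large against the interfacial width (here
        R >= 5.5 eps_bar).
        """
        from cellforce.verification import shrinking_circle_benchmark

        out = shrinking_circle_benchmark(
            n=128, eps_bar=0.04, dt=3e-5, r_stop_factor=5.5, n_checkpoints=3
        )
        assert out["max_rel_err"] < 0.02

    def test_grid_refinement_consistency(self):
        """Zero-level radius at fixed time moves < 1% from 128^2 to 256^2."""
        t_end, dt, eps = 0.005, 2e-5, 0.04
        radii = {}
        for n in (128, 256):
            grid = GridSpec(n=n)
            params = DimensionlessParams(eps_bar=eps, tau_bar=1.0, delta_bar=1.0)
            eta = np.zeros((int(t_end / dt),) + grid.shape)
            traj = solve_forward(disk(grid, eps=eps), eta, None, params, dt, grid, store_every=len(eta))
            radii[n] = zero_level_radius(traj.states[-1], grid)
        assert abs(radii[128] - radii[256]) / radii[256] < 0.01

    def test_store_every_strides_states(self, grid32, params_small):
        eta = np.zeros((10,) + grid32.shape)
        traj = solve_forward(np.ones(grid32.shape), eta, None, params_small, 0.01, grid32, store_every=5)
        assert traj.states.shape[0] == 3
        assert traj.times[-1] == pytest.approx(0.1)

    def test_blowup_is_diagnosed(self, grid32):
        params = DimensionlessParams(eps_bar=0.02, tau_bar=1.0, delta_bar=1.0)
        eta = np.zeros((200,) + grid32.shape)
        from cellforce.forward_solver import SolverError

        with pytest.raises(SolverError):
            solve_forward(disk(grid32, eps=0.02), eta, None, params, 0.05, grid32)


class TestControlAndMassContainers:
    def test_control_zeroed_outside_mask(self, grid32, rng):
        vals = rng.standard_normal((3,) + grid32.shape)
        mask = np.zeros((3,) + grid32.shape, dtype=bool)
        mask[:, 10:20, 10:20] = True
        cf = ControlField(vals, mask)
        assert np.all(cf.values[~mask] == 0.0)
        assert np.any(cf.values[mask] != 0.0)

    def test_mass_target_linear_ramp(self):
        mt = MassTarget.linear(-0.5, -0.3, 4)
        assert np.allclose(mt.values, [-0.45, -0.4, -0.35, -0.3])

    def test_stable_substeps_scales_with_interface_width(self):
        p_fine = DimensionlessParams(eps_bar=0.01, tau_bar=4.83, delta_bar=1.0, RTS=10)
        p_coarse = DimensionlessParams(eps_bar=0.05, tau_bar=7.04, delta_bar=1.0, RTS=5)
        assert stable_substeps(p_fine, 1.0 / 18) > stable_substeps(p_coarse, 1.0 / 6)
        assert stable_substeps(p_coarse, 1e-6) == 1
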