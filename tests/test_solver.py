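import numpy as np
import pytest

from clgflow3d import (
    FlowParams,
    MotionField,
    clg_energy,
    divergence,
    jacobi_sweep,
    jacobi_sweep_incompressible,
    neg_laplacian,
    residual_norm,
    solve_flow,
)
from clgflow3d.derivatives import TensorField
from clgflow3d.solver import neighbor_count

from _oracles import dense_solve_motion, random_tensor_field, scalar_jacobi_sweep


def _tensor_from_dict(J):
    return TensorField(**J)


def _zero_tensor(dims):
    return TensorField(**{k: np.zeros(dims) for k in
                          ("j11", "j22", "j33", "j12", "j13", "j23", "j14", "j24", "j34")})


class TestFlowParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": -1.0},
            {"beta": -0.5},
            {"h": 0.0},
            {"jacobi_iters": 0},
            {"outer_passes": 0},
            {"tol": -1e-3},
            {"border": "mirror"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FlowParams(**kwargs)


class TestNegLaplacian:
    def test_constant_field_zero(self):
        assert np.all(neg_laplacian(np.full((4, 5, 6), 2.5), h=1.0) == 0)

    def test_linear_ramp_zero_in_interior(self):
        x = np.arange(6.0)
        f = np.broadcast_to(x[:, None, None], (6, 5, 5)).copy()
        out = neg_laplacian(f, h=1.0)
        assert np.all(np.abs(out[1:-1, 1:-1, 1:-1]) < 1e-12)

    def test_quadratic_gives_minus_two(self):
        # f = x^2: stencil (x+1)^2 + (x-1)^2 - 2x^2 = 2, sign-flipped -> -2
        x = np.arange(7.0)
        f = np.broadcast_to((x**2)[:, None, None], (7, 5, 5)).copy()
        out = neg_laplacian(f, h=1.0)
        assert np.all(np.abs(out[1:-1, 1:-1, 1:-1] - (-2.0)) < 1e-12)

    def test_h_scaling(self):
        x = np.arange(7.0)
        f = np.broadcast_to((x**2)[:, None, None], (7, 5, 5)).copy()
        out = neg_laplacian(f, h=0.5)
        assert out[3, 2, 2] == pytest.approx(-8.0)

    def test_neighbor_count_stencil(self):
        n = neighbor_count((4, 4, 4))
        assert n[0, 0, 0] == 3  # corner
        assert n[0, 0, 2] == 4  # edge
        assert n[0, 2, 2] == 5  # face
        assert n[2, 2, 2] == 6  # interior
        assert set(np.unique(n)) == {3.0, 4.0, 5.0, 6.0}


class TestJacobiSweep:
    def test_zero_system_fixed_point(self):
        dims = (4, 4, 4)
        out = jacobi_sweep(MotionField.zeros(dims), _zero_tensor(dims), FlowParams(alpha=1.0))
        assert np.all(out.u == 0) and np.all(out.v == 0) and np.all(out.w == 0)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 100.0])
    def test_analytic_fixed_point_unit_diagonal(self, alpha):
        # j11=j22=j33=1, j14=-1: u=1, v=w=0 reproduces itself exactly
        dims = (4, 5, 4)
        J = {k: np.zeros(dims) for k in
             ("j11", "j22", "j33", "j12", "j13", "j23", "j14", "j24", "j34")}
        J["j11"] = np.ones(dims)
        J["j22"] = np.ones(dims)
        J["j33"] = np.ones(dims)
        J["j14"] = -np.ones(dims)
        motion = MotionField(np.ones(dims), np.zeros(dims), np.zeros(dims))
        out = jacobi_sweep(motion, _tensor_from_dict(J), FlowParams(alpha=alpha))
        np.testing.assert_array_equal(out.u, np.ones(dims))
        np.testing.assert_array_equal(out.v, np.zeros(dims))
        np.testing.assert_array_equal(out.w, np.zeros(dims))

    def test_single_sweep_matches_scalar_loop_oracle(self, rng):
        dims = (3, 3, 3)
        J = random_tensor_field(rng, dims)
        motion = MotionField(*(rng.normal(size=dims) for _ in range(3)))
        p = FlowParams(alpha=0.7, h=1.3)
        out = jacobi_sweep(motion, _tensor_from_dict(J), p)
        eu, ev, ew = scalar_jacobi_sweep(motion.u, motion.v, motion.w, J, p.alpha, p.h)
        np.testing.assert_allclose(out.u, eu, atol=1e-13)
        np.testing.assert_allclose(out.v, ev, atol=1e-13)
        np.testing.assert_allclose(out.w, ew, atol=1e-13)

    def test_rejects_nonzero_beta(self):
        dims = (3, 3, 3)
        with pytest.raises(ValueError):
            jacobi_sweep(MotionField.zeros(dims), _zero_tensor(dims), FlowParams(beta=1.0))

    def test_alpha_tensor_joint_scaling_invariance(self, rng):
        # multiplying alpha and all tensor entries by the same factor leaves
        # the update unchanged (only h^2 J / alpha enters)
        dims = (4, 4, 4)
        J = random_tensor_field(rng, dims)
        motion = MotionField(*(rng.normal(size=dims) for _ in range(3)))
        out1 = jacobi_sweep(motion, _tensor_from_dict(J), FlowParams(alpha=1.0))
        J5 = {k: 5.0 * v for k, v in J.items()}
        out2 = jacobi_sweep(motion, _tensor_from_dict(J5), FlowParams(alpha=5.0))
        np.testing.assert_allclose(out1.u, out2.u, atol=1e-13)
        np.testing.assert_allclose(out1.v, out2.v, atol=1e-13)
        np.testing.assert_allclose(out1.w, out2.w, atol=1e-13)

    def test_axis_relabel_symmetry(self, rng):
        # swapping x and y (with the matching tensor permutation) swaps u,v
        dims = (4, 4, 4)
        J = random_tensor_field(rng, dims)
        motion = MotionField(*(rng.normal(size=dims) for _ in range(3)))
        p = FlowParams(alpha=1.0)
        out = jacobi_sweep(motion, _tensor_from_dict(J), p)

        def sw(a):
            return np.swapaxes(a, 0, 1)

        J_perm = {
            "j11": sw(J["j22"]), "j22": sw(J["j11"]), "j33": sw(J["j33"]),
            "j12": sw(J["j12"]), "j13": sw(J["j23"]), "j23": sw(J["j13"]),
            "j14": sw(J["j24"]), "j24": sw(J["j14"]), "j34": sw(J["j34"]),
        }
        motion_perm = MotionField(sw(motion.v), sw(motion.u), sw(motion.w))
        out_perm = jacobi_sweep(motion_perm, _tensor_from_dict(J_perm), p)
        np.testing.assert_allclose(out_perm.u, sw(out.v), atol=1e-13)
        np.testing.assert_allclose(out_perm.v, sw(out.u), atol=1e-13)
        np.testing.assert_allclose(out_perm.w, sw(out.w), atol=1e-13)


class TestIncompressibleSweep:
    def test_beta_zero_bitwise_identical_to_base(self, rng):
        dims = (4, 4, 4)
        J = random_tensor_field(rng, dims)
        motion = MotionField(*(rng.normal(size=dims) for _ in range(3)))
        p = FlowParams(alpha=1.0, beta=0.0)
        a = jacobi_sweep(motion, _tensor_from_dict(J), p)
        b = jacobi_sweep_incompressible(motion, _tensor_from_dict(J), p)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v) and np.array_equal(a.w, b.w)

    @pytest.mark.parametrize("beta_frac", [0.0, 0.5])
    def test_converged_solution_matches_dense_direct_solve(self, rng, beta_frac):
        # gradient scale ~3 with alpha=0.3 keeps the data term strong enough
        # that the Jacobi iteration contracts fast on all modes
        dims = (5, 5, 5)
        J = random_tensor_field(rng, dims, grad_scale=3.0)
        alpha = 0.3
        p = FlowParams(alpha=alpha, beta=beta_frac * alpha, jacobi_iters=2000)
        sol = solve_flow(_tensor_from_dict(J), p)
        eu, ev, ew = dense_solve_motion(J, alpha, p.beta, p.h, dims)
        assert np.max(np.abs(sol.u - eu)) < 1e-6
        assert np.max(np.abs(sol.v - ev)) < 1e-6
        assert np.max(np.abs(sol.w - ew)) < 1e-6

    def test_fixed_point_consistency_with_direct_solve(self, rng):
        dims = (4, 4, 4)
        J = random_tensor_field(rng, dims)
        p = FlowParams(alpha=1.0, beta=0.5)
        eu, ev, ew = dense_solve_motion(J, p.alpha, p.beta, p.h, dims)
        exact = MotionField(eu, ev, ew)
        out = jacobi_sweep_incompressible(exact, _tensor_from_dict(J), p)
        assert np.max(np.abs(out.u - eu)) < 1e-8
        assert np.max(np.abs(out.v - ev)) < 1e-8
        assert np.max(np.abs(out.w - ew)) < 1e-8


class TestSolveFlow:
    def test_zero_rhs_zero_solution(self, rng):
        dims = (4, 4, 4)
        J = random_tensor_field(rng, dims)
        for k in ("j14", "j24", "j34"):
            J[k] = np.zeros(dims)
        sol = solve_flow(_tensor_from_dict(J), FlowParams(alpha=1.0, jacobi_iters=50))
        assert np.all(sol.u == 0) and np.all(sol.v == 0) and np.all(sol.w == 0)

    def test_residual_not_increased(self, rng):
        dims = (5, 5, 5)
        J = random_tensor_field(rng, dims)
        p = FlowParams(alpha=1.0, jacobi_iters=100)
        init = MotionField.zeros(dims)
        r0 = residual_norm(init, _tensor_from_dict(J), p)
        sol = solve_flow(_tensor_from_dict(J), p)
        assert residual_norm(sol, _tensor_from_dict(J), p) <= r0

    def test_early_stop_reduces_sweeps(self, rng):
        dims = (5, 5, 5)
        J = random_tensor_field(rng, dims, grad_scale=3.0)
        log: list = []
        p = FlowParams(alpha=0.3, jacobi_iters=2000, tol=1e-8)
        solve_flow(_tensor_from_dict(J), p, residual_log=log)
        assert 0 < len(log) < 2000


class TestResidualAndEnergy:
    def test_hand_assembled_exact_solution_has_zero_residual(self, rng):
        # build rhs from a known solution: j14 = -alpha*neg_lap(u) - j11*u
        # with pure diagonal tensor and decoupled components
        dims = (2, 2, 2)
        alpha = 2.0
        u = rng.normal(size=dims)
        J = {k: np.zeros(dims) for k in
             ("j11", "j22", "j33", "j12", "j13", "j23", "j14", "j24", "j34")}
        J["j11"] = np.full(dims, 1.5)
        J["j14"] = -alpha * neg_laplacian(u, 1.0) - J["j11"] * u
        motion = MotionField(u, np.zeros(dims), np.zeros(dims))
        p = FlowParams(alpha=alpha)
        assert residual_norm(motion, _tensor_from_dict(J), p) < 1e-10

    def test_zero_everything_zero_residual_and_energy(self):
        dims = (3, 3, 3)
        p = FlowParams(alpha=1.0)
        motion = MotionField.zeros(dims)
        assert residual_norm(motion, _zero_tensor(dims), p) == 0
        assert clg_energy(motion, _zero_tensor(dims), p) == 0

    def test_zero_motion_energy_drops_constant_term(self, rng):
        # with zero motion only the (excluded) j44 term of w^T J w survives,
        # so the reported energy is exactly zero
        dims = (4, 4, 4)
        J = random_tensor_field(rng, dims)
        p = FlowParams(alpha=1.0)
        assert clg_energy(MotionField.zeros(dims), _tensor_from_dict(J), p) == 0

    def test_solver_output_lowers_energy(self, rng):
        dims = (6, 6, 6)
        J = random_tensor_field(rng, dims)
        p = FlowParams(alpha=1.0, jacobi_iters=500)
        sol = solve_flow(_tensor_from_dict(J), p)
        e0 = clg_energy(MotionField.zeros(dims), _tensor_from_dict(J), p)
        assert clg_energy(sol, _tensor_from_dict(J), p) <= e0


class TestDivergence:
    def test_uniform_field_divergence_free(self):
        dims = (5, 5, 5)
        f = MotionField(np.full(dims, 0.3), np.full(dims, -0.2), np.full(dims, 0.1))
        assert np.all(divergence(f) == 0)

    def test_linear_expansion_rate(self):
        dims = (6, 6, 6)
        x, y, z = np.meshgrid(*(np.arange(6.0),) * 3, indexing="ij")
        f = MotionField(0.1 * x, 0.1 * y, 0.1 * z)
        np.testing.assert_allclose(divergence(f), 0.3, atol=1e-12)
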