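import math

import numpy as np
import pytest

from wanscfd.exact import ExactSolutionParams, exact_temperature, exact_velocity
from wanscfd.fractional import cpc_kernels
from wanscfd.params import PhysicalParams, compute_pde_coefficients
from wanscfd.solver import (
    BoundaryData,
    FieldHistory,
    SchemeSpec,
    advance,
    assemble_temperature_step,
    assemble_velocity_step,
    solve,
)
from wanscfd.stencils import GridSpec, interior_operator, second_order_stencil


def classical_theta_stepper(grid, D, omega, left_value=1.0):
    """Independent classical theta-scheme for the heat equation (reference).

    (u^{j+1} - u^j)/dt = D [ (1-omega) S u^{j+1} + omega S u^j ], 3-point S.
    """
    S, b_lo, b_hi = interior_operator(grid.N, second_order_stencil(grid.h))
    S = S.toarray()
    n = grid.N - 1
    M = np.eye(n) / grid.dt - D * (1.0 - omega) * S
    field = np.zeros(grid.N + 1)
    out = [field.copy()]
    for j in range(grid.Z):
        rhs = field[1:-1] / grid.dt + D * omega * (S @ field[1:-1] + b_lo * field[0])
        rhs += D * (1.0 - omega) * b_lo * left_value
        new = np.zeros(grid.N + 1)
        new[0] = left_value
        new[1:-1] = np.linalg.solve(M, rhs)
        field = new
        out.append(field.copy())
    return np.array(out)


@pytest.fixture
def small_grid():
    return GridSpec(l=2.0, N=16, T=0.4, Z=20)


class TestAssembly:
    def test_zero_state_zero_boundary_stays_zero(self, neutral_params, small_grid):
        coef = compute_pde_coefficients(neutral_params)
        cpc = cpc_kernels(0.7, small_grid.T)
        hist = FieldHistory.initial(small_grid)
        sys_ = assemble_temperature_step(
            hist, coef, cpc, SchemeSpec(), small_grid, boundary=BoundaryData.homogeneous()
        )
        assert np.abs(sys_.rhs).max() == 0.0

    def test_alpha_one_implicit_matrix_is_backward_euler(self, neutral_params, small_grid):
        coef = compute_pde_coefficients(neutral_params)
        cpc = cpc_kernels(1.0, small_grid.T)
        scheme = SchemeSpec(omega=0.0, stencil_order=2)
        hist = FieldHistory.initial(small_grid)
        sys_ = assemble_temperature_step(hist, coef, cpc, scheme, small_grid)
        S, _, _ = interior_operator(small_grid.N, second_order_stencil(small_grid.h))
        be = np.eye(small_grid.N - 1) - small_grid.dt * coef.F * S.toarray()
        assert np.allclose(small_grid.dt * sys_.matrix.toarray(), be, atol=1e-13)

    def test_fully_explicit_matrix_is_scaled_identity(self, neutral_params, small_grid):
        coef = compute_pde_coefficients(neutral_params)
        cpc = cpc_kernels(0.8, small_grid.T)
        sys_ = assemble_velocity_step(
            FieldHistory.initial(small_grid), coef, cpc, SchemeSpec(omega=1.0), small_grid
        )
        M = sys_.matrix.toarray()
        assert np.allclose(M, M[0, 0] * np.eye(small_grid.N - 1), atol=1e-14)

    def test_velocity_system_ignores_theta_when_gr_zero(self, neutral_params, small_grid):
        coef = compute_pde_coefficients(neutral_params)  # Gr=0 -> C=0
        cpc = cpc_kernels(0.8, small_grid.T)
        hist = FieldHistory.initial(small_grid)
        hist.theta[0] = np.random.default_rng(3).uniform(size=small_grid.N + 1)
        sys_a = assemble_velocity_step(hist, coef, cpc, SchemeSpec(), small_grid)
        hist.theta[0] = 0.0
        sys_b = assemble_velocity_step(hist, coef, cpc, SchemeSpec(), small_grid)
        assert np.array_equal(sys_a.rhs, sys_b.rhs)

    def test_one_implicit_step_respects_maximum_principle(self, neutral_params):
        # start from rest with wall value 1: interior stays within [0, 1]
        grid = GridSpec(l=2.0, N=16, T=0.01, Z=1)
        coef = compute_pde_coefficients(neutral_params)
        cpc = cpc_kernels(0.9, grid.T)
        hist = FieldHistory.initial(grid)
        hist = advance(hist, coef, cpc, SchemeSpec(omega=0.0), grid)
        assert np.all(hist.u[1, 1:-1] >= -1e-12)
        assert np.all(hist.u[1, 1:-1] <= 1.0 + 1e-12)


class TestAdvanceAndSolve:
    def test_zero_steps_returns_initial_only(self, neutral_params):
        grid = GridSpec(l=2.0, N=8, T=1.0, Z=0)
        hist = solve(neutral_params, grid, SchemeSpec(), alpha=0.5)
        assert hist.level == 0 and np.abs(hist.u).max() == 0.0

    def test_boundary_enforced_with_oscillation(self):
        params = PhysicalParams(phi=0.0, gamma=1.0, M_mag=0.5, K_perm=1.0, Pr=25.0,
                                Gr=0.0, Q_freq=2.0)
        grid = GridSpec(l=2.0, N=10, T=1.0, Z=8)
        hist = solve(params, grid, SchemeSpec(), alpha=0.6)
        for j in range(1, grid.Z + 1):
            assert hist.u[j, 0] == pytest.approx(math.cos(2.0 * grid.times[j]))
            assert hist.theta[j, 0] == 1.0
            assert hist.u[j, -1] == 0.0
        assert hist.u[0, 0] == 0.0  # initial condition owns the corner

    def test_deterministic(self, neutral_params, small_grid):
        a = solve(neutral_params, small_grid, SchemeSpec(), alpha=0.7)
        b = solve(neutral_params, small_grid, SchemeSpec(), alpha=0.7)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.theta, b.theta)

    def test_linearity_in_boundary_data(self, neutral_params, small_grid):
        cpc = cpc_kernels(0.6, small_grid.T)
        base = BoundaryData.plate(0.0)
        scaled = BoundaryData(
            u_left=lambda t: 3.0, u_right=lambda t: 0.0,
            theta_left=lambda t: 3.0, theta_right=lambda t: 0.0,
        )
        h1 = solve(neutral_params, small_grid, SchemeSpec(), cpc, boundary=base)
        h3 = solve(neutral_params, small_grid, SchemeSpec(), cpc, boundary=scaled)
        assert np.allclose(3.0 * h1.u, h3.u, atol=1e-11)
        assert np.allclose(3.0 * h1.theta, h3.theta, atol=1e-11)

    def test_temperature_decoupled_from_velocity_parameters(self, small_grid):
        p1 = PhysicalParams(phi=0.0, gamma=1.0, M_mag=0.5, K_perm=1.0, Pr=25.0, Gr=0.0)
        p2 = PhysicalParams(phi=0.0, gamma=0.2, M_mag=4.0, K_perm=0.5, Pr=25.0, Gr=0.0)
        h1 = solve(p1, small_grid, SchemeSpec(), alpha=0.7)
        h2 = solve(p2, small_grid, SchemeSpec(), alpha=0.7)
        assert np.array_equal(h1.theta, h2.theta)

    def test_theta_profile_monotone_in_space(self, neutral_params):
        # the 3-point implicit operator is an M-matrix: diffusion from the hot
        # wall gives strictly monotone profiles; the compact stencil is only
        # near-monotone (tiny oscillations at an under-resolved front)
        grid = GridSpec(l=3.0, N=30, T=0.5, Z=40)
        hist = solve(neutral_params, grid, SchemeSpec(omega=0.0, stencil_order=2), alpha=1.0)
        for j in (10, 25, 40):
            assert np.all(np.diff(hist.theta[j]) <= 1e-12)
        hist4 = solve(neutral_params, grid, SchemeSpec(omega=0.0, stencil_order=4), alpha=1.0)
        for j in (10, 25, 40):
            assert np.all(np.diff(hist4.theta[j]) <= 1e-3)

    def test_alpha_one_matches_classical_reference_stepper(self, neutral_params):
        # K1 = 0 kills the RL history; the L1 sum collapses to a first
        # difference: the CPC stepper must agree with a plain theta-scheme
        grid = GridSpec(l=2.0, N=12, T=0.2, Z=10)
        coef = compute_pde_coefficients(neutral_params)
        for omega in (0.0, 0.5):
            hist = solve(neutral_params, grid, SchemeSpec(omega=omega, stencil_order=2),
                         alpha=1.0)
            ref = classical_theta_stepper(grid, coef.F, omega)
            assert np.abs(hist.theta - ref).max() < 1e-10

    def test_classical_crank_nicolson_converges_to_erfc(self, neutral_params):
        p = ExactSolutionParams.from_physical(neutral_params)
        errs_th, errs_u = [], []
        for N, Z in ((60, 30), (120, 120)):
            grid = GridSpec(l=6.0, N=N, T=0.5, Z=Z)
            hist = solve(neutral_params, grid, SchemeSpec(omega=0.5), alpha=1.0)
            xi = grid.xi[1:-1]
            errs_th.append(np.abs(hist.theta[-1, 1:-1] - exact_temperature(xi, 0.5, p)).max())
            errs_u.append(np.abs(hist.u[-1, 1:-1] - exact_velocity(xi, 0.5, p)).max())
        assert errs_th[1] < errs_th[0] and errs_th[1] < 5e-3
        assert errs_u[1] < errs_u[0] and errs_u[1] < 1e-3

    def test_fractional_refinement_reduces_error(self, neutral_params):
        # against the classical reference the *discretization* part of the
        # error shrinks when the mesh is refined at fixed alpha
        p = ExactSolutionParams.from_physical(neutral_params)
        errs = []
        for N, Z in ((20, 30), (40, 60)):
            grid = GridSpec(l=4.0, N=N, T=0.5, Z=Z)
            hist = solve(neutral_params, grid, SchemeSpec(omega=0.0), alpha=0.95)
            xi = grid.xi[1:-1]
            errs.append(np.abs(hist.u[-1, 1:-1] - exact_velocity(xi, 0.5, p)).max())
        assert errs[1] < errs[0]

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_blowup_reported_with_context(self, neutral_params):
        grid = GridSpec(l=2.0, N=32, T=20.0, Z=200)  # explicit, huge dt
        with pytest.raises(np.linalg.LinAlgError, match="omega=1.0"):
            solve(neutral_params, grid, SchemeSpec(omega=1.0), alpha=0.9)
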