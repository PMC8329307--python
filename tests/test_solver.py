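"""Residual assembly, objective, Lagrangian, stationarity and solve()."""

import math

import numpy as np
import pytest

import fracspectral as fs
from fracspectral.basis import gslp_q_matrix
from fracspectral.model import FractionalOrders, fbccm_system
from fracspectral.oracle import manufactured_system
from fracspectral.solver import (
    CandidateSolution,
    QuadratureRule,
    SolverOptions,
    assemble_residuals,
    constraint_vector,
    embed_candidate,
    evaluate_solution,
    lagrangian,
    objective,
    solve,
    stationarity_system,
)


def exact_manufactured_candidate(p, eta):
    """Candidate that represents y = t^p exactly in an m = 1 basis.

    With alpha_1 = p - 1 the basis functions are (1, -1 + 2 t^p), so
    y = 0.5 * 1 + 0.5 * (-1 + 2 t^p) = t^p.
    """
    return CandidateSolution(
        coeffs=[np.array([0.5, 0.5])], control_params=[np.array([p - 1.0])]
    )


@pytest.fixture
def small_candidate(rng):
    """Random admissible candidate on the five-compartment model, m_i = 2."""
    return CandidateSolution(
        coeffs=[rng.standard_normal(3) * s for s in (1e6, 1e7, 1e7, 1e5, 1e2)],
        control_params=[rng.uniform(-0.4, 0.5, 2) for _ in range(5)],
    )


@pytest.fixture
def quad16():
    return QuadratureRule.gauss_legendre(16, 1.0)


class TestResiduals:
    def test_manufactured_candidate_is_exact(self):
        p, eta = 1.3, 0.5
        system = manufactured_system(p, eta)
        cand = exact_manufactured_candidate(p, eta)
        t = np.linspace(0.05, 1.0, 10)
        res = assemble_residuals(cand, t, system)
        assert np.max(np.abs(res)) < 1e-10

    def test_equilibrium_constant_candidate(self):
        """A constant expansion at a fixed point has zero residuals: the
        spectral derivative of a constant vanishes and so does the rhs."""
        system = manufactured_system(2.0, 0.8)  # D^0.8 y = forcing, y(0)=0

        # for the zero-forcing system dy = 0 use rhs = 0 via a null system
        def zero_rhs(t, state, orders):
            return np.zeros_like(np.asarray(state))

        null = fs.FractionalSystem(
            dimension=1,
            rhs=zero_rhs,
            initial_state=np.array([3.0]),
            orders=system.orders,
        )
        cand = CandidateSolution(
            coeffs=[np.array([3.0, 0.0])], control_params=[np.array([0.0])]
        )
        res = assemble_residuals(cand, np.linspace(0.1, 1, 7), null)
        assert np.max(np.abs(res)) == 0.0

    def test_domain_error_at_zero(self, small_candidate):
        system = fbccm_system()
        with pytest.raises(ValueError):
            assemble_residuals(small_candidate, 0.0, system)

    def test_coefficient_sensitivity(self, small_candidate, quad16):
        system = fbccm_system()
        base = assemble_residuals(small_candidate, quad16.nodes, system, scaled=True)
        for i in (0, 3):
            pert = CandidateSolution(
                coeffs=[c.copy() for c in small_candidate.coeffs],
                control_params=[a.copy() for a in small_candidate.control_params],
            )
            pert.coeffs[i][1] *= 1.01
            moved = assemble_residuals(pert, quad16.nodes, system, scaled=True)
            assert np.max(np.abs(moved - base)) > 0


class TestConstraints:
    def test_leading_coefficient_only(self):
        ic = np.array(fs.example_initial_conditions())
        cand = CandidateSolution(
            coeffs=[np.concatenate(([v], np.zeros(2))) for v in ic],
            control_params=[np.zeros(2)] * 5,
        )
        assert np.allclose(constraint_vector(cand, ic), 0.0)

    def test_zero_candidate(self):
        ic = np.array(fs.example_initial_conditions())
        cand = CandidateSolution(
            coeffs=[np.zeros(3)] * 5, control_params=[np.zeros(2)] * 5
        )
        assert np.allclose(constraint_vector(cand, ic), -ic)

    def test_linearity_in_coefficients(self, rng):
        ic = np.zeros(5)
        a = CandidateSolution(
            coeffs=[rng.standard_normal(3) for _ in range(5)],
            control_params=[np.zeros(2)] * 5,
        )
        b = CandidateSolution(
            coeffs=[2 * c for c in a.coeffs], control_params=[np.zeros(2)] * 5
        )
        assert np.allclose(
            constraint_vector(b, ic), 2 * constraint_vector(a, ic), rtol=1e-13
        )


class TestObjective:
    def test_exact_solution_gives_zero(self, quad16):
        system = manufactured_system(1.3, 0.5)
        cand = exact_manufactured_candidate(1.3, 0.5)
        assert objective(cand, quad16, system) < 1e-18

    def test_quadratic_scaling(self, quad16):
        """For a linear residual map (zero rhs), doubling the coefficients
        quadruples the objective."""

        def zero_rhs(t, state, orders):
            return np.zeros_like(np.asarray(state))

        null = fs.FractionalSystem(
            dimension=1,
            rhs=zero_rhs,
            initial_state=np.zeros(1),
            orders=FractionalOrders(0.6, 1, 1, 1, 1),
        )
        c1 = CandidateSolution(
            coeffs=[np.array([0.0, 1.0, -0.3])],
            control_params=[np.array([0.2, -0.1])],
        )
        c2 = CandidateSolution(
            coeffs=[2 * c1.coeffs[0]], control_params=[c1.control_params[0]]
        )
        m1 = objective(c1, quad16, null)
        assert objective(c2, quad16, null) == pytest.approx(4 * m1, rel=1e-12)

    def test_against_dense_trapezoid(self, rng):
        """Gauss-Legendre objective vs a 1e4-point trapezoid reference, on a
        smooth candidate (classical orders, zero exponent shifts) where both
        rules converge."""
        system = fbccm_system()
        # positive trajectories keep the rational terms pole-free on [0, 1]
        cand = CandidateSolution(
            coeffs=[np.array([rng.uniform(0.5, 1.5), *(0.1 * rng.standard_normal(2))]) * s
                    for s in (1e6, 1e7, 1e7, 1e5, 1e2)],
            control_params=[np.zeros(2)] * 5,
        )
        quad = QuadratureRule.gauss_legendre(64, 1.0)
        m_gauss = objective(cand, quad, system, scaled=True)
        t = np.linspace(1e-9, 1.0, 10_001)
        res = assemble_residuals(cand, t, system, scaled=True)
        m_trap = np.trapezoid(np.sum(res**2, axis=0), t)
        assert m_gauss == pytest.approx(m_trap, rel=1e-6)

    def test_nonnegative(self, small_candidate, quad16):
        assert objective(small_candidate, quad16, fbccm_system()) >= 0


class TestLagrangianAndStationarity:
    def test_lambda_zero_reduces_to_objective(self, small_candidate, quad16):
        system = fbccm_system()
        J = lagrangian(small_candidate, np.zeros(5), quad16, system)
        assert J == pytest.approx(objective(small_candidate, quad16, system))

    def test_feasible_candidate_multiplier_free(self, quad16, rng):
        system = fbccm_system()
        ic = system.initial_state
        cand = CandidateSolution(
            coeffs=[np.concatenate(([v], rng.standard_normal(2) * abs(v) * 0.1))
                    for v in ic],
            control_params=[rng.uniform(-0.2, 0.4, 2) for _ in range(5)],
        )
        # enforce feasibility exactly: adjust leading coefficient
        for i in range(5):
            theta = constraint_vector(cand, ic)[i]
            cand.coeffs[i][0] -= theta
        J1 = lagrangian(cand, rng.standard_normal(5) * 10, quad16, system)
        J2 = lagrangian(cand, np.zeros(5), quad16, system)
        assert J1 == pytest.approx(J2, rel=1e-10)

    def test_linear_in_multipliers(self, small_candidate, quad16):
        system = fbccm_system()
        lam = np.arange(1.0, 6.0)
        J0 = lagrangian(small_candidate, np.zeros(5), quad16, system)
        J1 = lagrangian(small_candidate, lam, quad16, system)
        J2 = lagrangian(small_candidate, 2 * lam, quad16, system)
        assert J2 - J1 == pytest.approx(J1 - J0, rel=1e-10)

    def test_lambda_block_is_theta_exactly(self, quad16, rng):
        system = fbccm_system()
        cand = CandidateSolution(
            coeffs=[rng.standard_normal(3) * s for s in (1e6, 1e7, 1e7, 1e5, 1e2)],
            control_params=[rng.uniform(-0.3, 0.4, 2) for _ in range(5)],
        )
        grad = stationarity_system(cand, rng.standard_normal(5), quad16, system)
        theta = constraint_vector(cand, system.initial_state)
        assert np.array_equal(grad[-5:], theta)
        n_cand = sum(m + 1 for m in cand.basis_sizes) + sum(cand.basis_sizes)
        assert grad.size == n_cand + 5

    @staticmethod
    def _fd4(func, x0, k, h):
        """Fourth-order central difference along coordinate k."""
        def at(delta):
            x = x0.copy()
            x[k] += delta
            return func(x)

        return (-at(2 * h) + 8 * at(h) - 8 * at(-h) + at(-2 * h)) / (12 * h)

    def test_gradient_matches_finite_differences(self, quad16, rng):
        """Complex-step partials of the Lagrangian vs a 4th-order central
        finite-difference oracle, on random candidates (m_i = 2)."""
        from fracspectral.solver import _pack, _unpack

        system = fbccm_system()
        scales = np.array([1e6, 1e7, 1e7, 1e5, 1e2])
        for trial in range(3):
            cand = CandidateSolution(
                coeffs=[rng.standard_normal(3) * s for s in scales],
                control_params=[rng.uniform(-0.3, 0.4, 2) for _ in range(5)],
            )
            lam = rng.standard_normal(5)
            grad = stationarity_system(cand, lam, quad16, system)
            sizes = cand.basis_sizes
            x0 = _pack(cand)

            def J(x):
                return lagrangian(_unpack(x, sizes), lam, quad16, system)

            for k in rng.choice(x0.size, size=6, replace=False):
                h = 1e-4 * max(1.0, abs(x0[k]))
                fd = self._fd4(J, x0, k, h)
                # the FD oracle itself carries roundoff ~ eps*|J|/h
                noise = 1e-15 * abs(J(x0)) / h
                scale = max(abs(fd), abs(grad[k]), 1e-4)
                assert abs(grad[k] - fd) <= 1e-5 * scale + 4 * noise


class TestSolve:
    def test_manufactured_recovery(self):
        p, eta = 1.3, 0.5
        system = manufactured_system(p, eta)
        sol = solve(
            system,
            [1],
            SolverOptions(
                multistarts=2, initial_alphas=[np.array([p - 1])], quad_nodes=32
            ),
        )
        t = np.linspace(0, 1, 101)
        err = np.max(np.abs(sol.evaluate(t)["y1"].to_numpy() - t**p))
        assert err < 1e-8
        assert sol.objective < 1e-16

    def test_constraints_and_stationarity_at_optimum(self):
        system = manufactured_system(1.5, 0.7)
        sol = solve(
            system,
            [2],
            SolverOptions(multistarts=2, quad_nodes=32),
        )
        theta = constraint_vector(sol.candidate, system.initial_state)
        assert np.max(np.abs(theta)) < 1e-10  # eliminated exactly
        assert sol.diagnostics["stationarity_norm"] < 1e-4
        assert sol.objective >= 0

    def test_invalid_arguments(self):
        system = manufactured_system(1.0, 0.5)
        with pytest.raises(ValueError):
            solve(system, [0])
        with pytest.raises(ValueError):
            solve(system, [1, 1])
        with pytest.raises(ValueError):
            solve(system, [1], SolverOptions(horizon=-1.0))

    def test_deterministic_given_seed(self):
        system = manufactured_system(1.3, 0.5)
        opts = dict(multistarts=2, quad_nodes=16, seed=7, max_nfev=60,
                    polish_max_nfev=60)
        a = solve(system, [2], SolverOptions(**opts))
        b = solve(system, [2], SolverOptions(**opts))
        assert a.objective == b.objective
        for ca, cb in zip(a.candidate.coeffs, b.candidate.coeffs):
            assert np.array_equal(ca, cb)


class TestEmbedding:
    def test_embedding_preserves_trajectory(self, rng):
        cand = CandidateSolution(
            coeffs=[rng.standard_normal(3) for _ in range(2)],
            control_params=[rng.uniform(-0.3, 0.4, 2) for _ in range(2)],
        )
        big = embed_candidate(cand, [4, 3], np.array([0.7, 0.9]))
        t = np.linspace(0.0, 1.0, 33)
        for i in range(2):
            assert np.allclose(big.expansion(i, t), cand.expansion(i, t), atol=1e-9)


class TestEvaluate:
    def test_initial_row_and_shapes(self):
        system = manufactured_system(2.0, 1.0)
        sol = solve(system, [2], SolverOptions(multistarts=1, quad_nodes=16))
        t = np.linspace(0, 1, 11)
        table = sol.evaluate(t)
        assert len(table) == 11
        assert table["y1"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        with pytest.raises(ValueError):
            sol.evaluate([1.5])

    def test_constant_candidate_rows(self, quad16):
        sol = fs.SpectralSolution(
            candidate=CandidateSolution(
                coeffs=[np.array([4.2, 0.0])], control_params=[np.array([0.1])]
            ),
            multipliers=np.zeros(1),
            objective=0.0,
            horizon=1.0,
            diagnostics={},
            system=manufactured_system(1.0, 0.5),
            quad=quad16,
        )
        table = evaluate_solution(sol, np.linspace(0, 1, 5))
        assert np.allclose(table["y1"], 4.2)
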