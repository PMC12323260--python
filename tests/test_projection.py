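"""Multiplier solve, manifold projection and tangent-space noise projection."""

import numpy as np
import pytest

from shakediff.chains import build_chain, extended_chain_spec
from shakediff.constraints import (
    ConstraintSet,
    GeometricConstraint,
    RankDeficiencyError,
    gradient,
)
from shakediff.projection import (
    correction_norm,
    project,
    project_noise,
    solve_multipliers,
)
from conftest import random_se3


class TestSolveMultipliers:
    def test_zero_residual_gives_zero_multipliers(self, chain6, bond_set6):
        J, _ = bond_set6.jacobian(chain6)
        lam = solve_multipliers(J, np.zeros(5)).values
        assert np.allclose(lam, 0.0)

    def test_single_constraint_closed_form(self, rng):
        coords = rng.normal(size=(2, 3)) * 3.0
        con = GeometricConstraint("distance", (0, 1), 1.0)
        cs = ConstraintSet([con])
        J, sigma = cs.jacobian(coords)
        lam = solve_multipliers(J, sigma).values
        g = gradient(con, coords)
        assert lam[0] == pytest.approx(-sigma[0] / (g @ g), rel=1e-12)

    def test_orthogonal_gradients_decouple(self):
        # two distance constraints with disjoint atoms: diagonal Gram
        coords = np.array([[0.0, 0, 0], [0, 0, 2], [5, 0, 0], [5, 0, 3]])
        cs = ConstraintSet(
            [
                GeometricConstraint("distance", (0, 1), 1.0),
                GeometricConstraint("distance", (2, 3), 1.0),
            ]
        )
        J, sigma = cs.jacobian(coords)
        lam = solve_multipliers(J, sigma).values
        for a in range(2):
            assert lam[a] == pytest.approx(-sigma[a] / (J[a] @ J[a]), rel=1e-12)

    def test_duplicated_constraints_survive_via_regularization(self, chain6):
        # exactly-dependent but consistent rows: the Tikhonov rescue yields a
        # finite multiplier vector instead of failing
        c = GeometricConstraint("distance", (0, 1), 1.0)
        J, sigma = ConstraintSet([c, c]).jacobian(chain6)
        lam = solve_multipliers(J, sigma + 1.0).values
        assert np.all(np.isfinite(lam))

    def test_zero_jacobian_raises_rank_deficiency(self):
        with pytest.raises(RankDeficiencyError):
            solve_multipliers(np.zeros((2, 6)), np.ones(2))


class TestProject:
    def test_single_constraint_symmetric_split(self):
        x = np.array([[0.0, 0, 0], [0, 0, 2]])
        cs = ConstraintSet([GeometricConstraint("distance", (0, 1), 1.0)])
        res = project(x, cs, tol=1e-10)
        assert res.converged
        # both atoms displace by 0.5 along the axis
        assert np.allclose(res.coordinates, [[0, 0, 0.5], [0, 0, 1.5]], atol=1e-9)
        assert res.correction_norm == pytest.approx(np.sqrt(0.5), rel=1e-9)

    def test_feasible_input_is_fixed_point(self, chain6, bond_set6):
        res = project(chain6.coordinates, bond_set6)
        assert res.converged and res.iterations_used == 0
        assert np.array_equal(res.coordinates, chain6.coordinates)

    def test_default_tolerance_is_the_violation_acceptance(self, rng, chain6,
                                                           bond_set6):
        trial = chain6.coordinates + rng.normal(size=(6, 3)) * 0.4
        res = project(trial, bond_set6)
        assert res.converged
        assert res.final_max_residual <= 0.003

    def test_feasibility_over_randomized_trials(self, rng):
        chain = build_chain(extended_chain_spec(6))
        cs = ConstraintSet(
            [GeometricConstraint("distance", (i, i + 1), 1.53) for i in range(3)]
        )
        for _ in range(200):
            trial = chain.coordinates + rng.normal(size=(6, 3)) * 0.5
            res = project(trial, cs, tol=0.003)
            assert res.converged
            assert np.abs(cs.residuals(res.coordinates)).max() <= 0.003

    def test_idempotence_on_the_manifold(self, rng, chain6, bond_set6):
        trial = chain6.coordinates + rng.normal(size=(6, 3)) * 0.3
        once = project(trial, bond_set6, tol=0.003).coordinates
        twice = project(once, bond_set6, tol=0.003).coordinates
        assert np.linalg.norm(twice - once) < 0.003 / 10

    def test_correction_lies_in_jacobian_row_space(self, rng, chain6, bond_set6):
        # with the Jacobian frozen at the trial point, every correction is a
        # combination of the trial gradients, so the total displacement lies
        # exactly in the trial Jacobian's row space
        trial = chain6.coordinates + rng.normal(size=(6, 3)) * 0.3
        res = project(trial, bond_set6, tol=1e-7, refresh_jacobian=False,
                      max_iter=500)
        delta = (res.coordinates - trial).ravel()
        J, _ = bond_set6.jacobian(trial)
        coef, *_ = np.linalg.lstsq(J.T, delta, rcond=None)
        fit_residual = np.linalg.norm(J.T @ coef - delta)
        assert fit_residual < 1e-8

    def test_single_iteration_correction_identity(self, rng, chain6, bond_set6):
        trial = chain6.coordinates + rng.normal(size=(6, 3)) * 0.2
        J, sigma = bond_set6.jacobian(trial)
        lam = solve_multipliers(J, sigma).values
        res = project(trial, bond_set6, tol=1e30, max_iter=1)  # exactly one sweep
        # a tol this large converges immediately; force one iterate manually
        x1 = trial + (J.T @ lam).reshape(6, 3)
        assert correction_norm(trial, x1) == pytest.approx(
            np.linalg.norm(J.T @ lam), abs=1e-12
        )

    def test_se3_equivariance(self, rng):
        chain = build_chain(extended_chain_spec(5, torsion=70.0))
        cs = ConstraintSet(
            [
                GeometricConstraint("distance", (0, 4), 4.0),
                GeometricConstraint("angle", (0, 1, 2), 100.0),
                GeometricConstraint("dihedral", (0, 1, 2, 3), 60.0),
            ]
        )
        trial = chain.coordinates + rng.normal(size=(5, 3)) * 0.1
        R, t = random_se3(rng)
        direct = project(trial @ R.T + t, cs, tol=1e-10).coordinates
        mapped = project(trial, cs, tol=1e-10).coordinates @ R.T + t
        assert np.abs(direct - mapped).max() < 1e-8

    def test_single_constraint_matches_analytic_projection(self, rng):
        # nearest feasible point moves both atoms along the interatomic axis
        coords = rng.normal(size=(2, 3)) * 2.0
        target = 1.7
        cs = ConstraintSet([GeometricConstraint("distance", (0, 1), target)])
        res = project(coords, cs, tol=1e-10)
        axis = coords[0] - coords[1]
        r = np.linalg.norm(axis)
        axis /= r
        shift = 0.5 * (r - target)
        expected = np.array([coords[0] - shift * axis, coords[1] + shift * axis])
        assert np.abs(res.coordinates - expected).max() < 1e-6

    def test_nonconvergence_policy(self, chain6, bond_set6):
        far = chain6.coordinates * 50.0
        with pytest.raises(RuntimeError):
            project(far, bond_set6, tol=1e-12, max_iter=1)
        res = project(far, bond_set6, tol=1e-12, max_iter=1, on_failure="ignore")
        assert not res.converged

    def test_empty_set_returns_input(self, chain6):
        res = project(chain6.coordinates, ConstraintSet())
        assert res.converged and res.correction_norm == 0.0


class TestProjectNoise:
    def test_parallel_noise_is_annihilated(self, rng):
        coords = rng.normal(size=(2, 3)) * 2.0
        cs = ConstraintSet([GeometricConstraint("distance", (0, 1), 1.0)])
        g = cs[0].gradient(coords)
        out = project_noise(3.7 * g, cs, coords)
        assert np.abs(out).max() < 1e-10

    def test_idempotence(self, rng, chain6, bond_set6):
        eta = rng.normal(size=18)
        p1 = project_noise(eta, bond_set6, chain6)
        p2 = project_noise(p1, bond_set6, chain6)
        assert np.abs(p1 - p2).max() < 1e-10

    def test_orthogonal_to_every_gradient(self, rng, chain6, bond_set6):
        eta = rng.normal(size=18)
        out = project_noise(eta, bond_set6, chain6)
        J, _ = bond_set6.jacobian(chain6)
        assert np.abs(J @ out).max() < 1e-10

    def test_matches_gram_schmidt_oracle(self, rng):
        chain = build_chain(extended_chain_spec(5, torsion=70.0))
        cs = ConstraintSet(
            [
                GeometricConstraint("distance", (0, 1), 1.0),
                GeometricConstraint("distance", (1, 3), 2.0),
                GeometricConstraint("angle", (1, 2, 3), 100.0),
            ]
        )
        eta = rng.normal(size=15)
        out = project_noise(eta, cs, chain)
        # oracle: orthonormalize the gradient rows, subtract components
        J, _ = cs.jacobian(chain)
        basis = []
        for row in J:
            v = row.copy()
            for b in basis:
                v -= (v @ b) * b
            basis.append(v / np.linalg.norm(v))
        expected = eta.copy()
        for b in basis:
            expected -= (expected @ b) * b
        assert np.abs(out - expected).max() < 1e-10

    def test_rank_deficiency_raises(self, chain6, rng):
        c = GeometricConstraint("distance", (0, 1), 1.0)
        with pytest.raises(RankDeficiencyError):
            project_noise(rng.normal(size=18), ConstraintSet([c, c]), chain6)


class TestCorrectionNorm:
    def test_identity_and_pythagoras(self):
        x = np.zeros((2, 3))
        assert correction_norm(x, x) == 0.0
        y = x.copy()
        y[0] = [3.0, 4.0, 0.0]
        assert correction_norm(x, y) == pytest.approx(5.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            correction_norm(np.zeros((2, 3)), np.zeros((3, 3)))
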