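"""SHAKE-style Lagrange-multiplier projection onto the constraint manifold.

After an unconstrained trial step produces coordinates x~ that violate the
constraints, the projection repeats

    solve  sum_b lambda_b (grad sigma_a . grad sigma_b) = -sigma_a
    update x <- x - sum_a lambda_a grad sigma_a

until the largest (unit-weighted) residual falls below the violation
acceptance ``tol``.  The multiplier system is the A x A Gram system solved
directly (matrix SHAKE) so the gradient information of all constraints is
incorporated simultaneously; by default the Jacobian is re-evaluated every
iteration, i.e. full Newton iteration on sigma(x) = 0.

Tangent-space noise projection removes the component of a stochastic
increment along the constraint gradients:

    P = I - J^T (J J^T)^{-1} J,

the multi-constraint generalization of the single-constraint projector
I - (grad sigma)(grad sigma)^T / |grad sigma|^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .constraints import ConstraintSet, RankDeficiencyError, _coords_of

__all__ = [
    "Multipliers",
    "ProjectionResult",
    "ProjectionWarning",
    "solve_multipliers",
    "project",
    "project_noise",
    "correction_norm",
]

#: Default constraint-violation acceptance (Angstrom-equivalent units).
DEFAULT_TOL = 0.003

#: Degrees-to-Angstrom equivalence used when mixing angular and distance
#: residuals in one convergence norm: 1 degree counts as 0.01 A.
ANGULAR_WEIGHT = 0.01


class ProjectionWarning(UserWarning):
    pass


@dataclass
class Multipliers:
    """Lagrange multipliers lambda_a of one projection iteration."""

    values: np.ndarray


@dataclass
class ProjectionResult:
    coordinates: np.ndarray
    iterations_used: int
    final_max_residual: float
    converged: bool
    correction_norm: float


def _residual_weights(cset) -> np.ndarray:
    return np.array(
        [ANGULAR_WEIGHT if getattr(c, "angular", False) else 1.0 for c in cset]
    )


def solve_multipliers(jacobian: np.ndarray, residual: np.ndarray,
                      regularization: float = 0.0) -> Multipliers:
    """Solve the Gram system (G + regularization I) lambda = -sigma,
    G_ab = grad sigma_a . grad sigma_b.

    Falls back to a Tikhonov-regularized solve (eps = 1e-10 tr(G)/A) if the
    Cholesky factorization fails; raises :class:`RankDeficiencyError` if
    even the regularized system is numerically singular.
    """
    J = np.asarray(jacobian, dtype=float)
    sigma = np.asarray(residual, dtype=float)
    A = J.shape[0]
    if A == 0:
        return Multipliers(np.empty(0))
    G = J @ J.T
    if regularization:
        G = G + regularization * np.eye(A)
    try:
        lam = cho_solve(cho_factor(G), -sigma)
    except np.linalg.LinAlgError:
        eps = 1e-10 * np.trace(G) / A
        try:
            lam = cho_solve(cho_factor(G + eps * np.eye(A)), -sigma)
        except np.linalg.LinAlgError:
            from .constraints import RankReport

            sv = np.sqrt(np.maximum(np.linalg.eigvalsh(G)[::-1], 0.0))
            top = sv[0] if sv.size and sv[0] > 0 else 0.0
            rank = int(np.sum(sv > 1e-8 * top)) if top else 0
            report = RankReport(rank, sv, np.inf, rank == A)
            raise RankDeficiencyError(
                "constraint Gram matrix is numerically singular "
                "(linearly dependent constraint gradients)",
                report,
            ) from None
    if not np.all(np.isfinite(lam)):
        raise RankDeficiencyError("multiplier solve produced non-finite values")
    return Multipliers(lam)


def project(conf, cset: ConstraintSet, targets=None, tol: float = DEFAULT_TOL,
            max_iter: int = 100, refresh_jacobian: bool = True,
            on_failure: str = "raise") -> ProjectionResult:
    """Project trial coordinates onto the constraint manifold.

    Parameters
    ----------
    conf
        Trial coordinates (Conformation or (N, D) array). Not modified.
    cset
        Constraints to enforce as equalities.
    targets
        Optional per-constraint equality targets overriding each
        constraint's own (used for scheduled bound enforcement).
    tol
        Constraint-violation acceptance on the weighted max residual.
    max_iter
        Iteration cap.
    refresh_jacobian
        Re-evaluate the Jacobian at every iterate (full Newton); if False
        the Jacobian is frozen at the trial point, reproducing the classic
        SHAKE linearization.
    on_failure
        "raise" (default), "warn" or "ignore" on non-convergence.
    """
    coords0 = _coords_of(conf).copy()
    x = coords0.copy()
    weights = _residual_weights(cset)
    if len(cset) == 0:
        return ProjectionResult(x, 0, 0.0, True, 0.0)

    J_frozen = None
    iterations = 0
    converged = False
    max_res = np.inf
    for iterations in range(max_iter + 1):
        J, sigma = cset.jacobian(x, targets)
        max_res = float(np.max(np.abs(sigma) * weights))
        if max_res <= tol:
            converged = True
            break
        if iterations == max_iter:
            break
        if refresh_jacobian or J_frozen is None:
            J_use = J
            if not refresh_jacobian:
                J_frozen = J
        else:
            J_use = J_frozen
        lam = solve_multipliers(J_use, sigma).values
        # with G lam = -sigma, the Newton correction toward the manifold is
        # +J^T lam (equivalently -J^T G^{-1} sigma)
        x = x + (J_use.T @ lam).reshape(x.shape)

    if not converged:
        msg = (
            f"projection did not converge in {max_iter} iterations "
            f"(max residual {max_res:.3g} > tol {tol:g})"
        )
        if on_failure == "raise":
            raise RuntimeError(msg)
        if on_failure == "warn":
            warnings.warn(msg, ProjectionWarning, stacklevel=2)

    corr = float(np.linalg.norm(x - coords0))
    return ProjectionResult(x, iterations, max_res, converged, corr)


def project_noise(noise: np.ndarray, cset: ConstraintSet, conf,
                  targets=None) -> np.ndarray:
    """Project a flattened noise vector onto the constraint tangent space.

    Output = (I - J^T (J J^T)^{-1} J) noise; orthogonal to every constraint
    gradient.  Requires the Jacobian to have full row rank at ``conf``.
    """
    eta = np.asarray(noise, dtype=float).ravel()
    if len(cset) == 0:
        return eta.copy()
    J, _ = cset.jacobian(conf, targets)
    sv = np.linalg.svd(J, compute_uv=False)
    if sv[0] == 0 or sv[-1] <= 1e-10 * sv[0]:
        report = cset.rank_diagnostic(conf)
        raise RankDeficiencyError(
            "constraint Jacobian is rank deficient; tangent projection undefined",
            report,
        )
    coef = np.linalg.solve(J @ J.T, J @ eta)
    return eta - J.T @ coef


def correction_norm(before, after) -> float:
    """Euclidean norm of the flattened coordinate difference."""
    a = _coords_of(before)
    b = _coords_of(after)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(b - a))
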