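"""Harmonic-restraint guidance baseline.

Instead of projecting onto the constraint manifold, guidance adds the
gradient of a quadratic penalty

    U(x) = sum_a (k_a / 2) residual_a(x)^2

to each sampling step,

    x <- x - gamma * grad U(x),

treating every constraint independently (no multiplier solve couples
them).  For distance constraints this is exactly the harmonic-restraint
force k (r - d*) (x_i - x_j)/r; angular constraints use the analogous
quadratic penalty on their residuals.  Soft by construction: a single
guidance pass never guarantees residuals below a tolerance, which is the
behavior the projection method is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constraints import ConstraintSet, _coords_of

__all__ = ["GuidanceParams", "harmonic_energy", "harmonic_gradient", "guidance_step"]


@dataclass
class GuidanceParams:
    """Step size gamma, per-constraint force constants k_a and the number
    of inner iterations applied per sampler step.

    Defaults (k = 10 energy/A^2, gamma = 1e-3, one inner iteration) keep
    the update stable but visibly under-correcting, the regime in which
    soft guidance is a meaningful baseline.
    """

    step_size: float = 1e-3
    force_constants: object = 10.0  # scalar or per-constraint sequence
    inner_iterations: int = 1

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.inner_iterations < 1:
            raise ValueError("inner_iterations must be >= 1")
        ks = np.atleast_1d(np.asarray(self.force_constants, dtype=float))
        if np.any(ks <= 0):
            raise ValueError("force constants must be positive")

    def constants_for(self, n: int) -> np.ndarray:
        ks = np.atleast_1d(np.asarray(self.force_constants, dtype=float))
        if ks.size == 1:
            return np.full(n, ks[0])
        if ks.size != n:
            raise ValueError(f"{ks.size} force constants for {n} constraints")
        return ks


def harmonic_energy(cset: ConstraintSet, conf, params: GuidanceParams,
                    targets: Optional[Sequence[float]] = None) -> float:
    """Total restraint energy sum_a (k_a/2) residual_a^2 (zero iff all
    residuals vanish)."""
    ks = params.constants_for(len(cset))
    r = cset.residuals(conf, targets)
    return float(0.5 * np.sum(ks * r * r))


def harmonic_gradient(cset: ConstraintSet, conf,
                      params: GuidanceParams,
                      targets: Optional[Sequence[float]] = None) -> np.ndarray:
    """grad U(x) = sum_a k_a residual_a grad residual_a, flattened."""
    J, r = cset.jacobian(conf, targets)
    ks = params.constants_for(len(cset))
    return (ks * r) @ J


def guidance_step(conf, cset: ConstraintSet, params: GuidanceParams,
                  targets: Optional[Sequence[float]] = None):
    """Apply ``inner_iterations`` independent harmonic updates.

    Returns (new coordinates, correction norm).  Per-constraint increments
    are summed — constraints sharing an atom simply add their forces, with
    no coupling solve.
    """
    x = _coords_of(conf).copy()
    if len(cset) == 0:
        return x, 0.0
    x0 = x.copy()
    for _ in range(params.inner_iterations):
        g = harmonic_gradient(cset, x, params, targets)
        x = x - params.step_size * g.reshape(x.shape)
    return x, float(np.linalg.norm(x - x0))
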