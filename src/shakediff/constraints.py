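"""Geometric constraint primitives with analytic gradients.

A constraint is a scalar function sigma(x) of the Cartesian coordinates
x in R^{N x D} of a molecular system (D = 3 for molecules; 2D is allowed
for toy densities).  The residual is the *linear* form

    sigma(x) = value(x) - target,

where ``value`` is an interatomic distance (Angstrom), a bond angle or a
torsion (degrees).  The linear form keeps the constraint gradient nonzero
at feasibility, so the Gram matrix used by the multiplier solve stays
well conditioned near the solution; the squared form used in classical
presentations is available through :class:`SquaredConstraint`.

Angular residuals are wrapped to the shortest arc in (-180, 180] and the
gradients are expressed in degrees per Angstrom so that analytic and
finite-difference derivatives agree in a single unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Conformation",
    "GeometricConstraint",
    "RadialConstraint",
    "SquaredConstraint",
    "ConstraintSet",
    "RankReport",
    "DegenerateGeometryError",
    "RankDeficiencyError",
    "evaluate",
    "gradient",
    "jacobian",
    "rank_diagnostic",
    "wrap_degrees",
]

#: Interatomic separations below this (Angstrom) are treated as degenerate.
MIN_SEPARATION = 1e-8

_RAD2DEG = 180.0 / np.pi


class DegenerateGeometryError(ValueError):
    """Raised when a constraint frame is geometrically degenerate
    (coincident atoms, collinear dihedral frame, ...)."""


class RankDeficiencyError(RuntimeError):
    """Raised when the constraint Jacobian loses rank. Carries the
    :class:`RankReport` describing the failure in ``report``."""

    def __init__(self, message: str, report: "RankReport | None" = None):
        super().__init__(message)
        self.report = report


def wrap_degrees(angle):
    """Wrap an angle difference (degrees) to the shortest arc (-180, 180]."""
    wrapped = np.asarray(angle) - 360.0 * np.floor((np.asarray(angle) + 180.0) / 360.0)
    # floor maps exactly -180 to -180; convention picks +180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.ndim(angle) == 0 else wrapped


@dataclass
class Conformation:
    """Cartesian coordinates of N atoms (Angstrom), optionally labelled.

    Parameters
    ----------
    coordinates
        (N, D) array, D in {2, 3}.
    elements
        Optional element symbols, length N.
    """

    coordinates: np.ndarray
    elements: Optional[Sequence[str]] = None

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(f"coordinates must be (N, 2) or (N, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if self.elements is not None and len(self.elements) != coords.shape[0]:
            raise ValueError(
                f"elements has length {len(self.elements)} but there are "
                f"{coords.shape[0]} atoms"
            )
        self.coordinates = coords

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]

    def copy(self) -> "Conformation":
        els = list(self.elements) if self.elements is not None else None
        return Conformation(self.coordinates.copy(), els)


def _coords_of(conf) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.coordinates
    coords = np.asarray(conf, dtype=float)
    if coords.ndim != 2:
        raise ValueError("expected an (N, D) coordinate array or Conformation")
    return coords


# ---------------------------------------------------------------------------
# geometric values and analytic gradients
# ---------------------------------------------------------------------------

def _distance(coords, i, j):
    d = coords[i] - coords[j]
    r = float(np.linalg.norm(d))
    if r < MIN_SEPARATION:
        raise DegenerateGeometryError(f"atoms {i} and {j} are coincident (r={r:.2e})")
    return r, d / r


def _angle(coords, i, j, k, tolerant=False):
    """Bond angle at j in degrees plus gradients w.r.t. the three atoms
    (degrees / Angstrom).

    With ``tolerant=True`` a collinear frame returns a clamped (bounded,
    continuous) gradient instead of raising — used by the smooth toy energy
    where exact collinearity is a measure-zero coordinate singularity.
    """
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    ru = float(np.linalg.norm(u))
    rv = float(np.linalg.norm(v))
    if ru < MIN_SEPARATION or rv < MIN_SEPARATION:
        raise DegenerateGeometryError(f"degenerate angle frame at atoms ({i},{j},{k})")
    uh, vh = u / ru, v / rv
    cos_t = float(np.clip(uh @ vh, -1.0, 1.0))
    sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 0.0)))
    theta = float(np.degrees(np.arccos(cos_t)))
    if sin_t < 1e-10:
        if not tolerant:
            raise DegenerateGeometryError(
                f"angle at atoms ({i},{j},{k}) is collinear; gradient undefined"
            )
        sin_t = 1e-10  # numerators scale with sin, so the ratio stays bounded
    gi = (cos_t * uh - vh) / (ru * sin_t) * _RAD2DEG
    gk = (cos_t * vh - uh) / (rv * sin_t) * _RAD2DEG
    gj = -(gi + gk)
    return theta, (gi, gj, gk)


def _torsion(coords, i, j, k, l):
    """IUPAC torsion i-j-k-l in degrees plus gradients (degrees / Angstrom).

    Sign convention: looking from j to k, a clockwise rotation of l
    relative to i is positive; trans/anti is 180 degrees.
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(n1 @ n1)
    n2sq = float(n2 @ n2)
    rb2 = float(np.linalg.norm(b2))
    if rb2 < MIN_SEPARATION or n1sq < MIN_SEPARATION**2 or n2sq < MIN_SEPARATION**2:
        raise DegenerateGeometryError(
            f"degenerate (collinear) dihedral frame at atoms ({i},{j},{k},{l})"
        )
    phi = float(np.degrees(np.arctan2(np.cross(n1, n2) @ b2 / rb2, n1 @ n2)))
    # standard analytic dihedral derivatives
    gi = -(rb2 / n1sq) * n1
    gl = (rb2 / n2sq) * n2
    c12 = float(b1 @ b2) / (rb2 * rb2)
    c32 = float(b3 @ b2) / (rb2 * rb2)
    gj = -(1.0 + c12) * gi + c32 * gl
    gk = c12 * gi - (1.0 + c32) * gl
    return phi, (gi * _RAD2DEG, gj * _RAD2DEG, gk * _RAD2DEG, gl * _RAD2DEG)


_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}


@dataclass
class GeometricConstraint:
    """One holonomic geometric constraint sigma_a.

    Parameters
    ----------
    kind
        "distance", "angle" or "dihedral".
    atom_indices
        2, 3 or 4 distinct 0-based atom indices.
    target
        Target value (Angstrom for distance, degrees otherwise).
    slack_max
        Permitted symmetric deviation from the target (the bounded-constraint
        slack limit); 0 means strict equality.
    lower_final, upper_final
        Final strict bounds; default to target -/+ slack_max.
    lower_initial, upper_initial
        Initial bounds; ``None`` means unbounded.
    schedule
        Optional :class:`shakediff.schedules.BoundSchedule` controlling how
        the bounds tighten over sampler progress.
    """

    kind: str
    atom_indices: tuple
    target: float
    slack_max: float = 0.0
    lower_final: Optional[float] = None
    upper_final: Optional[float] = None
    lower_initial: Optional[float] = None
    upper_initial: Optional[float] = None
    schedule: object = None
    schedule_id: Optional[str] = None

    def __post_init__(self):
        if self.kind not in _ARITY:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        idx = tuple(int(a) for a in self.atom_indices)
        if len(idx) != _ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} constraint needs {_ARITY[self.kind]} atoms, got {len(idx)}"
            )
        if len(set(idx)) != len(idx) or min(idx) < 0:
            raise ValueError(f"atom indices must be distinct and non-negative: {idx}")
        if self.slack_max < 0:
            raise ValueError("slack_max must be non-negative")
        self.atom_indices = idx
        if self.lower_final is None:
            self.lower_final = self.target - self.slack_max
        if self.upper_final is None:
            self.upper_final = self.target + self.slack_max
        if self.lower_final > self.upper_final:
            raise ValueError("lower_final must not exceed upper_final")
        if (
            self.lower_initial is not None
            and self.upper_initial is not None
            and self.lower_initial > self.upper_initial
        ):
            raise ValueError("lower_initial must not exceed upper_initial")

    # -- protocol -----------------------------------------------------------
    @property
    def angular(self) -> bool:
        return self.kind in ("angle", "dihedral")

    def value(self, conf) -> float:
        coords = _coords_of(conf)
        self._check_indices(coords)
        i = self.atom_indices
        if self.kind == "distance":
            return _distance(coords, *i)[0]
        if self.kind == "angle":
            return _angle(coords, *i)[0]
        return _torsion(coords, *i)[0]

    def residual(self, conf, target: Optional[float] = None) -> float:
        t = self.target if target is None else target
        diff = self.value(conf) - t
        return wrap_degrees(diff) if self.angular else diff

    def gradient(self, conf) -> np.ndarray:
        """Gradient of the residual, flattened to length N*D.

        Entries are zero for atoms not in ``atom_indices``; the per-atom
        blocks sum to zero (translation invariance of internal coordinates).
        """
        coords = _coords_of(conf)
        self._check_indices(coords)
        grad = np.zeros_like(coords)
        i = self.atom_indices
        if self.kind == "distance":
            _, axis = _distance(coords, *i)
            grad[i[0]] = axis
            grad[i[1]] = -axis
        elif self.kind == "angle":
            _, blocks = _angle(coords, *i)
            for a, g in zip(i, blocks):
                grad[a] = g
        else:
            _, blocks = _torsion(coords, *i)
            for a, g in zip(i, blocks):
                grad[a] = g
        return grad.ravel()

    def _check_indices(self, coords):
        if max(self.atom_indices) >= coords.shape[0]:
            raise IndexError(
                f"constraint references atom {max(self.atom_indices)} but the "
                f"conformation has {coords.shape[0]} atoms"
            )


@dataclass
class RadialConstraint:
    """Distance of one atom from a fixed point in space.

    Used by the 2D toy-density demonstration, where scheduled circular
    constraints herd samples into a disc.
    """

    atom_index: int
    center: np.ndarray
    target: float
    slack_max: float = 0.0
    lower_final: Optional[float] = None
    upper_final: Optional[float] = None
    lower_initial: Optional[float] = None
    upper_initial: Optional[float] = None
    schedule: object = None
    schedule_id: Optional[str] = None
    kind: str = field(default="radial", init=False)
    angular: bool = field(default=False, init=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.lower_final is None:
            self.lower_final = self.target - self.slack_max
        if self.upper_final is None:
            self.upper_final = self.target + self.slack_max

    @property
    def atom_indices(self):
        return (self.atom_index,)

    def value(self, conf) -> float:
        coords = _coords_of(conf)
        r = float(np.linalg.norm(coords[self.atom_index] - self.center))
        if r < MIN_SEPARATION:
            raise DegenerateGeometryError("atom coincides with the constraint center")
        return r

    def residual(self, conf, target: Optional[float] = None) -> float:
        t = self.target if target is None else target
        return self.value(conf) - t

    def gradient(self, conf) -> np.ndarray:
        coords = _coords_of(conf)
        d = coords[self.atom_index] - self.center
        r = float(np.linalg.norm(d))
        if r < MIN_SEPARATION:
            raise DegenerateGeometryError("atom coincides with the constraint center")
        grad = np.zeros_like(coords)
        grad[self.atom_index] = d / r
        return grad.ravel()


@dataclass
class SquaredConstraint:
    """Squared-residual wrapper sigma = (value - target)^2.

    Provided for comparison with the classical squared constraint form;
    note its gradient vanishes at feasibility, which degrades the Gram
    conditioning of the multiplier solve near the solution.
    """

    base: GeometricConstraint

    @property
    def kind(self):
        return self.base.kind + "_squared"

    @property
    def atom_indices(self):
        return self.base.atom_indices

    @property
    def target(self):
        return 0.0

    angular = False
    schedule = None
    slack_max = 0.0

    @property
    def lower_final(self):
        return 0.0

    @property
    def upper_final(self):
        return 0.0

    lower_initial = None
    upper_initial = None

    def value(self, conf) -> float:
        return self.base.residual(conf) ** 2

    def residual(self, conf, target: Optional[float] = None) -> float:
        return self.value(conf) - (target or 0.0)

    def gradient(self, conf) -> np.ndarray:
        return 2.0 * self.base.residual(conf) * self.base.gradient(conf)


@dataclass
class RankReport:
    """SVD-based diagnostic of the constraint Jacobian (Theorem-style local
    rank check: the projection is well posed only while the Jacobian keeps
    full row rank)."""

    rank: int
    singular_values: np.ndarray
    condition_estimate: float
    full_rank: bool


class ConstraintSet:
    """Ordered collection of constraints with stacked residual/Jacobian."""

    def __init__(self, constraints: Sequence = ()):  # noqa: D401
        self.constraints = list(constraints)

    def __len__(self):
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def __getitem__(self, i):
        return self.constraints[i]

    def append(self, c):
        self.constraints.append(c)

    def residuals(self, conf, targets=None) -> np.ndarray:
        out = np.empty(len(self.constraints))
        for a, c in enumerate(self.constraints):
            t = None if targets is None else targets[a]
            try:
                out[a] = c.residual(conf, t)
            except DegenerateGeometryError as err:
                raise DegenerateGeometryError(f"constraint {a}: {err}") from err
        return out

    def jacobian(self, conf, targets=None):
        """Stacked Jacobian (A, N*D) and residual vector (A,)."""
        coords = _coords_of(conf)
        A = len(self.constraints)
        J = np.zeros((A, coords.size))
        sigma = np.empty(A)
        for a, c in enumerate(self.constraints):
            t = None if targets is None else targets[a]
            try:
                J[a] = c.gradient(coords)
                sigma[a] = c.residual(coords, t)
            except DegenerateGeometryError as err:
                raise DegenerateGeometryError(f"constraint {a}: {err}") from err
        return J, sigma

    def rank_diagnostic(self, conf, tol: float = 1e-8) -> RankReport:
        J, _ = self.jacobian(conf)
        if J.shape[0] == 0:
            return RankReport(0, np.empty(0), 0.0, True)
        sv = np.linalg.svd(J, compute_uv=False)
        rank = int(np.sum(sv > tol * sv[0])) if sv[0] > 0 else 0
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        return RankReport(rank, sv, cond, rank == J.shape[0])


# -- module-level operation aliases ----------------------------------------

def evaluate(constraint, conf) -> float:
    """Residual of one constraint at a conformation."""
    return constraint.residual(conf)


def gradient(constraint, conf) -> np.ndarray:
    """Flattened analytic gradient of one constraint's residual."""
    return constraint.gradient(conf)


def jacobian(cset: ConstraintSet, conf, targets=None):
    return cset.jacobian(conf, targets)


def rank_diagnostic(cset: ConstraintSet, conf, tol: float = 1e-8) -> RankReport:
    return cset.rank_diagnostic(conf, tol)
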