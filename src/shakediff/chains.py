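"""Synthetic molecular geometry: internal-coordinate chain building,
geometric measurements, a toy classical energy, and ensemble generators.

Everything here is generated programmatically — chains are placed from
bond lengths, bond angles and torsions (natural extension reference frame),
so every fixture used by the constraint, projection, sampling and mining
machinery can be built on the fly with no external data.

The butane fixture uses standard alkane geometry (C-C 1.53 A, C-C-C
112.5 deg).  The anti (staggered, 180 deg torsion) skeleton then has a
C1-C4 distance of about 3.9 A, and the experimentally motivated eclipsed
end-to-end target is 3.15 A; these two distances are the canonical pair of
constraint targets that steer generation toward one torsional conformer or
the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .constraints import (
    Conformation,
    ConstraintSet,
    DegenerateGeometryError,
    GeometricConstraint,
    _coords_of,
    _distance,
    _angle,
    _torsion,
)

__all__ = [
    "InternalChainSpec",
    "ToyEnergyParams",
    "build_chain",
    "measure_distance",
    "measure_angle",
    "measure_torsion",
    "toy_energy",
    "toy_energy_gradient",
    "make_two_mode_ensemble",
    "butane_fixture",
    "extended_chain_spec",
    "BUTANE_CC_BOND",
    "BUTANE_CCC_ANGLE",
    "BUTANE_STAGGERED_DISTANCE",
    "BUTANE_ECLIPSED_DISTANCE",
]

# standard alkane fixture constants
BUTANE_CC_BOND = 1.53        # Angstrom
BUTANE_CCC_ANGLE = 112.5     # degrees
#: end-to-end C1-C4 targets selecting the two torsional conformers
BUTANE_STAGGERED_DISTANCE = 3.9
BUTANE_ECLIPSED_DISTANCE = 3.15


@dataclass
class InternalChainSpec:
    """Internal coordinates of an n-atom chain: n-1 bond lengths (A),
    n-2 bond angles and n-3 torsions (degrees)."""

    bond_lengths: Sequence[float]
    bond_angles: Sequence[float] = ()
    torsions: Sequence[float] = ()

    def __post_init__(self):
        self.bond_lengths = [float(b) for b in self.bond_lengths]
        self.bond_angles = [float(a) for a in self.bond_angles]
        self.torsions = [float(t) for t in self.torsions]
        n = self.n_atoms
        if n < 2:
            raise ValueError("a chain needs at least two atoms")
        if len(self.bond_angles) != max(n - 2, 0):
            raise ValueError(
                f"expected {max(n - 2, 0)} bond angles, got {len(self.bond_angles)}"
            )
        if len(self.torsions) != max(n - 3, 0):
            raise ValueError(
                f"expected {max(n - 3, 0)} torsions, got {len(self.torsions)}"
            )
        if any(b <= 0 for b in self.bond_lengths):
            raise ValueError("bond lengths must be positive")
        if any(not 0.0 < a < 180.0 for a in self.bond_angles):
            raise ValueError("bond angles must lie strictly inside (0, 180) degrees")

    @property
    def n_atoms(self) -> int:
        return len(self.bond_lengths) + 1


def extended_chain_spec(n_atoms: int, bond: float = BUTANE_CC_BOND,
                        angle: float = BUTANE_CCC_ANGLE,
                        torsion: float = 180.0) -> InternalChainSpec:
    """All-equal chain spec (all-trans by default)."""
    return InternalChainSpec(
        [bond] * (n_atoms - 1),
        [angle] * max(n_atoms - 2, 0),
        [torsion] * max(n_atoms - 3, 0),
    )


def build_chain(spec: InternalChainSpec, elements: Optional[Sequence[str]] = None
                ) -> Conformation:
    """Place a chain in Cartesian space from internal coordinates.

    Atom 0 sits at the origin, atom 1 on +x, atom 2 in the xy-plane; each
    later atom is placed to realize its bond length, bond angle and torsion
    using the standard extension-frame construction.  Measured internals
    round-trip to the spec within 1e-8 (angles on the shortest arc).
    """
    n = spec.n_atoms
    coords = np.zeros((n, 3))
    coords[1] = (spec.bond_lengths[0], 0.0, 0.0)
    if n > 2:
        th = np.radians(spec.bond_angles[0])
        b = spec.bond_lengths[1]
        coords[2] = coords[1] + b * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(3, n):
        b = spec.bond_lengths[i - 1]
        th = np.radians(spec.bond_angles[i - 2])
        phi = np.radians(spec.torsions[i - 3])
        a3, a2, a1 = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = a1 - a2
        bc /= np.linalg.norm(bc)
        ab = a2 - a3
        nvec = np.cross(ab, bc)
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            raise DegenerateGeometryError(
                "three consecutive collinear atoms: torsion frame undefined"
            )
        nvec /= nn
        mvec = np.cross(nvec, bc)
        d_local = np.array(
            [-b * np.cos(th), b * np.sin(th) * np.cos(phi), b * np.sin(th) * np.sin(phi)]
        )
        coords[i] = a1 + d_local[0] * bc + d_local[1] * mvec + d_local[2] * nvec
    if elements is None:
        elements = ["C"] * n
    return Conformation(coords, list(elements))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def measure_distance(conf, i: int, j: int) -> float:
    """Interatomic distance in Angstrom."""
    return _distance(_coords_of(conf), i, j)[0]


def measure_angle(conf, i: int, j: int, k: int) -> float:
    """Bond angle at atom j in degrees."""
    return _angle(_coords_of(conf), i, j, k)[0]


def measure_torsion(conf, i: int, j: int, k: int, l: int) -> float:
    """Torsion i-j-k-l in degrees, wrapped to (-180, 180] (IUPAC sign)."""
    return _torsion(_coords_of(conf), i, j, k, l)[0]


# ---------------------------------------------------------------------------
# toy energy
# ---------------------------------------------------------------------------

@dataclass
class ToyEnergyParams:
    """Classical toy force field for a chain: harmonic bonds + angles and
    a Lennard-Jones term on 1-4 and more distant pairs.

    Units are nominal kcal/mol with distances in Angstrom and angles in
    radians inside the energy (inputs in degrees).
    """

    bond_k: float = 300.0
    bond_r0: Sequence[float] = field(default_factory=lambda: [BUTANE_CC_BOND])
    angle_k: float = 60.0        # per rad^2
    angle_theta0: Sequence[float] = field(default_factory=lambda: [BUTANE_CCC_ANGLE])
    lj_epsilon: float = 0.25
    lj_sigma: float = 3.4
    #: soft-core floor (A): LJ terms evaluate at max(r, lj_r_floor) so the
    #: hot, near-random start of annealed sampling cannot produce divergent
    #: forces from incidental close contacts
    lj_r_floor: float = 0.8

    def __post_init__(self):
        if self.bond_k <= 0 or self.angle_k <= 0:
            raise ValueError("force constants must be positive")


def _pair_distance_tolerant(coords, i, j):
    """Distance plus unit axis; a coincident pair returns a zero axis and a
    tiny distance instead of raising (smooth-energy path only)."""
    d = coords[i] - coords[j]
    r = float(np.linalg.norm(d))
    if r < 1e-8:
        return 1e-8, np.zeros_like(d)
    return r, d / r


def _chain_pairs(n: int):
    bonds = [(i, i + 1) for i in range(n - 1)]
    angles = [(i, i + 1, i + 2) for i in range(n - 2)]
    nonbonded = [(i, j) for i in range(n) for j in range(i + 3, n)]
    return bonds, angles, nonbonded


def _term_params(values, count, what):
    vals = list(values)
    if len(vals) == 1:
        vals = vals * count
    if len(vals) != count:
        raise ValueError(f"need {count} {what} parameters, got {len(vals)}")
    return vals


def toy_energy(conf, params: ToyEnergyParams) -> float:
    """Chain energy: sum of 1/2 k (r - r0)^2 bonds, 1/2 k (theta - theta0)^2
    angles and 4 eps [(sigma/r)^12 - (sigma/r)^6] on 1-4+ pairs."""
    coords = _coords_of(conf)
    n = coords.shape[0]
    bonds, angles, nonbonded = _chain_pairs(n)
    r0s = _term_params(params.bond_r0, len(bonds), "bond")
    th0s = _term_params(params.angle_theta0, len(angles), "angle")
    e = 0.0
    for (i, j), r0 in zip(bonds, r0s):
        r = _pair_distance_tolerant(coords, i, j)[0]
        e += 0.5 * params.bond_k * (r - r0) ** 2
    for (i, j, k), th0 in zip(angles, th0s):
        th = np.radians(_angle(coords, i, j, k, tolerant=True)[0])
        e += 0.5 * params.angle_k * (th - np.radians(th0)) ** 2
    for i, j in nonbonded:
        r = max(_pair_distance_tolerant(coords, i, j)[0], params.lj_r_floor)
        sr6 = (params.lj_sigma / r) ** 6
        e += 4.0 * params.lj_epsilon * (sr6 * sr6 - sr6)
    return float(e)


def toy_energy_gradient(conf, params: ToyEnergyParams) -> np.ndarray:
    """Analytic gradient of :func:`toy_energy`, shape (N, 3)."""
    coords = _coords_of(conf)
    n = coords.shape[0]
    bonds, angles, nonbonded = _chain_pairs(n)
    r0s = _term_params(params.bond_r0, len(bonds), "bond")
    th0s = _term_params(params.angle_theta0, len(angles), "angle")
    grad = np.zeros_like(coords)
    for (i, j), r0 in zip(bonds, r0s):
        r, axis = _pair_distance_tolerant(coords, i, j)
        f = params.bond_k * (r - r0)
        grad[i] += f * axis
        grad[j] -= f * axis
    for (i, j, k), th0 in zip(angles, th0s):
        th, blocks = _angle(coords, i, j, k, tolerant=True)
        # blocks are in degrees/A; energy works in radians
        f = params.angle_k * np.radians(th - th0) * (np.pi / 180.0)
        for a, g in zip((i, j, k), blocks):
            grad[a] += f * g
    for i, j in nonbonded:
        r, axis = _pair_distance_tolerant(coords, i, j)
        if r < params.lj_r_floor:
            continue  # inside the soft core the LJ energy is flat
        sr6 = (params.lj_sigma / r) ** 6
        dedr = 4.0 * params.lj_epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        grad[i] += dedr * axis
        grad[j] -= dedr * axis
    return grad


# ---------------------------------------------------------------------------
# ensembles and the butane fixture
# ---------------------------------------------------------------------------

def make_two_mode_ensemble(mode_specs: Sequence[InternalChainSpec], m: int,
                           seed: int = 0, torsion_sd: float = 5.0,
                           angle_sd: float = 1.0, bond_sd: float = 0.005,
                           weights: Optional[Sequence[float]] = None):
    """Draw ``m`` conformers from jittered internal-coordinate modes.

    Gaussian jitter is applied in internal coordinates (defaults: 5 deg on
    torsions, 1 deg on angles, 0.005 A on bonds — tight vibrational noise
    around well-separated torsional minima, the regime in which clustering
    of conformer ensembles is meaningful).

    Returns (list of Conformation, mode labels) with the ground-truth mode
    assignment recorded for recovery tests.
    """
    if m < 2:
        raise ValueError("need at least two conformers")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.full(len(mode_specs), 1.0 / len(mode_specs))
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    labels = rng.choice(len(mode_specs), size=m, p=weights)
    confs = []
    for lab in labels:
        spec = mode_specs[lab]
        bonds = np.maximum(
            np.asarray(spec.bond_lengths) + rng.normal(0, bond_sd, len(spec.bond_lengths)),
            0.3,
        )
        angs = np.clip(
            np.asarray(spec.bond_angles) + rng.normal(0, angle_sd, len(spec.bond_angles)),
            10.0, 170.0,
        )
        tors = np.asarray(spec.torsions) + rng.normal(0, torsion_sd, len(spec.torsions))
        confs.append(build_chain(InternalChainSpec(bonds, angs, tors)))
    return confs, labels


def _add_hydrogens(skeleton: Conformation, ch_bond: float = 1.09) -> Conformation:
    """Decorate a carbon chain with explicit hydrogens (approximately
    tetrahedral placement; geometric, not force-field optimized)."""
    coords = skeleton.coordinates
    n = coords.shape[0]
    out = [c for c in coords]
    elements = ["C"] * n
    for i in range(n):
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < n]
        vecs = [coords[j] - coords[i] for j in neighbors]
        vecs = [v / np.linalg.norm(v) for v in vecs]
        n_h = 4 - len(neighbors)
        if len(vecs) == 2:
            bisector = -(vecs[0] + vecs[1])
            bisector /= np.linalg.norm(bisector)
            perp = np.cross(vecs[0], vecs[1])
            perp /= np.linalg.norm(perp)
            half = np.radians(109.5 / 2.0)
            dirs = [
                np.cos(half) * bisector + np.sin(half) * perp,
                np.cos(half) * bisector - np.sin(half) * perp,
            ]
        else:
            axis = vecs[0]
            ref = np.array([0.0, 0.0, 1.0])
            if abs(axis @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            th = np.radians(180.0 - 109.5)
            dirs = []
            for k in range(n_h):
                az = 2.0 * np.pi * k / n_h
                dirs.append(
                    np.cos(th) * (-axis)
                    + np.sin(th) * (np.cos(az) * e1 + np.sin(az) * e2)
                )
        for d in dirs[:n_h]:
            out.append(coords[i] + ch_bond * d / np.linalg.norm(d))
            elements.append("H")
    return Conformation(np.array(out), elements)


def butane_fixture(explicit_hydrogens: bool = False):
    """Butane test system: skeleton template plus the two constraint sets
    selecting the staggered (3.9 A) or eclipsed (3.15 A) conformer.

    Each set couples the end-to-end C1-C4 distance target with the three
    C-C covalent-bond constraints at equilibrium length, so enforcing the
    end-to-end distance cannot be satisfied by stretching bonds.

    Returns (template Conformation, staggered ConstraintSet,
    eclipsed ConstraintSet, ToyEnergyParams).
    """
    spec = extended_chain_spec(4)
    template = build_chain(spec)
    if explicit_hydrogens:
        template = _add_hydrogens(template)

    def _set(end_to_end: float) -> ConstraintSet:
        cs = [GeometricConstraint("distance", (0, 3), end_to_end)]
        for i in range(3):
            cs.append(GeometricConstraint("distance", (i, i + 1), BUTANE_CC_BOND))
        return ConstraintSet(cs)

    params = ToyEnergyParams(
        bond_r0=[BUTANE_CC_BOND], angle_theta0=[BUTANE_CCC_ANGLE]
    )
    return template, _set(BUTANE_STAGGERED_DISTANCE), _set(BUTANE_ECLIPSED_DISTANCE), params
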