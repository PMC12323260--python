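"""Readers and writers: multi-frame XYZ, SDF (V2000, via RDKit), and the
YAML/JSON constraint configuration schema.

Constraint config schema (atoms are 1-based in files, converted to 0-based
internally, matching the SDF convention)::

    schedules:
      tighten: {beta: 10, t0: 0.5}
    constraints:
      - kind: distance       # distance | angle | dihedral
        atoms: [1, 4]
        target: 3.9
        slack_max: 0.0       # optional, default 0 (strict)
        lower: 3.8           # optional final bounds (else target +- slack)
        upper: 4.0
        lower_initial: null  # optional; null/omitted = unbounded
        upper_initial: null
        schedule: tighten    # optional schedule reference
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .constraints import Conformation, ConstraintSet, GeometricConstraint
from .schedules import BoundSchedule

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "write_sdf",
    "bond_constraints",
    "load_constraints",
    "write_constraints",
]


def read_xyz(path) -> List[Conformation]:
    """Read a (multi-frame) XYZ file."""
    frames = []
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise ValueError(
                f"{path}: line {pos + 1}: expected an atom count, got "
                f"{lines[pos]!r}"
            ) from None
        if pos + 1 + count >= len(lines) + 1 and pos + 2 + count > len(lines):
            raise ValueError(f"{path}: truncated frame starting at line {pos + 1}")
        elements, coords = [], []
        for ln in lines[pos + 2: pos + 2 + count]:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom line {ln!r}")
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(Conformation(np.asarray(coords), elements))
        pos += 2 + count
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_xyz(path, conformations, comment: str = "") -> None:
    """Write conformations as a multi-frame XYZ file (6 decimals)."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    with open(path, "w") as fh:
        for conf in conformations:
            coords = conf.coordinates
            if coords.shape[1] == 2:  # pad toy 2D systems
                coords = np.column_stack([coords, np.zeros(coords.shape[0])])
            elements = conf.elements or ["X"] * conf.n_atoms
            fh.write(f"{conf.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(elements, coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_sdf(path) -> List[Tuple[Conformation, List[Tuple[int, int]]]]:
    """Read a (multi-molecule) SDF; returns (conformation, bond list) pairs
    with 0-based bond indices."""
    from rdkit import Chem

    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for mol in supplier:
        if mol is None:
            raise ValueError(f"{path}: unparseable molecule block")
        conf = mol.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
              conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
        )
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        ]
        out.append((Conformation(coords, elements), bonds))
    if not out:
        raise ValueError(f"{path}: no molecules found")
    return out


def write_sdf(path, conformations, bonds: Sequence[Tuple[int, int]],
              title: str = "mol") -> None:
    """Write conformations with a shared bond list as a V2000 SDF."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Geometry import Point3D

    if isinstance(conformations, Conformation):
        conformations = [conformations]
    writer = Chem.SDWriter(str(path))
    try:
        for conf in conformations:
            mol = Chem.RWMol()
            for el in conf.elements or ["C"] * conf.n_atoms:
                mol.AddAtom(Chem.Atom(el))
            for i, j in bonds:
                mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
            rdconf = Chem.Conformer(conf.n_atoms)
            coords = conf.coordinates
            for i in range(conf.n_atoms):
                rdconf.SetAtomPosition(i, Point3D(*map(float, coords[i])))
            m = mol.GetMol()
            m.SetProp("_Name", title)
            m.AddConformer(rdconf)
            Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
            writer.write(m)
    finally:
        writer.close()


def bond_constraints(conf: Conformation, bonds: Sequence[Tuple[int, int]]
                     ) -> ConstraintSet:
    """Distance constraints fixing each bond at its current length
    (covalent-bond constraints at equilibrium distances)."""
    from .chains import measure_distance

    return ConstraintSet(
        [
            GeometricConstraint("distance", (i, j), measure_distance(conf, i, j))
            for i, j in bonds
        ]
    )


_KINDS = {"distance": 2, "angle": 3, "dihedral": 4}


def _schema_error(pathspec, msg):
    raise ValueError(f"constraint config: {pathspec}: {msg}")


def load_constraints(path) -> ConstraintSet:
    """Load and validate a YAML/JSON constraint configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "constraints" not in raw:
        _schema_error("<root>", "expected a mapping with a 'constraints' list")
    schedules = {}
    for name, blk in (raw.get("schedules") or {}).items():
        if not isinstance(blk, dict):
            _schema_error(f"schedules.{name}", "expected a mapping")
        try:
            schedules[name] = BoundSchedule(
                beta=float(blk.get("beta", 10.0)),
                t0=float(blk.get("t0", 0.5)),
                unbound_scale=float(blk.get("unbound_scale", 10.0)),
            )
        except (TypeError, ValueError) as err:
            _schema_error(f"schedules.{name}", str(err))
    constraints = []
    for idx, blk in enumerate(raw["constraints"]):
        loc = f"constraints[{idx}]"
        if not isinstance(blk, dict):
            _schema_error(loc, "expected a mapping")
        kind = blk.get("kind")
        if kind not in _KINDS:
            _schema_error(f"{loc}.kind", f"unknown kind {kind!r}")
        atoms = blk.get("atoms")
        if not isinstance(atoms, (list, tuple)) or len(atoms) != _KINDS[kind]:
            _schema_error(f"{loc}.atoms", f"{kind} needs {_KINDS[kind]} atoms")
        if any(int(a) < 1 for a in atoms):
            _schema_error(f"{loc}.atoms", "atoms are 1-based in config files")
        if "target" not in blk:
            _schema_error(f"{loc}.target", "missing")
        lower = blk.get("lower")
        upper = blk.get("upper")
        if lower is not None and upper is not None and lower > upper:
            _schema_error(loc, f"lower {lower} > upper {upper}")
        sched = None
        sched_id = blk.get("schedule")
        if sched_id is not None:
            if sched_id not in schedules:
                _schema_error(f"{loc}.schedule", f"unknown schedule {sched_id!r}")
            sched = schedules[sched_id]
        try:
            constraints.append(
                GeometricConstraint(
                    kind,
                    tuple(int(a) - 1 for a in atoms),
                    float(blk["target"]),
                    slack_max=float(blk.get("slack_max", 0.0)),
                    lower_final=lower,
                    upper_final=upper,
                    lower_initial=blk.get("lower_initial"),
                    upper_initial=blk.get("upper_initial"),
                    schedule=sched,
                    schedule_id=sched_id,
                )
            )
        except (TypeError, ValueError) as err:
            _schema_error(loc, str(err))
    return ConstraintSet(constraints)


def write_constraints(path, cset: ConstraintSet, schedules: Optional[dict] = None
                      ) -> None:
    """Write a constraint set back to YAML (1-based atoms)."""
    doc = {"constraints": []}
    if schedules:
        doc["schedules"] = {
            name: {"beta": s.beta, "t0": s.t0, "unbound_scale": s.unbound_scale}
            for name, s in schedules.items()
        }
    for c in cset:
        blk = {
            "kind": c.kind,
            "atoms": [int(a) + 1 for a in c.atom_indices],
            "target": float(c.target),
        }
        if c.slack_max:
            blk["slack_max"] = float(c.slack_max)
        if getattr(c, "schedule_id", None):
            blk["schedule"] = c.schedule_id
        doc["constraints"].append(blk)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
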