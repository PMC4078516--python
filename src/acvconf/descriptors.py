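"""Conformational observables of an acyclovir-like conformation.

The chain placement is captured by five exocyclic torsions (phi1..phi5),
the pseudo-bond distance R = N9...O5' and the two angles beta (C4-N9...O5')
and Phi (C1'-N9...O5') through that pseudo-bond with vertex at N9.  Base
nonplanarity is quantified by five ring dihedrals nu0..nu4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Conformation, DegenerateFrameError

__all__ = [
    "TORSION_ATOMS",
    "NU_ATOMS",
    "DescriptorSet",
    "RingPlanarity",
    "DescriptorError",
    "dihedral_angle",
    "bond_angle",
    "descriptor_set",
    "base_nonplanarity",
    "set_torsion",
    "wrap_angle",
]

#: Quadruples defining the five exocyclic chain torsions.
TORSION_ATOMS = {
    "phi1": ("C4", "N9", "C1'", "O2'"),
    "phi2": ("N9", "C1'", "O2'", "C3'"),
    "phi3": ("C1'", "O2'", "C3'", "C4'"),
    "phi4": ("O2'", "C3'", "C4'", "O5'"),
    "phi5": ("C3'", "C4'", "O5'", "H5'"),
}

#: Quadruples defining the purine-ring nonplanarity dihedrals.
NU_ATOMS = {
    "nu0": ("N1", "C2", "N3", "C4"),
    "nu1": ("C2", "N3", "C4", "C5"),
    "nu2": ("N3", "C4", "C5", "C6"),
    "nu3": ("N7", "C8", "N9", "C4"),
    "nu4": ("C6", "N1", "C2", "N3"),
}

TORSION_NAMES = tuple(TORSION_ATOMS)


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed (missing atom etc.)."""


def wrap_angle(value: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = math.fmod(value, 360.0)
    if wrapped > 180.0:
        wrapped -= 360.0
    elif wrapped <= -180.0:
        wrapped += 360.0
    return wrapped


def dihedral_angle(a, b, c, d) -> float:
    """Signed torsion a-b-c-d in degrees, in (-180, 180].

    IUPAC sign convention: looking from b to c, the angle is positive if d
    is rotated clockwise from a.  Satisfies
    dihedral(a, b, c, d) == dihedral(d, c, b, a).
    """
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n2 = np.linalg.norm(b2)
    if n2 < 1e-10:
        raise DegenerateFrameError("axis atoms b and c coincide")
    n1v = np.cross(b1, b2)
    n2v = np.cross(b2, b3)
    if np.linalg.norm(n1v) < 1e-8 or np.linalg.norm(n2v) < 1e-8:
        raise DegenerateFrameError("colinear atoms: dihedral undefined")
    y = np.dot(np.cross(n1v, n2v), b2 / n2)
    x = np.dot(n1v, n2v)
    return wrap_angle(math.degrees(math.atan2(y, x)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees (vertex at b)."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    u = a - b
    v = c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateFrameError("coincident atoms: angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


@dataclass
class DescriptorSet:
    """The eight chain-placement observables of one conformation."""

    phi1: float
    phi2: float
    phi3: float
    phi4: float
    phi5: float
    R: float
    beta: float
    Phi: float

    def torsions(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TORSION_NAMES}

    def to_dict(self) -> dict[str, float]:
        return {"R": self.R, "beta": self.beta, "Phi": self.Phi,
                **self.torsions()}


@dataclass
class RingPlanarity:
    """Ring nonplanarity dihedrals with threshold flagging."""

    nu0: float
    nu1: float
    nu2: float
    nu3: float
    nu4: float
    threshold: float = 1.0
    max_abs: float = field(init=False)
    flagged: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        values = {name: getattr(self, name) for name in NU_ATOMS}
        self.max_abs = max(abs(v) for v in values.values())
        self.flagged = tuple(name for name, v in values.items()
                             if abs(v) > self.threshold)

    @classmethod
    def from_values(cls, nus, threshold: float = 1.0) -> "RingPlanarity":
        return cls(*nus, threshold=threshold)


def _atom_positions(conf: Conformation, labels, molecule_id: int):
    out = []
    for label in labels:
        try:
            out.append(conf.position(label, molecule_id))
        except KeyError as exc:
            raise DescriptorError(f"missing atom {label}") from exc
    return out


def descriptor_set(conf: Conformation, molecule_id: int = 0) -> DescriptorSet:
    """Compute phi1..phi5, R, beta and Phi from labeled coordinates."""
    torsions = {
        name: dihedral_angle(*_atom_positions(conf, quad, molecule_id))
        for name, quad in TORSION_ATOMS.items()
    }
    n9, o5, c4, c1 = _atom_positions(conf, ("N9", "O5'", "C4", "C1'"),
                                     molecule_id)
    return DescriptorSet(
        **torsions,
        R=float(np.linalg.norm(n9 - o5)),
        beta=bond_angle(c4, n9, o5),
        Phi=bond_angle(c1, n9, o5),
    )


def base_nonplanarity(conf: Conformation, threshold: float = 1.0,
                      molecule_id: int = 0) -> RingPlanarity:
    """Five nu dihedrals of the purine bicycle plus |nu| > threshold flags."""
    nus = [dihedral_angle(*_atom_positions(conf, quad, molecule_id))
           for quad in NU_ATOMS.values()]
    return RingPlanarity.from_values(nus, threshold=threshold)


def _rotating_side(conf: Conformation, b_key, c_key) -> set:
    """Atom keys on the c-side when bond b-c is removed; error if none."""
    graph = conf.graph
    bond = frozenset({b_key, c_key})
    if bond not in graph.bonds:
        raise DescriptorError(f"no bond between {b_key} and {c_key}")
    visited = {c_key}
    stack = [c_key]
    while stack:
        current = stack.pop()
        for nb in graph.neighbors(current):
            if frozenset({current, nb}) == bond:
                continue
            if nb not in visited:
                visited.add(nb)
                stack.append(nb)
    if b_key in visited:
        raise DescriptorError(
            "rotation axis lies on a ring: bond removal does not "
            "bipartition the molecule")
    return visited


def set_torsion(conf: Conformation, torsion: str, value: float,
                molecule_id: int = 0) -> Conformation:
    """Return a copy with the named chain torsion driven to ``value``.

    Atoms on the base side of the torsion's bond axis stay fixed; the distal
    fragment is rotated rigidly about the axis, so bond lengths and angles
    are untouched.
    """
    if torsion not in TORSION_ATOMS:
        raise KeyError(f"unknown torsion {torsion!r}; "
                       f"expected one of {TORSION_NAMES}")
    quad = TORSION_ATOMS[torsion]
    out = conf.copy()
    a, b, c, d = _atom_positions(out, quad, molecule_id)
    current = dihedral_angle(a, b, c, d)
    delta = wrap_angle(value - current)
    if abs(delta) < 1e-12:
        return out
    b_key = (molecule_id, quad[1])
    c_key = (molecule_id, quad[2])
    moving = _rotating_side(out, b_key, c_key)
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    # right-hand rotation of the distal side about the b->c axis by +delta
    # increases the measured dihedral by delta
    rot = Rotation.from_rotvec(np.radians(delta) * axis)
    for atom in out.graph.atoms:
        if atom.key in moving and atom.key != c_key:
            atom.position = rot.apply(atom.position - b) + b
    return out
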