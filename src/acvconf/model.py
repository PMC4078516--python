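"""Labeled molecular structures, topology validation and coordinate I/O.

Atoms carry canonical labels (``N9``, ``O5'``, ``H5'`` ...) so that the
conformational descriptors can be computed by name.  Coordinates are in
Angstrom throughout; angles everywhere in the package are in degrees,
reported in the interval (-180, 180].
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "MolecularGraph",
    "Conformation",
    "ParseError",
    "LabelingError",
    "DegenerateFrameError",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "read_label_map",
    "validate_topology",
    "zmatrix_to_cartesian",
    "infer_bonds",
]

TAUTOMER_IDS = ("N1", "N3", "N7", "OHC", "OHT")

#: Covalent radii (Angstrom) used for distance-based bond inference.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

#: Multiplier applied to the sum of covalent radii when inferring bonds.
BOND_FACTOR = 1.6

#: Aliases mapping common crystal-file spellings to canonical labels.
LABEL_ALIASES = {
    "H(N1)": "H1",
    "H(N2)": "H2",
    "H(N2')": "H2'",
    "H(O5')": "H5'",
    "HN1": "H1",
    "HO5'": "H5'",
}


class ParseError(ValueError):
    """Raised for malformed coordinate or table files."""


class LabelingError(ValueError):
    """Raised when a label map does not cover the parsed atoms."""


class DegenerateFrameError(ValueError):
    """Raised when a geometric frame cannot be constructed (colinear refs)."""


def _normalize_label(label: str) -> str:
    label = label.replace("*", "'").strip()
    return LABEL_ALIASES.get(label, label)


@dataclass
class Atom:
    """One labeled atom of a (possibly multi-molecule) assembly."""

    label: str
    element: str
    position: np.ndarray
    charge: float | None = None
    molecule_id: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.label}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.label}: non-finite position")

    @property
    def key(self) -> tuple[int, str]:
        return (self.molecule_id, self.label)


BondKey = frozenset  # frozenset of two (molecule_id, label) keys


@dataclass
class MolecularGraph:
    """Ordered atoms plus covalent bonds, optionally split into molecules."""

    atoms: list[Atom]
    bonds: set = field(default_factory=set)
    tautomer_id: str = "other"

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise ValueError(f"duplicate atom label {atom.label!r} "
                                 f"in molecule {atom.molecule_id}")
            seen.add(atom.key)
        for bond in self.bonds:
            for end in bond:
                if end not in seen:
                    raise ValueError(f"bond endpoint {end!r} has no atom")

    def atom(self, label: str, molecule_id: int = 0) -> Atom:
        for a in self.atoms:
            if a.label == label and a.molecule_id == molecule_id:
                return a
        raise KeyError(f"no atom {label!r} in molecule {molecule_id}")

    def has_atom(self, label: str, molecule_id: int = 0) -> bool:
        return any(a.label == label and a.molecule_id == molecule_id
                   for a in self.atoms)

    def has_bond(self, label1: str, label2: str, molecule_id: int = 0) -> bool:
        return frozenset({(molecule_id, label1), (molecule_id, label2)}) in self.bonds

    def molecule_ids(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if a.molecule_id not in seen:
                seen.append(a.molecule_id)
        return seen

    def neighbors(self, key: tuple[int, str]) -> list[tuple[int, str]]:
        out = []
        for bond in self.bonds:
            if key in bond:
                (other,) = set(bond) - {key}
                out.append(other)
        return out

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            bonds=set(self.bonds),
            tautomer_id=self.tautomer_id,
        )


@dataclass
class Conformation:
    """A MolecularGraph with a concrete coordinate snapshot."""

    graph: MolecularGraph
    provenance: str = ""

    MIN_SEPARATION = 0.3  # Angstrom; closer pairs are rejected as overlapping

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.graph.atoms])

    def position(self, label: str, molecule_id: int = 0) -> np.ndarray:
        return self.graph.atom(label, molecule_id).position

    def copy(self) -> "Conformation":
        return Conformation(graph=self.graph.copy(), provenance=self.provenance)

    def check_separation(self) -> None:
        pos = self.positions()
        if len(pos) < 2:
            return
        from scipy.spatial.distance import pdist

        if pdist(pos).min() < self.MIN_SEPARATION:
            raise ValueError("two atoms closer than "
                             f"{self.MIN_SEPARATION} Angstrom")

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Conformation":
        """Return a rigidly moved copy (rotation applied first)."""
        out = self.copy()
        for atom in out.graph.atoms:
            p = atom.position
            if rotation is not None:
                p = np.asarray(rotation) @ p
            if translation is not None:
                p = p + np.asarray(translation)
            atom.position = p
        return out


# ---------------------------------------------------------------------------
# bond inference and molecule segmentation
# ---------------------------------------------------------------------------

def infer_bonds(atoms: Sequence[Atom], factor: float = BOND_FACTOR) -> set:
    """Distance-based covalent bonds: d < factor * (r_cov(i) + r_cov(j))."""
    bonds: set = set()
    pos = np.array([a.position for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.8) for a in atoms])
    n = len(atoms)
    for i in range(n):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        cut = factor * (radii[i] + radii[i + 1:])
        for j in np.nonzero(d < cut)[0] + i + 1:
            bonds.add(frozenset({atoms[i].key, atoms[int(j)].key}))
    return bonds


def _connected_components(n: int, edges: Iterable[tuple[int, int]]) -> list[int]:
    """Union-find component index per node, ordered by first appearance."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    comp: dict[int, int] = {}
    out = []
    for i in range(n):
        r = find(i)
        if r not in comp:
            comp[r] = len(comp)
        out.append(comp[r])
    return out


def _segment_molecules(atoms: list[Atom], factor: float = BOND_FACTOR) -> None:
    """Assign molecule_ids by connected components of the inferred bond graph."""
    pos = np.array([a.position for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.8) for a in atoms])
    edges = []
    for i in range(len(atoms)):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        cut = factor * (radii[i] + radii[i + 1:])
        edges.extend((i, int(j)) for j in np.nonzero(d < cut)[0] + i + 1)
    comps = _connected_components(len(atoms), edges)
    for atom, c in zip(atoms, comps):
        atom.molecule_id = c


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

_MOLECULES_RE = re.compile(r"molecules=([\d,]+)")


def read_label_map(path: str | Path) -> dict[str, str]:
    """Two-column delimited text: auto label (element+ordinal) -> canonical."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(f"label map line not two columns: {line!r}")
        mapping[parts[0]] = _normalize_label(parts[1])
    return mapping


def read_xyz(path: str | Path,
             label_map: Mapping[str, str] | None = None,
             tautomer_id: str = "other") -> Conformation:
    """Read an XYZ file (count / comment / ``element x y z`` records).

    Atom labels are taken from ``label_map`` keyed by the auto-generated
    ``element + ordinal`` name (e.g. ``N1`` for the first nitrogen read), or
    fall back to those auto names.  Multimer files are split either by a
    ``molecules=n1,n2,...`` marker on the comment line or by connected
    components of the distance-inferred bond graph.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: line 1 must be an atom count") from exc
    if len(lines) < count + 2:
        raise ParseError(f"{path}: expected {count} atom records, "
                         f"file has {len(lines) - 2}")
    comment = lines[1] if len(lines) > 1 else ""

    atoms: list[Atom] = []
    counters: dict[str, int] = {}
    for ln, line in enumerate(lines[2:2 + count], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {ln}: malformed record {line!r}")
        element = parts[0].capitalize()
        if element not in COVALENT_RADII:
            raise ParseError(f"{path}: line {ln}: unknown element {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: bad coordinate") from exc
        counters[element] = counters.get(element, 0) + 1
        auto = f"{element}{counters[element]}"
        atoms.append(Atom(label=auto, element=element, position=np.array(xyz)))

    # split into molecules before labels are applied (labels unique per molecule)
    match = _MOLECULES_RE.search(comment)
    if match:
        sizes = [int(s) for s in match.group(1).split(",") if s]
        if sum(sizes) != count:
            raise ParseError(f"{path}: molecules= sizes {sizes} do not sum "
                             f"to atom count {count}")
        idx = 0
        for mol_id, size in enumerate(sizes):
            for atom in atoms[idx:idx + size]:
                atom.molecule_id = mol_id
            idx += size
    else:
        _segment_molecules(atoms)

    if label_map is not None:
        missing = [a.label for a in atoms if a.label not in label_map]
        if missing:
            raise LabelingError(f"label map missing atoms: {missing}")
        per_mol_counters: dict[tuple[int, str], int] = {}
        for atom in atoms:
            atom.label = _normalize_label(label_map[atom.label])
        # re-generate per-molecule auto ordinals were not mapped; nothing to do
    else:
        # labels must be unique per molecule, regenerate ordinals per molecule
        per: dict[tuple[int, str], int] = {}
        for atom in atoms:
            k = (atom.molecule_id, atom.element)
            per[k] = per.get(k, 0) + 1
            atom.label = f"{atom.element}{per[k]}"

    graph = MolecularGraph(atoms=atoms, bonds=infer_bonds(atoms),
                           tautomer_id=tautomer_id)
    conf = Conformation(graph=graph, provenance=str(path))
    conf.check_separation()
    return conf


def write_xyz(conf: Conformation, path: str | Path, comment: str | None = None) -> None:
    """Write re-readable XYZ with >= 6 decimals; multimers keep a marker."""
    path = Path(path)
    atoms = conf.graph.atoms
    if comment is None:
        comment = conf.provenance or ""
    mol_ids = conf.graph.molecule_ids()
    if len(mol_ids) > 1:
        sizes = [sum(1 for a in atoms if a.molecule_id == m) for m in mol_ids]
        marker = "molecules=" + ",".join(str(s) for s in sizes)
        comment = f"{comment} {marker}".strip()
        atoms = sorted(atoms, key=lambda a: mol_ids.index(a.molecule_id))
    lines = [str(len(atoms)), comment]
    for a in atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDB (read-only subset)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, tautomer_id: str = "other") -> Conformation:
    """Read ATOM/HETATM records from a PDB v3 file (read-only support).

    Atom labels come from the atom-name column verbatim after prime
    normalization (``O5*`` -> ``O5'``); chains map to molecule_ids.
    """
    atoms: list[Atom] = []
    chain_ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = _normalize_label(line[12:16].strip())
        chain = line[21]
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError as exc:
            raise ParseError(f"bad coordinates in PDB record: {line!r}") from exc
        element = line[76:78].strip().capitalize() or name[0]
        if chain not in chain_ids:
            chain_ids.append(chain)
        atoms.append(Atom(label=name, element=element, position=np.array(xyz),
                          molecule_id=chain_ids.index(chain)))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    graph = MolecularGraph(atoms=atoms, bonds=infer_bonds(atoms),
                           tautomer_id=tautomer_id)
    return Conformation(graph=graph, provenance=str(path))


# ---------------------------------------------------------------------------
# topology validation
# ---------------------------------------------------------------------------

RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
CHAIN_ATOMS = ("C1'", "O2'", "C3'", "C4'", "O5'", "H5'")
RING_BONDS = (
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
    ("C6", "N1"), ("C4", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
)
CHAIN_BONDS = (
    ("N9", "C1'"), ("C1'", "O2'"), ("O2'", "C3'"), ("C3'", "C4'"),
    ("C4'", "O5'"), ("O5'", "H5'"),
)
SUBSTITUENT_BONDS = (("C6", "O6"), ("C2", "N2"))

#: Bonds whose absence makes a chain torsion axis undefined.
TORSION_AXIS_BONDS = {
    ("N9", "C1'"): "phi1",
    ("C1'", "O2'"): "phi2",
    ("O2'", "C3'"): "phi3",
    ("C3'", "C4'"): "phi4",
    ("C4'", "O5'"): "phi5",
}

#: Proton expected on the tautomeric site, per tautomer id.
TAUTOMER_PROTON = {
    "N1": ("N1", "H1"), "N3": ("N3", "H3"), "N7": ("N7", "H7"),
    "OHC": ("O6", "H6"), "OHT": ("O6", "H6"),
}


def validate_topology(graph: MolecularGraph) -> list[str]:
    """Check the acyclovir template atoms and bonding; violations are data.

    Returns an empty list iff every atom needed by the descriptor set and
    the hydrogen-bond site inventory is present with the expected bonding.
    """
    violations: list[str] = []
    required_atoms = RING_ATOMS + ("O6", "N2") + CHAIN_ATOMS
    for mol_id in graph.molecule_ids() or [0]:
        prefix = "" if len(graph.molecule_ids()) <= 1 else f"molecule {mol_id}: "
        present = {a.label for a in graph.atoms if a.molecule_id == mol_id}
        for label in required_atoms:
            if label not in present:
                violations.append(f"{prefix}missing atom {label}")
        proton = TAUTOMER_PROTON.get(graph.tautomer_id)
        if proton is not None and proton[1] not in present:
            violations.append(f"{prefix}missing atom {proton[1]} "
                              f"(tautomer {graph.tautomer_id} proton)")
        for l1, l2 in RING_BONDS + SUBSTITUENT_BONDS:
            if l1 in present and l2 in present and not graph.has_bond(l1, l2, mol_id):
                violations.append(f"{prefix}missing bond {l1}-{l2}")
        for (l1, l2), torsion in TORSION_AXIS_BONDS.items():
            if l1 in present and l2 in present and not graph.has_bond(l1, l2, mol_id):
                violations.append(f"{prefix}missing bond {l1}-{l2} "
                                  f"({torsion} axis undefined)")
        for l1, l2 in CHAIN_BONDS:
            if (l1, l2) in TORSION_AXIS_BONDS:
                continue
            if l1 in present and l2 in present and not graph.has_bond(l1, l2, mol_id):
                violations.append(f"{prefix}missing bond {l1}-{l2}")
    return violations


# ---------------------------------------------------------------------------
# Z-matrix construction
# ---------------------------------------------------------------------------

@dataclass
class ZMatrixEntry:
    """One internal-coordinate record.

    ``refs`` lists, in order, the bond, angle and dihedral reference labels:
    the new atom X satisfies |X-refs[0]| = bond_length,
    angle(X, refs[0], refs[1]) = bond_angle and
    dihedral(refs[2], refs[1], refs[0], X) = dihedral.
    """

    label: str
    element: str
    refs: tuple[str, ...]
    bond_length: float | None = None
    bond_angle: float | None = None
    dihedral: float | None = None


def place_atom(c: np.ndarray, b: np.ndarray, a: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D bonded to c, so that angle(D,c,b)=angle and
    dihedral(a,b,c,D)=dihedral (IUPAC sign convention)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-10:
        raise DegenerateFrameError("angle reference coincides with bond reference")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise DegenerateFrameError("colinear dihedral reference triple")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def zmatrix_to_cartesian(entries: Sequence[ZMatrixEntry],
                         provenance: str = "zmatrix") -> Conformation:
    """Build Cartesian coordinates from internal coordinates.

    The first three entries must carry progressively fewer references
    (0, 1, 2); all references must precede their atom.  The measured
    internal coordinates of the result reproduce the inputs to 1e-6 A
    (lengths) and 1e-4 degrees (angles).
    """
    positions: dict[str, np.ndarray] = {}
    atoms: list[Atom] = []
    bonds: set = set()
    for i, e in enumerate(entries):
        for ref in e.refs:
            if ref not in positions:
                raise ValueError(f"entry {e.label!r}: reference {ref!r} "
                                 "does not precede its atom")
        if i == 0:
            if e.refs:
                raise ValueError("first entry must have no references")
            pos = np.zeros(3)
        elif i == 1:
            if len(e.refs) != 1:
                raise ValueError("second entry must have one reference")
            pos = positions[e.refs[0]] + np.array([e.bond_length, 0.0, 0.0])
        elif i == 2:
            if len(e.refs) != 2:
                raise ValueError("third entry must have two references")
            c = positions[e.refs[0]]
            b = positions[e.refs[1]]
            theta = math.radians(e.bond_angle)
            bc = c - b
            nbc = np.linalg.norm(bc)
            if nbc < 1e-10:
                raise DegenerateFrameError("coincident references")
            u = bc / nbc
            # any perpendicular to u, deterministic
            helper = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(helper, u)) > 0.99:
                helper = np.array([0.0, 1.0, 0.0])
            v = np.cross(u, helper)
            v = v / np.linalg.norm(v)
            pos = c + e.bond_length * (-math.cos(theta) * u + math.sin(theta) * v)
        else:
            if len(e.refs) != 3:
                raise ValueError(f"entry {e.label!r}: need three references")
            pos = place_atom(positions[e.refs[0]], positions[e.refs[1]],
                             positions[e.refs[2]], e.bond_length,
                             e.bond_angle, e.dihedral)
        positions[e.label] = pos
        atoms.append(Atom(label=e.label, element=e.element, position=pos))
        if e.refs:
            bonds.add(frozenset({(0, e.label), (0, e.refs[0])}))
    graph = MolecularGraph(atoms=atoms, bonds=bonds)
    return Conformation(graph=graph, provenance=provenance)
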