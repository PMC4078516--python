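"""Synthetic inputs: template geometry, posed assemblies, toy energy models,
ensemble generators and the packaged table fixtures.

The template uses idealized standard bond lengths and angles (documented in
:data:`GEOMETRY`); no claim of coordinate-level agreement with any published
optimized geometry is made anywhere.  What the template guarantees is exact:
a perfectly planar purine bicycle and chain torsions realized exactly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .analysis import ConformerTable, read_conformer_table
from .descriptors import TORSION_NAMES, bond_angle, dihedral_angle, wrap_angle
from .model import Atom, Conformation, MolecularGraph, place_atom

__all__ = [
    "GEOMETRY",
    "DEFAULT_TORSIONS",
    "EnsembleSpec",
    "build_template",
    "set_chain_torsions",
    "generate_ensemble_table",
    "SeparableCosineModel",
    "ToyEnergyModel",
    "toy_energy",
    "pose_hbond_dimer",
    "pose_monomer_hbond",
    "motif_poses",
    "load_table1",
    "load_table2",
    "load_table4",
    "fixture_checksums",
    "FIXTURE_SHA256",
]

#: Standard small-molecule internal coordinates for the template (A, deg).
GEOMETRY = {
    "ring_bond": 1.39,          # aromatic ring bond (hexagon & pentagon side)
    "C6=O6": 1.23, "C2-N2": 1.36, "N-H": 1.01, "O-H": 0.97,
    "N9-C1'": 1.46, "C1'-O2'": 1.41, "O2'-C3'": 1.42,
    "C3'-C4'": 1.51, "C4'-O5'": 1.42,
    "C4-N9-C1'": 126.0, "N9-C1'-O2'": 109.5, "C1'-O2'-C3'": 113.0,
    "O2'-C3'-C4'": 108.0, "C3'-C4'-O5'": 108.0, "C4'-O5'-H5'": 108.0,
    "C6-O6-H6": 108.0, "N2-H": 1.01,
}

#: Default chain torsions for the N1 template (global-minimum-like pose).
DEFAULT_TORSIONS = {"phi1": -74.1, "phi2": 144.7, "phi3": -93.4,
                    "phi4": 71.1, "phi5": -73.3}

SUPPORTED_TAUTOMERS = ("N1", "N3", "N7", "OHC", "OHT")

_CHAIN_PLACEMENT = (
    # label, element, (bond-ref, angle-ref, dihedral-ref), bond, angle, torsion
    ("O2'", "O", ("C1'", "N9", "C4"), "C1'-O2'", "N9-C1'-O2'", "phi1"),
    ("C3'", "C", ("O2'", "C1'", "N9"), "O2'-C3'", "C1'-O2'-C3'", "phi2"),
    ("C4'", "C", ("C3'", "O2'", "C1'"), "C3'-C4'", "O2'-C3'-C4'", "phi3"),
    ("O5'", "O", ("C4'", "C3'", "O2'"), "C4'-O5'", "C3'-C4'-O5'", "phi4"),
    ("H5'", "H", ("O5'", "C4'", "C3'"), "O-H", "C4'-O5'-H5'", "phi5"),
)


def _rot2d(v: np.ndarray, deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([v[0] * math.cos(t) - v[1] * math.sin(t),
                     v[0] * math.sin(t) + v[1] * math.cos(t), 0.0])


def _ring_positions() -> dict[str, np.ndarray]:
    """Planar purine bicycle: regular hexagon fused with a regular pentagon."""
    s = GEOMETRY["ring_bond"]
    hexagon = {"N1": 150.0, "C2": 210.0, "N3": 270.0,
               "C4": 330.0, "C5": 30.0, "C6": 90.0}
    pos = {name: s * np.array([math.cos(math.radians(a)),
                               math.sin(math.radians(a)), 0.0])
           for name, a in hexagon.items()}
    c4, c5 = pos["C4"], pos["C5"]
    e = (c5 - c4) / np.linalg.norm(c5 - c4)
    pos["N9"] = c4 + s * _rot2d(e, -108.0)
    pos["N7"] = c5 + s * _rot2d(-e, 108.0)
    mid = 0.5 * (pos["N9"] + pos["N7"])
    half = np.linalg.norm(pos["N7"] - pos["N9"]) / 2.0
    apex = math.sqrt(max(s * s - half * half, 0.0))
    pos["C8"] = mid + apex * np.array([1.0, 0.0, 0.0])
    return pos


def build_template(tautomer: str = "N1",
                   torsions: dict[str, float] | None = None) -> Conformation:
    """Construct the 20-atom acyclovir-like template.

    The purine ring and its in-plane substituents are exact (planar to
    machine precision); the five chain torsions are realized exactly at the
    requested values (defaults: :data:`DEFAULT_TORSIONS`).  Tautomers differ
    only in the placement of the mobile proton.
    """
    if tautomer not in SUPPORTED_TAUTOMERS:
        raise NotImplementedError(f"unsupported tautomer {tautomer!r}; "
                                  f"expected one of {SUPPORTED_TAUTOMERS}")
    phis = dict(DEFAULT_TORSIONS)
    if torsions:
        unknown = set(torsions) - set(TORSION_NAMES)
        if unknown:
            raise ValueError(f"unknown torsions {sorted(unknown)}")
        phis.update(torsions)

    pos = _ring_positions()
    # in-plane exocyclic substituents, pointing away from the ring centroid
    def outward(label: str) -> np.ndarray:
        centroid = np.mean([pos[n] for n in
                            ("N1", "C2", "N3", "C4", "C5", "C6")], axis=0)
        d = pos[label] - centroid
        return d / np.linalg.norm(d)

    pos["O6"] = pos["C6"] + GEOMETRY["C6=O6"] * outward("C6")
    pos["N2"] = pos["C2"] + GEOMETRY["C2-N2"] * outward("C2")
    # sp2 amino hydrogens in the ring plane, +-120 deg from the N2->C2 bond
    n2c2 = (pos["C2"] - pos["N2"]) / np.linalg.norm(pos["C2"] - pos["N2"])
    pos["H2"] = pos["N2"] + GEOMETRY["N-H"] * _rot2d(n2c2, 120.0)
    pos["H2'"] = pos["N2"] + GEOMETRY["N-H"] * _rot2d(n2c2, -120.0)

    bonds_spec = [
        ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
        ("C5", "C6"), ("C6", "N1"), ("C4", "N9"), ("N9", "C8"),
        ("C8", "N7"), ("N7", "C5"), ("C6", "O6"), ("C2", "N2"),
        ("N2", "H2"), ("N2", "H2'"),
        ("N9", "C1'"), ("C1'", "O2'"), ("O2'", "C3'"),
        ("C3'", "C4'"), ("C4'", "O5'"), ("O5'", "H5'"),
    ]

    # tautomeric proton
    if tautomer == "N1":
        pos["H1"] = pos["N1"] + GEOMETRY["N-H"] * outward("N1")
        bonds_spec.append(("N1", "H1"))
    elif tautomer == "N3":
        pos["H3"] = pos["N3"] + GEOMETRY["N-H"] * outward("N3")
        bonds_spec.append(("N3", "H3"))
    elif tautomer == "N7":
        n7dir = pos["N7"] - pos["C8"] + pos["N7"] - pos["C5"]
        pos["H7"] = pos["N7"] + GEOMETRY["N-H"] * n7dir / np.linalg.norm(n7dir)
        bonds_spec.append(("N7", "H7"))
    else:  # OHC / OHT: enol proton on O6; the two differ only in its dihedral
        dihedral = 0.0 if tautomer == "OHC" else 180.0
        pos["H6"] = place_atom(pos["O6"], pos["C6"], pos["N1"],
                               GEOMETRY["O-H"], GEOMETRY["C6-O6-H6"], dihedral)
        bonds_spec.append(("O6", "H6"))

    # chain: C1' in-plane, anti to C5 across the C4-N9 axis
    pos["C1'"] = place_atom(pos["N9"], pos["C4"], pos["C5"],
                            GEOMETRY["N9-C1'"], GEOMETRY["C4-N9-C1'"], 180.0)
    for label, _el, refs, bond_key, angle_key, phi_key in _CHAIN_PLACEMENT:
        pos[label] = place_atom(pos[refs[0]], pos[refs[1]], pos[refs[2]],
                                GEOMETRY[bond_key], GEOMETRY[angle_key],
                                phis[phi_key])

    elements = {label: ("H" if label.startswith("H") else label[0])
                for label in pos}
    atoms = [Atom(label=label, element=elements[label], position=p)
             for label, p in pos.items()]
    bonds = {frozenset({(0, a), (0, b)}) for a, b in bonds_spec}
    graph = MolecularGraph(atoms=atoms, bonds=bonds, tautomer_id=tautomer)
    return Conformation(graph=graph,
                        provenance=f"template:{tautomer}")


def set_chain_torsions(conf: Conformation, torsions: dict[str, float],
                       molecule_id: int = 0) -> Conformation:
    """Rebuild the chain atoms of a template at the given torsions.

    Faster than repeated :func:`~acvconf.descriptors.set_torsion` calls when
    all five torsions change at once (grid search, ensembles).
    """
    out = conf.copy()
    g = out.graph
    phis = {name: dihedral_angle(*(out.position(l, molecule_id)
                                   for l in _quad(name)))
            for name in TORSION_NAMES}
    phis.update(torsions)
    for label, _el, refs, bond_key, angle_key, phi_key in _CHAIN_PLACEMENT:
        p = place_atom(g.atom(refs[0], molecule_id).position,
                       g.atom(refs[1], molecule_id).position,
                       g.atom(refs[2], molecule_id).position,
                       GEOMETRY[bond_key], GEOMETRY[angle_key], phis[phi_key])
        g.atom(label, molecule_id).position = p
    return out


def _quad(name: str):
    from .descriptors import TORSION_ATOMS
    return TORSION_ATOMS[name]


# ---------------------------------------------------------------------------
# toy energy models
# ---------------------------------------------------------------------------

class SeparableCosineModel:
    """E = sum_i k_i * (1 - cos(phi_i - center_i)); analytic per-torsion form.

    A convex-per-torsion surrogate landscape with a single known minimum,
    used to exercise the grid search.
    """

    per_torsion_analytic = True

    def __init__(self, centers: dict[str, float] | None = None,
                 k: float = 1.0) -> None:
        self.centers = dict(centers or DEFAULT_TORSIONS)
        self.k = float(k)

    def torsion_energy(self, torsions: dict[str, float]) -> float:
        return sum(
            self.k * (1.0 - math.cos(math.radians(v - self.centers[name])))
            for name, v in torsions.items() if name in self.centers)

    def torsion_gradient(self, torsions: dict[str, float]) -> dict[str, float]:
        """dE/dphi in kcal/mol per degree."""
        return {
            name: self.k * math.sin(math.radians(v - self.centers[name]))
            * math.pi / 180.0
            for name, v in torsions.items() if name in self.centers}

    def energy(self, conf: Conformation, molecule_id: int = 0) -> float:
        torsions = {name: dihedral_angle(*(conf.position(l, molecule_id)
                                           for l in _quad(name)))
                    for name in self.centers}
        return self.torsion_energy(torsions)


class TwoWellModel:
    """Per-torsion double well: E = sum_i k*(1 - cos(2*(phi_i - offset_i))).

    Minima at offset and offset+180 for each torsion; used for brute-force
    basin comparisons.
    """

    per_torsion_analytic = True

    def __init__(self, offsets: dict[str, float], k: float = 1.0) -> None:
        self.offsets = dict(offsets)
        self.k = float(k)

    def torsion_energy(self, torsions: dict[str, float]) -> float:
        return sum(
            self.k * (1.0 - math.cos(2.0 * math.radians(v - self.offsets[n])))
            for n, v in torsions.items() if n in self.offsets)

    def energy(self, conf: Conformation, molecule_id: int = 0) -> float:
        torsions = {n: dihedral_angle(*(conf.position(l, molecule_id)
                                        for l in _quad(n)))
                    for n in self.offsets}
        return self.torsion_energy(torsions)


class ToyEnergyModel:
    """Surrogate energy for the grid search; NOT a physical potential.

    Sum of per-torsion cosine terms, a soft-sphere repulsion between
    nonbonded atom pairs, and a bounded attractive well between H5' and the
    chain-to-base acceptors N3 / O2', so the intramolecular H-bond motifs
    are energetically favored.  Invariant under rigid motion.  Overlapping
    atoms (< 0.3 A) yield an infinite-energy sentinel, not an exception.
    """

    per_torsion_analytic = False
    OVERLAP = 0.3

    def __init__(self, centers: dict[str, float] | None = None,
                 k_torsion: float = 1.5, eps: float = 0.05,
                 well_depth: float = 3.0, well_r: float = 1.9,
                 well_sigma: float = 0.35, with_well: bool = True) -> None:
        self.centers = dict(centers or DEFAULT_TORSIONS)
        self.k_torsion = k_torsion
        self.eps = eps
        self.well_depth = well_depth
        self.well_r = well_r
        self.well_sigma = well_sigma
        self.with_well = with_well
        self._exclusions: dict = {}

    def _excluded_pairs(self, conf: Conformation) -> set:
        key = frozenset(conf.graph.bonds)
        cached = self._exclusions.get(key)
        if cached is not None:
            return cached
        excluded = set(conf.graph.bonds)
        adjacency: dict = {}
        for bond in conf.graph.bonds:
            x, y = tuple(bond)
            adjacency.setdefault(x, set()).add(y)
            adjacency.setdefault(y, set()).add(x)
        for center, nbs in adjacency.items():
            for x in nbs:
                for y in nbs:
                    if x != y:
                        excluded.add(frozenset({x, y}))
        self._exclusions[key] = excluded
        return excluded

    def energy(self, conf: Conformation, molecule_id: int = 0) -> float:
        e = 0.0
        for name, center in self.centers.items():
            v = dihedral_angle(*(conf.position(l, molecule_id)
                                 for l in _quad(name)))
            e += self.k_torsion * (1.0 - math.cos(math.radians(v - center)))

        atoms = conf.graph.atoms
        excluded = self._excluded_pairs(conf)
        from .model import COVALENT_RADII
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                ai, aj = atoms[i], atoms[j]
                if frozenset({ai.key, aj.key}) in excluded:
                    continue
                r = float(np.linalg.norm(ai.position - aj.position))
                if r < self.OVERLAP:
                    return math.inf
                r0 = 0.9 * (COVALENT_RADII.get(ai.element, 0.8)
                            + COVALENT_RADII.get(aj.element, 0.8))
                e += self.eps * (r0 / r) ** 12

        if self.with_well:
            try:
                h5 = conf.position("H5'", molecule_id)
            except KeyError:
                return e
            for acc in ("N3", "O2'"):
                try:
                    p = conf.position(acc, molecule_id)
                except KeyError:
                    continue
                r = float(np.linalg.norm(h5 - p))
                e -= self.well_depth * math.exp(
                    -((r - self.well_r) ** 2) / (2.0 * self.well_sigma ** 2))
        return e


def toy_energy(conf: Conformation) -> float:
    """Module-level convenience: default ToyEnergyModel energy, kcal/mol."""
    return ToyEnergyModel().energy(conf)


# ---------------------------------------------------------------------------
# posed assemblies for H-bond tests
# ---------------------------------------------------------------------------

def pose_hbond_dimer(distance: float = 1.733, dha_angle: float = 170.0,
                     tautomer: str = "N1") -> Conformation:
    """Two templates posed so H1(mol 0)...O6(mol 1) sits at ``distance``.

    The second molecule is oriented so its C6->O6 vector points back toward
    the donor, giving a roughly linear N1-H1...O6 contact at the requested
    donor-H...acceptor angle.
    """
    mol_a = build_template(tautomer)
    mol_b = build_template(tautomer)

    n1 = mol_a.position("H1") - mol_a.position("N1")
    n1 = n1 / np.linalg.norm(n1)
    # acceptor direction rotated off the N1-H1 axis by (180 - dha_angle)
    perp = np.cross(n1, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(n1, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    tilt = Rotation.from_rotvec(math.radians(180.0 - dha_angle) * perp)
    direction = tilt.apply(n1)
    target = mol_a.position("H1") + distance * direction

    v_b = mol_b.position("O6") - mol_b.position("C6")
    rot, _ = Rotation.align_vectors([-direction], [v_b / np.linalg.norm(v_b)])
    moved = mol_b.transformed(rotation=rot.as_matrix())
    shift = target - moved.position("O6")
    moved = moved.transformed(translation=shift)

    atoms = [a for a in mol_a.graph.atoms]
    for a in moved.graph.atoms:
        a.molecule_id = 1
        atoms.append(a)
    bonds = set(mol_a.graph.bonds)
    for bond in moved.graph.bonds:
        bonds.add(frozenset({(1, lbl) for (_m, lbl) in bond}))
    graph = MolecularGraph(atoms=atoms, bonds=bonds, tautomer_id=tautomer)
    conf = Conformation(graph=graph,
                        provenance=f"pose:dimer d={distance} a={dha_angle}")
    conf.check_separation()
    return conf


def pose_monomer_hbond(acceptor: str = "N3", distance: float = 1.9,
                       start: dict[str, float] | None = None) -> Conformation:
    """Monomer posed (by torsion adjustment) so H5'...acceptor = distance.

    Deterministic: a derivative-free local fit of the five chain torsions,
    started from ``start`` (default: the template defaults), targeting the
    requested contact distance with a near-linear O5'-H5'...acceptor angle.
    """
    template = build_template("N1", torsions=start)
    x0 = np.array([DEFAULT_TORSIONS[n] if not start else
                   start.get(n, DEFAULT_TORSIONS[n]) for n in TORSION_NAMES])

    def objective(x: np.ndarray) -> float:
        conf = set_chain_torsions(template, dict(zip(TORSION_NAMES, x)))
        h5 = conf.position("H5'")
        acc = conf.position(acceptor)
        d = float(np.linalg.norm(h5 - acc))
        ang = bond_angle(conf.position("O5'"), h5, acc)
        return (d - distance) ** 2 + 2e-4 * max(0.0, 155.0 - ang) ** 2

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 5000})
    conf = set_chain_torsions(template, dict(zip(TORSION_NAMES, res.x)))
    conf.provenance = f"pose:monomer {acceptor} d={distance}"
    return conf


#: conformer-like start poses and the intramolecular motif each realizes
_MOTIF_TARGETS = {
    "A1": ("N3", 1.9), "B1": ("N3", 1.9), "B2": ("N3", 1.9), "A2": ("N3", 1.9),
    "B3": ("O2'", 2.346), "A3": ("O2'", 2.350),
}


def motif_poses() -> dict[str, tuple[Conformation, str]]:
    """Six monomer poses realizing the two intramolecular motifs by design.

    Returns name -> (conformation, expected type 'i' or 'ii'); starts are
    the fixture torsions of the corresponding conformer.
    """
    table = load_table2()
    frame = table.frame
    out: dict[str, tuple[Conformation, str]] = {}
    for name, (acceptor, dist) in _MOTIF_TARGETS.items():
        row = frame[frame["name"] == name].iloc[0]
        start = {n: float(row[n]) for n in TORSION_NAMES}
        conf = pose_monomer_hbond(acceptor=acceptor, distance=dist,
                                  start=start)
        out[name] = (conf, "i" if acceptor == "N3" else "ii")
    return out


# ---------------------------------------------------------------------------
# synthetic conformer ensembles
# ---------------------------------------------------------------------------

#: (center deg, circular spread deg, weight) mixtures per torsion; the
#: defaults encode the bimodal phi1/phi2/phi3 and trimodal phi4/phi5
#: structure of the reference ensemble (weights from the observed counts).
DEFAULT_MODES = {
    "phi1": [(-95.0, 14.0, 47 / 78), (90.0, 13.0, 31 / 78)],
    "phi2": [(110.0, 35.0, 49 / 78), (-115.0, 35.0, 29 / 78)],
    "phi3": [(105.0, 35.0, 32 / 78), (-115.0, 35.0, 46 / 78)],
    "phi4": [(180.0, 12.0, 28 / 78), (70.0, 18.0, 28 / 78),
             (-60.0, 9.0, 22 / 78)],
    "phi5": [(180.0, 15.0, 29 / 78), (70.0, 22.0, 29 / 78),
             (-70.0, 18.0, 20 / 78)],
}


@dataclass
class EnsembleSpec:
    """Configuration for the synthetic conformer-ensemble generator."""

    n: int = 100
    modes: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_MODES.items()})
    energy_scale: float = 1.5   # kcal/mol, exponential decay constant
    energy_max: float = 8.5     # kcal/mol, truncation of the energy spread
    seed: int = 0
    with_geometry: bool = True

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("ensemble size must be >= 0")
        for torsion, modes in self.modes.items():
            weights = [w for (_c, _s, w) in modes]
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"{torsion}: mode weights must sum to 1")
            if any(s <= 0 for (_c, s, _w) in modes):
                raise ValueError(f"{torsion}: spreads must be positive")


def generate_ensemble_table(spec: EnsembleSpec) -> ConformerTable:
    """Draw a synthetic conformer table from circular torsion mixtures.

    Torsions are wrapped-normal draws from the per-torsion mode mixtures;
    energies are truncated-exponential on [0, energy_max].  Names follow the
    ranking convention (class by sign of phi1, numbered by ascending energy).
    The returned table carries a ``true_mode_<torsion>`` column per torsion
    recording the generating mode index, for parameter-recovery checks.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    data: dict[str, np.ndarray] = {}
    mode_idx: dict[str, np.ndarray] = {}
    for torsion, modes in spec.modes.items():
        weights = np.array([w for (_c, _s, w) in modes])
        idx = rng.choice(len(modes), size=n, p=weights / weights.sum())
        centers = np.array([c for (c, _s, _w) in modes])[idx]
        spreads = np.array([s for (_c, s, _w) in modes])[idx]
        values = centers + rng.normal(0.0, 1.0, size=n) * spreads
        data[torsion] = np.array([wrap_angle(v) for v in values])
        mode_idx[torsion] = idx

    u = rng.uniform(0.0, 1.0, size=n)
    trunc = 1.0 - math.exp(-spec.energy_max / spec.energy_scale)
    energies = -spec.energy_scale * np.log1p(-u * trunc)
    energies = np.sort(energies)  # rank by energy; torsion draws stay iid
    if n:
        energies -= energies.min()

    frame = pd.DataFrame(data)
    frame["dE"] = energies
    frame["dG"] = energies
    frame["mu"] = np.nan
    for torsion, idx in mode_idx.items():
        frame[f"true_mode_{torsion}"] = idx

    if spec.with_geometry and n:
        template = build_template("N1")
        geom = {"R": [], "beta": [], "Phi": []}
        from .descriptors import descriptor_set
        for i in range(n):
            conf = set_chain_torsions(
                template, {t: float(frame[t][i]) for t in TORSION_NAMES})
            ds = descriptor_set(conf)
            geom["R"].append(ds.R)
            geom["beta"].append(ds.beta)
            geom["Phi"].append(ds.Phi)
        for k, v in geom.items():
            frame[k] = v
    else:
        frame["R"] = np.nan
        frame["beta"] = np.nan
        frame["Phi"] = np.nan

    counters = {"A": 0, "B": 0, "U": 0}
    names = []
    for phi1 in frame["phi1"]:
        cls = "A" if phi1 < 0 else ("B" if phi1 > 0 else "U")
        counters[cls] += 1
        names.append(f"{cls}{counters[cls]}")
    frame.insert(0, "name", names)
    frame["level"] = "synthetic"
    return ConformerTable(frame, provenance=f"ensemble:seed={spec.seed},n={n}")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_SHA256 = {
    "table1_tautomers.tsv":
        "03e8e6ae9a09800a2eacbd9b5b6268385c8223692e8b4eb6707524749ad0abad",
    "table2_conformers.tsv":
        "df895f30512bc48630a4039aa0a1b17a874b12ffcd6afcdba1b746bc35cdee96",
    "table4_solid.tsv":
        "97a163676771782487ee110ef8b5fc15a10e3459d021604e5bfec2f3a862868c",
}


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("acvconf") / "data" / name))


def fixture_checksums() -> dict[str, str]:
    """sha256 of each packaged fixture, computed from the shipped bytes."""
    out = {}
    for name in FIXTURE_SHA256:
        out[name] = hashlib.sha256(
            _fixture_path(name).read_bytes()).hexdigest()
    return out


def _load_fixture(name: str, level: str | None) -> ConformerTable:
    path = _fixture_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    return read_conformer_table(path, level=level)


def load_table1(level: str | None = "B3LYP/6-31G(d,p)") -> ConformerTable:
    """Tautomer fixture (5 records at the default level)."""
    return _load_fixture("table1_tautomers.tsv", level)


def load_table2(level: str | None = "B3LYP/6-31G(d,p)") -> ConformerTable:
    """Conformer fixture (78 records at the default level)."""
    return _load_fixture("table2_conformers.tsv", level)


def load_table4():
    """Solid-state (dimer/tetramer) descriptor rows, with a flag column
    marking entries whose printed Phi duplicates phi1 (source artifact)."""
    import pandas as pd

    return pd.read_csv(_fixture_path("table4_solid.tsv"), sep="\t")
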