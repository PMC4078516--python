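"""Hydrogen-bond detection and typing.

Detects donor-H...acceptor contacts within and between molecules of an
assembly, and types the two intramolecular motifs available to the acyclic
chain: (i) H5'...N3 and (ii) H5'...O2'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .descriptors import bond_angle
from .model import Conformation

logger = logging.getLogger(__name__)

__all__ = [
    "HBondSpec",
    "HBond",
    "HBondConfigError",
    "detect_hbonds",
    "classify_intramolecular_type",
]

#: donor (heavy atom, hydrogen) pairs of the acyclovir template
DEFAULT_DONORS = (("N1", "H1"), ("N2", "H2"), ("N2", "H2'"), ("O5'", "H5'"))
#: heavy-atom acceptor sites
DEFAULT_ACCEPTORS = ("O6", "N3", "N7", "O2'", "O5'")


class HBondConfigError(ValueError):
    """Raised when a spec references labels absent from the conformation."""


@dataclass
class HBondSpec:
    """Site inventory plus geometric criteria licensing a hydrogen bond.

    The distance criterion applies to the H...acceptor separation (the
    scale of reported contact values, 1.7-2.4 A), not donor...acceptor.
    The angular cut on the donor-H...acceptor angle is an added guard on
    top of the distance criterion; both are configurable.
    """

    donors: tuple = DEFAULT_DONORS
    acceptors: tuple = DEFAULT_ACCEPTORS
    max_HA_distance: float = 2.6
    min_DHA_angle: float = 110.0

    def __post_init__(self) -> None:
        if self.max_HA_distance <= 0:
            raise ValueError("max_HA_distance must be positive")
        if not 0.0 <= self.min_DHA_angle <= 180.0:
            raise ValueError("min_DHA_angle must lie in [0, 180] degrees")


@dataclass
class HBond:
    """A detected donor-H...acceptor contact."""

    donor_mol: int
    donor: str
    hydrogen: str
    acceptor_mol: int
    acceptor: str
    HA_distance: float
    DHA_angle: float

    @property
    def scope(self) -> str:
        return "intra" if self.donor_mol == self.acceptor_mol else "inter"

    def to_dict(self) -> dict:
        return {
            "donor_mol": self.donor_mol, "donor": self.donor,
            "hydrogen": self.hydrogen, "acceptor_mol": self.acceptor_mol,
            "acceptor": self.acceptor,
            "distance_A": round(self.HA_distance, 3),
            "angle_deg": round(self.DHA_angle, 1),
            "scope": self.scope,
        }


def detect_hbonds(conf: Conformation, spec: HBondSpec | None = None) -> list[HBond]:
    """All donor/acceptor pairs meeting both geometric criteria.

    Donor and acceptor may sit in the same molecule (intra) or different
    molecules (inter); a donor's own heavy atom is never its acceptor.
    Results are sorted by H...A distance.  Spec labels that resolve in no
    molecule of the assembly raise :class:`HBondConfigError` listing them.
    """
    spec = spec or HBondSpec()
    mol_ids = conf.graph.molecule_ids()

    resolved_donors = []   # (mol, heavy, hydrogen, pos_heavy, pos_h)
    resolved_acceptors = []  # (mol, label, pos)
    seen_labels: set[str] = set()
    for mol in mol_ids:
        present = {a.label: a for a in conf.graph.atoms if a.molecule_id == mol}
        seen_labels.update(present)
        for heavy, hydrogen in spec.donors:
            if heavy in present and hydrogen in present:
                resolved_donors.append((mol, heavy, hydrogen,
                                        present[heavy].position,
                                        present[hydrogen].position))
        for label in spec.acceptors:
            if label in present:
                resolved_acceptors.append((mol, label, present[label].position))

    missing = sorted(
        {lbl for pair in spec.donors for lbl in pair if lbl not in seen_labels}
        | {lbl for lbl in spec.acceptors if lbl not in seen_labels})
    if missing:
        raise HBondConfigError(
            f"spec references labels absent from the assembly: {missing}")

    bonds: list[HBond] = []
    seen_pairs: set[tuple] = set()
    for dmol, heavy, hydrogen, p_heavy, p_h in resolved_donors:
        for amol, acc, p_acc in resolved_acceptors:
            if amol == dmol and acc == heavy:
                continue
            key = ((dmol, hydrogen), (amol, acc))
            if key in seen_pairs:
                continue
            dist = float(np.linalg.norm(p_h - p_acc))
            if dist > spec.max_HA_distance:
                continue
            angle = bond_angle(p_heavy, p_h, p_acc)
            if angle < spec.min_DHA_angle:
                continue
            seen_pairs.add(key)
            bonds.append(HBond(donor_mol=dmol, donor=heavy, hydrogen=hydrogen,
                               acceptor_mol=amol, acceptor=acc,
                               HA_distance=dist, DHA_angle=angle))
    bonds.sort(key=lambda b: b.HA_distance)
    return bonds


def classify_intramolecular_type(bonds: list[HBond]) -> str:
    """Type the intramolecular chain-to-base motif of a monomer.

    Returns ``"i"`` if an H5'...N3 contact is present, ``"ii"`` for
    H5'...O2', ``"both"`` or ``"none"``.  Bonds from donors other than H5'
    are ignored with a warning (the typing is scoped to the hydroxyl
    hydrogen); intermolecular bonds violate the precondition.
    """
    if any(b.scope != "intra" for b in bonds):
        raise ValueError("intramolecular typing requires intra-scope bonds only")
    relevant = []
    for b in bonds:
        if b.hydrogen != "H5'":
            logger.warning("ignoring bond from donor %s (typing is scoped "
                           "to H5')", b.hydrogen)
            continue
        relevant.append(b)
    has_i = any(b.acceptor == "N3" for b in relevant)
    has_ii = any(b.acceptor == "O2'" for b in relevant)
    if has_i and has_ii:
        return "both"
    if has_i:
        return "i"
    if has_ii:
        return "ii"
    return "none"
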