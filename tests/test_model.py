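"""molecule_model: I/O round trips, segmentation, topology, Z-matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acvconf.descriptors import bond_angle, descriptor_set, dihedral_angle
from acvconf.model import (Atom, DegenerateFrameError, LabelingError,
                           MolecularGraph, ParseError, ZMatrixEntry,
                           infer_bonds, read_label_map, read_pdb, read_xyz,
                           validate_topology, write_xyz, zmatrix_to_cartesian)
from acvconf.synthetic import build_template

from conftest import random_rotation


# ---------------------------------------------------------------------------
# XYZ round trips
# ---------------------------------------------------------------------------

def test_write_read_roundtrip_positions(template, tmp_path):
    path = tmp_path / "mono.xyz"
    write_xyz(template, path)
    back = read_xyz(path)
    assert len(back.graph.atoms) == 20
    np.testing.assert_allclose(back.positions(), template.positions(),
                               atol=1e-6)
    # atom order preserved
    assert [a.element for a in back.graph.atoms] == \
        [a.element for a in template.graph.atoms]


def test_roundtrip_preserves_dihedrals(template, tmp_path):
    path = tmp_path / "mono.xyz"
    write_xyz(template, path)
    # map auto element+ordinal labels back to the template's canonical ones
    mapping = {}
    counters = {}
    for atom in template.graph.atoms:
        counters[atom.element] = counters.get(atom.element, 0) + 1
        mapping[f"{atom.element}{counters[atom.element]}"] = atom.label
    back = read_xyz(path, label_map=mapping)
    before = descriptor_set(template)
    after = descriptor_set(back)
    for name, value in before.torsions().items():
        assert math.isclose(after.torsions()[name], value, abs_tol=1e-6)


def test_read_xyz_header_count(template, tmp_path):
    path = tmp_path / "m.xyz"
    write_xyz(template, path)
    assert path.read_text().splitlines()[0].strip() == "20"


def test_label_map_file(template, tmp_path):
    path = tmp_path / "m.xyz"
    write_xyz(template, path)
    mapping = {}
    counters = {}
    lines = []
    for atom in template.graph.atoms:
        counters[atom.element] = counters.get(atom.element, 0) + 1
        auto = f"{atom.element}{counters[atom.element]}"
        lines.append(f"{auto}\t{atom.label}")
    map_path = tmp_path / "labels.tsv"
    map_path.write_text("\n".join(lines) + "\n")
    conf = read_xyz(path, label_map=read_label_map(map_path))
    assert {a.label for a in conf.graph.atoms} == \
        {a.label for a in template.graph.atoms}
    assert all(a.molecule_id == 0 for a in conf.graph.atoms)


def test_label_map_missing_atom_errors(template, tmp_path):
    path = tmp_path / "m.xyz"
    write_xyz(template, path)
    with pytest.raises(LabelingError):
        read_xyz(path, label_map={"N1": "N1"})


def test_count_mismatch_errors(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("3\ncomment\nC 0 0 0\nC 1 0 0\n")
    with pytest.raises(ParseError):
        read_xyz(path)


def test_unknown_element_errors(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("1\ncomment\nXx 0 0 0\n")
    with pytest.raises(ParseError, match="unknown element"):
        read_xyz(path)


# ---------------------------------------------------------------------------
# multimer segmentation
# ---------------------------------------------------------------------------

def _two_blocks(template, offset):
    shifted = template.transformed(translation=np.array(offset))
    return template.positions(), shifted.positions()


def test_multimer_split_by_connectivity(template, tmp_path):
    pos_a, pos_b = _two_blocks(template, (20.0, 0.0, 0.0))
    elements = [a.element for a in template.graph.atoms]
    lines = [str(2 * len(elements)), "two far-apart copies"]
    for block in (pos_a, pos_b):
        for el, p in zip(elements, block):
            lines.append(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    path = tmp_path / "dimer.xyz"
    path.write_text("\n".join(lines) + "\n")
    conf = read_xyz(path)
    ids = [a.molecule_id for a in conf.graph.atoms]
    assert set(ids) == {0, 1}
    assert ids.count(0) == ids.count(1) == 20

    # independent oracle: connected components of the distance-threshold
    # bond graph via scipy sparse
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    atoms = conf.graph.atoms
    n = len(atoms)
    rows, cols = [], []
    for bond in infer_bonds(atoms):
        keys = [a.key for a in atoms]
        i, j = (keys.index(k) for k in bond)
        rows += [i, j]
        cols += [j, i]
    n_comp, labels = connected_components(
        csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)))
    assert n_comp == 2
    # oracle components agree with assigned molecule_ids up to relabeling
    pairs = {(ids[i], labels[i]) for i in range(n)}
    assert len(pairs) == 2


def test_multimer_marker_takes_precedence(template, tmp_path):
    # close enough that connectivity would merge them; marker must win
    pos_a, pos_b = _two_blocks(template, (50.0, 0.0, 0.0))
    elements = [a.element for a in template.graph.atoms]
    lines = [str(2 * len(elements)), "molecules=20,20"]
    for block in (pos_a, pos_b):
        for el, p in zip(elements, block):
            lines.append(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    path = tmp_path / "dimer.xyz"
    path.write_text("\n".join(lines) + "\n")
    conf = read_xyz(path)
    ids = [a.molecule_id for a in conf.graph.atoms]
    assert ids == [0] * 20 + [1] * 20


def test_multimer_write_roundtrip(template, tmp_path):
    from acvconf.synthetic import pose_hbond_dimer

    dimer = pose_hbond_dimer()
    path = tmp_path / "dimer.xyz"
    write_xyz(dimer, path)
    back = read_xyz(path)
    assert sorted(back.graph.molecule_ids()) == [0, 1]
    np.testing.assert_allclose(back.positions(), dimer.positions(), atol=1e-6)


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------

def test_read_pdb_prime_normalization(tmp_path):
    pdb = tmp_path / "m.pdb"
    pdb.write_text(
        "ATOM      1  N9  ACV A   1       0.000   0.000   0.000"
        "  1.00  0.00           N\n"
        "ATOM      2  O5* ACV A   1       3.900   0.000   0.000"
        "  1.00  0.00           O\n")
    conf = read_pdb(pdb)
    labels = {a.label for a in conf.graph.atoms}
    assert labels == {"N9", "O5'"}


# ---------------------------------------------------------------------------
# topology validation
# ---------------------------------------------------------------------------

def test_template_topology_clean(template):
    assert validate_topology(template.graph) == []


def test_missing_atom_reported(template):
    graph = template.graph.copy()
    graph.atoms = [a for a in graph.atoms if a.label != "O5'"]
    graph.bonds = {b for b in graph.bonds
                   if all(lbl != "O5'" for (_m, lbl) in b)}
    report = validate_topology(graph)
    assert any("missing atom O5'" in v for v in report)


def test_missing_phi1_axis_reported(template):
    graph = template.graph.copy()
    graph.bonds = {b for b in graph.bonds
                   if b != frozenset({(0, "N9"), (0, "C1'")})}
    report = validate_topology(graph)
    assert any("phi1 axis undefined" in v for v in report)


def test_rigid_motion_invariance(template, rng):
    rot = random_rotation(rng)
    moved = template.transformed(rotation=rot, translation=rng.normal(size=3))
    assert validate_topology(moved.graph) == validate_topology(template.graph)
    from scipy.spatial.distance import pdist

    np.testing.assert_allclose(pdist(moved.positions()),
                               pdist(template.positions()), atol=1e-9)


# ---------------------------------------------------------------------------
# Z-matrix
# ---------------------------------------------------------------------------

def _chain_entries(dihedral):
    return [
        ZMatrixEntry("A1", "C", ()),
        ZMatrixEntry("A2", "C", ("A1",), 1.5),
        ZMatrixEntry("A3", "C", ("A2", "A1"), 1.5, 110.0),
        ZMatrixEntry("A4", "C", ("A3", "A2", "A1"), 1.5, 110.0, dihedral),
    ]


@pytest.mark.parametrize("dihedral", [0.0, 60.0, -60.0, 180.0, -75.3])
def test_zmatrix_dihedral_exact(dihedral):
    conf = zmatrix_to_cartesian(_chain_entries(dihedral))
    p = {a.label: a.position for a in conf.graph.atoms}
    measured = dihedral_angle(p["A1"], p["A2"], p["A3"], p["A4"])
    assert math.isclose(measured, dihedral, abs_tol=1e-4) or \
        math.isclose(abs(measured), 180.0, abs_tol=1e-4)


def test_zmatrix_plus60_matches_rotation_oracle():
    from scipy.spatial.transform import Rotation

    conf = zmatrix_to_cartesian(_chain_entries(0.0))
    p = {a.label: a.position for a in conf.graph.atoms}
    axis = p["A3"] - p["A2"]
    axis = axis / np.linalg.norm(axis)
    oracle = Rotation.from_rotvec(np.radians(60.0) * axis).apply(
        p["A4"] - p["A3"]) + p["A3"]
    built = zmatrix_to_cartesian(_chain_entries(60.0))
    q = {a.label: a.position for a in built.graph.atoms}
    np.testing.assert_allclose(q["A4"], oracle, atol=1e-8)


def test_zmatrix_colinear_errors():
    entries = [
        ZMatrixEntry("A1", "C", ()),
        ZMatrixEntry("A2", "C", ("A1",), 1.5),
        ZMatrixEntry("A3", "C", ("A2", "A1"), 1.5, 180.0),
        ZMatrixEntry("A4", "C", ("A3", "A2", "A1"), 1.5, 110.0, 60.0),
    ]
    with pytest.raises(DegenerateFrameError):
        zmatrix_to_cartesian(entries)


def test_full_template_from_builder_validates(template):
    assert validate_topology(template.graph) == []


@settings(max_examples=40, deadline=None)
@given(
    bonds=st.lists(st.floats(1.0, 2.0), min_size=4, max_size=4),
    angles=st.lists(st.floats(20.0, 160.0), min_size=3, max_size=3),
    dihedrals=st.lists(st.floats(-179.0, 180.0), min_size=2, max_size=2),
)
def test_zmatrix_measurement_identity(bonds, angles, dihedrals):
    entries = [
        ZMatrixEntry("A1", "C", ()),
        ZMatrixEntry("A2", "C", ("A1",), bonds[0]),
        ZMatrixEntry("A3", "C", ("A2", "A1"), bonds[1], angles[0]),
        ZMatrixEntry("A4", "C", ("A3", "A2", "A1"), bonds[2], angles[1],
                     dihedrals[0]),
        ZMatrixEntry("A5", "C", ("A4", "A3", "A2"), bonds[3], angles[2],
                     dihedrals[1]),
    ]
    conf = zmatrix_to_cartesian(entries)
    p = {a.label: a.position for a in conf.graph.atoms}
    assert math.isclose(np.linalg.norm(p["A2"] - p["A1"]), bonds[0],
                        abs_tol=1e-6)
    assert math.isclose(np.linalg.norm(p["A3"] - p["A2"]), bonds[1],
                        abs_tol=1e-6)
    assert math.isclose(bond_angle(p["A2"], p["A3"], p["A4"]), angles[1],
                        abs_tol=1e-4)
    assert math.isclose(
        dihedral_angle(p["A1"], p["A2"], p["A3"], p["A4"]), dihedrals[0],
        abs_tol=1e-4)
    assert math.isclose(
        dihedral_angle(p["A2"], p["A3"], p["A4"], p["A5"]), dihedrals[1],
        abs_tol=1e-4)


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        MolecularGraph(atoms=[
            Atom("C1", "C", np.zeros(3)),
            Atom("C1", "C", np.ones(3)),
        ])
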