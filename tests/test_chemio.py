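"""Structure I/O, bond/ring perception, typing and H-bond inventories."""

import numpy as np
import pytest

from cocryst.chemio import (
    Atom,
    ChemistryError,
    CrystalStructure,
    FormatError,
    SymmetryOp,
    UnitCell,
    assign_typing,
    classify_hbond_sites,
    perceive_bonds,
    read_cif,
    write_cif,
)
from cocryst.synthdata import make_ribbon_crystal

from conftest import random_rotation


# --------------------------------------------------------------------------
# unit cell and symmetry


def test_unit_cell_volume_triclinic():
    cell = UnitCell(5.0, 6.0, 7.0, 80.0, 95.0, 100.0)
    a, b, c = cell.vectors
    assert np.isclose(cell.volume, abs(np.dot(a, np.cross(b, c))))
    assert np.isclose(np.linalg.norm(a), 5.0)
    # a along x, right-handed
    assert np.allclose(a[1:], 0.0, atol=1e-12)
    assert np.dot(np.cross(a, b), c) > 0


@pytest.mark.parametrize("bad", [dict(a=-1), dict(alpha=0.0), dict(gamma=180.0)])
def test_unit_cell_rejects_degenerate(bad):
    kw = dict(a=5.0, b=5.0, c=5.0, alpha=90.0, beta=90.0, gamma=90.0)
    kw.update(bad)
    with pytest.raises(ValueError):
        UnitCell(**kw)


def test_symmetry_op_xyz_roundtrip():
    op = SymmetryOp.from_xyz("-x,y+1/2,-z")
    assert np.array_equal(op.rotation, np.diag([-1, 1, -1]))
    assert np.allclose(op.translation, [0, 0.5, 0])
    assert SymmetryOp.from_xyz(op.to_xyz()).to_xyz() == op.to_xyz()


def test_symmetry_op_rejects_singular():
    with pytest.raises(ValueError):
        SymmetryOp(np.zeros((3, 3)), np.zeros(3))


# --------------------------------------------------------------------------
# CIF round trips


def test_p1_water_cif(tmp_path, water):
    xtal = CrystalStructure(
        UnitCell(10, 10, 10), [SymmetryOp.identity()], [water], "P 1"
    )
    path = tmp_path / "w.cif"
    write_cif(xtal, path)
    back = read_cif(path)
    assert len(back.ops) == 1 and back.ops[0].is_identity
    assert len(back.asym_molecules) == 1
    assert len(back.asym_molecules[0].atoms) == 3


def test_inversion_doubles_cell_content(water):
    mol = water.translated([2.0, 2.0, 2.0])
    xtal = CrystalStructure(
        UnitCell(10, 10, 10),
        [SymmetryOp.identity(), SymmetryOp.inversion()],
        [mol],
        "P -1",
    )
    cellmols = xtal.unit_cell_molecules()
    assert len(cellmols) == 2 * xtal.z_prime
    # expanded copies congruent to the asymmetric unit (inversion of a planar
    # molecule is a proper motion): compare sorted interatomic distances
    def dist_spectrum(m):
        x = m.coords
        return np.sort(np.linalg.norm(x[:, None] - x[None, :], axis=-1).ravel())

    assert np.allclose(dist_spectrum(cellmols[0]), dist_spectrum(cellmols[1]),
                       atol=1e-9)


def test_ribbon_cif_roundtrip(tmp_path):
    xtal = make_ribbon_crystal()
    path = tmp_path / "r.cif"
    write_cif(xtal, path)
    back = read_cif(path)
    for attr in ("a", "b", "c", "alpha", "beta", "gamma"):
        assert np.isclose(getattr(back.cell, attr), getattr(xtal.cell, attr),
                          atol=1e-7)
    # whole-molecule reassembly may shift by a lattice vector and reorder
    # atoms: compare fractional coordinates modulo the lattice
    f1 = xtal.cell.cart_to_frac(xtal.asym_molecules[0].coords) % 1.0
    f2 = back.cell.cart_to_frac(back.asym_molecules[0].coords) % 1.0
    assert len(f1) == len(f2)
    for row in f2:
        d = f1 - row
        d -= np.rint(d)
        assert np.min(np.linalg.norm(d @ xtal.cell.vectors, axis=1)) < 1e-6
    # designed charges survive the round trip
    assert np.isclose(sorted(back.asym_molecules[0].charges)[0], -0.38, atol=1e-8)


_CIF_CELL = """_cell_length_a 10
_cell_length_b 10
_cell_length_c 10
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
"""
_CIF_SYM = """loop_
_symmetry_equiv_pos_as_xyz
 'x,y,z'
"""
_CIF_ATOMS = """loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.1 0.1 0.1
"""


@pytest.mark.parametrize(
    "parts,missing",
    [
        ((_CIF_SYM, _CIF_ATOMS), "cell"),
        ((_CIF_CELL, _CIF_ATOMS), "symmetry"),
        ((_CIF_CELL, _CIF_SYM), "atom site"),
    ],
)
def test_cif_missing_items_raise(tmp_path, parts, missing):
    bad = tmp_path / "bad.cif"
    bad.write_text("data_x\n" + "".join(parts))
    with pytest.raises(FormatError, match=missing):
        read_cif(bad)


def test_cif_disorder_rejected_and_opt_in(tmp_path):
    cif = """data_x
_cell_length_a 10
_cell_length_b 10
_cell_length_c 10
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_symmetry_equiv_pos_as_xyz
 'x,y,z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
C1 C 0.1 0.1 0.1 0.5
C2 C 0.6 0.6 0.6 1.0
"""
    path = tmp_path / "dis.cif"
    path.write_text(cif)
    with pytest.raises(FormatError, match="C1"):
        read_cif(path)
    ok = read_cif(path, keep_major_occupancy=True)
    assert sum(len(m.atoms) for m in ok.asym_molecules) == 2


# --------------------------------------------------------------------------
# bond perception


def test_benzene_perception(benzene):
    cc = sum(
        1
        for b in benzene.bonds
        if benzene.atoms[b.i].element == benzene.atoms[b.j].element == "C"
    )
    ch = len(benzene.bonds) - cc
    assert (cc, ch) == (6, 6)
    assert [(len(r.indices), r.aromatic) for r in benzene.rings] == [(6, True)]


def test_distant_atoms_unbonded():
    mol = perceive_bonds([Atom("C", [0, 0, 0]), Atom("C", [5, 0, 0])])
    assert mol.bonds == []


def test_clash_raises():
    with pytest.raises(ChemistryError, match="clash"):
        perceive_bonds([Atom("C", [0, 0, 0]), Atom("C", [0.3, 0, 0])])


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_bond_perception_rigid_motion_invariant(quercetin, seed):
    rot = random_rotation(seed)
    moved = quercetin.transformed(rot, np.array([3.0, -7.0, 11.0]))
    re = perceive_bonds(moved.atoms)
    orig = {tuple(sorted((b.i, b.j))) for b in quercetin.bonds}
    new = {tuple(sorted((b.i, b.j))) for b in re.bonds}
    assert orig == new


def test_quercetin_perception(quercetin):
    rings = quercetin.rings
    assert len(rings) == 3
    carbocycles = [
        r
        for r in rings
        if all(quercetin.atoms[i].element == "C" for i in r.indices)
    ]
    assert len(carbocycles) == 2 and all(r.aromatic for r in carbocycles)
    # the pyrone ring contains O and is not flagged aromatic
    (pyrone,) = [r for r in rings if r not in carbocycles]
    assert any(quercetin.atoms[i].element == "O" for i in pyrone.indices)
    assert not pyrone.aromatic


# --------------------------------------------------------------------------
# typing, charges, donor/acceptor sites


def test_water_typing(water):
    types = sorted(a.ff_type for a in water.atoms)
    assert types == ["H__HB", "H__HB", "O_3"]
    assert abs(sum(a.charge for a in water.atoms)) < 1e-6


def test_methane_no_hb_sites(methane):
    assert all(a.ff_type == "H_" for a in methane.atoms if a.element == "H")
    inv = classify_hbond_sites(methane)
    assert (inv.n_donors, inv.n_acceptors) == (0, 0)
    assert abs(sum(a.charge for a in methane.atoms)) < 1e-6


def test_imidazole_sites(imidazole):
    inv = classify_hbond_sites(imidazole)
    assert inv.n_donors == 1
    assert inv.n_acceptors == 1
    (h, d) = inv.donors[0]
    assert imidazole.atoms[d].element == "N"
    assert imidazole.atoms[inv.acceptors[0]].element == "N"
    assert inv.acceptors[0] != d
    # both ring nitrogens typed aromatic
    assert all(
        a.ff_type == "N_R" for a in imidazole.atoms if a.element == "N"
    )


def test_quercetin_sites(quercetin):
    inv = classify_hbond_sites(quercetin)
    assert inv.n_donors == 5   # five hydroxyls
    assert inv.n_acceptors == 7  # 5 OH + carbonyl + ring ether oxygens


def test_unsupported_element_raises():
    mol = perceive_bonds([Atom("U", [0, 0, 0])])
    with pytest.raises(ChemistryError, match="U"):
        assign_typing(mol)


def test_charge_conservation(quercetin, imidazole, benzene):
    for mol in (quercetin, imidazole, benzene):
        assert abs(sum(a.charge for a in mol.atoms)) < 1e-6
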