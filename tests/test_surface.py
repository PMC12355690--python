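"""Slab terminations, vdW topology maps, facet chemistry densities."""

import numpy as np
import pytest

from cocryst.chemio import Atom, CrystalStructure, Molecule, SymmetryOp, UnitCell
from cocryst.energy import ForceFieldParams, KCAL_TO_KJ, LatticeModel
from cocryst.morphology import attachment_energy
from cocryst.surface import (
    bond_densities,
    candidate_offsets,
    crossing_energy,
    cut_slab,
    plane_lattice_basis,
    surface_report,
    topology_map,
)
from cocryst.synthdata import make_ribbon_crystal


def monolayer_crystal(a=1.5, c=20.0):
    """Dense square monolayer of carbons — a near-flat reference surface."""
    mol = Molecule([Atom("C", [a / 2, a / 2, c / 2], ff_type="C_3")], name="pt")
    return CrystalStructure(UnitCell(a, a, c), [SymmetryOp.identity()], [mol], "P 1")


def test_plane_basis_orthogonal_to_normal(ribbon):
    for hkl in ((1, 0, 0), (0, 1, 1), (1, -1, 1)):
        a1, a2, a3 = plane_lattice_basis(ribbon, hkl)
        n = ribbon.cell.plane_normal(hkl)
        assert abs(a1 @ n) < 1e-9 and abs(a2 @ n) < 1e-9
        assert a3 @ n == pytest.approx(ribbon.cell.d_spacing(hkl), abs=1e-9)


def test_cut_slab_rejects_zero_plane(ribbon, ribbon_model):
    with pytest.raises(ValueError):
        cut_slab(ribbon, (0, 0, 0), model=ribbon_model)


def test_termination_offset_matches_grid_oracle(ribbon, ribbon_model):
    for hkl in ((1, 0, 0), (0, 0, 1)):
        slab = cut_slab(ribbon, hkl, model=ribbon_model)
        d = ribbon.cell.d_spacing(hkl)
        grid = min(
            crossing_energy(ribbon_model, hkl, o)
            for o in np.linspace(0.0, d, 50, endpoint=False)
        )
        sel = crossing_energy(ribbon_model, hkl, slab.termination_offset)
        assert sel == pytest.approx(grid, abs=1e-9)


def test_equivalent_offsets_give_identical_chemistry(ribbon, ribbon_model):
    d = ribbon.cell.d_spacing((0, 0, 1))
    s1 = cut_slab(ribbon, (0, 0, 1), termination_offset=0.1 * d, model=ribbon_model)
    s2 = cut_slab(ribbon, (0, 0, 1), termination_offset=0.1 * d + d, model=ribbon_model)
    c1, c2 = bond_densities(s1), bond_densities(s2)
    assert c1.counts == c2.counts
    assert c1.hbd_density == pytest.approx(c2.hbd_density, abs=1e-12)


def test_chain_cut_exposes_chain_ends(ribbon, ribbon_model):
    # the (100) termination breaks the H-bond chain: the outermost atoms along
    # the normal are the donor-arm atoms (O-H tip), not ring atoms
    slab = cut_slab(ribbon, (1, 0, 0), model=ribbon_model)
    _, heights, _, _ = slab.atom_table()
    pos = np.vstack([m.coords for m in slab.molecules])
    elements = [a.element for m in slab.molecules for a in m.atoms]
    top = np.argsort(heights)[-4:]
    assert any(elements[i] in ("O", "H") for i in top)


def test_monolayer_rugosity_near_flat():
    xtal = monolayer_crystal()
    slab = cut_slab(xtal, (0, 0, 1), termination_offset=0.0, patch=(4, 4))
    topo = topology_map(slab, grid_spacing=0.25)
    assert topo.rugosity < 0.2
    assert abs(topo.height.mean()) < 1e-9  # mean-plane definition


def test_raised_molecule_increases_rugosity(ribbon, ribbon_model):
    slab = cut_slab(ribbon, (0, 0, 1), model=ribbon_model)
    base = topology_map(slab).rugosity
    # lift the topmost in-patch molecule so the envelope actually changes
    lifted_idx = max(
        (i for i, inp in enumerate(slab.in_patch) if inp),
        key=lambda i: slab.molecules[i].centroid() @ slab.normal,
    )
    slab.molecules[lifted_idx] = slab.molecules[lifted_idx].translated(
        2.0 * slab.normal
    )
    assert topology_map(slab).rugosity > base


def test_rugosity_grid_convergence(ribbon, ribbon_model):
    slab = cut_slab(ribbon, (0, 1, 0), model=ribbon_model)
    r_coarse = topology_map(slab, 0.25).rugosity
    r_fine = topology_map(slab, 0.10).rugosity
    assert abs(r_fine - r_coarse) / r_fine < 0.02


def test_rugosity_translation_invariance(ribbon, ribbon_model):
    slab = cut_slab(ribbon, (0, 0, 1), model=ribbon_model)
    base = topology_map(slab).rugosity
    # shift the whole slab in-plane by an arbitrary sub-cell vector
    shift = 0.37 * slab.a1 + 0.61 * slab.a2
    slab.molecules = [m.translated(shift) for m in slab.molecules]
    moved = topology_map(slab).rugosity
    assert abs(moved - base) / base < 0.01


def test_empty_or_bad_inputs():
    xtal = monolayer_crystal()
    slab = cut_slab(xtal, (0, 0, 1), termination_offset=0.0)
    with pytest.raises(ValueError):
        topology_map(slab, grid_spacing=-1.0)
    with pytest.raises(ValueError):
        bond_densities(slab, exposure_depth=0.0)


def test_aliphatic_surface_zero_aromatic_density():
    xtal = monolayer_crystal()
    slab = cut_slab(xtal, (0, 0, 1), termination_offset=0.0)
    chem = bond_densities(slab)
    assert chem.aromatic_density == 0.0
    assert chem.hbd_density == 0.0 and chem.hba_density == 0.0


def test_density_intensivity_2x2_vs_4x4(ribbon, ribbon_model):
    c2 = bond_densities(cut_slab(ribbon, (1, 0, 0), model=ribbon_model, patch=(2, 2)))
    c4 = bond_densities(cut_slab(ribbon, (1, 0, 0), model=ribbon_model, patch=(4, 4)))
    for attr in ("hbd_density", "hba_density", "aromatic_density"):
        a, b = getattr(c2, attr), getattr(c4, attr)
        assert a == pytest.approx(b, rel=0.05)


def test_donors_buried_along_ribbon_exposed_at_chain_end(ribbon, ribbon_model):
    # in-plane H-bonded hydroxyls are buried on the stacking facet but stick
    # out of the facet normal to the ribbon axis
    chem_end = bond_densities(cut_slab(ribbon, (1, 0, 0), model=ribbon_model))
    chem_stack = bond_densities(cut_slab(ribbon, (0, 0, 1), model=ribbon_model))
    assert chem_end.hbd_density > chem_stack.hbd_density


def test_surface_report_units_and_shape(ribbon, ribbon_model):
    facets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    df = surface_report(ribbon, facets, model=ribbon_model)
    assert len(df) == 3
    assert np.allclose(df["e_att_kj"], df["e_att_kcal"] * KCAL_TO_KJ)
    assert (df["hbd_density"] >= 0).all() and (df["rugosity_A"] >= 0).all()
    # default ordering: |E_att| descending
    assert df["e_att_kcal"].abs().is_monotonic_decreasing


def test_surface_report_observed_order(ribbon, ribbon_model):
    df = surface_report(
        ribbon,
        [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
        model=ribbon_model,
        observed_order=[(0, 0, 1), (1, 0, 0), (0, 1, 0)],
    )
    assert list(df["hkl"]) == [(0, 0, 1), (1, 0, 0), (0, 1, 0)]


def test_polar_anisotropy_layered_vs_uniform(dreiding):
    # a layered polar crystal shows a wide polar-fraction spread over facets;
    # a charge-free analogue with the H-bond term disabled shows none
    polar = make_ribbon_crystal()
    apolar = make_ribbon_crystal(charge_scale=0.0)
    params0 = ForceFieldParams.default()
    params0.d_hb = 0.0
    facets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    mp = LatticeModel(polar, dreiding, 15.0)
    ma = LatticeModel(apolar, params0, 15.0)
    spread_p = np.ptp(
        [attachment_energy(polar, hkl=h, model=mp).polar_fraction for h in facets]
    )
    spread_a = np.ptp(
        [attachment_energy(apolar, hkl=h, model=ma).polar_fraction for h in facets]
    )
    assert spread_p > 0.5
    assert spread_a < 1e-9


def test_candidate_offsets_within_one_spacing(ribbon, ribbon_model):
    d = ribbon.cell.d_spacing((0, 0, 1))
    offs = candidate_offsets(ribbon_model, (0, 0, 1))
    assert all(0.0 <= o < d for o in offs)
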