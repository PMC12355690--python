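"""Pair potentials, environments, lattice energy, synthon ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cocryst.chemio import (
    Atom,
    Bond,
    CrystalStructure,
    Molecule,
    SymmetryOp,
    UnitCell,
)
from cocryst.energy import (
    COULOMB_KCAL,
    ForceFieldParams,
    LatticeModel,
    aggregate_by_type,
    build_environment,
    classify_interaction,
    group_decomposition,
    lattice_energy,
    pair_energy,
    rank_synthons,
)
from cocryst.synthdata import make_ribbon_crystal

from conftest import random_rotation


def lj_atom(x, t="C_3", q=0.0):
    return Molecule([Atom("C", x, charge=q, ff_type=t)])


def brute_force_lattice(xtal, params, cutoff, nmax=3):
    """Independent oracle: explicit (2n+1)^3 supercell enumeration."""
    mols = xtal.unit_cell_molecules()
    A = xtal.cell.vectors
    cens = [m.centroid() for m in mols]
    total = 0.0
    for ref in range(len(mols)):
        for j, m in enumerate(mols):
            for s in itertools.product(range(-nmax, nmax + 1), repeat=3):
                if j == ref and s == (0, 0, 0):
                    continue
                shift = np.array(s) @ A
                if np.linalg.norm(cens[j] + shift - cens[ref]) <= cutoff:
                    total += 0.5 * pair_energy(
                        mols[ref], m.translated(shift), params
                    ).e_total
    return total


# --------------------------------------------------------------------------
# closed-form pair energies


def test_lj_dimer_minimum(dreiding):
    r0, d0 = dreiding.lookup("C_3")
    t = pair_energy(lj_atom([0, 0, 0]), lj_atom([r0, 0, 0]), dreiding)
    assert t.e_vdw == pytest.approx(-d0, abs=1e-12)
    assert t.e_coul == 0.0 and t.e_hb == 0.0


def test_coulomb_distance_dependent_dielectric():
    p = ForceFieldParams(lj={"C_3": (3.9, 0.0)})
    t = pair_energy(
        lj_atom([0, 0, 0], q=0.3), lj_atom([3.0, 0, 0], q=-0.3), p
    )
    assert t.e_coul == pytest.approx(COULOMB_KCAL * (-0.09) / 9.0, abs=1e-12)


def test_hbond_1210_minimum():
    p = ForceFieldParams(
        lj={"O_3": (3.4046, 0.0), "H__HB": (3.195, 0.0)}, d_hb=4.0, r_hb=2.75
    )
    donor = Molecule(
        [
            Atom("O", [0, 0, 0], ff_type="O_3"),
            Atom("H", [0.96, 0, 0], ff_type="H__HB"),
        ],
        bonds=[Bond(0, 1)],
    )
    acceptor = Molecule([Atom("O", [p.r_hb, 0, 0], ff_type="O_3")])
    t = pair_energy(donor, acceptor, p)
    assert t.e_hb == pytest.approx(-p.d_hb, abs=1e-12)
    assert t.e_vdw == 0.0  # the 12-10 term replaces the LJ H...A term


def test_hbond_angle_gating():
    p = ForceFieldParams(lj={"O_3": (3.4046, 0.0), "H__HB": (3.195, 0.0)})
    donor = Molecule(
        [
            Atom("O", [0, 0, 0], ff_type="O_3"),
            Atom("H", [0.96, 0, 0], ff_type="H__HB"),
        ],
        bonds=[Bond(0, 1)],
    )
    # acceptor behind the donor: theta(D-H...A) < 90° -> no H-bond term
    behind = Molecule([Atom("O", [-2.75, 0, 0], ff_type="O_3")])
    assert pair_energy(donor, behind, p).e_hb == 0.0


@pytest.mark.parametrize("seed", [0, 1])
def test_pair_energy_symmetric(ribbon, dreiding, seed):
    mols = ribbon.unit_cell_molecules()
    rot = random_rotation(seed)
    b = mols[0].transformed(rot, np.array([6.0, 1.0, 2.0]))
    t_ab = pair_energy(mols[0], b, dreiding)
    t_ba = pair_energy(b, mols[0], dreiding)
    assert t_ab.e_total == pytest.approx(t_ba.e_total, abs=1e-12)
    assert t_ab.e_total == pytest.approx(
        t_ab.e_vdw + t_ab.e_coul + t_ab.e_hb, abs=1e-12
    )


def test_missing_parameters_named():
    p = ForceFieldParams(lj={"C_3": (3.9, 0.1)})
    weird = Molecule([Atom("S", [0, 0, 0], ff_type="S_3")])
    with pytest.raises(KeyError, match="S_3"):
        pair_energy(lj_atom([0, 0, 0]), weird.translated([4.0, 0, 0]), p)


def test_param_file_roundtrip(tmp_path, dreiding):
    path = tmp_path / "ff.toml"
    dreiding.to_file(path)
    back = ForceFieldParams.from_file(path)
    assert back == dreiding


# --------------------------------------------------------------------------
# environments


def test_cubic_neighbor_count_matches_brute_force(point_cubic, dreiding):
    # cutoff 2a: shells |n| in {1, √2, √3, 2} -> 6+12+8+6 = 32 images
    env = build_environment(point_cubic, 0, cutoff=20.0)
    assert len(env) == 32
    count = 0
    for s in itertools.product(range(-3, 4), repeat=3):
        if s != (0, 0, 0) and np.linalg.norm(np.array(s) * 10.0) <= 20.0:
            count += 1
    assert count == 32


def test_empty_environment_below_nearest_neighbor(point_cubic):
    assert build_environment(point_cubic, 0, cutoff=5.0) == []


def test_environment_complete_for_skewed_cell(dreiding):
    # highly oblique cell: axis lengths alone underestimate the search range
    mol = Molecule([Atom("C", [0, 0, 0], ff_type="C_3")], name="pt")
    xtal = CrystalStructure(
        UnitCell(8, 8, 8, 60, 70, 60), [SymmetryOp.identity()], [mol], "P 1"
    )
    env = build_environment(xtal, 0, cutoff=18.0)
    A = xtal.cell.vectors
    brute = sum(
        1
        for s in itertools.product(range(-6, 7), repeat=3)
        if s != (0, 0, 0) and np.linalg.norm(np.array(s) @ A) <= 18.0
    )
    assert len(env) == brute


def test_noninteracting_crystal_energy_zero(dreiding):
    mol = Molecule([Atom("C", [0, 0, 0], ff_type="C_3")], name="pt")
    xtal = CrystalStructure(
        UnitCell(60, 60, 60), [SymmetryOp.identity()], [mol], "P 1"
    )
    _, total, _ = lattice_energy(xtal, dreiding, cutoff=65.0)
    assert abs(total) < 1e-6


def test_1d_lj_chain_analytic_series():
    eps, r0 = 0.2, 4.0
    p = ForceFieldParams(lj={"C_3": (r0, eps)})
    mol = Molecule([Atom("C", [r0 / 2, 30, 30], ff_type="C_3")])
    xtal = CrystalStructure(
        UnitCell(r0, 60, 60), [SymmetryOp.identity()], [mol], "P 1"
    )
    cutoff = 25.0
    _, total, _ = lattice_energy(xtal, p, cutoff=cutoff)
    nmax = int(cutoff // r0)
    analytic = sum(
        eps * ((1.0 / n) ** 12 - 2.0 * (1.0 / n) ** 6) for n in range(1, nmax + 1)
    )
    assert total == pytest.approx(analytic, abs=1e-6)


def test_cutoff_convergence_on_ribbon(ribbon, dreiding):
    _, e30, flag = lattice_energy(
        ribbon, dreiding, cutoff=30.0, check_convergence=True
    )
    assert flag is True
    _, e50, _ = lattice_energy(ribbon, dreiding, cutoff=50.0)
    assert abs(e50 - e30) < 0.1


def test_supercell_oracle_equivalence(ribbon, dreiding):
    _, total, _ = lattice_energy(ribbon, dreiding, cutoff=9.0)
    assert total == pytest.approx(
        brute_force_lattice(ribbon, dreiding, 9.0), abs=1e-6
    )


# --------------------------------------------------------------------------
# synthons


def test_ribbon_rank1_is_hbond(ribbon_model):
    ranking = rank_synthons(ribbon_model.xtal, model=ribbon_model)
    assert ranking.synthons[0].type_label == "H-bond"
    assert ranking.synthons[1].type_label == "pi-pi stacking"


def test_grouped_ranking_matches_flat_sort(ribbon_model):
    ranking = rank_synthons(ribbon_model.xtal, model=ribbon_model)
    flat = sorted(
        (p for r in range(ribbon_model.n_ref) for p in ribbon_model.pairs(r)),
        key=lambda p: -abs(p.e_total),
    )
    grouped_energies = [s.e_total for s in ranking.synthons for _ in range(s.multiplicity)]
    flat_energies = [p.e_total for p in flat if abs(p.e_total) >= 1e-4]
    assert np.allclose(sorted(grouped_energies), sorted(flat_energies), atol=1e-9)


def test_inversion_related_pair_merged(dreiding):
    xtal = make_ribbon_crystal(centrosymmetric=True)
    model = LatticeModel(xtal, dreiding, cutoff=12.0)
    ranking = rank_synthons(xtal, model=model)
    # Z' = 1 in P1̅: two molecules per cell, every contact has an
    # inversion-related mate -> multiplicities are even
    assert all(s.multiplicity % 2 == 0 for s in ranking.synthons)
    # symmetry-equivalent reference molecules report equal packing energies
    e = [model.molecule_energy(i) for i in range(model.n_ref)]
    assert abs(e[0] - e[1]) < 1e-6


def test_half_counting_conservation(ribbon_model):
    ranking = rank_synthons(
        ribbon_model.xtal, model=ribbon_model, energy_floor=0.0
    )
    assert sum(s.contribution for s in ranking.synthons) == pytest.approx(
        ranking.e_lattice, abs=1e-9
    )
    assert sum(
        s.rank and True for s in ranking.synthons
    )  # ranks assigned
    df = ranking.to_frame()
    assert df["percent_of_lattice"].sum() == pytest.approx(100.0, abs=1e-6)


# --------------------------------------------------------------------------
# classification


def _parallel_rings(offset, gap=3.5):
    th = np.arange(6) * np.pi / 3
    a = [Atom("C", [1.39 * np.cos(t), 1.39 * np.sin(t), 0]) for t in th]
    b = [
        Atom("C", [1.39 * np.cos(t) + offset, 1.39 * np.sin(t), gap]) for t in th
    ]
    from cocryst.chemio import perceive_bonds

    return perceive_bonds(a), perceive_bonds(b)


def test_classify_pi_pi_and_offset():
    a, b = _parallel_rings(0.0)
    assert classify_interaction(a, b) == "pi-pi stacking"
    a, b = _parallel_rings(3.0)
    assert classify_interaction(a, b) == "offset stacking"


def test_classify_hbond_beats_stacking(ribbon_model):
    mols = ribbon_model.cell_molecules
    chain = mols[0].translated(ribbon_model.xtal.cell.vectors[0])
    assert classify_interaction(mols[0], chain) == "H-bond"


def test_classify_vdw_other(methane):
    assert classify_interaction(methane, methane.translated([4.0, 0, 0])) == "vdW/other"


# --------------------------------------------------------------------------
# aggregation / decomposition


def test_aggregate_empty():
    out = aggregate_by_type(pd.DataFrame())
    assert out.loc[0, "energy_abs_kcal"] == 0.0


def test_aggregate_accepts_unicode_type_labels():
    df = pd.DataFrame(
        {"type": ["π–π stacking", "H-bond"], "energy_kcal": [-2.0, -3.0]}
    )
    agg = aggregate_by_type(df).set_index("class")
    assert agg.loc["stacking", "energy_abs_kcal"] == pytest.approx(2.0)
    assert agg.loc["H-bond", "energy_abs_kcal"] == pytest.approx(3.0)


def test_group_decomposition_conserves(ribbon_model):
    xtal = ribbon_model.xtal
    whole = group_decomposition(xtal, model=ribbon_model)
    total = ribbon_model.total_energy()
    assert whole["energy_kcal"].sum() == pytest.approx(total, abs=1e-6)

    def grouping(mol, i):
        a = mol.atoms[i]
        return "hydroxyl" if a.element in ("O", "H") and abs(a.charge) > 0 else "ring"

    split = group_decomposition(xtal, model=ribbon_model, grouping=grouping)
    assert split["energy_kcal"].sum() == pytest.approx(total, abs=1e-6)
    assert set(split["group"]) == {"hydroxyl", "ring"}


def test_group_decomposition_charged_hydroxyls_dominate_polar(ribbon_model):
    # charges live only on the donor/acceptor arms: the electrostatic part of
    # the lattice energy concentrates there
    def grouping(mol, i):
        return "charged" if abs(mol.atoms[i].charge) > 0 else "neutral"

    df = group_decomposition(
        ribbon_model.xtal, model=ribbon_model, grouping=grouping
    ).set_index("group")
    assert df.loc["charged", "energy_kcal"] < df.loc["neutral", "energy_kcal"]


def test_group_decomposition_unassigned_atom_listed(ribbon_model):
    with pytest.raises(ValueError, match="without a functional group"):
        group_decomposition(
            ribbon_model.xtal,
            model=ribbon_model,
            grouping=lambda mol, i: None if i == 0 else "g",
        )
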