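"""Deterministic synthetic fixtures for every pipeline stage.

The generators build *geometric idealizations*, not chemically accurate
molecules: rigid planar polycyclic scaffolds with hydroxyl donors and
carbonyl acceptors, packed into small orthorhombic P1 (or P1̅) crystals whose
strongest contacts are, by construction, an in-chain hydrogen bond and a
π-stack.  Ground truth (donor counts, planted PASS flags, planted ΔHBP signs,
which synthon dominates) is known analytically, so every downstream stage can
be tested end-to-end without external data.  All generators are bit-stable
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from cocryst.chemio import (
    Atom,
    Bond,
    CrystalStructure,
    Molecule,
    SymmetryOp,
    UnitCell,
    assign_typing,
    perceive_bonds,
)
from cocryst.screen_hbp import PropensityTable
from cocryst.screen_mc import DESCRIPTOR_NAMES, MCThresholds, descriptor_vector

RING_CC = 1.39      # aromatic C-C, Å
CH = 1.08           # aromatic C-H
CO_SINGLE = 1.36    # C-OH
CO_DOUBLE = 1.22    # C=O
OH = 0.96           # O-H
RING_PITCH = RING_CC * math.sqrt(3.0)  # fused-hexagon center spacing

# designed partial charges (e) for the hydroxyl / carbonyl idealization
Q_O_DONOR, Q_H_DONOR, Q_C_DONOR = -0.38, 0.30, 0.08
Q_O_ACC, Q_C_ACC = -0.35, 0.35


class FixtureError(ValueError):
    """Raised when requested fixture parameters are infeasible."""


# --------------------------------------------------------------------------
# molecules


def _acene_scaffold(n_rings: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Carbon positions and peripheral C-H direction list of a linear fused
    polycyclic scaffold lying in the z=0 plane."""
    pts: list[np.ndarray] = []
    for i in range(n_rings):
        cx = i * RING_PITCH
        for ang in range(6):
            th = math.radians(30 + 60 * ang)
            p = np.array([cx + RING_CC * math.cos(th), RING_CC * math.sin(th), 0.0])
            if not any(np.linalg.norm(p - q) < 1e-6 for q in pts):
                pts.append(p)
    return pts


def make_planar_donor_molecule(
    n_oh: int, n_rings: int, seed: int = 0, name: str = ""
) -> Molecule:
    """Rigid planar polycyclic molecule with ``n_oh`` peripheral hydroxyls.

    Every non-fused ring carbon carries either H or OH; hydroxyls get the
    designed donor charges (net molecular charge 0), everything else is
    neutral.  Donor/acceptor inventory is analytic: n_oh donors, n_oh
    acceptors.
    """
    if n_rings < 1:
        raise FixtureError("n_rings must be >= 1")
    if n_oh < 0:
        raise FixtureError("n_oh must be >= 0")
    rng = np.random.default_rng(seed)
    carbons = _acene_scaffold(n_rings)
    # peripheral carbons have exactly two carbon neighbours
    nbr_count = [
        sum(
            1
            for q in carbons
            if 1e-6 < np.linalg.norm(p - q) < RING_CC + 0.1
        )
        for p in carbons
    ]
    peripheral = [i for i, c in enumerate(nbr_count) if c == 2]
    if n_oh > len(peripheral):
        raise FixtureError(
            f"cannot place {n_oh} hydroxyls on {len(peripheral)} peripheral sites"
        )
    oh_sites = sorted(rng.choice(peripheral, size=n_oh, replace=False).tolist())

    atoms = [Atom("C", p) for p in carbons]
    for i in peripheral:
        nbrs = [
            q
            for q in carbons
            if 1e-6 < np.linalg.norm(carbons[i] - q) < RING_CC + 0.1
        ]
        direction = carbons[i] - np.mean(nbrs, axis=0)
        direction /= np.linalg.norm(direction)
        if i in oh_sites:
            o_pos = carbons[i] + CO_SINGLE * direction
            # in-plane O-H, bent ~109° from the C-O axis to stay planar
            perp = np.array([-direction[1], direction[0], 0.0])
            h_dir = math.cos(math.radians(71)) * direction + math.sin(
                math.radians(71)
            ) * perp
            atoms[i].charge = Q_C_DONOR
            atoms.append(Atom("O", o_pos, charge=Q_O_DONOR))
            atoms.append(Atom("H", o_pos + OH * h_dir, charge=Q_H_DONOR))
        else:
            atoms.append(Atom("H", carbons[i] + CH * direction))
    mol = perceive_bonds(atoms, name=name or f"planar_{n_rings}r_{n_oh}oh")
    assign_typing(mol, charge_scheme="keep")
    return mol


def make_ribbon_molecule() -> Molecule:
    """The ribbon-crystal building block: a benzene-like ring with a hydroxyl
    donor arm along +x and a carbonyl acceptor along −x, planar in z=0.

    Designed so that translation along x forms a linear O–H···O chain with
    θ(D–H···A) = 180°.
    """
    atoms = []
    ring = []
    for ang in range(6):
        th = math.radians(60 * ang)
        ring.append(np.array([RING_CC * math.cos(th), RING_CC * math.sin(th), 0.0]))
    # ring[0] = (+1.39, 0): donor arm; ring[3] = (−1.39, 0): acceptor arm
    for idx, p in enumerate(ring):
        q = Q_C_DONOR if idx == 0 else (Q_C_ACC if idx == 3 else 0.0)
        atoms.append(Atom("C", p, charge=q))
    o_d = np.array([RING_CC + CO_SINGLE, 0.0, 0.0])
    atoms.append(Atom("O", o_d, charge=Q_O_DONOR))
    atoms.append(Atom("H", o_d + np.array([OH, 0.0, 0.0]), charge=Q_H_DONOR))
    atoms.append(Atom("O", np.array([-(RING_CC + CO_DOUBLE), 0.0, 0.0]),
                      charge=Q_O_ACC))
    for idx in (1, 2, 4, 5):
        direction = ring[idx] / np.linalg.norm(ring[idx])
        atoms.append(Atom("H", ring[idx] + CH * direction))
    mol = perceive_bonds(atoms, name="ribbon_unit")
    assign_typing(mol, charge_scheme="keep")
    return mol


_RIBBON_X_MIN = -(RING_CC + CO_DOUBLE)          # acceptor O
_RIBBON_X_MAX = RING_CC + CO_SINGLE + OH        # donor H
_RIBBON_Y_HALF = (RING_CC + CH) * math.sin(math.radians(60))


def make_ribbon_crystal(
    spacing_hb: float = 2.75,
    spacing_stack: float = 3.5,
    cell_padding: float = 3.5,
    seed: int = 0,
    charge_scale: float = 1.0,
    centrosymmetric: bool = False,
) -> CrystalStructure:
    """Orthorhombic model crystal: H-bonded chains along **a**, π-stacks along
    **c**, van-der-Waals contacts along **b**.

    ``spacing_hb`` is the donor–acceptor O···O distance in the chain (2.5–4.5
    Å), ``spacing_stack`` the interplanar ring distance (3.2–4.0 Å),
    ``cell_padding`` the extra gap along **b**.  ``charge_scale`` scales all
    partial charges, which (together with the force-field H-bond well depth)
    controls whether the H-bond or the stack is the dominant synthon.  With
    ``centrosymmetric`` the cell is doubled along a and b and an inversion
    centre added (Z′ = 1 in P1̅).
    """
    if not 2.5 <= spacing_hb <= 4.5:
        raise FixtureError("spacing_hb must be in [2.5, 4.5] Å")
    if not 3.2 <= spacing_stack <= 4.0:
        raise FixtureError("spacing_stack must be in [3.2, 4.0] Å")
    if cell_padding < 1.0:
        raise FixtureError("cell_padding must be >= 1 Å")
    del seed  # geometry is fully deterministic; parameter kept for API uniformity
    mol = make_ribbon_molecule()
    for a in mol.atoms:
        a.charge *= charge_scale
    a_len = (_RIBBON_X_MAX - _RIBBON_X_MIN - OH) + spacing_hb
    b_len = 2 * _RIBBON_Y_HALF + cell_padding
    c_len = spacing_stack
    if not centrosymmetric:
        cell = UnitCell(a_len, b_len, c_len)
        mol = mol.translated(
            np.array([a_len / 2, b_len / 2, 0.0]) - mol.centroid()
        )
        xtal = CrystalStructure(cell, [SymmetryOp.identity()], [mol], "P 1")
    else:
        cell = UnitCell(2 * a_len, 2 * b_len, c_len)
        mol = mol.translated(
            np.array([a_len / 2, b_len / 2, 0.0]) - mol.centroid()
        )
        xtal = CrystalStructure(
            cell,
            [SymmetryOp.identity(), SymmetryOp.inversion()],
            [mol],
            "P -1",
        )
    xtal.unit_cell_molecules()  # raises on overlap
    return xtal


def make_random_ribbon_crystal(seed: int) -> CrystalStructure:
    """A ribbon crystal with seed-drawn spacings (used for property suites)."""
    rng = np.random.default_rng(seed)
    return make_ribbon_crystal(
        spacing_hb=float(rng.uniform(2.6, 3.1)),
        spacing_stack=float(rng.uniform(3.3, 3.9)),
        cell_padding=float(rng.uniform(3.0, 4.5)),
        seed=seed,
    )


# --------------------------------------------------------------------------
# coformer libraries with planted PASS/FAIL flags


@dataclass
class PlantedLibrary:
    target: Molecule
    members: list[Molecule]
    expected_pass: list[bool]

    @property
    def n_pass(self) -> int:
        return sum(self.expected_pass)


def _descriptor_diffs(target_desc, mol) -> dict[str, float]:
    d = descriptor_vector(mol)
    return {
        k: abs(getattr(target_desc, k) - getattr(d, k)) for k in DESCRIPTOR_NAMES
    }


def make_coformer_library(
    n: int,
    n_pass: int,
    thresholds: MCThresholds | None = None,
    seed: int = 0,
    target: Molecule | None = None,
) -> PlantedLibrary:
    """Library of ``n`` molecules of which exactly ``n_pass`` sit inside all
    PASS windows relative to the target.

    PASS members are small coordinate jitters of the target; FAIL members are
    progressively stretched along the long molecular axis until at least one
    shape window is violated.  Construction is verified against the actual
    descriptor windows and raises if infeasible.
    """
    if not 0 <= n_pass <= n:
        raise FixtureError("need 0 <= n_pass <= n")
    thresholds = thresholds or MCThresholds.default()
    rng = np.random.default_rng(seed)
    target = target or make_planar_donor_molecule(2, 2, seed=seed, name="target")
    tdesc = descriptor_vector(target)
    windows = thresholds.as_dict()

    members, flags = [], []
    for idx in range(n):
        want_pass = idx < n_pass
        base = target.coords
        if want_pass:
            for jitter in (0.03, 0.01, 0.003, 0.0):
                coords = base + rng.normal(0.0, jitter, size=base.shape)
                cand = _clone_with_coords(target, coords, f"pass_{idx}")
                diffs = _descriptor_diffs(tdesc, cand)
                if all(diffs[k] <= windows[k] for k in DESCRIPTOR_NAMES):
                    break
            else:
                raise FixtureError("could not construct an in-window member")
        else:
            stretch = 1.8
            for _ in range(20):
                coords = base.copy()
                axis = _long_axis(base)
                proj = (coords - coords.mean(axis=0)) @ axis
                coords = coords + np.outer(proj * (stretch - 1.0), axis)
                cand = _clone_with_coords(target, coords, f"fail_{idx}")
                diffs = _descriptor_diffs(tdesc, cand)
                if any(diffs[k] > windows[k] for k in DESCRIPTOR_NAMES):
                    break
                stretch *= 1.5
            else:
                raise FixtureError("could not construct an out-of-window member")
        members.append(cand)
        flags.append(want_pass)
    return PlantedLibrary(target=target, members=members, expected_pass=flags)


def _long_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(centered.T @ centered)
    return vecs[:, -1]


def _clone_with_coords(mol: Molecule, coords: np.ndarray, name: str) -> Molecule:
    return Molecule(
        atoms=[replace(a, position=p) for a, p in zip(mol.atoms, coords)],
        bonds=list(mol.bonds),
        rings=list(mol.rings),
        name=name,
    )


# --------------------------------------------------------------------------
# propensity tables with planted ΔHBP signs


def make_propensity_table(
    n_pairs: int,
    n_positive_delta: int,
    seed: int = 0,
    target: str = "target",
) -> tuple[PropensityTable, pd.DataFrame]:
    """Synthetic donor–acceptor propensity table for ``n_pairs`` coformers,
    exactly ``n_positive_delta`` of which have ΔHBP > 0 by construction.

    Returns the table and the expected per-coformer ΔHBP frame (descending).
    """
    if not 0 <= n_positive_delta <= n_pairs:
        raise FixtureError("need 0 <= n_positive_delta <= n_pairs")
    rng = np.random.default_rng(seed)
    p_tt = 0.45
    rows = [
        {
            "donor_group": "OH",
            "acceptor_group": "OH",
            "mol_a": target,
            "mol_b": target,
            "propensity": p_tt,
        }
    ]
    expected = []
    for i in range(n_pairs):
        name = f"coformer_{i:03d}"
        p_cc = float(rng.uniform(0.10, 0.60))
        p_homo = max(p_tt, p_cc)
        if i < n_positive_delta:
            delta = float(rng.uniform(0.02, min(0.30, 0.97 - p_homo)))
        else:
            delta = -float(rng.uniform(0.02, min(0.30, p_homo - 0.01)))
        p_het = p_homo + delta
        # a second, weaker heteromeric pairing that never changes the max
        p_het2 = float(rng.uniform(0.01, max(p_het - 0.01, 0.02)))
        rows.append(
            {
                "donor_group": "OH",
                "acceptor_group": "Nsp2",
                "mol_a": target,
                "mol_b": name,
                "propensity": round(p_het, 6),
            }
        )
        rows.append(
            {
                "donor_group": "OH",
                "acceptor_group": "C=O",
                "mol_a": target,
                "mol_b": name,
                "propensity": round(min(p_het2, p_het), 6),
            }
        )
        rows.append(
            {
                "donor_group": "NH",
                "acceptor_group": "Nsp2",
                "mol_a": name,
                "mol_b": name,
                "propensity": round(p_cc, 6),
            }
        )
        expected.append(
            {
                "coformer": name,
                "delta": round(p_het, 6) - p_homo,
                "positive": delta > 0,
            }
        )
    table = PropensityTable(
        pd.DataFrame(rows), provenance=f"synthetic (seed={seed})"
    )
    exp = (
        pd.DataFrame(expected)
        .sort_values(["delta", "coformer"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return table, exp
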