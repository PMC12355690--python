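"""Molecular and crystal structure I/O, chemical perception, force-field typing.

The in-memory model is deliberately small: an :class:`Atom` carries Cartesian
coordinates (Å), a partial charge (e) and a Dreiding-style atom-type label;
a :class:`Molecule` is an ordered atom list plus a bond graph and perceived
rings; a :class:`CrystalStructure` is a unit cell, a set of symmetry
operations and the asymmetric-unit molecules.  Fractional coordinates appear
only at the CIF boundary — everything else works in Cartesian Å with a
right-handed cell, **a** along x.

Element data (covalent and van der Waals radii, atomic weights) come from
gemmi; CIF parsing uses the gemmi CIF reader.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

BOND_TOLERANCE = 0.4  # Å added to the covalent-radius sum when perceiving bonds
CLASH_DISTANCE = 0.5  # Å below which two atom sites are considered the same/clashing
PLANARITY_RMS = 0.1   # Å RMS out-of-plane limit for flagging a ring aromatic


class FormatError(ValueError):
    """Raised when a structure file is missing a required item."""


class ChemistryError(ValueError):
    """Raised on chemically impossible input (clashes, bad valences...)."""


def covalent_radius(element: str) -> float:
    r = gemmi.Element(element).covalent_r
    if r <= 0:
        raise ChemistryError(f"no covalent radius for element {element!r}")
    return float(r)


def vdw_radius(element: str) -> float:
    r = gemmi.Element(element).vdw_r
    if r <= 0:
        raise ChemistryError(f"no van der Waals radius for element {element!r}")
    return float(r)


def atomic_weight(element: str) -> float:
    el = gemmi.Element(element)
    if el.weight <= 0 or el.name == "X":
        raise ChemistryError(f"unknown element {element!r}")
    return float(el.weight)


# --------------------------------------------------------------------------
# domain types


@dataclass
class Atom:
    """A single atom: element symbol, Cartesian position (Å), partial charge (e)."""

    element: str
    position: np.ndarray
    charge: float = 0.0
    ff_type: str | None = None
    label: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if gemmi.Element(self.element).name == "X":
            raise ChemistryError(f"invalid element symbol {self.element!r}")

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)

    @property
    def covalent_radius(self) -> float:
        return covalent_radius(self.element)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Bond:
    i: int
    j: int
    order: str = "single"  # single | double | triple | aromatic


@dataclass
class Ring:
    indices: tuple[int, ...]
    aromatic: bool = False


@dataclass
class Molecule:
    """An ordered atom collection with a bond graph and perceived rings."""

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    rings: list[Ring] = field(default_factory=list)
    name: str = ""

    # -- geometry ----------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def centroid(self) -> np.ndarray:
        """Unweighted geometric centroid of all atoms (Å)."""
        return self.coords.mean(axis=0)

    def translated(self, shift: np.ndarray) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        return Molecule(
            atoms=[replace(a, position=a.position + shift) for a in self.atoms],
            bonds=list(self.bonds),
            rings=list(self.rings),
            name=self.name,
        )

    def transformed(self, rot: np.ndarray, shift: np.ndarray) -> "Molecule":
        rot = np.asarray(rot, dtype=float)
        return Molecule(
            atoms=[
                replace(a, position=rot @ a.position + shift) for a in self.atoms
            ],
            bonds=list(self.bonds),
            rings=list(self.rings),
            name=self.name,
        )

    # -- graph -------------------------------------------------------------
    def neighbor_map(self) -> dict[int, list[int]]:
        nbrs: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            nbrs[b.i].append(b.j)
            nbrs[b.j].append(b.i)
        return nbrs

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def aromatic_rings(self) -> list[Ring]:
        return [r for r in self.rings if r.aromatic]

    def aromatic_bonds(self) -> list[tuple[int, int]]:
        """Bonds whose both endpoints lie in the same aromatic ring."""
        out = []
        arom_sets = [set(r.indices) for r in self.aromatic_rings()]
        for b in self.bonds:
            if any(b.i in s and b.j in s for s in arom_sets):
                out.append((b.i, b.j))
        return out

    def validate(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ChemistryError(f"bond index out of range: {b}")
        if n > 1 and self.bonds:
            g = self.bond_graph()
            if not nx.is_connected(g):
                raise ChemistryError(f"molecule {self.name!r} bond graph not connected")


@dataclass
class UnitCell:
    """Triclinic unit cell; lengths in Å, angles in degrees.

    ``vectors`` returns the 3×3 matrix whose rows are the cell vectors a, b, c
    in Cartesian Å with a along x (right-handed convention).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        ca, cb, cg = (
            math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma)
        )
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def vectors(self) -> np.ndarray:
        m = self._gemmi.orth.mat
        # gemmi's orthogonalization matrix has the cell vectors as columns
        return np.array(m.tolist(), dtype=float).T

    @property
    def reciprocal_vectors(self) -> np.ndarray:
        """Rows are a*, b*, c* (no 2π factor), so that A_recip @ A.T = I."""
        return np.linalg.inv(self.vectors).T

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.vectors

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.vectors)

    def d_spacing(self, hkl: tuple[int, int, int]) -> float:
        g = np.asarray(hkl, dtype=float) @ self.reciprocal_vectors
        return 1.0 / float(np.linalg.norm(g))

    def plane_normal(self, hkl: tuple[int, int, int]) -> np.ndarray:
        """Unit normal of the (hkl) lattice planes (Cartesian)."""
        g = np.asarray(hkl, dtype=float) @ self.reciprocal_vectors
        return g / np.linalg.norm(g)

    def axis_spacings(self) -> np.ndarray:
        """Interplanar spacings of the (100), (010), (001) plane families."""
        return np.array([self.d_spacing(h) for h in ((1, 0, 0), (0, 1, 0), (0, 0, 1))])


@dataclass
class SymmetryOp:
    """Symmetry operation in the fractional basis: x' = R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=int).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        det = int(round(np.linalg.det(self.rotation)))
        if det not in (1, -1):
            raise ValueError(f"symmetry rotation determinant must be ±1, got {det}")

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(np.eye(3, dtype=int), np.zeros(3))

    @classmethod
    def inversion(cls) -> "SymmetryOp":
        return cls(-np.eye(3, dtype=int), np.zeros(3))

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        op = gemmi.Op(triplet)
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
        return cls(np.rint(rot).astype(int), tran)

    def to_xyz(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(x) * gemmi.Op.DEN for x in row] for row in self.rotation]
        op.tran = [int(round(t * gemmi.Op.DEN)) for t in self.translation]
        return op.triplet()

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.rotation, np.eye(3, dtype=int)) and np.allclose(
            self.translation % 1.0, 0.0
        )


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operations + asymmetric-unit molecules.

    ``asym_molecules`` hold Cartesian coordinates consistent with
    ``cell.vectors``; symmetry expansion produces whole molecules (no covalent
    bond broken across a cell boundary).
    """

    cell: UnitCell
    ops: list[SymmetryOp]
    asym_molecules: list[Molecule]
    space_group_label: str = "P 1"

    _cell_cache: list[Molecule] | None = field(default=None, repr=False, compare=False)

    @property
    def z_prime(self) -> int:
        return len(self.asym_molecules)

    @property
    def is_centrosymmetric(self) -> bool:
        return any(
            np.array_equal(op.rotation, -np.eye(3, dtype=int)) for op in self.ops
        )

    def unit_cell_molecules(self) -> list[Molecule]:
        """All whole symmetry-distinct molecules of one unit cell (deduplicated).

        Each asymmetric-unit molecule is mapped through every operation; copies
        whose centroids coincide modulo a lattice translation (within 0.5 Å)
        are merged.  Molecules are kept whole: the operation acts on the whole
        Cartesian molecule, only its centroid is wrapped into the cell.
        """
        if self._cell_cache is not None:
            return self._cell_cache
        A = self.cell.vectors
        out: list[Molecule] = []
        frac_centroids: list[np.ndarray] = []
        for mi, mol in enumerate(self.asym_molecules):
            frac = self.cell.cart_to_frac(mol.coords)
            for op in self.ops:
                new_frac = op.apply(frac)
                cen = new_frac.mean(axis=0)
                wrapped = cen - np.floor(cen)
                new_frac = new_frac + (wrapped - cen)
                dup = False
                for prev in frac_centroids:
                    d = wrapped - prev
                    d -= np.rint(d)
                    if np.linalg.norm(d @ A) < CLASH_DISTANCE:
                        dup = True
                        break
                if dup:
                    continue
                frac_centroids.append(wrapped)
                cart = new_frac @ A
                out.append(
                    Molecule(
                        atoms=[
                            replace(a, position=p)
                            for a, p in zip(mol.atoms, cart)
                        ],
                        bonds=list(mol.bonds),
                        rings=list(mol.rings),
                        name=f"{mol.name or 'mol'}@{mi}",
                    )
                )
        self._check_no_clashes(out)
        self._cell_cache = out
        return out

    def _check_no_clashes(self, mols: list[Molecule]) -> None:
        A = self.cell.vectors
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        ) @ A
        for ai in range(len(mols)):
            for bi in range(ai, len(mols)):
                xa = mols[ai].coords
                xb = mols[bi].coords
                for s in shifts:
                    if ai == bi and np.allclose(s, 0):
                        continue
                    d = np.linalg.norm(
                        xa[:, None, :] - (xb + s)[None, :, :], axis=-1
                    )
                    if d.min() < CLASH_DISTANCE:
                        raise ChemistryError(
                            f"symmetry-expanded molecules {ai} and {bi} clash "
                            f"(min distance {d.min():.2f} Å)"
                        )


# --------------------------------------------------------------------------
# bond / ring perception


def perceive_bonds(mol_atoms: list[Atom] | Molecule, tolerance: float = BOND_TOLERANCE,
                   name: str = "") -> Molecule:
    """Build the bond graph by the covalent-radius criterion and perceive rings.

    A bond i–j exists iff d(i,j) < r_cov(i) + r_cov(j) + ``tolerance``.
    Rings come from a minimum cycle basis (SSSR-like); a ring is flagged
    aromatic when it is planar (RMS out-of-plane < 0.1 Å), has 5–7 members,
    all members are C or N, and every member has ≤ 3 connections (sp²).
    """
    if isinstance(mol_atoms, Molecule):
        atoms = mol_atoms.atoms
        name = name or mol_atoms.name
    else:
        atoms = list(mol_atoms)
    if not atoms:
        raise ValueError("no atoms")
    coords = np.array([a.position for a in atoms])
    n = len(atoms)
    bonds: list[Bond] = []
    if n > 1:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        rc = np.array([a.covalent_radius for a in atoms])
        iu, ju = np.triu_indices(n, k=1)
        close = d[iu, ju] < CLASH_DISTANCE
        if close.any():
            k = int(np.argmax(close))
            raise ChemistryError(
                f"atoms {iu[k]} and {ju[k]} clash ({d[iu[k], ju[k]]:.2f} Å apart)"
            )
        cut = rc[:, None] + rc[None, :] + tolerance
        for i, j in zip(*np.where(np.triu(d < cut, k=1))):
            bonds.append(Bond(int(i), int(j)))
    mol = Molecule(atoms=atoms, bonds=bonds, name=name)
    mol.rings = _perceive_rings(mol)
    return mol


def _ring_planarity_rms(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    # smallest principal direction = ring normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return float(np.sqrt(np.mean((centered @ normal) ** 2)))


def _perceive_rings(mol: Molecule) -> list[Ring]:
    g = mol.bond_graph()
    rings: list[Ring] = []
    nbrs = mol.neighbor_map()
    for cycle in nx.minimum_cycle_basis(g):
        idx = tuple(sorted(cycle))
        coords = mol.coords[list(idx)]
        planar = len(idx) >= 3 and _ring_planarity_rms(coords) < PLANARITY_RMS
        elements = [mol.atoms[i].element for i in idx]
        sp2_like = all(len(nbrs[i]) <= 3 for i in idx)
        aromatic = (
            planar
            and 5 <= len(idx) <= 7
            and all(e in ("C", "N") for e in elements)
            and sp2_like
        )
        rings.append(Ring(indices=idx, aromatic=aromatic))
    return rings


# --------------------------------------------------------------------------
# force-field typing and charges


def _hybridization(mol: Molecule, i: int, nbrs: dict[int, list[int]]) -> int:
    """Crude hybridization from connection count (H counts as a connection)."""
    atom = mol.atoms[i]
    n = len(nbrs[i])
    if atom.element == "C":
        return {4: 3, 3: 2, 2: 1, 1: 1}.get(n, 3)
    if atom.element == "N":
        return {4: 3, 3: 3, 2: 2, 1: 1}.get(n, 3)
    if atom.element == "O":
        return 3 if n >= 2 else 2
    return 3


def assign_typing(mol: Molecule, charge_scheme: str = "gasteiger") -> Molecule:
    """Assign Dreiding-style atom types and partial charges in place.

    Types follow simple hybridization rules: ``C_3/C_2/C_1/C_R`` (R for
    aromatic-ring members), likewise N and O; hydrogens bonded to N/O become
    the hydrogen-bonding type ``H__HB``, all others ``H_``.

    ``charge_scheme``: ``"gasteiger"`` (iterative partial-equalization via
    RDKit, the default), ``"keep"`` (leave charges as found — used for
    synthetic fixtures that carry designed charges), or ``"zero"``.
    """
    nbrs = mol.neighbor_map()
    arom_atoms = {i for r in mol.aromatic_rings() for i in r.indices}
    supported = {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B"}
    for i, atom in enumerate(mol.atoms):
        el = atom.element
        if el not in supported:
            raise ChemistryError(f"unsupported element for Dreiding typing: {el!r}")
        if el == "H":
            heavy = [mol.atoms[j].element for j in nbrs[i]]
            atom.ff_type = "H__HB" if any(e in ("N", "O") for e in heavy) else "H_"
        elif el in ("C", "N", "O"):
            if i in arom_atoms:
                atom.ff_type = f"{el}_R"
            else:
                atom.ff_type = f"{el}_{_hybridization(mol, i, nbrs)}"
        else:
            atom.ff_type = f"{el}_3"
    if charge_scheme == "zero":
        for a in mol.atoms:
            a.charge = 0.0
    elif charge_scheme == "gasteiger":
        _gasteiger_charges(mol)
    elif charge_scheme != "keep":
        raise ValueError(f"unknown charge scheme {charge_scheme!r}")
    return mol


def to_rdkit(mol: Molecule):
    """Convert to an RDKit Mol (with 3D conformer).  Bond orders are taken
    from the bond list; perception quality therefore bounds chemistry quality."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401

    em = Chem.RWMol()
    for a in mol.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)  # our atom list is complete; no implicit H
        em.AddAtom(at)
    order_map = {
        "single": Chem.BondType.SINGLE,
        "double": Chem.BondType.DOUBLE,
        "triple": Chem.BondType.TRIPLE,
        "aromatic": Chem.BondType.SINGLE,
    }
    for b in mol.bonds:
        em.AddBond(b.i, b.j, order_map[b.order])
    m = em.GetMol()
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, tuple(float(x) for x in a.position))
    m.AddConformer(conf)
    return m


def from_rdkit(rdmol, name: str = "", conf_id: int = 0) -> Molecule:
    """Build a Molecule from an RDKit Mol with a 3D conformer."""
    conf = rdmol.GetConformer(conf_id)
    atoms = [
        Atom(
            element=a.GetSymbol(),
            position=np.array(conf.GetAtomPosition(a.GetIdx())),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = []
    for b in rdmol.GetBonds():
        bt = str(b.GetBondType())
        order = {"SINGLE": "single", "DOUBLE": "double", "TRIPLE": "triple",
                 "AROMATIC": "aromatic"}.get(bt, "single")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    mol = Molecule(atoms=atoms, bonds=bonds, name=name)
    mol.rings = _perceive_rings(mol)
    return mol


def _gasteiger_charges(mol: Molecule) -> None:
    from rdkit import Chem
    from rdkit.Chem import rdPartialCharges

    m = to_rdkit(mol)
    try:
        Chem.SanitizeMol(m)
        rdPartialCharges.ComputeGasteigerCharges(m)
        charges = [float(a.GetDoubleProp("_GasteigerCharge")) for a in m.GetAtoms()]
    except Exception as exc:  # valence model rejected → fall back, keep net charge
        log.warning("Gasteiger charge assignment failed (%s); charges set to 0", exc)
        charges = [0.0] * len(mol.atoms)
    if any(math.isnan(q) for q in charges):
        charges = [0.0 if math.isnan(q) else q for q in charges]
    for a, q in zip(mol.atoms, charges):
        a.charge = q


# --------------------------------------------------------------------------
# hydrogen-bond site inventory


@dataclass
class HBondInventory:
    """Donor/acceptor classification of one molecule.

    donors: (H index, heavy donor index) pairs — every H bonded to N or O.
    acceptors: heavy-atom indices with an available lone pair — every O, and
    every N carrying no hydrogen (pyridine-type sp² N; a protonated/pyrrolic
    N is donor-only).
    """

    donors: list[tuple[int, int]]
    acceptors: list[int]

    @property
    def donor_h(self) -> list[int]:
        return [h for h, _ in self.donors]

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_acceptors(self) -> int:
        return len(self.acceptors)


def classify_hbond_sites(mol: Molecule) -> HBondInventory:
    nbrs = mol.neighbor_map()
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            for j in nbrs[i]:
                if mol.atoms[j].element in ("N", "O"):
                    donors.append((i, j))
                    break
        elif atom.element == "O":
            acceptors.append(i)
        elif atom.element == "N":
            has_h = any(mol.atoms[j].element == "H" for j in nbrs[i])
            if not has_h:
                acceptors.append(i)
    return HBondInventory(donors=donors, acceptors=acceptors)


# --------------------------------------------------------------------------
# CIF I/O


def _cif_number(s: str) -> float:
    """Parse a CIF numeric value, stripping an s.u. suffix like 1.234(5)."""
    return float(re.sub(r"\(\d+\)$", "", s.strip()))


def read_cif(path, keep_major_occupancy: bool = False) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    Symmetry is taken from explicit xyz operation strings when present;
    otherwise from the Hermann–Mauguin symbol.  When both are present the xyz
    strings win (a warning is logged on conflict).  Atom sites are expanded
    through all operations, deduplicated on special positions, bonded with the
    covalent-radius rule under periodic boundary conditions, and reassembled
    into whole molecules.

    Sites with occupancy < 1 are rejected unless ``keep_major_occupancy`` is
    set, in which case only sites with occupancy ≥ 0.5 are kept.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    cell_vals = {}
    for key in ("a", "b", "c", "alpha", "beta", "gamma"):
        v = block.find_value(f"_cell_length_{key}") or block.find_value(
            f"_cell_angle_{key}"
        )
        if v is None:
            raise FormatError(f"CIF missing cell item _cell_*_{key}")
        cell_vals[key] = _cif_number(v)
    cell = UnitCell(**cell_vals)

    ops = _read_symmetry(block)

    labels, elements, fracs, charges = _read_atom_sites(block, keep_major_occupancy)
    if len(labels) == 0:
        raise FormatError("CIF missing atom site loop (_atom_site_*)")

    sg = (
        block.find_value("_symmetry_space_group_name_H-M")
        or block.find_value("_space_group_name_H-M_alt")
        or ("P 1" if len(ops) == 1 else "")
    )
    sg = gemmi.cif.as_string(sg) if sg else ""

    molecules = _reassemble_molecules(cell, ops, labels, elements, fracs, charges)
    xtal = CrystalStructure(
        cell=cell, ops=ops, asym_molecules=molecules, space_group_label=sg or "P 1"
    )
    return xtal


def _read_symmetry(block) -> list[SymmetryOp]:
    xyz_ops: list[SymmetryOp] = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        vals = [gemmi.cif.as_string(v) for v in col]
        if vals:
            xyz_ops = [SymmetryOp.from_xyz(v) for v in vals]
            break
    sg_name = block.find_value("_symmetry_space_group_name_H-M") or block.find_value(
        "_space_group_name_H-M_alt"
    )
    sg_ops: list[SymmetryOp] = []
    if sg_name:
        name = gemmi.cif.as_string(sg_name)
        sg = gemmi.find_spacegroup_by_name(name)
        if sg is not None:
            sg_ops = [
                SymmetryOp.from_xyz(op.triplet()) for op in sg.operations()
            ]
    if xyz_ops:
        if sg_ops and len(sg_ops) != len(xyz_ops):
            log.warning(
                "CIF symmetry xyz strings (%d ops) conflict with space-group "
                "symbol (%d ops); using xyz strings",
                len(xyz_ops),
                len(sg_ops),
            )
        return xyz_ops
    if sg_ops:
        return sg_ops
    raise FormatError(
        "CIF missing symmetry (no _symmetry_equiv_pos_as_xyz loop, no "
        "_space_group_symop_operation_xyz loop, no space-group symbol)"
    )


def _read_atom_sites(block, keep_major_occupancy: bool):
    table = block.find(
        "_atom_site_",
        ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy",
         "?charge"],
    )
    labels, elements, fracs, charges = [], [], [], []
    bad_occ = []
    for row in table:
        label = row[0]
        if row.has(1):
            el = re.match(r"[A-Za-z]+", row[1]).group(0)
        else:
            el = re.match(r"[A-Za-z]+", label).group(0)
        el = el[0].upper() + el[1:2].lower()
        if gemmi.Element(el).name == "X" and len(el) > 1:
            el = el[0]
        occ = _cif_number(row[5]) if row.has(5) and row[5] not in (".", "?") else 1.0
        if occ < 1.0 - 1e-9:
            if not keep_major_occupancy:
                bad_occ.append(label)
                continue
            if occ < 0.5:
                continue
        q = _cif_number(row[6]) if row.has(6) and row[6] not in (".", "?") else 0.0
        labels.append(label)
        elements.append(el)
        fracs.append([_cif_number(row[i]) for i in (2, 3, 4)])
        charges.append(q)
    if bad_occ:
        raise FormatError(
            "unresolved disorder: sites with occupancy < 1: " + ", ".join(bad_occ)
        )
    return labels, elements, np.array(fracs).reshape(-1, 3), np.array(charges)


def _reassemble_molecules(cell, ops, labels, elements, fracs, charges):
    """Expand sites through symmetry, bond under PBC, unwrap whole molecules."""
    A = cell.vectors
    all_frac, all_el, all_q, all_lab = [], [], [], []
    for op in ops:
        nf = op.apply(fracs)
        nf -= np.floor(nf)
        for k in range(len(nf)):
            dup = False
            for p in all_frac:
                d = nf[k] - p
                d -= np.rint(d)
                if np.linalg.norm(d @ A) < CLASH_DISTANCE:
                    dup = True  # special position
                    break
            if not dup:
                all_frac.append(nf[k])
                all_el.append(elements[k])
                all_q.append(charges[k])
                all_lab.append(labels[k])
    all_frac = np.array(all_frac)
    n = len(all_frac)

    # periodic bond graph with minimum-image shifts
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rc = np.array([covalent_radius(e) for e in all_el])
    for i in range(n):
        for j in range(i + 1, n):
            d = all_frac[j] - all_frac[i]
            shift = -np.rint(d)
            v = (d + shift) @ A
            if np.linalg.norm(v) < rc[i] + rc[j] + BOND_TOLERANCE:
                g.add_edge(i, j, shift=tuple(shift))

    molecules = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        pos_frac = {comp[0]: all_frac[comp[0]]}
        for u, v in nx.bfs_edges(g.subgraph(comp), comp[0]):
            shift = np.array(g[u][v]["shift"])
            if v in pos_frac:
                continue
            # shift stored for edge (min(i,j) -> max(i,j))
            if u < v:
                pos_frac[v] = pos_frac[u] + (all_frac[v] - all_frac[u]) + shift
            else:
                pos_frac[v] = pos_frac[u] + (all_frac[v] - all_frac[u]) - shift
        atoms = [
            Atom(
                element=all_el[i],
                position=pos_frac[i] @ A,
                charge=all_q[i],
                label=all_lab[i],
            )
            for i in comp
        ]
        mol = perceive_bonds(atoms)
        mol.name = f"mol{len(molecules)}"
        molecules.append(mol)

    # keep one representative per symmetry orbit: molecules congruent under an
    # op are the expanded images; the asymmetric unit is the orbit set
    return _select_asymmetric_unit(cell, ops, molecules)


def _select_asymmetric_unit(cell, ops, molecules):
    """Pick one molecule per symmetry orbit of the full-cell molecule list."""
    if len(ops) == 1:
        return molecules
    A = cell.vectors
    taken: list[Molecule] = []
    covered = [False] * len(molecules)
    cens = [cell.cart_to_frac(m.centroid()) for m in molecules]
    for i, mol in enumerate(molecules):
        if covered[i]:
            continue
        taken.append(mol)
        covered[i] = True
        for op in ops:
            img = op.apply(cens[i])
            for j in range(len(molecules)):
                if covered[j]:
                    continue
                d = img - cens[j]
                d -= np.rint(d)
                if np.linalg.norm(d @ A) < CLASH_DISTANCE:
                    covered[j] = True
    return taken


def write_cif(xtal: CrystalStructure, path, data_name: str = "cocryst") -> None:
    """Write a CrystalStructure as a standard small-molecule CIF.

    Fractional coordinates of the asymmetric unit are written with enough
    digits to round-trip below 1e-6 Å; partial charges go into the optional
    ``_atom_site_charge`` column, which :func:`read_cif` reads back.
    """
    cell = xtal.cell
    lines = [f"data_{data_name}"]
    for k, v in (("length_a", cell.a), ("length_b", cell.b), ("length_c", cell.c),
                 ("angle_alpha", cell.alpha), ("angle_beta", cell.beta),
                 ("angle_gamma", cell.gamma)):
        lines.append(f"_cell_{k}  {v:.9f}")
    lines.append(f"_symmetry_space_group_name_H-M  '{xtal.space_group_label}'")
    lines.append("loop_")
    lines.append("_symmetry_equiv_pos_as_xyz")
    for op in xtal.ops:
        lines.append(f"  '{op.to_xyz()}'")
    lines.append("loop_")
    for tag in ("label", "type_symbol", "fract_x", "fract_y", "fract_z",
                "occupancy", "charge"):
        lines.append(f"_atom_site_{tag}")
    counter: dict[str, int] = {}
    for mol in xtal.asym_molecules:
        frac = cell.cart_to_frac(mol.coords)
        for atom, f in zip(mol.atoms, frac):
            counter[atom.element] = counter.get(atom.element, 0) + 1
            label = atom.label or f"{atom.element}{counter[atom.element]}"
            lines.append(
                f"{label:8s} {atom.element:2s} "
                f"{f[0]:.9f} {f[1]:.9f} {f[2]:.9f} 1.0 {atom.charge:.9f}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# small-molecule file formats (SDF / MOL / MOL2) via RDKit


def read_molecule(path, name: str = "", embed_seed: int = 7) -> Molecule:
    """Read a molecule from MOL/SDF (V2000) or MOL2.

    If the file has no 3D coordinates, a single conformer is embedded with a
    fixed RNG seed so that descriptor evaluation is deterministic.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    path = str(path)
    if path.lower().endswith(".mol2"):
        rdmol = Chem.MolFromMol2File(path, removeHs=False)
    else:
        rdmol = Chem.MolFromMolFile(path, removeHs=False)
    if rdmol is None:
        raise FormatError(f"could not parse molecule file {path}")
    rdmol = Chem.AddHs(rdmol)
    if rdmol.GetNumConformers() == 0 or not rdmol.GetConformer().Is3D():
        params = AllChem.ETKDGv3()
        params.randomSeed = embed_seed
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise ChemistryError(f"conformer embedding failed for {path}")
    mol = from_rdkit(rdmol, name=name or path.rsplit("/", 1)[-1])
    return mol


def write_sdf(mol: Molecule, path) -> None:
    from rdkit import Chem

    m = to_rdkit(mol)
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        w.write(m)
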