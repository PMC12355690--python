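"""Crystal synthon energetics under a Dreiding-style nonbonded potential.

The model: a reference molecule interacts with every whole molecule whose
centroid lies within a cutoff (default 30 Å) of its own centroid.  Pair
energies decompose into

* van der Waals — Lennard-Jones 12-6, ``D0[(R0/r)^12 − 2(R0/r)^6]``,
* electrostatics — atomic monopoles with a distance-dependent dielectric,
  ``332.0637·qiqj/(ε0·r²)`` kcal/mol (ε(r) = ε0·r),
* hydrogen bonds — an explicit Lennard-Jones 12-10 term on
  donor–H···acceptor triples,
  ``D_hb[5(R_hb/r_DA)^12 − 6(R_hb/r_DA)^10]·cos⁴θ(D–H···A)``,
  active for r_DA < 4.5 Å and θ > 90°; it replaces the 12-6 term for the
  H···acceptor atom pair.

Lattice energy per reference molecule is the half-sum over its environment;
symmetry-equivalent molecule–molecule contacts are merged into *synthons* and
ranked by interaction strength, mirroring the per-contact tables produced by
crystal-particle analysis tools.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from cocryst.chemio import (
    CrystalStructure,
    HBondInventory,
    Molecule,
    classify_hbond_sites,
)

COULOMB_KCAL = 332.0637  # (e^2/Å) -> kcal/mol
KCAL_TO_KJ = 4.184


class ParameterError(KeyError):
    """Missing force-field parameters for an atom type."""


# --------------------------------------------------------------------------
# parameters


@dataclass
class ForceFieldParams:
    """Nonbonded parameter set (kcal/mol, Å).

    ``lj`` maps atom-type label -> (R0, D0) of the 12-6 potential written in
    well-depth form.  Combination rules are configurable; geometric mixing for
    both R0 and D0 is the default.
    """

    lj: dict[str, tuple[float, float]]
    d_hb: float = 4.0
    r_hb: float = 2.75
    hb_r_cut: float = 4.5
    hb_theta_min_deg: float = 90.0
    eps0: float = 1.0
    combine_r0: str = "geometric"
    combine_d0: str = "geometric"

    @classmethod
    def default(cls) -> "ForceFieldParams":
        path = resources.files("cocryst.data") / "dreiding.toml"
        return cls.from_file(path)

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        with open(str(path), "rb") as fh:
            raw = tomllib.load(fh)
        lj = {k: (float(v["r0"]), float(v["d0"])) for k, v in raw["lj"].items()}
        hb = raw.get("hbond", {})
        es = raw.get("electrostatics", {})
        comb = raw.get("combining", {})
        return cls(
            lj=lj,
            d_hb=float(hb.get("d_hb", 4.0)),
            r_hb=float(hb.get("r_hb", 2.75)),
            hb_r_cut=float(hb.get("r_cut", 4.5)),
            hb_theta_min_deg=float(hb.get("theta_min_deg", 90.0)),
            eps0=float(es.get("eps0", 1.0)),
            combine_r0=comb.get("r0", "geometric"),
            combine_d0=comb.get("d0", "geometric"),
        )

    def to_file(self, path) -> None:
        lines = ["[lj]"]
        for k, (r0, d0) in self.lj.items():
            lines.append(f"{k} = {{ r0 = {r0!r}, d0 = {d0!r} }}")
        lines += [
            "",
            "[hbond]",
            f"d_hb = {self.d_hb!r}",
            f"r_hb = {self.r_hb!r}",
            f"r_cut = {self.hb_r_cut!r}",
            f"theta_min_deg = {self.hb_theta_min_deg!r}",
            "",
            "[electrostatics]",
            f"eps0 = {self.eps0!r}",
            "",
            "[combining]",
            f'r0 = "{self.combine_r0}"',
            f'd0 = "{self.combine_d0}"',
        ]
        with open(str(path), "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def lookup(self, ff_type: str) -> tuple[float, float]:
        if ff_type in self.lj:
            return self.lj[ff_type]
        raise ParameterError(f"no Lennard-Jones parameters for atom type {ff_type!r}")

    def arrays(self, mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
        r0, d0 = [], []
        for a in mol.atoms:
            if a.ff_type is None:
                raise ParameterError(
                    f"atom {a.element} has no force-field type; run assign_typing first"
                )
            pr = self.lookup(a.ff_type)
            r0.append(pr[0])
            d0.append(pr[1])
        return np.array(r0), np.array(d0)


def _combine(x: np.ndarray, y: np.ndarray, rule: str) -> np.ndarray:
    if rule == "geometric":
        return np.sqrt(x[:, None] * y[None, :])
    if rule == "arithmetic":
        return 0.5 * (x[:, None] + y[None, :])
    raise ValueError(f"unknown combining rule {rule!r}")


# --------------------------------------------------------------------------
# pair energies


@dataclass
class EnergyTerms:
    e_vdw: float
    e_coul: float
    e_hb: float

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_coul + self.e_hb

    @property
    def e_polar(self) -> float:
        return self.e_coul + self.e_hb

    def __add__(self, other: "EnergyTerms") -> "EnergyTerms":
        return EnergyTerms(
            self.e_vdw + other.e_vdw,
            self.e_coul + other.e_coul,
            self.e_hb + other.e_hb,
        )

    def scaled(self, f: float) -> "EnergyTerms":
        return EnergyTerms(f * self.e_vdw, f * self.e_coul, f * self.e_hb)


def _hb_contacts(
    mol_d: Molecule,
    inv_d: HBondInventory,
    mol_a: Molecule,
    inv_a: HBondInventory,
    params: ForceFieldParams,
):
    """Active donor(mol_d)-H···acceptor(mol_a) triples with their 12-10 energy.

    Returns (list of (h_idx, acc_idx, energy)); h_idx indexes mol_d, acc_idx
    indexes mol_a.
    """
    out = []
    cos_min = math.cos(math.radians(params.hb_theta_min_deg))
    xa = mol_a.coords
    for h, d in inv_d.donors:
        ph = mol_d.atoms[h].position
        pd = mol_d.atoms[d].position
        for acc in inv_a.acceptors:
            pa = xa[acc]
            r_da = float(np.linalg.norm(pa - pd))
            if r_da >= params.hb_r_cut or r_da < 1e-6:
                continue
            v1 = pd - ph
            v2 = pa - ph
            n1 = np.linalg.norm(v1)
            n2 = np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            cos_t = float(v1 @ v2) / (n1 * n2)
            # theta = angle D-H...A; theta > theta_min <=> cos(theta) < cos(theta_min)
            if cos_t >= cos_min:
                continue
            x = params.r_hb / r_da
            e = params.d_hb * (5.0 * x**12 - 6.0 * x**10) * cos_t**4
            out.append((h, acc, e))
    return out


def pair_energy(
    mol_a: Molecule,
    mol_b: Molecule,
    params: ForceFieldParams,
    return_atom_terms: bool = False,
):
    """Intermolecular interaction energy between two molecules (kcal/mol).

    Returns :class:`EnergyTerms`; with ``return_atom_terms`` also a pair of
    per-atom attribution arrays (half of every pair term to each atom), whose
    sums each equal half the total.
    """
    xa, xb = mol_a.coords, mol_b.coords
    r = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    if r.min() < 1e-6:
        raise ValueError("pair_energy: molecules overlap (zero interatomic distance)")
    r0a, d0a = params.arrays(mol_a)
    r0b, d0b = params.arrays(mol_b)
    R0 = _combine(r0a, r0b, params.combine_r0)
    D0 = _combine(d0a, d0b, params.combine_d0)

    inv_a_sites = classify_hbond_sites(mol_a)
    inv_b_sites = classify_hbond_sites(mol_b)
    hb_ab = _hb_contacts(mol_a, inv_a_sites, mol_b, inv_b_sites, params)
    hb_ba = _hb_contacts(mol_b, inv_b_sites, mol_a, inv_a_sites, params)

    # the explicit H-bond term replaces the 12-6 term for the H...A atom pair
    lj_mask = np.ones_like(r, dtype=bool)
    for h, acc, _ in hb_ab:
        lj_mask[h, acc] = False
    for h, acc, _ in hb_ba:
        lj_mask[acc, h] = False

    x6 = (R0 / r) ** 6
    lj = D0 * (x6 * x6 - 2.0 * x6) * lj_mask
    qa, qb = mol_a.charges, mol_b.charges
    coul = COULOMB_KCAL * qa[:, None] * qb[None, :] / (params.eps0 * r * r)

    e_vdw = float(lj.sum())
    e_coul = float(coul.sum())
    e_hb = float(sum(e for *_, e in hb_ab) + sum(e for *_, e in hb_ba))
    terms = EnergyTerms(e_vdw, e_coul, e_hb)
    if not return_atom_terms:
        return terms

    per = lj + coul
    atom_a = 0.5 * per.sum(axis=1)
    atom_b = 0.5 * per.sum(axis=0)
    for h, acc, e in hb_ab:
        atom_a[h] += 0.5 * e
        atom_b[acc] += 0.5 * e
    for h, acc, e in hb_ba:
        atom_b[h] += 0.5 * e
        atom_a[acc] += 0.5 * e
    return terms, atom_a, atom_b


# --------------------------------------------------------------------------
# environment construction


@dataclass
class EnvPartner:
    """A whole molecule image in the environment of a reference molecule."""

    molecule: Molecule
    cell_index: int          # index into unit_cell_molecules()
    shift: tuple[int, int, int]
    centroid_distance: float


def build_environment(
    xtal: CrystalStructure, ref: int, cutoff: float = 30.0
) -> list[EnvPartner]:
    """Whole molecule images whose centroid is within ``cutoff`` of molecule
    ``ref`` of the expanded unit cell.

    The supercell extent is derived from the axis interplanar spacings with a
    one-cell safety margin, which guarantees completeness; doubling the extent
    changes nothing.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cell_mols = xtal.unit_cell_molecules()
    if ref < 0 or ref >= len(cell_mols):
        raise IndexError(f"reference molecule index {ref} out of range")
    A = xtal.cell.vectors
    spac = xtal.cell.axis_spacings()
    # molecules can extend beyond their centroid's cell; pad by the largest
    # centroid offset so every in-range image is enumerated
    cens = np.array([m.centroid() for m in cell_mols])
    pad = float(np.max(np.linalg.norm(cens - cens[ref], axis=1), initial=0.0))
    extents = np.ceil((cutoff + pad) / spac).astype(int) + 1
    ref_cen = cens[ref]

    shifts = np.array(
        [
            (i, j, k)
            for i in range(-extents[0], extents[0] + 1)
            for j in range(-extents[1], extents[1] + 1)
            for k in range(-extents[2], extents[2] + 1)
        ]
    )
    cart_shifts = shifts @ A
    partners = []
    for j, mol in enumerate(cell_mols):
        d = np.linalg.norm(cens[j] + cart_shifts - ref_cen, axis=1)
        for s_idx in np.where(d <= cutoff)[0]:
            shift = tuple(int(x) for x in shifts[s_idx])
            if j == ref and shift == (0, 0, 0):
                continue
            partners.append(
                EnvPartner(
                    molecule=mol.translated(cart_shifts[s_idx]),
                    cell_index=j,
                    shift=shift,
                    centroid_distance=float(d[s_idx]),
                )
            )
    partners.sort(key=lambda p: (p.centroid_distance, p.cell_index, p.shift))
    return partners


# --------------------------------------------------------------------------
# interaction classification


def classify_interaction(
    mol_a: Molecule,
    mol_b: Molecule,
    hb_dist_max: float = 2.5,
    hb_angle_min_deg: float = 120.0,
    pipi_centroid_max: float = 4.0,
    stack_centroid_max: float = 6.5,
    stack_angle_max_deg: float = 20.0,
    pipi_offset_max: float = 1.5,
) -> str:
    """Label a molecule–molecule contact.

    Precedence H-bond > π–π stacking > offset stacking > vdW/other:

    * H-bond — a donor-H···acceptor contact with r(H···A) < 2.5 Å and
      D–H···A angle > 120°;
    * π–π stacking — two aromatic ring centroids < 4.0 Å apart, interplanar
      angle < 20°, lateral offset < 1.5 Å;
    * offset stacking — centroids < 6.5 Å, angle < 20°, offset ≥ 1.5 Å.
    """
    if _has_hbond_contact(mol_a, mol_b, hb_dist_max, hb_angle_min_deg):
        return "H-bond"
    label = "vdW/other"
    best = None
    for ca, na in _ring_frames(mol_a):
        for cb, nb in _ring_frames(mol_b):
            v = cb - ca
            dist = float(np.linalg.norm(v))
            if dist > stack_centroid_max or dist < 1e-6:
                continue
            cosang = abs(float(na @ nb))
            angle = math.degrees(math.acos(min(1.0, cosang)))
            if angle >= stack_angle_max_deg:
                continue
            offset = float(np.linalg.norm(v - (v @ na) * na))
            key = (dist, offset)
            if best is None or key < best:
                best = key
                label = (
                    "pi-pi stacking"
                    if dist < pipi_centroid_max and offset < pipi_offset_max
                    else "offset stacking"
                )
    return label


def _has_hbond_contact(mol_a, mol_b, dist_max, angle_min_deg) -> bool:
    for md, ma in ((mol_a, mol_b), (mol_b, mol_a)):
        inv_d = classify_hbond_sites(md)
        inv_a = classify_hbond_sites(ma)
        xa = ma.coords
        for h, d in inv_d.donors:
            ph = md.atoms[h].position
            pd = md.atoms[d].position
            for acc in inv_a.acceptors:
                pa = xa[acc]
                if np.linalg.norm(pa - ph) >= dist_max:
                    continue
                v1 = pd - ph
                v2 = pa - ph
                cos_t = float(v1 @ v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))
                if angle > angle_min_deg:
                    return True
    return False


def _ring_frames(mol: Molecule):
    """(centroid, unit normal) of every aromatic ring."""
    frames = []
    for ring in mol.aromatic_rings():
        coords = mol.coords[list(ring.indices)]
        cen = coords.mean(axis=0)
        centered = coords - cen
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        frames.append((cen, vt[-1]))
    return frames


# --------------------------------------------------------------------------
# lattice energy, synthons


@dataclass
class InteractionPair:
    ref_index: int
    partner: EnvPartner
    terms: EnergyTerms
    type_label: str

    @property
    def e_total(self) -> float:
        return self.terms.e_total

    @property
    def centroid_distance(self) -> float:
        return self.partner.centroid_distance


@dataclass
class Synthon:
    """A symmetry-merged molecule–molecule contact.

    ``multiplicity`` counts ordered (reference, partner) pairs across all
    reference molecules of the cell; ``contribution`` = multiplicity·E/2 is
    the amount this synthon adds to the total lattice energy.
    """

    rank: int
    type_label: str
    centroid_distance: float
    terms: EnergyTerms
    multiplicity: int
    members: list[InteractionPair]

    @property
    def e_total(self) -> float:
        return self.terms.e_total

    @property
    def contribution(self) -> float:
        return 0.5 * self.multiplicity * self.terms.e_total


@dataclass
class SynthonRanking:
    synthons: list[Synthon]
    e_lattice: float  # total over the reference set, kcal/mol

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.synthons:
            rows.append(
                {
                    "rank": s.rank,
                    "type": s.type_label,
                    "centroid_distance_A": s.centroid_distance,
                    "e_total_kcal": s.e_total,
                    "e_vdw_kcal": s.terms.e_vdw,
                    "e_coul_kcal": s.terms.e_coul,
                    "e_hb_kcal": s.terms.e_hb,
                    "multiplicity": s.multiplicity,
                    "percent_of_lattice": 100.0 * s.contribution / self.e_lattice
                    if self.e_lattice
                    else 0.0,
                }
            )
        return pd.DataFrame(rows)


class LatticeModel:
    """Caches environments and pair energies of a crystal for reuse across
    lattice-energy, synthon, attachment-energy and decomposition queries."""

    def __init__(
        self,
        xtal: CrystalStructure,
        params: ForceFieldParams | None = None,
        cutoff: float = 30.0,
    ):
        self.xtal = xtal
        self.params = params or ForceFieldParams.default()
        self.cutoff = cutoff
        self.cell_molecules = xtal.unit_cell_molecules()
        self.n_ref = len(self.cell_molecules)
        self._pairs: dict[int, list[InteractionPair]] = {}

    def pairs(self, ref: int) -> list[InteractionPair]:
        if ref not in self._pairs:
            env = build_environment(self.xtal, ref, self.cutoff)
            ref_mol = self.cell_molecules[ref]
            out = []
            for p in env:
                terms = pair_energy(ref_mol, p.molecule, self.params)
                label = classify_interaction(ref_mol, p.molecule)
                out.append(InteractionPair(ref, p, terms, label))
            self._pairs[ref] = out
        return self._pairs[ref]

    def molecule_energy(self, ref: int) -> float:
        return 0.5 * sum(p.e_total for p in self.pairs(ref))

    def molecule_terms(self, ref: int) -> EnergyTerms:
        tot = EnergyTerms(0.0, 0.0, 0.0)
        for p in self.pairs(ref):
            tot = tot + p.terms
        return tot.scaled(0.5)

    def total_energy(self) -> float:
        return sum(self.molecule_energy(i) for i in range(self.n_ref))


def lattice_energy(
    xtal: CrystalStructure,
    params: ForceFieldParams | None = None,
    cutoff: float = 30.0,
    check_convergence: bool = False,
    convergence_step: float = 10.0,
    convergence_tol: float = 0.1,
):
    """Lattice (packing) energy per cell molecule and total (kcal/mol).

    Returns ``(per_molecule, total, converged)``.  ``converged`` is None when
    the check is skipped, else True iff extending the cutoff by
    ``convergence_step`` Å changes the total by less than ``convergence_tol``.
    """
    model = LatticeModel(xtal, params, cutoff)
    per = [model.molecule_energy(i) for i in range(model.n_ref)]
    total = float(sum(per))
    converged = None
    if check_convergence:
        wide = LatticeModel(xtal, params, cutoff + convergence_step)
        converged = abs(wide.total_energy() - total) < convergence_tol
    return per, total, converged


def rank_synthons(
    xtal: CrystalStructure,
    params: ForceFieldParams | None = None,
    cutoff: float = 30.0,
    energy_floor: float = 1e-4,
    model: LatticeModel | None = None,
) -> SynthonRanking:
    """Merge symmetry-equivalent contacts and rank by interaction strength.

    Contacts are grouped when their total energies agree within 1e-6 kcal/mol,
    their centroid distances within 1e-4 Å and they carry the same type label
    (symmetry-equivalent contacts satisfy all three).  Sorting: |E| descending,
    then centroid distance ascending, then partner id.  Contacts weaker than
    ``energy_floor`` are dropped from the listing (they still count toward the
    lattice energy).
    """
    model = model or LatticeModel(xtal, params, cutoff)
    all_pairs: list[InteractionPair] = []
    for ref in range(model.n_ref):
        all_pairs.extend(model.pairs(ref))
    e_lattice = model.total_energy()

    groups: list[list[InteractionPair]] = []
    ordered = sorted(
        all_pairs,
        key=lambda p: (
            -abs(p.e_total),
            p.centroid_distance,
            p.partner.cell_index,
            p.partner.shift,
        ),
    )
    for p in ordered:
        placed = False
        for g in groups:
            q = g[0]
            if (
                q.type_label == p.type_label
                and abs(q.e_total - p.e_total) < 1e-6
                and abs(q.centroid_distance - p.centroid_distance) < 1e-4
            ):
                g.append(p)
                placed = True
                break
        if not placed:
            groups.append([p])

    synthons = []
    for g in groups:
        if abs(g[0].e_total) < energy_floor:
            continue
        synthons.append(
            Synthon(
                rank=0,
                type_label=g[0].type_label,
                centroid_distance=g[0].centroid_distance,
                terms=g[0].terms,
                multiplicity=len(g),
                members=g,
            )
        )
    synthons.sort(
        key=lambda s: (-abs(s.e_total), s.centroid_distance, s.members[0].partner.cell_index)
    )
    for i, s in enumerate(synthons):
        s.rank = i + 1
    return SynthonRanking(synthons=synthons, e_lattice=e_lattice)


# --------------------------------------------------------------------------
# aggregation (per interaction class) and per-group decomposition


_STACKING_ALIASES = {
    "pi-pi stacking",
    "offset stacking",
    "stacking",
}


def _normalize_type(label: str) -> str:
    t = str(label).strip().replace("π–π", "pi-pi").replace("π-π", "pi-pi")
    t = t.replace("π", "pi").replace("–", "-")
    return t


def interaction_class(label: str) -> str:
    t = _normalize_type(label)
    if t.lower().startswith("h-bond") or t.lower().startswith("hbond"):
        return "H-bond"
    if t in _STACKING_ALIASES:
        return "stacking"
    return "other"


def aggregate_by_type(table) -> pd.DataFrame:
    """Aggregate synthon energies by interaction class.

    Accepts a :class:`SynthonRanking` or any DataFrame with columns ``type``,
    an energy column (``e_total_kcal`` or ``energy_kcal``) and optionally
    ``percent_of_lattice``.  Returns one row per class (H-bond / stacking /
    other) plus a ``total`` row, with the summed |E| (kcal/mol) and summed
    percent contributions.
    """
    if isinstance(table, SynthonRanking):
        df = table.to_frame()
    else:
        df = pd.DataFrame(table).copy()
    ecol = next(
        (c for c in ("e_total_kcal", "energy_kcal", "energy") if c in df.columns),
        None,
    )
    if df.empty or ecol is None:
        return pd.DataFrame(
            [{"class": "total", "energy_abs_kcal": 0.0, "percent_of_lattice": 0.0}]
        )
    df["class"] = df["type"].map(interaction_class)
    if "percent_of_lattice" not in df.columns:
        df["percent_of_lattice"] = np.nan
    rows = []
    for cls, sub in df.groupby("class", sort=False):
        rows.append(
            {
                "class": cls,
                "energy_abs_kcal": float(sub[ecol].abs().sum()),
                "percent_of_lattice": float(sub["percent_of_lattice"].sum()),
            }
        )
    rows.append(
        {
            "class": "total",
            "energy_abs_kcal": float(df[ecol].abs().sum()),
            "percent_of_lattice": float(df["percent_of_lattice"].sum()),
        }
    )
    return pd.DataFrame(rows)


def group_decomposition(
    xtal: CrystalStructure,
    params: ForceFieldParams | None = None,
    cutoff: float = 30.0,
    grouping=None,
    model: LatticeModel | None = None,
) -> pd.DataFrame:
    """Decompose the lattice energy into functional-group contributions.

    ``grouping`` maps atoms to group names: either a callable
    ``f(molecule, atom_index) -> str`` or a list (one entry per cell molecule)
    of per-atom group-name lists.  Every pair term is attributed half to each
    participating atom's group; group sums add up to the lattice energy
    exactly.  Atoms mapped to None raise an error listing them.
    """
    model = model or LatticeModel(xtal, params, cutoff)
    if grouping is None:
        grouping = lambda mol, i: "all"  # noqa: E731
    if callable(grouping):
        gfun = grouping
    else:
        tables = grouping
        gfun = lambda mol, i, _t=tables: _t[model.cell_molecules.index(mol)][i]  # noqa: E731

    totals: dict[str, float] = {}
    unassigned = []
    for ref in range(model.n_ref):
        ref_mol = model.cell_molecules[ref]
        names = [gfun(ref_mol, i) for i in range(len(ref_mol.atoms))]
        for i, nm in enumerate(names):
            if nm is None:
                unassigned.append((ref, i))
        if unassigned:
            raise ValueError(f"atoms without a functional group: {unassigned}")
        for p in model.pairs(ref):
            _, atom_a, _ = pair_energy(
                ref_mol, p.partner.molecule, model.params, return_atom_terms=True
            )
            # atom_a already carries the reference-side half of every pair
            # term; summed over all reference molecules this reproduces the
            # total lattice energy exactly
            for i, nm in enumerate(names):
                totals[nm] = totals.get(nm, 0.0) + float(atom_a[i])
    df = pd.DataFrame(
        [{"group": k, "energy_kcal": v} for k, v in sorted(totals.items())]
    )
    return df
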