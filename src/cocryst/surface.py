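"""Facet termination analysis: slabs, vdW height maps, surface chemistry.

A facet (hkl) is modelled as a slab of whole molecules cut by a plane of the
(hkl) family.  The cutting level within one d-spacing (the *termination
offset*) is either supplied or chosen automatically as the level that
minimizes the interaction energy crossing the plane (a proxy for the most
stable termination); ties are resolved toward the smoother surface.

The exposed surface is the upper envelope of the atomic van der Waals
spheres, sampled on a regular in-plane grid.  Rugosity is the RMS deviation
of that height field from its average plane.  Surface chemistry is reported
as counts per projected Å²: hydrogen-bond donor H atoms, acceptor heavy
atoms, and aromatic bonds lying within an exposure depth of the local top
surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cocryst.chemio import CrystalStructure, Molecule, classify_hbond_sites
from cocryst.energy import ForceFieldParams, KCAL_TO_KJ, LatticeModel
from cocryst.morphology import FacetFamily, attachment_energy, normalize_hkl


# --------------------------------------------------------------------------
# lattice geometry helpers


def plane_lattice_basis(xtal: CrystalStructure, hkl, search: int = 4):
    """(A1, A2, A3): two shortest independent lattice vectors lying in the
    (hkl) plane and one lattice vector advancing exactly one d-spacing
    (h·u + k·v + l·w = 1).  Cartesian Å."""
    h, k, l = normalize_hkl(hkl)
    A = xtal.cell.vectors
    in_plane, step = [], []
    for u in itertools.product(range(-search, search + 1), repeat=3):
        if u == (0, 0, 0):
            continue
        dot = h * u[0] + k * u[1] + l * u[2]
        v = np.array(u) @ A
        if dot == 0:
            in_plane.append((np.linalg.norm(v), u, v))
        elif dot == 1:
            step.append((np.linalg.norm(v), u, v))
    if not step:
        raise ValueError(f"no lattice step vector found for {hkl} (search={search})")
    in_plane.sort(key=lambda t: t[0])
    a1 = in_plane[0][2]
    a2 = None
    for _, _, v in in_plane[1:]:
        if np.linalg.norm(np.cross(a1, v)) > 1e-6 * np.linalg.norm(a1) * np.linalg.norm(v):
            a2 = v
            break
    if a2 is None:
        raise ValueError(f"no independent in-plane lattice vector for {hkl}")
    step.sort(key=lambda t: t[0])
    return a1, a2, step[0][2]


# --------------------------------------------------------------------------
# slab


@dataclass
class Slab:
    """Whole-molecule termination slab of one (hkl) facet.

    Heights are Cartesian distances along the outward unit normal; the cut
    plane sits at ``cut_height`` and molecules with centroid height in
    (cut_height − thickness, cut_height] are retained over a
    ``patch=(px, py)`` surface supercell (plus a one-cell margin for periodic
    coverage of the map)."""

    hkl: tuple[int, int, int]
    termination_offset: float
    molecules: list[Molecule]          # patch + margin images
    normal: np.ndarray
    a1: np.ndarray                     # in-plane surface cell vectors
    a2: np.ndarray
    patch: tuple[int, int]
    cut_height: float
    thickness: float
    d_hkl: float
    in_patch: list[bool] = field(default_factory=list)  # per molecule

    @property
    def surface_mesh_area(self) -> float:
        return float(np.linalg.norm(np.cross(self.a1, self.a2))) * self.patch[0] * self.patch[1]

    def inplane_frame(self):
        e1 = self.a1 / np.linalg.norm(self.a1)
        e2 = np.cross(self.normal, e1)
        return e1, e2

    def atom_table(self):
        """(positions (N,3), heights (N,), inplane (N,2), molecule index)."""
        pos, molidx = [], []
        for mi, mol in enumerate(self.molecules):
            pos.append(mol.coords)
            molidx.extend([mi] * len(mol.atoms))
        pos = np.vstack(pos)
        e1, e2 = self.inplane_frame()
        heights = pos @ self.normal
        inplane = np.stack([pos @ e1, pos @ e2], axis=1)
        return pos, heights, inplane, np.array(molidx)


def _image_heights(model: LatticeModel, n_hat: np.ndarray, d: float):
    """Centroid heights (mod d) of the unit-cell molecules."""
    return np.array(
        [m.centroid() @ n_hat for m in model.cell_molecules]
    ) % d


def crossing_energy(model: LatticeModel, hkl, offset: float) -> float:
    """Total |pair energy| crossing the (hkl) plane family cut at ``offset``
    (per unit cell, kcal/mol).  Piecewise constant in the offset."""
    hkl = normalize_hkl(hkl)
    n_hat = model.xtal.cell.plane_normal(hkl)
    d = model.xtal.cell.d_spacing(hkl)
    total = 0.0
    for ref in range(model.n_ref):
        a = model.cell_molecules[ref].centroid() @ n_hat
        for p in model.pairs(ref):
            b = p.partner.molecule.centroid() @ n_hat
            planes = math.floor((b - offset) / d) - math.floor((a - offset) / d)
            total += 0.5 * abs(p.e_total) * abs(planes)
    return total


def candidate_offsets(model: LatticeModel, hkl) -> list[float]:
    """Midpoints between consecutive centroid levels within one d-spacing —
    one representative per constant-crossing-energy plateau."""
    hkl = normalize_hkl(hkl)
    n_hat = model.xtal.cell.plane_normal(hkl)
    d = model.xtal.cell.d_spacing(hkl)
    levels = np.sort(np.unique(np.round(_image_heights(model, n_hat, d), 6)))
    cands = []
    for i in range(len(levels)):
        nxt = levels[(i + 1) % len(levels)] + (d if i + 1 == len(levels) else 0.0)
        cands.append(((levels[i] + nxt) / 2.0) % d)
    return sorted(set(cands))


def cut_slab(
    xtal: CrystalStructure,
    hkl,
    termination_offset: float | None = None,
    thickness: float | None = None,
    patch: tuple[int, int] = (2, 2),
    params: ForceFieldParams | None = None,
    cutoff: float = 30.0,
    model: LatticeModel | None = None,
    grid_spacing: float = 0.25,
) -> Slab:
    """Cut a whole-molecule slab exposing the (hkl) facet.

    With no ``termination_offset``, symmetry-distinct candidate offsets are
    enumerated and the one minimizing the plane-crossing energy is selected
    (ties → smaller rugosity, then smaller offset).
    """
    hkl = normalize_hkl(hkl)
    n_hat = xtal.cell.plane_normal(hkl)
    d = xtal.cell.d_spacing(hkl)
    thickness = thickness if thickness is not None else max(2.0 * d, 8.0)

    if termination_offset is None:
        model = model or LatticeModel(xtal, params, cutoff)
        cands = candidate_offsets(model, hkl)
        scored = [(crossing_energy(model, hkl, o), o) for o in cands]
        emin = min(s for s, _ in scored)
        tied = sorted(o for s, o in scored if s < emin + 1e-9)
        if len(tied) > 1:
            rug = []
            for o in tied:
                slab = _build_slab(xtal, hkl, n_hat, d, o, thickness, patch)
                rug.append((topology_map(slab, grid_spacing).rugosity, o))
            rug.sort()
            offset = rug[0][1]
        else:
            offset = tied[0]
    else:
        offset = float(termination_offset) % d
    return _build_slab(xtal, hkl, n_hat, d, offset, thickness, patch)


def _build_slab(xtal, hkl, n_hat, d, offset, thickness, patch) -> Slab:
    a1, a2, a3 = plane_lattice_basis(xtal, hkl)
    cell_mols = xtal.unit_cell_molecules()
    if not cell_mols:
        raise ValueError("empty crystal")
    px, py = patch
    # cut level: highest plane of the family at `offset` below ~one cell
    heights0 = np.array([m.centroid() @ n_hat for m in cell_mols])
    cut = offset + d * math.ceil((heights0.max() - offset) / d)

    n_layers = math.ceil(thickness / d) + 1
    mols: list[Molecule] = []
    in_patch: list[bool] = []
    e1 = a1 / np.linalg.norm(a1)
    e2 = np.cross(n_hat, e1)
    M = np.array([[a1 @ e1, a2 @ e1], [a1 @ e2, a2 @ e2]])
    Minv = np.linalg.inv(M)
    for kk in range(-n_layers - 1, 2):
        base = kk * a3
        for mol in cell_mols:
            h = mol.centroid() @ n_hat + kk * d
            if not (cut - thickness < h <= cut):
                continue
            # in-plane offset of this layer's origin
            for i in range(-1, px + 1):
                for j in range(-1, py + 1):
                    shift = base + i * a1 + j * a2
                    cen = mol.centroid() + shift
                    uv = Minv @ np.array([cen @ e1, cen @ e2])
                    # keep patch plus one-cell margin
                    if -1.0 <= uv[0] < px + 1.0 and -1.0 <= uv[1] < py + 1.0:
                        mols.append(mol.translated(shift))
                        in_patch.append(
                            0.0 <= uv[0] < px and 0.0 <= uv[1] < py
                        )
    if not mols:
        raise ValueError(f"slab for {hkl} is empty")
    return Slab(
        hkl=hkl,
        termination_offset=offset,
        molecules=mols,
        normal=n_hat,
        a1=a1,
        a2=a2,
        patch=patch,
        cut_height=cut,
        thickness=thickness,
        d_hkl=d,
        in_patch=in_patch,
    )


# --------------------------------------------------------------------------
# topology / rugosity


@dataclass
class TopologyMap:
    grid_u: np.ndarray        # node coordinates along e1 (Å)
    grid_v: np.ndarray
    height: np.ndarray        # relative to the average plane (nu, nv)
    height_abs: np.ndarray    # absolute height along the normal
    rugosity: float


def topology_map(slab: Slab, grid_spacing: float = 0.25) -> TopologyMap:
    """Upper vdW-envelope height field over the slab patch.

    height(x, y) = max over atoms of (atom height + vertical extent of its vdW
    sphere at (x, y)), relative to the mean; rugosity is the RMS.  Grid nodes
    not covered by any sphere (holes) take the minimum covered height.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if not slab.molecules:
        raise ValueError("empty slab")
    pos, heights, inplane, _ = slab.atom_table()
    radii = np.concatenate(
        [[a.vdw_radius for a in m.atoms] for m in slab.molecules]
    )
    px, py = slab.patch
    e1, e2 = slab.inplane_frame()
    # patch parallelogram corners in the (e1, e2) frame
    corners = []
    for i in (0, px):
        for j in (0, py):
            c = i * slab.a1 + j * slab.a2
            corners.append([c @ e1, c @ e2])
    corners = np.array(corners)
    u0, v0 = corners.min(axis=0)
    u1, v1 = corners.max(axis=0)
    nu = max(8, int(round((u1 - u0) / grid_spacing)))
    nv = max(8, int(round((v1 - v0) / grid_spacing)))
    us = u0 + (np.arange(nu) + 0.5) * (u1 - u0) / nu
    vs = v0 + (np.arange(nv) + 0.5) * (v1 - v0) / nv
    UU, VV = np.meshgrid(us, vs, indexing="ij")
    nodes = np.stack([UU.ravel(), VV.ravel()], axis=1)

    hmap = np.full(len(nodes), -np.inf)
    for a in range(len(pos)):
        du = nodes[:, 0] - inplane[a, 0]
        dv = nodes[:, 1] - inplane[a, 1]
        rho2 = du * du + dv * dv
        mask = rho2 < radii[a] ** 2
        if not mask.any():
            continue
        cand = heights[a] + np.sqrt(radii[a] ** 2 - rho2[mask])
        np.maximum.at(hmap, np.where(mask)[0], cand)
    covered = np.isfinite(hmap)
    if not covered.any():
        raise ValueError("no atom covers the surface patch")
    hmap[~covered] = hmap[covered].min()
    hmap = hmap.reshape(nu, nv)
    mean = float(hmap.mean())
    rel = hmap - mean
    return TopologyMap(
        grid_u=us,
        grid_v=vs,
        height=rel,
        height_abs=hmap,
        rugosity=float(np.sqrt(np.mean(rel**2))),
    )


# --------------------------------------------------------------------------
# surface chemistry


@dataclass
class SurfaceChemistry:
    hkl: tuple[int, int, int]
    hbd_density: float       # donor H per projected Å²
    hba_density: float       # acceptor heavy atoms per projected Å²
    aromatic_density: float  # aromatic bonds per projected Å²
    exposure_depth: float
    rugosity: float
    counts: dict = field(default_factory=dict)
    area: float = 0.0


def bond_densities(
    slab: Slab,
    exposure_depth: float = 3.0,
    grid_spacing: float = 0.25,
    topo: TopologyMap | None = None,
) -> SurfaceChemistry:
    """HBD/HBA/aromatic-bond counts per projected area of the slab patch.

    An atom is *exposed* when its vdW-sphere top reaches within
    ``exposure_depth`` of the local top surface; an aromatic bond counts when
    either end is exposed.  Only molecules whose centroid falls inside the
    patch proper (margin images excluded) are counted, so densities are
    intensive in the patch size.
    """
    if exposure_depth <= 0:
        raise ValueError("exposure_depth must be positive")
    topo = topo or topology_map(slab, grid_spacing)
    pos, heights, inplane, molidx = slab.atom_table()
    radii = np.concatenate(
        [[a.vdw_radius for a in m.atoms] for m in slab.molecules]
    )
    us, vs = topo.grid_u, topo.grid_v
    iu = np.clip(np.searchsorted(us, inplane[:, 0]) - 0, 0, len(us) - 1)
    iv = np.clip(np.searchsorted(vs, inplane[:, 1]) - 0, 0, len(vs) - 1)
    local_top = topo.height_abs[iu, iv]
    exposed = heights + radii >= local_top - exposure_depth

    n_don = n_acc = n_arom = 0
    offset = 0
    for mi, mol in enumerate(slab.molecules):
        n = len(mol.atoms)
        if slab.in_patch[mi]:
            exp = exposed[offset : offset + n]
            inv = classify_hbond_sites(mol)
            n_don += sum(1 for h, _ in inv.donors if exp[h])
            n_acc += sum(1 for a in inv.acceptors if exp[a])
            n_arom += sum(1 for i, j in mol.aromatic_bonds() if exp[i] or exp[j])
        offset += n
    area = slab.surface_mesh_area
    return SurfaceChemistry(
        hkl=slab.hkl,
        hbd_density=n_don / area,
        hba_density=n_acc / area,
        aromatic_density=n_arom / area,
        exposure_depth=exposure_depth,
        rugosity=topo.rugosity,
        counts={"donors": n_don, "acceptors": n_acc, "aromatic_bonds": n_arom},
        area=area,
    )


# --------------------------------------------------------------------------
# facet report


def surface_report(
    xtal: CrystalStructure,
    facets,
    params: ForceFieldParams | None = None,
    cutoff: float = 30.0,
    exposure_depth: float = 3.0,
    grid_spacing: float = 0.25,
    patch: tuple[int, int] = (2, 2),
    observed_order: list | None = None,
    model: LatticeModel | None = None,
) -> pd.DataFrame:
    """Per-facet surface properties table.

    ``facets`` is a list of (hkl) triples or :class:`FacetFamily`.  Columns
    mirror the facet-characterization summary: attachment-energy polar and
    nonpolar contributions (kJ/mol), donor/acceptor/aromatic densities
    (counts/Å²) and rugosity (Å).  When ``observed_order`` lists the facets of
    an experimental morphology, rows are ranked in that order; otherwise by
    |E_att| descending.
    """
    model = model or LatticeModel(xtal, params, cutoff)
    rows = []
    for f in facets:
        fam = (
            f
            if isinstance(f, FacetFamily)
            else attachment_energy(xtal, hkl=f, cutoff=cutoff, model=model)
        )
        slab = cut_slab(
            xtal, fam.hkl, patch=patch, cutoff=cutoff, model=model,
            grid_spacing=grid_spacing,
        )
        topo = topology_map(slab, grid_spacing)
        chem = bond_densities(slab, exposure_depth, grid_spacing, topo)
        rows.append(
            {
                "hkl": fam.hkl,
                "d_spacing_A": fam.d_spacing,
                "e_att_kcal": fam.e_att,
                "e_att_kj": fam.e_att * KCAL_TO_KJ,
                "e_att_polar_kj": fam.e_att_polar * KCAL_TO_KJ,
                "e_att_nonpolar_kj": fam.e_att_nonpolar * KCAL_TO_KJ,
                "polar_fraction": fam.polar_fraction,
                "hbd_density": chem.hbd_density,
                "hba_density": chem.hba_density,
                "aromatic_density": chem.aromatic_density,
                "rugosity_A": topo.rugosity,
                "relative_area": fam.relative_area,
            }
        )
    df = pd.DataFrame(rows)
    if observed_order:
        order = [normalize_hkl(h) for h in observed_order]
        df["__rank"] = df["hkl"].map(
            lambda h: order.index(h) if h in order else len(order)
        )
        df = df.sort_values("__rank").drop(columns="__rank").reset_index(drop=True)
    else:
        df = (
            df.assign(__a=df["e_att_kcal"].abs())
            .sort_values("__a", ascending=False)
            .drop(columns="__a")
            .reset_index(drop=True)
        )
    if len(df) and df["hbd_density"].min() >= 0:
        pol = df["e_att_polar_kj"].abs()
        df.attrs["polar_anisotropy"] = float(
            pol.max() / pol.min() if pol.min() > 0 else np.inf
        )
    return df
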