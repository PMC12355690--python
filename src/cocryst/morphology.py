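"""Attachment-energy morphology: slice/attachment partition and Wulff habit.

For a lattice-plane family (hkl) with spacing d_hkl, every interaction of a
reference molecule is assigned to the *growth slice* (partner centroid within
the d_hkl-thick slab through the reference centroid) or to the *attachment*
set (outside it).  This makes E_lattice = E_slice + E_att an identity by
construction for every (hkl).  Facet growth rate is taken proportional to
|E_att| (the standard attachment-energy assumption, no solvent correction),
and the predicted habit is the Wulff polyhedron: the intersection of
half-spaces at center distances proportional to the growth rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from cocryst.chemio import CrystalStructure
from cocryst.energy import (
    EnergyTerms,
    ForceFieldParams,
    InteractionPair,
    KCAL_TO_KJ,
    LatticeModel,
)


@dataclass
class FacetFamily:
    """A symmetry-merged {hkl} family with its energy partition.

    ``e_att_polar`` collects the Coulomb + hydrogen-bond parts of the
    attachment energy, ``e_att_nonpolar`` the Lennard-Jones part; they sum to
    ``e_att`` identically.
    """

    hkl: tuple[int, int, int]
    d_spacing: float
    e_slice: float
    e_att: float
    e_att_polar: float
    e_att_nonpolar: float
    relative_area: float = 0.0
    attachment_pairs: list[InteractionPair] = field(default_factory=list)

    @property
    def e_att_kj(self) -> float:
        return self.e_att * KCAL_TO_KJ

    @property
    def polar_fraction(self) -> float:
        return abs(self.e_att_polar) / abs(self.e_att) if self.e_att else 0.0


@dataclass
class Habit:
    facets: list[FacetFamily]
    vertices: np.ndarray
    faces: list[dict]  # {"hkl", "normal", "distance", "area", "vertex_indices"}

    @property
    def total_area(self) -> float:
        return sum(f["area"] for f in self.faces)


# --------------------------------------------------------------------------
# form enumeration


def _gcd3(h: int, k: int, l: int) -> int:
    return math.gcd(math.gcd(abs(h), abs(k)), abs(l))


def normalize_hkl(hkl) -> tuple[int, int, int]:
    """Reduce to coprime indices with a sign-canonical representative
    (first non-zero index positive — Friedel mates merge)."""
    h, k, l = (int(x) for x in hkl)
    g = _gcd3(h, k, l)
    if g == 0:
        raise ValueError("hkl must not be (0, 0, 0)")
    h, k, l = h // g, k // g, l // g
    for x in (h, k, l):
        if x != 0:
            if x < 0:
                h, k, l = -h, -k, -l
            break
    return (h, k, l)


def enumerate_forms(
    xtal: CrystalStructure, max_index: int = 1
) -> list[tuple[int, int, int]]:
    """Symmetry-unique coprime (hkl) up to ``max_index``, sorted by d-spacing
    descending.  Friedel mates are always merged (attachment energies are
    inversion-symmetric by construction); rotational symmetry of the crystal
    merges further equivalents."""
    if max_index < 1:
        raise ValueError("max_index must be >= 1")
    seen: dict[tuple[int, int, int], None] = {}
    rng = range(-max_index, max_index + 1)
    rotations = [op.rotation for op in xtal.ops]
    for h in rng:
        for k in rng:
            for l in rng:
                if (h, k, l) == (0, 0, 0) or _gcd3(h, k, l) != 1:
                    continue
                cand = normalize_hkl((h, k, l))
                # a plane (hkl) maps under fractional rotation R to hkl·R^{-1};
                # for integer R with det ±1 equivalents stay integral
                equivalent = None
                for rot in rotations:
                    rinv = np.rint(np.linalg.inv(rot)).astype(int)
                    img = normalize_hkl(tuple(np.array(cand) @ rinv))
                    if img in seen:
                        equivalent = img
                        break
                if equivalent is None and cand not in seen:
                    seen[cand] = None
    forms = sorted(seen, key=lambda f: -xtal.cell.d_spacing(f))
    return forms


# --------------------------------------------------------------------------
# attachment energy


def attachment_energy(
    xtal: CrystalStructure,
    params: ForceFieldParams | None = None,
    hkl=(0, 0, 1),
    cutoff: float = 30.0,
    model: LatticeModel | None = None,
) -> FacetFamily:
    """Slice/attachment partition of the lattice energy for one (hkl).

    A partner belongs to the slice when the component of the centroid–centroid
    vector along the facet normal is smaller than d_hkl/2 in magnitude.  The
    per-pair attribution is retained on the returned family so the specific
    synthons feeding a facet's growth can be listed.
    """
    hkl = normalize_hkl(hkl)
    model = model or LatticeModel(xtal, params, cutoff)
    n_hat = xtal.cell.plane_normal(hkl)
    d = xtal.cell.d_spacing(hkl)
    e_slice = EnergyTerms(0.0, 0.0, 0.0)
    e_att = EnergyTerms(0.0, 0.0, 0.0)
    att_pairs: list[InteractionPair] = []
    for ref in range(model.n_ref):
        ref_cen = model.cell_molecules[ref].centroid()
        for p in model.pairs(ref):
            t = float((p.partner.molecule.centroid() - ref_cen) @ n_hat)
            if abs(t) < d / 2.0:
                e_slice = e_slice + p.terms.scaled(0.5)
            else:
                e_att = e_att + p.terms.scaled(0.5)
                att_pairs.append(p)
    return FacetFamily(
        hkl=hkl,
        d_spacing=d,
        e_slice=e_slice.e_total,
        e_att=e_att.e_total,
        e_att_polar=e_att.e_polar,
        e_att_nonpolar=e_att.e_vdw,
        attachment_pairs=att_pairs,
    )


def polar_split(facet: FacetFamily) -> dict:
    """Polar/nonpolar attachment-energy split in kcal/mol and kJ/mol."""
    return {
        "e_att_polar_kcal": facet.e_att_polar,
        "e_att_nonpolar_kcal": facet.e_att_nonpolar,
        "e_att_polar_kj": facet.e_att_polar * KCAL_TO_KJ,
        "e_att_nonpolar_kj": facet.e_att_nonpolar * KCAL_TO_KJ,
    }


# --------------------------------------------------------------------------
# Wulff construction


def wulff_habit(
    facets: list[FacetFamily],
    xtal: CrystalStructure,
    drop_below_area: float = 1e-9,
) -> Habit:
    """Wulff polyhedron from attachment energies.

    Center-to-plane distance ∝ |e_att|; each family contributes the (hkl) and
    (−h−k−l) half-spaces.  Families whose planes end up with zero area are
    dropped (relative_area 0).  Raises on degenerate input (normals not
    spanning 3D, or a zero growth rate that would collapse the polyhedron).
    """
    if len(facets) < 3:
        raise ValueError("need at least 3 facet families")
    normals, dists, owners = [], [], []
    scale = max(abs(f.e_att) for f in facets)
    if scale <= 0:
        raise ValueError("all attachment energies are zero")
    for idx, f in enumerate(facets):
        h = abs(f.e_att) / scale
        if h < 1e-12:
            raise ValueError(
                f"facet {f.hkl} has zero growth rate; habit degenerate"
            )
        n = xtal.cell.plane_normal(f.hkl)
        for sgn in (+1.0, -1.0):
            normals.append(sgn * n)
            dists.append(h)
            owners.append(idx)
    normals = np.array(normals)
    dists = np.array(dists)
    rank = np.linalg.matrix_rank(normals)
    if rank < 3:
        raise ValueError("facet normals do not span 3D; polyhedron unbounded")
    halfspaces = np.hstack([normals, -dists[:, None]])
    try:
        hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    except QhullError as exc:
        raise ValueError(f"polyhedron construction failed: {exc}") from exc
    verts = hs.intersections

    faces = []
    fam_area = np.zeros(len(facets))
    for i in range(len(normals)):
        on_plane = np.where(np.abs(verts @ normals[i] - dists[i]) < 1e-9)[0]
        if len(on_plane) < 3:
            continue
        area, ordered = _polygon_area(verts[on_plane], normals[i])
        if area <= drop_below_area:
            continue
        fam_area[owners[i]] += area
        faces.append(
            {
                "hkl": facets[owners[i]].hkl,
                "normal": normals[i],
                "distance": dists[i],
                "area": area,
                "vertex_indices": on_plane[ordered].tolist(),
            }
        )
    total = fam_area.sum()
    if total <= 0:
        raise ValueError("habit has no faces with positive area")
    kept = []
    for idx, f in enumerate(facets):
        f.relative_area = float(fam_area[idx] / total)
        kept.append(f)
    return Habit(facets=kept, vertices=verts, faces=faces)


def _polygon_area(pts: np.ndarray, normal: np.ndarray):
    """Area and angular ordering of coplanar points with outward normal."""
    cen = pts.mean(axis=0)
    u = pts[0] - cen
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)
    x = (pts - cen) @ u
    y = (pts - cen) @ v
    order = np.argsort(np.arctan2(y, x))
    xs, ys = x[order], y[order]
    area = 0.5 * abs(
        float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
    )
    return area, order


def wulff_area_mc(
    facets: list[FacetFamily],
    xtal: CrystalStructure,
    n_samples: int = 200_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo estimate of the Wulff relative facet areas.

    Samples uniform directions; each ray from the center hits the face whose
    plane is reached first, and the surface-area element there is
    r(u)²/(n̂·û) dΩ.  An independent check on the polyhedral area computation.
    """
    rng = np.random.default_rng(seed)
    scale = max(abs(f.e_att) for f in facets)
    normals, dists, owners = [], [], []
    for idx, f in enumerate(facets):
        n = xtal.cell.plane_normal(f.hkl)
        for sgn in (+1.0, -1.0):
            normals.append(sgn * n)
            dists.append(abs(f.e_att) / scale)
            owners.append(idx)
    normals = np.array(normals)
    dists = np.array(dists)
    owners = np.array(owners)

    u = rng.normal(size=(n_samples, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    dots = u @ normals.T  # (n, planes)
    with np.errstate(divide="ignore"):
        tvals = np.where(dots > 1e-12, dists[None, :] / dots, np.inf)
    hit = np.argmin(tvals, axis=1)
    r = tvals[np.arange(n_samples), hit]
    w = r**2 / dots[np.arange(n_samples), hit]
    areas = np.zeros(len(facets))
    np.add.at(areas, owners[hit], w)
    return areas / areas.sum()
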