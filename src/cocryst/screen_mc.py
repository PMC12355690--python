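"""Stage-1 coformer screening by molecular complementarity.

Five descriptors are compared between the target and each library coformer:
three shape descriptors from the rectangular box enclosing the van der Waals
volume (short-axis length, short/long and medium/long axis ratios, the box
axes being the principal axes of the atomic point cloud) and two polarity
descriptors (fraction of N and O atoms among heavy atoms, and dipole moment
magnitude).  Each descriptor PASSes when the target–coformer difference falls
inside a configured window; the overall verdict is PASS iff all five pass.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import pandas as pd

from cocryst.chemio import Molecule

log = logging.getLogger(__name__)

EA_TO_DEBYE = 4.80320427  # 1 e·Å in Debye

DESCRIPTOR_NAMES = ("s_axis", "s_over_l", "m_over_l", "no_fraction", "dipole")


@dataclass(frozen=True)
class DescriptorVector:
    """The five complementarity descriptors of one molecule."""

    s_axis: float      # short box-axis length, Å
    s_over_l: float    # short/long axis ratio
    m_over_l: float    # medium/long axis ratio
    no_fraction: float # (N+O)/heavy atoms (default denominator)
    dipole: float      # |dipole|, Debye

    def __post_init__(self):
        if not (0 < self.s_over_l <= self.m_over_l <= 1 + 1e-12):
            raise ValueError("axis ratios must satisfy 0 < S/L <= M/L <= 1")
        if not 0 <= self.no_fraction <= 1:
            raise ValueError("no_fraction must lie in [0, 1]")
        if self.dipole < 0 or self.s_axis <= 0:
            raise ValueError("dipole must be >= 0 and s_axis > 0")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))


@dataclass(frozen=True)
class MCThresholds:
    """Per-descriptor PASS windows (maximum allowed |difference|)."""

    s_axis: float
    s_over_l: float
    m_over_l: float
    no_fraction: float
    dipole: float

    @classmethod
    def default(cls) -> "MCThresholds":
        return cls.from_file(resources.files("cocryst.data") / "mc_thresholds.toml")

    @classmethod
    def from_file(cls, path) -> "MCThresholds":
        with open(str(path), "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**{k: float(v) for k, v in raw["windows"].items()})

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class MCResult:
    target: str
    coformer: str
    target_descriptors: DescriptorVector | None
    coformer_descriptors: DescriptorVector | None
    per_descriptor: dict[str, bool]
    overall: bool
    evaluated: bool = True


# --------------------------------------------------------------------------
# descriptors


def bounding_box_axes(mol: Molecule) -> np.ndarray:
    """Principal-axis bounding-box extents sorted L >= M >= S (Å).

    The box frame is the PCA frame of the atomic point cloud; each extent is
    inflated by the vdW radii of the extreme atoms, so a single atom gives a
    box of side 2·r_vdW and a strictly planar molecule gets 2·max(r_vdW)
    along its normal.  Rotation- and translation-invariant by construction.
    """
    if not mol.atoms:
        raise ValueError("cannot compute a bounding box for an empty molecule")
    coords = mol.coords
    radii = np.array([a.vdw_radius for a in mol.atoms])
    centered = coords - coords.mean(axis=0)
    if len(mol.atoms) == 1:
        r = 2.0 * radii[0]
        return np.array([r, r, r])
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs  # columns = principal axes (ascending variance)
    hi = (proj + radii[:, None]).max(axis=0)
    lo = (proj - radii[:, None]).min(axis=0)
    ext = np.sort(hi - lo)[::-1]
    return ext


def bounding_box_descriptors(mol: Molecule) -> tuple[float, float, float]:
    """(s_axis, s_over_l, m_over_l) from the vdW bounding box."""
    L, M, S = bounding_box_axes(mol)
    return float(S), float(S / L), float(M / L)


def dipole_moment(mol: Molecule) -> float:
    """|Σ qᵢ rᵢ| in Debye, about the centre of charge.

    For a net-charged molecule the dipole is origin-dependent; it is then
    computed about the centre of mass and a warning is logged.
    """
    q = mol.charges
    coords = mol.coords
    net = q.sum()
    if abs(net) > 1e-6:
        log.warning(
            "molecule %s carries net charge %.3f e: dipole is origin-dependent, "
            "computed about the centre of mass",
            mol.name,
            net,
        )
        from cocryst.chemio import atomic_weight

        w = np.array([atomic_weight(a.element) for a in mol.atoms])
        origin = (coords * w[:, None]).sum(axis=0) / w.sum()
    elif np.abs(q).sum() > 1e-12:
        origin = (coords * np.abs(q)[:, None]).sum(axis=0) / np.abs(q).sum()
    else:
        origin = coords.mean(axis=0)
    mu = ((coords - origin) * q[:, None]).sum(axis=0)
    return float(np.linalg.norm(mu)) * EA_TO_DEBYE


def polarity_descriptors(
    mol: Molecule, heavy_only_denominator: bool = True
) -> tuple[float, float]:
    """(no_fraction, dipole).  ``no_fraction`` counts N and O over heavy atoms
    by default; set ``heavy_only_denominator=False`` for an all-atom
    denominator."""
    n_no = sum(1 for a in mol.atoms if a.element in ("N", "O"))
    denom = sum(1 for a in mol.atoms if a.is_heavy) if heavy_only_denominator else len(
        mol.atoms
    )
    frac = n_no / denom if denom else 0.0
    return float(frac), dipole_moment(mol)


def descriptor_vector(
    mol: Molecule, heavy_only_denominator: bool = True
) -> DescriptorVector:
    s, sl, ml = bounding_box_descriptors(mol)
    frac, dip = polarity_descriptors(mol, heavy_only_denominator)
    return DescriptorVector(s, sl, ml, frac, dip)


# --------------------------------------------------------------------------
# screening


def mc_screen(
    target: Molecule,
    library: list[Molecule],
    thresholds: MCThresholds | None = None,
) -> list[MCResult]:
    """Screen a coformer library against a target molecule.

    Descriptor differences are compared to the PASS windows; the library order
    is preserved in the output.  A library entry whose descriptors cannot be
    evaluated is marked UNEVALUATED and the run continues.
    """
    thresholds = thresholds or MCThresholds.default()
    tdesc = descriptor_vector(target)
    windows = thresholds.as_dict()
    results = []
    for cof in library:
        try:
            cdesc = descriptor_vector(cof)
        except Exception as exc:
            log.warning("descriptor evaluation failed for %s: %s", cof.name, exc)
            results.append(
                MCResult(
                    target=target.name,
                    coformer=cof.name,
                    target_descriptors=tdesc,
                    coformer_descriptors=None,
                    per_descriptor={},
                    overall=False,
                    evaluated=False,
                )
            )
            continue
        flags = {
            name: abs(getattr(tdesc, name) - getattr(cdesc, name)) <= windows[name]
            for name in DESCRIPTOR_NAMES
        }
        results.append(
            MCResult(
                target=target.name,
                coformer=cof.name,
                target_descriptors=tdesc,
                coformer_descriptors=cdesc,
                per_descriptor=flags,
                overall=all(flags.values()),
            )
        )
    return results


def results_to_frame(results: list[MCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"target": r.target, "coformer": r.coformer}
        for name in DESCRIPTOR_NAMES:
            row[f"target_{name}"] = (
                getattr(r.target_descriptors, name) if r.target_descriptors else np.nan
            )
            row[f"coformer_{name}"] = (
                getattr(r.coformer_descriptors, name)
                if r.coformer_descriptors
                else np.nan
            )
        for name in DESCRIPTOR_NAMES:
            row[f"pass_{name}"] = (
                "PASS" if r.per_descriptor.get(name) else "FAIL"
            ) if r.evaluated else "UNEVALUATED"
        row["overall"] = (
            ("PASS" if r.overall else "FAIL") if r.evaluated else "UNEVALUATED"
        )
        rows.append(row)
    return pd.DataFrame(rows)
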