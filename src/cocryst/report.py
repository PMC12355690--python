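"""Workflow orchestration, literature-input tables, stoichiometry utilities.

The end-to-end workflow runs the five computational stages in order —
complementarity screen → ΔHBP ranking → synthon energetics → morphology →
surface chemistry — on synthetic fixtures or user inputs, writing one table
per stage plus a manifest (seeds, configuration, SHA-256 of every output)
that makes a run bit-reproducible.

Also shipped: the published per-synthon interaction table and multicomponent
H-bond-propensity scores of the 2:1 quercetin–imidazole cocrystal (CCDC
2405458), as *inputs* for aggregation utilities.  Names of the non-positive
MCHBP entries were not published; those rows carry placeholder names with
the reported score values.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd

from cocryst import __version__
from cocryst.chemio import atomic_weight
from cocryst.energy import (
    ForceFieldParams,
    KCAL_TO_KJ,
    LatticeModel,
    aggregate_by_type,
    rank_synthons,
)
from cocryst.morphology import attachment_energy, enumerate_forms, wulff_habit
from cocryst.screen_hbp import rank_coformers, score_all
from cocryst.screen_mc import MCThresholds, mc_screen, results_to_frame
from cocryst.surface import surface_report
from cocryst import synthdata


# --------------------------------------------------------------------------
# literature tables (inputs, not computed results)


def load_reference_synthons() -> pd.DataFrame:
    """Published synthon table of the quercetin–imidazole cocrystal: type,
    centroid distance (Å), interaction energy (kcal/mol), % of lattice
    energy."""
    path = resources.files("cocryst.data") / "queim_synthons.tsv"
    return pd.read_csv(str(path), sep="\t")


def load_reference_mchbp_scores() -> pd.DataFrame:
    """Published multicomponent H-bond-propensity scores for quercetin
    coformer pairs (positive block fully named; non-positive entries carry
    placeholder names)."""
    path = resources.files("cocryst.data") / "queim_mchbp.tsv"
    return pd.read_csv(str(path), sep="\t")


# --------------------------------------------------------------------------
# stoichiometry


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molecular_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a plain element-count formula, e.g.
    C15H10O7 (no parentheses/hydrate dots — expand those by hand)."""
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        total += atomic_weight(m.group(1)) * (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula) or total == 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


def stoichiometric_mass_fraction(components, leaving: str) -> float:
    """Theoretical mass-loss percentage of one component of a stoichiometric
    multi-component solid.

    ``components`` is a list of (formula, count); ``leaving`` names the
    formula of the departing component.  Example: water in CuSO4·5H2O →
    stoichiometric_mass_fraction([("CuSO4", 1), ("H2O", 5)], "H2O") ≈ 36.08.
    """
    weights = {f: molecular_weight(f) for f, _ in components}
    if leaving not in weights:
        raise ValueError(f"leaving component {leaving!r} not among components")
    total = sum(cnt * weights[f] for f, cnt in components)
    lost = sum(cnt * weights[f] for f, cnt in components if f == leaving)
    return 100.0 * lost / total


# --------------------------------------------------------------------------
# workflow


@dataclass
class WorkflowConfig:
    """All knobs of one end-to-end run; serialized into the manifest."""

    outdir: str = "cocryst_run"
    seed: int = 0
    stages: tuple[str, ...] = ("screen_mc", "screen_hbp", "energy", "morphology",
                               "surface")
    cutoff: float = 30.0
    library_size: int = 20
    library_n_pass: int = 8
    propensity_pairs: int = 56
    propensity_positive: int = 18
    max_index: int = 1
    exposure_depth: float = 3.0
    grid_spacing: float = 0.25
    ff_file: str | None = None
    thresholds_file: str | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: WorkflowConfig) -> dict:
    """Run the configured stages on synthetic fixtures; returns the manifest.

    Stage order is fixed; a stage failure is recorded and later stages are
    skipped (their outputs would be undefined).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = (
        ForceFieldParams.from_file(config.ff_file)
        if config.ff_file
        else ForceFieldParams.default()
    )
    thresholds = (
        MCThresholds.from_file(config.thresholds_file)
        if config.thresholds_file
        else MCThresholds.default()
    )
    manifest: dict = {
        "tool": "cocryst",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    xtal = None
    model = None
    habit_facets = None
    for stage in ("screen_mc", "screen_hbp", "energy", "morphology", "surface"):
        if stage not in config.stages:
            manifest["stages"][stage] = "disabled"
            continue
        try:
            if stage == "screen_mc":
                lib = synthdata.make_coformer_library(
                    config.library_size,
                    config.library_n_pass,
                    thresholds,
                    seed=config.seed,
                )
                res = mc_screen(lib.target, lib.members, thresholds)
                df = results_to_frame(res)
                df.to_csv(out / "mc_results.tsv", sep="\t", index=False)
                manifest["stages"][stage] = {
                    "n": len(res),
                    "n_pass": sum(r.overall for r in res),
                }
            elif stage == "screen_hbp":
                table, _ = synthdata.make_propensity_table(
                    config.propensity_pairs,
                    config.propensity_positive,
                    seed=config.seed,
                )
                ranking = rank_coformers(score_all(table, "target"))
                ranking.to_csv(out / "hbp_ranking.tsv", sep="\t", index=False)
                manifest["stages"][stage] = ranking.attrs["partition"]
            elif stage == "energy":
                xtal = synthdata.make_ribbon_crystal(seed=config.seed)
                model = LatticeModel(xtal, params, config.cutoff)
                ranking = rank_synthons(xtal, model=model)
                df = ranking.to_frame()
                df.to_csv(out / "synthons.tsv", sep="\t", index=False)
                agg = aggregate_by_type(ranking)
                agg.to_csv(out / "synthon_classes.tsv", sep="\t", index=False)
                manifest["stages"][stage] = {
                    "e_lattice_kcal": ranking.e_lattice,
                    "n_synthons": len(ranking.synthons),
                    "rank1_type": ranking.synthons[0].type_label
                    if ranking.synthons
                    else None,
                }
            elif stage == "morphology":
                if model is None:
                    raise RuntimeError("energy stage required before morphology")
                forms = enumerate_forms(xtal, config.max_index)
                habit_facets = [
                    attachment_energy(xtal, hkl=h, model=model) for h in forms
                ]
                habit = wulff_habit(habit_facets, xtal)
                payload = {
                    "facets": [
                        {
                            "hkl": list(f.hkl),
                            "d_spacing_A": f.d_spacing,
                            "e_slice_kcal": f.e_slice,
                            "e_att_kcal": f.e_att,
                            "e_att_polar_kj": f.e_att_polar * KCAL_TO_KJ,
                            "e_att_nonpolar_kj": f.e_att_nonpolar * KCAL_TO_KJ,
                            "relative_area": f.relative_area,
                        }
                        for f in habit.facets
                    ],
                    "vertices": habit.vertices.tolist(),
                }
                (out / "habit.json").write_text(json.dumps(payload, indent=1))
                manifest["stages"][stage] = {"n_facets": len(habit.facets)}
            elif stage == "surface":
                if model is None or habit_facets is None:
                    raise RuntimeError("morphology stage required before surface")
                top = sorted(habit_facets, key=lambda f: -f.relative_area)[:3]
                df = surface_report(
                    xtal,
                    top,
                    cutoff=config.cutoff,
                    exposure_depth=config.exposure_depth,
                    grid_spacing=config.grid_spacing,
                    model=model,
                )
                df.to_csv(out / "surface_report.tsv", sep="\t", index=False)
                manifest["stages"][stage] = {"n_facets": len(df)}
        except Exception as exc:
            manifest["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
            break

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# table assembly


def aggregate_tables(outdir) -> dict[str, pd.DataFrame]:
    """Re-read a workflow output directory into tidy per-stage DataFrames
    (empty frames for missing stages); idempotent."""
    out = Path(outdir)
    tables: dict[str, pd.DataFrame] = {}
    for name in ("mc_results", "hbp_ranking", "synthons", "synthon_classes",
                 "surface_report"):
        p = out / f"{name}.tsv"
        tables[name] = pd.read_csv(p, sep="\t") if p.exists() else pd.DataFrame()
    return tables
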