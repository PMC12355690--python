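# cocryst

In-silico cocrystal design toolkit for molecular crystals: coformer virtual
screening, crystal synthon energetics under a Dreiding-style force field,
attachment-energy morphology prediction, and facet-specific surface-chemistry
characterization.

## Who this is for

Crystal engineers and formulation scientists working on pharmaceutical or
nutraceutical cocrystals (the motivating system is the 2:1
quercetin–imidazole cocrystal, CCDC 2405458) who want the computational half
of a cocrystal design campaign as one scriptable, testable pipeline:

1. **Molecular complementarity (MC) screen** — a coformer is plausible when
   it matches the target in five descriptors: the short axis *S* of the
   principal-axis box enclosing the van der Waals volume, the axis ratios
   *S/L* and *M/L*, the fraction of N+O among heavy atoms, and the dipole
   magnitude |μ|. Each descriptor yields PASS/FAIL against a configurable
   window; overall PASS requires all five.
2. **Hydrogen-bond propensity difference** — with P(A–B) the best
   donor–acceptor propensity between molecules A and B,

       ΔHBP = max P(T–C) − max( max P(T–T), max P(C–C) )

   for target T and coformer C; positive values favour cocrystallization.
   Propensities are tabulated inputs (a logistic surrogate model is included
   for end-to-end synthetic runs).
3. **Synthon analysis** — every whole molecule within 30 Å of a reference
   molecule contributes a pair energy
   E = E_LJ(12-6) + 332.0637·qiqj/(ε₀·r²) + E_HB, with an explicit 12-10
   hydrogen-bond term D_hb[5(R_hb/r_DA)¹² − 6(R_hb/r_DA)¹⁰]·cos⁴θ.
   Symmetry-equivalent contacts merge into ranked synthons with per-type,
   per-functional-group and per-atom decompositions of the lattice energy.
4. **Attachment-energy morphology** — per lattice-plane family {hkl} the
   lattice energy splits identically into a slice term (partners within a
   d_hkl-thick slab) and an attachment term E_att; growth rate ∝ |E_att|
   gives the Wulff habit and relative facet areas.
5. **Surface chemistry** — for each facet a whole-molecule termination slab
   is cut, the upper van der Waals envelope is mapped on a grid (rugosity =
   RMS height), and hydrogen-bond donor/acceptor and aromatic-bond densities
   per projected Å² are reported.

## Worked example

The whole pipeline on built-in synthetic fixtures (a planar H-bonding model
crystal; no downloads):

```bash
cocryst run --outdir demo --seed 0
```

Stage summary printed by the run:

```
"screen_mc":  {"n": 20, "n_pass": 8}
"screen_hbp": {"positive": 18, "zero": 0, "negative": 38}
"energy":     {"e_lattice_kcal": -14.69, "n_synthons": 36, "rank1_type": "H-bond"}
"morphology": {"n_facets": 13}
"surface":    {"n_facets": 3}
```

8 of 20 library members pass the complementarity windows and 18 of 56
synthetic coformers score ΔHBP > 0 — both by construction of the fixtures,
so the screen is verified against ground truth. `demo/synthons.tsv` ranks
the crystal's contacts:

```
rank  type            centroid_distance_A  e_total_kcal  multiplicity  percent_of_lattice
1     H-bond          8.110                -8.312        2             56.6
2     pi-pi stacking  3.500                -4.133        2             28.1
3     vdW/other       7.778                -0.410        2              2.8
```

The in-chain O–H···O hydrogen bond is the strongest synthon, the π-stack
second — the packing motif the fixture was designed to exhibit.
`demo/surface_report.tsv` links structure to surface chemistry:

```
hkl        e_att_kj  e_att_polar_kj  e_att_nonpolar_kj  hbd_density  rugosity_A
(1, 0, 0)  -39.91    -36.34           -3.57             0.037        1.28
(0, 0, 1)  -24.48      3.02          -27.50             0.016        0.65
(0, 1, 0)   -4.56      0.39           -4.95             0.035        1.06
```

The facet normal to the H-bond chains, (1 0 0), grows through polar
interactions (−36.3 of −39.9 kJ/mol) and exposes the most donors
(0.037/Ų); the stacking facet (0 0 1) is nonpolar-dominated and
donor-poor. That is the qualitative structure→surface link the pipeline is
built to expose.

Real structures enter through the same commands
(`cocryst synthons structure.cif`, `cocryst habit`, `cocryst surface`,
`cocryst screen-mc`, `cocryst screen-hbp`).

Utility arithmetic, e.g. the theoretical TGA mass loss of imidazole from the
2:1 quercetin:imidazole cocrystal:

```bash
$ cocryst mass-fraction --component C15H10O7:2 --component C3H4N2:1 --leaving C3H4N2
10.12%
```

## Layout

```
src/cocryst/chemio.py      structures, CIF/SDF I/O, perception, typing
src/cocryst/screen_mc.py   complementarity descriptors + PASS/FAIL screen
src/cocryst/screen_hbp.py  ΔHBP scoring, ranking, logistic surrogate
src/cocryst/energy.py      force field, environments, synthons, decompositions
src/cocryst/morphology.py  forms, attachment energies, Wulff habit
src/cocryst/surface.py     slabs, rugosity maps, HBD/HBA/aromatic densities
src/cocryst/synthdata.py   deterministic synthetic fixtures
src/cocryst/report.py      workflow orchestration, literature tables, TGA math
src/cocryst/cli.py         the `cocryst` command
docs/methods.md            model assumptions, parameters, limitations
```
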