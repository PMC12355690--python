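# Methods

This note records the models implemented in `cocryst`, the assumptions and
default parameters behind them, what the synthetic fixtures do and do not
emulate, and the numerical choices a maintainer would want to know about.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structures and chemical perception

Structures live in Cartesian Å with a right-handed cell and **a** along x;
fractional coordinates appear only at the CIF boundary (gemmi parses the
documents; element radii and weights come from gemmi's tables). Symmetry
expansion acts on whole molecules: an operation maps the Cartesian molecule
and only the centroid is wrapped, so no covalent bond ever crosses a cell
boundary. On reading, sites are expanded, deduplicated on special positions
(0.5 Å), bonded under periodic boundary conditions by the covalent-radius
rule d < r_i + r_j + 0.4 Å, and connected components are unwrapped into
whole molecules; one representative per symmetry orbit forms the asymmetric
unit.

Rings come from a minimum cycle basis. A ring is *aromatic* when it is
planar (RMS out-of-plane < 0.1 Å), has 5–7 members, contains only C/N, and
every member is sp²-like (≤ 3 connections). This is a geometric rule, not an
electronic one: it correctly flags benzene, imidazole and fused carbocycles
and leaves O-containing rings (pyrone) unflagged, which is the behaviour the
stacking classifier needs.

Atom types follow hybridization-rule typing (C_3/C_2/C_1/C_R and analogues;
H on N/O becomes the hydrogen-bonding type H__HB). Partial charges default
to Gasteiger iterative partial equalization (RDKit) — deterministic and
fitting-free; the scheme is pluggable (`keep` for designed fixture charges,
`zero`). The charge model used to produce the published reference energies
is not known, so absolute energies of real structures depend on this choice;
all identities and rankings tested here are charge-model-agnostic or use
designed charges.

Hydrogen positions are taken as given in the input (riding-model H from
refinement is assumed); no normalization is applied. Donors are H atoms
bonded to N/O; acceptors are all O plus N carrying no hydrogen
(pyridine-type). Amine nitrogens are deliberately not counted as acceptors —
a simplification consistent with treating N–H groups as donor sites only.

## Complementarity screen

The bounding box is the principal-axis (PCA) box of the atomic point cloud,
each extent inflated by the vdW radii of the extreme atoms. This is
deterministic and rotation/translation invariant; it is not the exhaustive
minimum-volume box (the two differ by a few percent for elongated
molecules, identically for near-ellipsoidal ones). Degenerate cases: a
single atom gives a cube of side 2·r_vdW; a strictly planar molecule gets
2·max(r_vdW) along its normal.

The N+O fraction uses a heavy-atom denominator (configurable to all-atom).
The dipole is computed about the centre of charge; for net-charged species
it is origin-dependent and is computed about the centre of mass with a
warning.

PASS windows (maximum |target − coformer| per descriptor) are shipped in
`data/mc_thresholds.toml`: s_axis 1.9 Å, S/L 0.17, M/L 0.23, N+O fraction
0.17, dipole 5.0 D. These defaults are the package's own calibration of the
complementarity idea, chosen to be of the order of typical descriptor
spreads among known cocrystal pairs; they are explicitly *defaults to
override*, and every screening fixture plants its ground truth against
whatever windows are in force, so tests do not depend on these numbers.

## ΔHBP scoring

ΔHBP = max heteromeric propensity − max homomeric propensity, with an empty
homomeric set treated as propensity 0 (the permissive convention, logged).
Propensities are inputs in [0, 1]; the bundled logistic surrogate
σ(β·x + b) exists so the pipeline runs end-to-end on synthetic tables, and
its coefficients are recoverable from labelled pairs (unpenalized logistic
regression) — it makes no claim to reproduce any trained literature model.
Ranking is ΔHBP-descending with a stable name tie-break, so output is a
total order.

## Force field and lattice energies

Nonbonded parameters (`data/dreiding.toml`) are the generic published
Dreiding set: 12-6 Lennard-Jones in well-depth form E = D₀[(R₀/r)¹² −
2(R₀/r)⁶] with geometric mixing for both R₀ and D₀; electrostatics are
atomic monopoles under a distance-dependent dielectric ε(r) = ε₀·r (ε₀ = 1),
giving E = 332.0637·qiqj/(ε₀r²) kcal/mol; hydrogen bonds use the explicit
12-10 term D_hb[5(R_hb/r_DA)¹² − 6(R_hb/r_DA)¹⁰]·cos⁴θ(D–H···A) on
donor–acceptor distance, active for r_DA < 4.5 Å and θ > 90°, replacing the
12-6 term for the H···A atom pair. D_hb = 4.0 kcal/mol and R_hb = 2.75 Å
(the charge-aware variant of the published set; 9.5 kcal/mol is the
charges-off variant). H__HB carries a near-zero LJ well so the explicit
term dominates genuine H-bond contacts.

The environment of a reference molecule is every whole molecule image whose
*centroid* lies within the cutoff (default 30 Å) — centroid metric chosen
because reported synthon tables list centroid–centroid distances; an
any-atom variant would only enlarge the environment. The supercell search
extent derives from the axis interplanar spacings plus the largest
intra-cell centroid offset and a one-cell margin, which makes the
enumeration provably complete (doubling the extent changes nothing; an
explicit 7×7×7 brute-force enumeration at the same cutoff agrees to
1e-6 kcal/mol and is part of the acceptance suite). Lattice energy is the
half-sum over the environment; no Ewald summation — molecules are neutral
and a convergence check (cutoff vs cutoff+10 Å, threshold 0.1 kcal/mol) is
available.

Synthons merge contacts whose total energies agree within 1e-6 kcal/mol,
centroid distances within 1e-4 Å and type labels match —
symmetry-equivalent contacts satisfy all three; sorting is |E| descending,
then centroid distance, then partner id. A synthon's *contribution* is
multiplicity·E/2 (half-counting), so contributions sum exactly to the
lattice energy and percentages to 100. Percentages are defined against the
intermolecular lattice energy only; intramolecular terms are out of scope
throughout.

Interaction classification (precedence H-bond > π–π > offset > other):
H-bond if some donor-H···acceptor contact has r(H···A) < 2.5 Å and angle
> 120°; π–π if aromatic ring centroids are < 4.0 Å apart with interplanar
angle < 20° and lateral offset < 1.5 Å; offset stacking up to 6.5 Å
centroid distance with offset ≥ 1.5 Å. The per-functional-group
decomposition attributes half of every atom-pair term to each atom's group,
so group sums conserve the lattice energy identically.

## Morphology

Forms are coprime (hkl) up to max index 1 by default (the experimentally
relevant low-index facets of the motivating system are index-1 in its
triclinic setting), Friedel mates always merged — the slice partition uses
|t| along the normal, so ±(hkl) are identical by construction — plus
rotational deduplication, sorted by d-spacing.

Slice membership is centroid-based: a partner is in the growth slice when
the normal component of the centroid–centroid vector is < d_hkl/2. This is
parameter-free and makes E_lattice = E_slice + E_att an *identity* (tested
to 1e-6 across ten randomized crystals and all forms). A bond-crossing
definition would need a bond-strength threshold and would not conserve
exactly. Growth rate ∝ |E_att| with no solvent correction — the standard
attachment-energy assumption; predicted and solution-grown morphologies are
expected to differ where solvent effects are strong.

The Wulff habit is the half-space intersection at distances ∝ |E_att|
(scipy's HalfspaceIntersection); facet areas come from the on-plane vertex
polygons and are cross-checked against a Monte-Carlo estimator that samples
uniform directions and weights each hit by r²/(n̂·û) (the exact surface
measure for a star-shaped body), agreeing within 1 % at 1.5×10⁵ samples.
A facet with exactly zero |E_att| makes the polyhedron degenerate and is
rejected rather than clamped.

## Surface analysis

Terminations retain whole molecules (centroid below the cut plane). When no
offset is supplied, candidate offsets are the midpoints between consecutive
centroid levels within one d-spacing — the crossing energy is piecewise
constant between levels, so these candidates cover all distinct
terminations — and the offset minimizing the total |pair energy| crossing
the plane is selected (ties broken toward smaller rugosity, then smaller
offset). This min-crossing rule is this package's own termination
heuristic; a fixed-offset mode exists for reproducibility against other
conventions.

The topology map is the upper envelope of atomic vdW spheres sampled on a
default 0.25 Å grid over a 2×2 surface-cell patch (with a one-cell margin of
periodic images so edges are covered); rugosity is the RMS deviation from
the mean plane. Grid holes (no covering sphere) take the minimum covered
height. Rugosity converges to < 2 % between 0.25 and 0.10 Å grids and
drifts < 1 % under in-plane origin shifts.

Surface chemistry counts donor H atoms, acceptor heavy atoms and aromatic
bonds whose vdW top reaches within an exposure depth (default 3.0 Å ≈ one
atomic layer; configurable) of the local top surface, divided by the
projected patch area — counts/Ų. Donors are counted as H atoms and
acceptors as heavy atoms (a group-based count would differ for, e.g.,
geminal diols). Densities are intensive: 2×2 vs 4×4 patches agree within
5 %. Only a qualitative polarity/hydrophilicity ranking across facets is
claimed, never a quantitative wettability prediction.

## Synthetic fixtures

`synthdata` builds geometric idealizations: planar fused-ring scaffolds with
peripheral hydroxyls (designed charges, net zero) and an orthorhombic model
crystal whose molecule carries a donor O–H arm and a carbonyl acceptor arm
along ±x, so that the a-translation forms a perfectly linear O–H···O chain
(θ = 180°, tunable O···O distance), the c-translation a face-to-face
π-stack (tunable 3.2–4.0 Å), and b a padded vdW contact. Which synthon
dominates is controlled by the designed charges and the H-bond well depth,
giving two verifiable regimes (H-bond-dominant default; stack-dominant with
compressed stacking and weakened polar terms).

What the fixtures do **not** emulate: conformational flexibility, realistic
valence chemistry at the substituted ring positions (a quinone-like carbon
is accepted as-is), competing polymorph packings, solvent, thermal motion,
and the statistics of real donor–acceptor propensity models. Passing the
fixture suite therefore demonstrates that the machinery — perception,
energy sums, symmetry handling, partitions, counting — is correct, not that
any specific real system's absolute energies are reproduced. Real-structure
absolute energies additionally depend on the charge scheme, which is
documented as unresolved above.

Generator defaults (O···O 2.75 Å, stack 3.5 Å, padding 3.5 Å) sit at the
centre of the chemically sensible ranges for strong O–H···O bonds and
aromatic stacking; randomized property suites draw spacings uniformly from
those ranges under a fixed seed. All generators are bit-deterministic under
their seed.

## Numerical choices and scales

* Internal units kcal/mol and Å; kJ/mol reporting multiplies by exactly
  4.184. 1 e·Å = 4.80320427 D; Coulomb constant 332.0637 kcal·Å/(mol·e²).
* Test and acceptance runs use cutoffs of 9–20 Å on model crystals with
  ≤ 15 Å cells and 10–14-atom molecules — small enough for brute-force
  cross-checks, and the conservation identities being tested are
  cutoff-independent by construction. The production default remains 30 Å.
* Synthon grouping tolerances: 1e-6 kcal/mol on energy, 1e-4 Å on centroid
  distance. Tie-breaks everywhere are deterministic (distance, then ids or
  names), so all outputs are stable and the workflow manifest hashes
  reproduce bit-for-bit under a fixed seed.
* Degenerate inputs raise rather than guess: (000) planes, zero growth
  rates, normals not spanning 3D, empty slabs, unresolved disorder
  (opt-in majority-occupancy mode exists), propensities outside [0, 1].

## Known limitations

* Absolute lattice/synthon energies of real structures depend on the
  unknown reference charge model; only identities, decompositions and
  rankings are acceptance-tested.
* The MC PASS windows are package defaults, not a validated published set.
* Termination selection is a heuristic; experimental terminations may
  differ.
* No geometry optimization: structures are analyzed as given.
* Proton transfer (salt vs cocrystal) is not predicted; neutrality is an
  input assumption.
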