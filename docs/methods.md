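# Methods

## Scope and model

`ternscan` implements a ligand-centric procedure for predicting ternary
complexes of diyne-linker PROTACs, together with 1:1 SPR kinetics analysis.
The central assumption is that a linear C≡C–C≡C spacer leaves exactly one
internal degree of freedom between the two rigid warheads — the torsion
about the linker axis — so the ternary-complex search space is a
one-dimensional angular grid rather than a high-dimensional docking problem.
The package covers conformer enumeration, warhead superposition, steric
screening, restrained-relaxation bookkeeping with representative-frame
selection, and kinetics; it does not run production molecular dynamics, rank
poses energetically, or model degradation pharmacology.

## Structure model and PDB handling

Structures are ordered columnar atom tables (element, name, residue, chain,
coordinates in Å, backbone/heavy/Cα flags). PDB parsing and writing go
through gemmi; on top of gemmi's parse we apply the altloc policy (keep the
highest-occupancy conformer; ties prefer altloc `A`, then first
encountered) and drop hydrogens by default, since the clash census concerns
heavy atoms only (a flag retains them). Backbone means {N, CA, C, O, OXT}
of polymer residues; HETATM ligand atoms are never backbone. Selections are
views that preserve atom order and record their parent indices; the
selector grammar (`chain`, `name`, `resname`, `backbone`, `sidechain`,
`calpha`, `heavy`, `protein`, `ligand`, combined with `and`/`or`) is
deliberately small and is what configs and the CLI expose.

## Conformer scan

The rotation axis is the total-least-squares line through the four linker
carbons, anchored at their centroid — the scan's result is insensitive to
the anchor choice for a genuinely linear linker. Inputs whose linker
carbons deviate more than 5° from collinearity are rejected loudly: a bent
"diyne" has no well-defined single torsion and silently scanning it would
produce geometry-dependent artefacts. The E3-side warhead is the mobile
group by convention; swapping the designation relabels the grid (θ ↔ 360−θ)
but yields the same conformer family, which the tests assert via internal
distance matrices. The grid starts at the input geometry (angle 0); the
default 10° step yields 36 conformers. Steps must divide 360.

## Superposition and screening

Warhead correspondences are explicit atom maps (index pairs in memory,
two-column name files on disk); no substructure inference is attempted.
The Kabsch fit delegates to `scipy.spatial.transform.Rotation.align_vectors`
after explicit centroid removal, with uniform weights by default and proper
rotations guaranteed (a mirror fit is never returned); collinear or
under-determined maps (< 3 pairs) raise. The whole complex moves with the
transform fitted on the mapped ligand atoms only, so internal geometry is
exactly preserved.

A clash is an unordered inter-complex heavy-atom pair at distance strictly
below 2.4 Å; a pose is viable iff it has zero backbone–backbone clashing
pairs and at most 20 heavy-atom clashing pairs ("more than 20" rejects).
"20 total clashes" is read as 20 atom *pairs*; the threshold is
configurable. The census runs protein-complex vs protein-complex; PROTAC–
protein contacts are excluded by default because warhead placement
reproduces the crystallographic binding pose (a toggle includes them), and
chain selectors allow trimming accessory chains (e.g. DDB1) from the
census. Counting has two routes — a naive O(n·m) distance matrix and a
KD-tree path — held to exact agreement by tests; the KD-tree route
re-checks distances with a strict `<` because tree queries include the
boundary radius.

## Relaxation protocol and representative frames

The staged-release schedule is data, not physics: four stages at
10 kcal mol⁻¹ Å⁻² (all protein/ligand heavy atoms → release protein
sidechains → release protein backbone → release ligand), each stage a
selector over the roster, with a validator asserting the restrained sets
only shrink. The schedule exports as a plain-text report for use with any
MD engine. A toy minimizer — gradient descent with backtracking on pairwise
soft-sphere repulsion ε(σ/r)¹², σ = 2.4 Å to echo the clash cutoff, plus
the stage's harmonic positional restraints k·|x − x_ref|² — exists so the
release semantics are executable and testable; it makes no claim to
force-field realism.

Trajectories are multi-model PDB files with frame times in a sidecar table
(`<file>.times.tsv`), so real MD output remains analyzable. The
equilibration filter keeps frames with t > 10 ns by default (50 ns sampled
at 0.5 ns thus keeps 80 of 100 frames). The representative snapshot is the
medoid: for each candidate frame every other frame is superposed onto it on
the alignment selection (ligase backbone in the intended use) and RMSD is
computed over the scoring selection (target Cα); the median over the other
frames — self-pair excluded, even counts take the midpoint average — is
minimised, ties breaking to the lowest index. Superposed pair RMSD is
symmetric, so each unordered pair is computed once.

## SPR kinetics

Association follows R(t) = R_eq(1 − e^(−(k_on·C + k_off)t)) with
R_eq = Rmax·C/(C + K_D); dissociation decays first-order from the response
at contact end. The ternary assay format is modelled as effective 1:1
binding of the pre-mixed PROTAC:target complex to the immobilised ligase;
partial occupancy of the pre-mix, mass transport, baseline drift and bulk
refractive-index steps are not modelled, and noise is i.i.d. Gaussian.

The global fit shares k_on, k_off and Rmax across all cycles and optimises
in log₁₀-parameter space (positivity by construction) with box bounds at
±12 to keep ill-conditioned problems finite. Initialisation is data-driven
and deterministic: k_off from a log-linear regression of the dissociation
tail of the highest-concentration cycle, k_on from the slope of observed
rate vs concentration, Rmax from the top cycle's plateau scaled by
(C + K_D)/C. Standard errors come from the Gauss–Newton covariance at the
solution, mapped from log space by the delta method. A warning is emitted
when the concentration series spans ≤ 4-fold, which cannot separate k_on
from Rmax well.

Derived constants: K_D = k_off/k_on and t½ = ln2/k_off. For one published
compound row (k_on = 1.47×10⁵ M⁻¹s⁻¹, k_off = 0.0085 s⁻¹) these reproduce
the printed K_D = 58 nM and t½ = 81 s within rounding; for the other rows
the printed half-lives are not ln2/k_off of their printed k_off (instrument
software may report a differently derived half-life), so only the
self-consistent row is used for verification. Cooperativity is
α = K_D(binary)/K_D(ternary), labelled positive (α > 1), negative (α < 1)
or neutral; α is scale-invariant in the two K_Ds.

Injection-series designs mirror the two assay formats: binary — 10-point
2-fold dilution (50 µM top in running buffer, from 50 mM DMSO stocks down
to ~98 µM stock ≙ ~98 nM running), 120 s contact / 180 s dissociation;
ternary — 2-fold from 1 µM to 62.5 nM, 400 s / 600 s. The stated "4-point"
ternary series with those endpoints spans four 2-fold steps, i.e. five
concentrations; the design honours the endpoints and emits five cycles.

## Synthetic data and what it does (not) show

The toy ligand is four collinear sp carbons with alternating 1.21/1.37 Å
bonds and a planar 6-atom ring at each end — the smallest rigid bodies that
give a well-conditioned superposition — placed at a seed-derived rigid pose.
The toy protein is a self-avoiding random walk of pseudo-residues
(backbone N/CA/C/O plus pseudo-sidechain carbons) with ≥ 2.6 Å spacing
between *all* atoms, so the cloud is free of self-clashes at the 2.4 Å
census cutoff; it is deliberately not covalently realistic (bonded
neighbours in a real protein sit at ~1.5 Å).

Planted scenes are constructed, not sampled: partner B carries a backbone
probe atom on a 20 Å-radius circle around the linker axis, and partner A
carries one blocking backbone atom at the probe's circle position for every
non-viable grid angle. The 10° chord at 20 Å is ≈ 3.49 Å > 2.4 Å, so each
blocker vetoes exactly its own angle. Posing partner B onto the conformer
at angle θ is, by construction, a rotation of B by θ about the axis, which
lets the generator verify the planted truth with an independent brute-force
distance census before returning; the screening pipeline must then
re-derive it via the full enumerate → superpose → count path. The whole
scene is finally moved by a seed-derived rigid transform so nothing is
axis-aligned when the pipeline sees it.

Passing on these scenes demonstrates the geometry, counting and decision
logic exactly; it does not demonstrate robustness to real-structure issues
(alternate conformations in the warhead, imperfect warhead/crystal-ligand
correspondence, accessory-chain choices), which is why the census toggles
and map files are explicit and reportable.

Sensorgram datasets derive per-cycle noise seeds from one master seed and
bundle their generating parameters; noisy recovery experiments in the tests
and the acceptance script use 2% of Rmax noise with the ternary timing.

## Numerical choices and problem sizes

Rigid transforms are validated to 1e-8 (orthonormality, unit determinant);
conformer rigidity is asserted to 1e-6 Å; PDB round-trips are exact at the
format's 3-decimal precision. Degenerate inputs fail loudly: empty
structures, zero-length axes, collinear point sets, < 3 map pairs,
non-divisor grid steps, non-positive cutoffs. Tests and the acceptance
script use desk-scale problem sizes chosen as the package's own defaults —
toy proteins of 4–8 residues, 36-conformer grids, 100-scene clash-census
comparisons, 5–20-frame trajectories, 20 kinetic replicates — which
exercise every code path in seconds.

## Known limitations

Single-torsion scans only (a multi-torsion linker needs an enumeration
strategy this package does not provide); no energetic scoring of viable
poses; the toy minimizer is not an MD engine; the 1:1 kinetic model cannot
represent two-state binding, surface heterogeneity or transport-limited
data; mmCIF, assemblies and sequence handling are out of scope.
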