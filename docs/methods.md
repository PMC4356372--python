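# Methods

This note records the models, numerical choices and known limitations of
`nucleofit`, module by module, in the order the pipeline runs.

## Crystallographic foundation (`crystal_maps`)

**Scattering model.** Atomic scattering is a single Gaussian per element,
f(s) = Z·exp(−B·s²/4) with B = b_overall + B_iso (default 20 + 20 Å²) and Z
the electron count (C 6, N 7, O 8, P 15). At the 2.5–4 Å resolutions this
package targets, any smooth peaked profile serves equally well; multi-term
form factors would change peak heights by a few percent without affecting
peak positions, which is all the downstream method consumes. Structure
factors are computed by direct summation over atoms and symmetry
operators; maps by inverse Fourier synthesis on a grid with spacing
≤ d_min/3 per axis (FFT, grid dimensions rounded up to fast even sizes).
Maps are normalized to zero mean and unit standard deviation; all density
thresholds downstream are therefore in σ units. Interpolation is trilinear
with periodic wrapping; its analytic gradient (piecewise constant per
cell) drives the refinement.

**Phase-bias simulator.** Acentric phases receive uniform noise
Δφ ~ U(−a, +a); the half-width is calibrated on the drawn sample so the
realized mean |Δφ| equals the target exactly (an uncalibrated draw misses
a ±1° window too often at small n). A fraction of centric phases is
inverted (180° flips), with the flip count chosen to keep the overall mean
on target — equivalently a flip probability of target/180. The figure of
merit is recomputed from the biased phases as ⟨cos Δφ⟩, unweighted (the
choice of unweighted means is deliberate; amplitude weighting would change
the third decimal). For uniform noise the analytic expectation is
FOM = sin(a)/a, giving 0.936/0.769/0.505 at target mean errors
18°/35°/54° — the canonical 0.92/0.75/0.50 levels within ±0.02. The
benchmark grid is 4 resolutions × 3 phase-error levels = 12 maps per
structure, each tagged with its realized FOM; per-map seeds derive from a
single integer seed through `numpy.random.SeedSequence`.

## Phosphate detection (`phosphate_detect`)

Peaks are local maxima ≥ 1σ, refined per axis by parabolic interpolation
(sub-voxel accuracy matters at 4 Å, where the voxel is 1.33 Å), then
greedily thinned so no two accepted peaks lie within 4.0 Å under lattice
translations and symmetry. Three descriptors per peak: (i) mean density
of voxels within 2.5 Å, rank-scaled so the strongest peak scores 1 and the
weakest 0 (ties by stronger-first ordering); (ii) the Pearson correlation
between trilinear samples at 50 antipodal direction pairs (deterministic
Fibonacci hemisphere) on a 1.56 Å sphere — +1 for centrosymmetric peaks,
negative for tetrahedral phosphate groups; (iii) the eigenvalue ratio
(λ₁−λ₃)/λ₂ of the density-weighted (values clipped at 0) moment-of-inertia
tensor of the 2.5 Å ball, ≤ 0 by construction, near 0 for isotropic peaks.
Descriptors (ii) and (iii) are min–max scaled per map onto (0, 1) so maps
of different quality are comparable.

The classifier is an RBF-kernel SVM; hyperparameters are selected from
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1} by stratified five-fold
cross-validation maximizing recall, with the positive class up-weighted
4:1, then refit on all data. Labels: a peak is positive when a reference
P atom (any symmetry mate, 27 neighbouring lattice shifts) lies within
1.5 Å. This deliberately yields an over-predicting detector — the
downstream matcher tolerates false positives but starves without true
ones. Measured per-peak descriptors carry grid-orientation noise of up to
~0.2 (in scaled units) at 2.5 Å; only their per-map statistics are stable,
which is why scaling is per map.

## Motif matching (`motif_match`)

All motif P-atom triplets with edges in [4, 25] Å (shorter edges do not
occur between phosphates; longer ones explode the candidate count) are
compared against target triplets whose three pairwise distances agree
within tol = threshold·√3 — the bound that cannot falsely dismiss any
triplet realizable at the RMSD threshold. Each correspondence proposes a
Kabsch transform, re-fit once on its matched pairs. Scoring pairs the
transformed pattern with targets greedily one-to-one within 2.0 Å and
requires at least max(3, 0.6·|M|) pairs; the RMSD over those pairs must
not exceed the active threshold. The 0.6 support fraction encodes the
method's central claim — a complete motif is placeable from a fraction of
the phosphates — while refusing placements supported by chance triangles.

Matching is sequential: at each threshold of the ascending schedule
{0.5, 0.75, 1.0} Å, the best remaining placement is accepted and its
matched points removed, until none remains. "Best" is lexicographic:
lowest RMSD, then the smallest summed distance of *unmatched* motif P
atoms to the full pre-consumption pattern (this keeps a shorter motif in
register with a longer planted helix instead of overhanging its end), then
the lowest consumed target index. Point sets larger than 1000 are first
split into boxes overlapping by the motif diameter, so no placement is
lost at a boundary.

## Model building (`builder`, `fiber`, `motifs`)

**Helix generator.** Nucleotides are assembled from standard planar base
geometries in the base-pair reference frame plus a stylized
sugar-phosphate backbone whose coordinates were solved numerically so the
phosphodiester chain closes exactly (O3′(i−1)–P(i) = 1.59 Å) under each
form's helical screw: A-form rise 2.81 Å / twist 32.7°, B-form 3.38 Å /
36.0° — canonical fiber-diffraction constants. Emergent geometry:
phosphate radius 9.2 Å, intra-strand P–P 5.89 Å (A) / 6.61 Å (B),
C1′–C1′ 10.8 Å, Watson–Crick N1–N3 3.0 Å. The geometry is idealized:
bases are exactly coplanar, the axis is straight, sugar puckers are
stylized, and A-form base-pair displacement/inclination is not modelled.
5′-terminal residues carry no phosphate.

**Loop motifs.** The bundled library (GNRA-type tetraloop, sarcin–ricin-
like loop, 2×2 internal loop) is synthetic: loop phosphates lie on a
Bézier arc closing the strand at ~6 Å P–P spacing, with each nucleotide
oriented so its chain direction follows the arc and its base points away
from the stem axis. The arc is expressed in the frame of the innermost
flanking pair, so loop geometry is independent of stem length — the
property that makes flank-superposition attachment exact. Real loops are
irregular; these stand-ins exercise the machinery, not loop biology.

**Placement and acceptance.** Per helix length (6, 4, 3 bp — the longest
pass first exploits long helical runs; the iterated shorter passes pick up
leftovers), matches are scored by the sum of interpolated map values over
atom centres; the ten best are refined; fragments with RSCC ≥ 0.5 are
accepted and consume their phosphates. RSCC is the Pearson correlation,
over voxels within 2.0 Å of the fragment's atoms, between the target map
and a model map synthesized with the same scattering model, resolution
cutoff and grid. Loop extension superposes each motif flanking pair onto
each stem terminal pair (both residue assignments), fine-tunes on ≥ 3
phosphate correspondences within 2.0 Å when available, refines the ten
best candidates, and emits individual nucleotides with RSCC > 0.6 that do
not duplicate an existing nucleotide (P, or C1′ for phosphate-free
residues, within 1.5 Å under symmetry). Emitting per nucleotide means
low-correlation fringe residues can enter the model; that is the intended
completeness-over-precision trade.

**Refinement.** A rigid-body pre-fit (Powell over 6 pose parameters
maximizing summed density) is followed by L-BFGS over all atom positions
of the objective [density − Σ k(d−d₀)²], with harmonic restraints:
covalent-range pairs (< 1.8 Å) at k = 150, 1–3 neighbour pairs (< 3.0 Å,
which also hold bases planar and rings rigid) at k = 10, and Watson–Crick
hydrogen bonds at 2.9 Å with k = 20 — units of (map σ)·Å⁻². Targets come
from the fragment's own idealized starting geometry. Convergence: 200
iterations or objective change < 1e-9 relative; if the optimizer fails to
improve, the best-so-far coordinates are returned. With these weights
bonded distances stay within 0.05 Å of ideal while a 1 Å misplacement is
pulled back to < 0.2 Å RMSD on a good 2.5 Å map.

**Isosteric variants.** For each W–C pair the two tested variants are G–C
and A–U (A–T for DNA) with the purine kept on the strand that carries it,
so the glycosidic orientation and C1′–C1′ distance are preserved; base
atoms are rebuilt from the standard frames via a Kabsch fit to the shared
frame atoms and the variant with the higher summed density over base atoms
wins (ties → G–C). Target sequence information is never used for base
assignment.

**Base-pair detection** is geometric: C1′–C1′ in [9.0, 11.5] Å, base-plane
angle < 30°, ≥ 2 polar-atom contacts < 3.4 Å; Watson–Crick when the bases
are complementary and every canonical W–C donor–acceptor pair is formed,
noncanonical otherwise. Noncanonical pairs contribute no H-bond restraints
(their geometry is held by the template restraints) — detection supplies
pair identity, which is all restraint generation needs.

## Validation (`validate`)

Three rules, each evaluated against the same symmetry image (operator
images × 27 lattice shifts) of a single reference residue: (1) P within
1.5 Å; (2) additionally C1′ within 1.0 Å; (3) additionally RMSD < 1.0 Å
over the base atoms present in both residues (the name-intersection rule
makes the published purine/pyrimidine list labelling immaterial; its
geometric consequence is that purine↔purine misassignments pass rule 3
while purine↔pyrimidine ones fail). Relaxed scores use rule 2, strict
scores rule 3. Assignment between built and reference residues is
one-to-one, greedy by ascending distance — on phosphate-like (sparse)
instances this equals the optimal assignment, verified against a
Hungarian-algorithm oracle. A built 5′-terminal nucleotide has no P atom;
its P condition is vacuous and placement rests on C1′. Precision is
correct/built, completeness correct/reference; `benchmark_curves`
aggregates means per (resolution, phase-error) cell.

## Synthetic benchmark and its scope

The benchmark suite plants one idealized motif (duplex of 6–10 bp, A or B
form, or an RNA stem-loop) per toy P1 cell at a uniformly random
orientation with ≥ 9 Å of solvent clearance. The detection benchmark
trains the SVM on three crystals and evaluates on five others (disjoint
seeds); the building benchmark runs the full pipeline on the simulated map
grid and validates against the planted truth. Problem sizes (5-crystal
suites, 16–20 nt structures, 20 000-reflection phase-statistics sets) keep
the whole suite in the minutes range while leaving the statistics stable
across seeds.

What these synthetic conditions do *not* emulate: protein components and
solvent (both degrade peak contrast and precision in real maps), crystal
packing contacts, non-P1 symmetry in the benchmark crystals (symmetry
handling is exercised by dedicated unit tests with explicit operator
sets), experimental noise in amplitudes, and irregular loop geometry.
Detection completeness near 100% at FOM 0.92 on these clean single-motif
cells is therefore an upper bound on real-map behaviour, and passing
benchmarks demonstrate correctness of the machinery and the direction of
quality trends (completeness degrades monotonically with FOM), not
real-data performance levels.

## Known limitations

- Single-stranded regions between motifs are not traced; only recurrent
  motifs (helices, library loops) are built.
- The motif library shipped is synthetic and minimal; users supply real
  fragment libraries as PDB + JSON sidecar directories.
- The scattering model ignores solvent and anisotropy; B-factors are
  uniform per element in practice.
- Space-group support is P1 plus explicit operator lists; symbols are
  parsed only at the I/O boundary (gemmi).
- Sequential matching with point consumption is greedy: an early accepted
  placement can shadow a better overlapping one. The density-scored top-10
  refinement stage mitigates but does not eliminate this.
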