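# Methods

This note documents the models, statistics and numerical choices behind
`perturbtrace`, and what its synthetic-data tests do and do not establish
about real imaging screens.

## The measurement model

The package analyses an image-based pooled CRISPR screen in which every
cell carries one sgRNA paired with a unique ternary RNA barcode, read out
in situ over ten sequential three-color FISH rounds, while highly
multiplexed DNA FISH (chromatin tracing) localizes the central 100-kb
regions of the 27 TADs of chromosome 22 in the same cell. The pipeline
starts downstream of image processing: its inputs are per-round/channel
barcode intensities, called 3D spot positions per chromosome copy, and
segmented nuclear voxel masks.

## Barcode codec

A barcode is ten ternary digits, so the design space holds 3^10 = 59,049
codes; at the DNA level each digit is a 41-nt segment (two 20-nt
hybridization sequences joined by a 1-nt spacer) and digits are separated
by a single `C`, giving a 419-nt body. Each (digit, value) pair owns one
linear and one padlock probe — 60 probes for the default design — and the
three values of a digit report in three distinct fluorophore channels.

**Trit calling.** Per round, the called value is the channel of maximal
intensity; the confidence is the top-to-second intensity ratio and digits
below `min_ratio` (default 2.0) are left uncalled. This is the simplest
defensible reduction of a three-channel readout; it is an artifact of this
package, not a published algorithm.

**Decoding policy.** A fully called code matching a known ambiguous
("bad") code is rejected outright — ambiguity safety precedes error
correction. An exact good match assigns with zero corrections. Otherwise
all good codes within trit distance `max_correction` (default 1) are
collected, with uncalled digits acting as free wildcards: a unique
candidate assigns, several reject as ambiguous, none as no-match. The
search is over the sorted codebook, so results are independent of
iteration order. With a codebook of minimum pairwise distance ≥ 3 (the
package provides a ternary [10, 7, 3] Hamming-style construction whose
parity-check columns are distinct projective points of GF(3)^3), radius-1
decoding provably corrects every single-digit miscall; the randomly
bottlenecked 420-code libraries used in practice have much larger typical
pairwise distances, so radius-1 correction is safe there too.

## Codebook construction

Because one sequencing read cannot span the sgRNA–barcode–UMI cassette,
two read tables are joined on their shared 20-nt UMI. Barcodes arrive as
two end-anchored partial codes; they assemble only if they overlap by at
least one digit and agree on the overlap. A code is *good* when exactly
one sgRNA supports it with at least `min_reads` (default 2) UMI-distinct
associations, *bad* when two or more do; the threshold suppresses
singleton chimeras from PCR or UMI collisions. A UMI carrying several
payloads emits every combination, so collisions and template switching
propagate into the bad-code class rather than silently corrupting the
good class. Dropout is reported as (designed − detected)/designed over
good-code sgRNAs, rounded to one decimal for reporting.

## Trace phenotypes

Traces are (27, 3) nm coordinate arrays with missing targets as NaN; all
metrics use pair-level deletion, which is unbiased for frequency ratios.
Traces with under 60% observed targets are dropped from population
statistics (configurable).

- **Contacts.** Two TADs with genomic index separation ≥ 2 are in contact
  when their distance is strictly below 500 nm (both knobs configurable).
  Long-range contacts are classed AA/AB/BB by the compartment labels of
  their endpoints, and per-trace class frequencies are the per-category
  contact fractions. Frequencies are computed per trace and compared
  across traces (matching figure legends that count traces); pooling
  pairs per perturbation is a noted alternative we did not adopt.
- **Radius of gyration** is the RMS distance of observed targets from
  their centroid.
- **Polarization index.** PI = sqrt((1 − Vs/Va)(1 − Vs/Vb)), where Va and
  Vb are convex-hull volumes of the A and B target positions and Vs their
  intersection volume; 1 means fully segregated hulls, 0 that one hull
  lies inside the other. The formula follows the chromatin-tracing
  literature this assay builds on (it is not restated in the screen
  itself). The hull intersection is computed exactly: the two halfspace
  systems are stacked, a Chebyshev-center linear program finds an interior
  point (none ⇒ Vs = 0), and `HalfspaceIntersection` plus a hull of the
  intersection vertices gives the volume. Compartments with fewer than 4
  observed, non-coplanar points return NaN. Scrambled controls permute
  compartment labels across TADs preserving the A:B count.

## Screen statistics

Per sgRNA, five chromatin phenotypes are summarized against the pooled
non-targeting controls: adjacent-TAD distance (26 pairs), the three
compartmental contact frequencies, and overall inter-TAD distance (351
pairs).

- **Distance phenotypes** use a two-sided Wilcoxon signed-rank test
  pairing the per-TAD-pair median distances of the two groups; log2fc is
  the mean per-pair log2 ratio of medians. Pairs observed in fewer than 5
  traces in either group are dropped; fewer than 6 usable pairs flags the
  test as insufficient.
- **Contact phenotypes** use a two-sided Wilcoxon rank-sum
  (Mann–Whitney, exact at small n) over per-trace frequencies; log2fc of
  group means uses a 1e-3 pseudocount.
- **FDR** is Benjamini–Hochberg per phenotype across perturbations (one
  family per volcano panel). The **z score** is (perturbation mean −
  control mean)/control SD of the per-trace (or per-cell) summary.
- **Hits** require FDR < 0.1 and |log2fc| ≥ 0.05, ranked by |log2fc|,
  never including controls. The effect floor is this package's own
  default, not a published value.

**A caveat worth stating plainly.** Pairing by TAD pair is
pseudo-replicated: the 351 pair medians of one group share the same
traces, so a chance ensemble-level size fluctuation shifts all pairs the
same way and the signed-rank p-value saturates even under the null. The
p-value therefore orders evidence but does not calibrate it; the effect
floor carries the false-positive control. In all-null simulations the
null |log2fc| of a 100-trace group reaches ~0.05–0.07 at its extreme,
i.e. the floor sits at the noise level for very small groups, while at
the 250+ traces per group typical of this screen's pooled analyses the
null tops out well under the floor. Parameter-recovery tests are run at
250 traces/group for this reason. A per-trace bootstrap would calibrate
the p-value properly and is the natural alternative pairing unit.

Correlation analyses (effect-matrix vs effect-matrix, vs the (s_i+s_j)/2
average compartment-score matrix, short-range/long-range splits at 3 Mb
of genomic midpoint separation, and the cross-feature matrix over hits)
use Pearson r over paired non-missing upper-triangle entries, a two-sided
t-test, and Fisher-z 95% intervals. Hit clustering uses 1 − r distances
and average linkage with inputs sorted by sgRNA id for determinism;
zero-variance matrices are excluded with a warning.

## Nuclear morphometrics

COV is SD/mean of in-mask voxel intensities (scale-invariant). Sphericity
is Ψ = π^(1/3)(6V)^(2/3)/A with V the voxel volume and A the area of a
marching-cubes mesh, computed after nearest-neighbor resampling of the
(typically anisotropic) grid to its finest lateral spacing. The binary
field is smoothed with a σ = 0.8 voxel Gaussian before meshing: raw
binary marching cubes overestimates a sphere's area by ~8% (staircase
effect), while the smoothed mesh reads a radius-30 sphere at Ψ ≈ 0.995
and convex polyhedra within ~0.03 of their closed forms (digitized cube:
0.834 vs 0.806 analytic; the stated mesh tolerance for closed-form checks
is 0.035 and 0.02 for rotation/scale invariance). Voxel-face area
counting was rejected as it overestimates A much more severely. Whether
to measure 3D meshes or a 2D projection proxy was an open choice; we
compute fully 3D.

## Polymer model

A minimal bead-spring chain links chromatin self-interaction to envelope
shape: harmonic bonds (k = 50, rest length 1), a hard core at 0.8, and a
square well of depth K (k_B T = 1) within radius 1.8. Defaults: 100
beads, 3,000 sweeps of single-bead displacements (step ±0.15/axis) plus
4 pivot moves per sweep, seeded Metropolis throughout; every parameter is
config-overridable. These are this package's choices — chain length, move
set and envelope construction are not published for the original
simulation; only the K ladder (1, 0.4, 0.1), N = 100 conformations per
energy, and the direction of the sphericity trend are anchored. The
chain starts from a compact serpentine lattice walk: attractive chains
then begin near the globule state and weak ones expand quickly, whereas
collapse from an extended rod can trap pearl-necklace intermediates
(observed in development as a bimodal Rg at K = 1). At these settings
K = 1/0.4/0.1 equilibrate to Rg ≈ 1.6/2.0/5 and the three regimes are
cleanly separated.

The bounding envelope is the union of probe-radius (default 1.0) spheres
around the beads, voxelized on an isotropic grid (64 voxels across the
padded bounding box) and scored with the same Ψ code path as nuclei — a
convex hull cannot be multi-lobed, which is the whole point of the
comparison. Energy bookkeeping is incremental with a from-scratch
recomputation check; with K = 0 and no excluded volume the bond-length
distribution matches the closed form r² exp(−k(r−r0)²/2) (KS-tested),
and with K = 0 the Rg² vs length slope exceeds the ideal-chain linear
law, consistent with self-avoiding-walk swelling (the test accepts a
widened 1.05–1.5 band because a 30-replicate, 3-length regression of a
fluctuating quantity cannot pin the 1.18 exponent).

## Synthetic screen generator

The generator defines the study conditions for every test. The library
reproduces the screen design (410 targeting sgRNAs over 137 genes at 2–3
per gene plus 10 non-targeting controls; codes sampled without
replacement from the 59,049-code space), with optional planted dropout
and planted code collisions. Read tables emit a configurable number of
UMIs per association (default 12, echoing deep coverage of the library)
and an optional UMI collision rate.

Baseline traces mix three nm-scale ingredients: two compartment anchor
points 600 nm apart (A targets scatter about one, B about the other, SD
120 nm), a random-walk backbone (per-axis step SD 150 nm, weight 0.7),
and 50 nm localization jitter, with TAD dropout applied last. These
values were chosen once to give adjacent-TAD distances of ~400–700 nm,
long-range contact frequencies well inside (0, 1) at the 500-nm rule,
polarized compartments, and Rg near the observed hundreds-of-nm scale.
Perturbation effects act on the matching geometry: `global` scales the
trace about its centroid, `aa`/`bb` scale a compartment about its own
centroid, `ab` scales the anchor separation, and `adjacent` scales the
local displacement terms. Barcode readouts give the true value's channel
a lognormal signal (median ≈ 1,200) over lognormal background (median ≈
60); a corrupted round either moves the signal to a wrong channel
(confident miscall, 2/3 of corruptions) or attenuates it 12.5-fold (digit
left uncalled). Nuclear phantoms are ellipsoids (semi-axes 3.0 × 4.2 ×
4.2 µm, ±5% per-cell variation) on a 400 × 216 × 216 nm voxel grid;
negative sphericity offsets split them into two lobes, and bright
Gaussian condensates (default 5 per nucleus) set the COV level.

What the generator does **not** emulate: optical PSFs and chromatic
shifts, Hi-C-derived baseline conformations, segmentation errors,
knockout-efficiency mosaicism, PCR bias, or indels in sequencing. Passing
tests therefore demonstrate that the statistics recover planted effects
under this idealized noise model at desk scale — not that the pipeline's
power matches the 57,286-trace screen.

## Problem sizes and determinism

The flagship integration run uses 60 sgRNAs (10 non-targeting) × 120
cells with 2–4 traces per cell (≈21,600 traces) and nuclear phantoms for
a 25-cell subset per sgRNA, with six planted effects (global ×0.8 twice,
×1.25 twice, one lobed-nucleus, one condensate-free); null calibration
uses 20 replicate screens of 20 sgRNAs × 60 cells with chromatin
phenotypes only. These sizes are the package's chosen desk-scale stand-in
for the published screen (17,304 cells / 57,286 traces). Everything is a
pure function of (config, seed): generators use `numpy` Generators
seeded explicitly, and the polymer kernel derives per-replicate seeds
from a `SeedSequence`. G1 gating is modeled as a pre-applied cell filter;
Geminin imaging is not simulated.

## Known limitations

- The published error-correction rule and digit-confidence threshold live
  in supplementary methods not available here; the decode policy above is
  a stated stand-in and is flagged as such.
- The signed-rank p-value pseudo-replication discussed above.
- Sphericity carries a small positive mesh bias on sharp-cornered shapes
  (≤ ~0.03); comparisons between groups measured identically are
  unaffected.
- `log2fc` matrices use medians, so perturbations acting purely on
  distance tails are invisible by design.
- Gene-level aggregation across sgRNAs is out of scope; results are
  per-sgRNA.
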