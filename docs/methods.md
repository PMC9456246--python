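# Methods

This note documents the models, parameter choices and numerical
conventions of `breakfish`, and states precisely what the synthetic-data
benchmarks do and do not demonstrate.

## 1. Image model and detection chain

A field is a 3- or 4-channel confocal z-stack: DNA counterstain, two
break-apart probe channels, and optionally a whole-chromosome paint.
All arrays are indexed `(z, y, x)`; all physical quantities are in nm
and honour anisotropic voxel spacing `(dz, dy, dx)` — axial spacing is
typically 2–4× the lateral spacing and every distance computation uses
the per-axis scale.

**Despeckling.** A 1×1×3 median filter along z (edge planes replicated)
removes isolated single-plane hot voxels. The output range is contained
in the input range; any speckle flanked by dimmer z-neighbours is
suppressed. Applied to every channel before detection.

**Nucleus detection.** Cultured cells flattened on a coverslip present
nuclei that are well approximated by a cylinder with axis along the
optical (z) axis — the only orientation that is stable under the strong
z-anisotropy. Detection is iterative on the Gaussian-blurred (σ = 1
voxel) counterstain: the global brightest voxel seeds a cylinder fit;
the fitted cylinder is zeroed; the loop repeats until the next seed is
dimmer than `stop_fraction` (default 0.3) of the initial global
maximum. Voxel-count thresholds (default 10³–10⁶) discard degenerate
fits. Ties among equal-brightness voxels are broken in lexicographic
`(z, y, x)` order, making the whole chain RNG-free and deterministic.

**Cylinder objective.** Raw total in-cylinder brightness grows without
bound with volume, so the fitted objective is

    mean in-cylinder brightness × volume^β,  β = 0.5 by default,

a density-biased compromise (β = 1 recovers raw total brightness,
β = 0 pure density). Three numerical choices matter:

* the *volume term counts the full, unclipped cylinder* even when part
  of it leaves the field; otherwise sliding the model off the field
  edge clips the disc and spuriously inflates density;
* optimization is coordinate-wise finite-difference ascent: continuous
  steps on `(cy, cx, r)` with step halving from 2 voxels down to 10⁻³
  (radius clamped to [1.5, 50] voxels), integer steps on the z-bounds;
  at most 200 sweeps;
* a fit whose interior density does not exceed `min_contrast` (default
  2×) times the mean of the *nonzero* voxels outside it is flagged
  unstable: this catches both the translation-degenerate uniform-image
  case and background artifacts seeded by residual noise. Unstable
  fits are discarded and only a small neighbourhood of their seed is
  cleared, so one degenerate fit cannot erase the rest of the field.

After a stable fit, a slightly dilated cylinder (radius + 2 voxels,
z ± 1 plane) is zeroed so that blurred rims cannot re-seed the loop.

**Locus and territory detection.** Within each nucleus cylinder the
top-k brightest voxels of a channel are selected (k tie-trimmed
lexicographically) and partitioned into connected components
(26-connectivity by default), followed by a voxel-count filter.
Territory channels are first Gaussian-blurred (σ = 1). Defaults: the
`detect_objects` function uses k = 300 (loci) / 3000 (territories); the
*pipeline configuration* defaults to k = 80 for loci, matched to the
~40 voxels a diffraction-limited spot occupies at the default geometry
so that the selection never dips into the noise floor (size filters:
loci 3–500, territories 100–50 000 voxels). Both are ordinary config
keys; on other optics a user should set k to roughly (expected voxels
per signal) × (signals per nucleus).

## 2. Allele metrics

**Centroids.** Each signal is the brightness-weighted centre of mass of
its component, in nm.

**Pairing.** Cross-channel signals are paired by greedy mutual-nearest-
neighbour extraction: repeatedly take the globally closest
(probe-1, probe-2) pair and remove both. The output is symmetric in the
channel labels and partitions the input; on well-separated alleles it
coincides with the exhaustive minimum-total-distance matching (tested
by enumeration). When *both* alleles of one nucleus are broken, the
cross-pairings can be closer than the true ones and the cell is then
usually rejected by the distance cutoff — a known limitation shared
with any nearest-neighbour pairing; at realistic break rates (a few
percent) the double-break configuration is rare.

**Cell QC.** A cell is retained iff it has exactly two signals per
probe channel, one or two territories (two territories may merge into
one connected component), and both pairs survive the cutoff. Pairs are
removed when the pair distance exceeds 2000 nm (strict `>`) or either
signal lies more than 2000 nm from the territory boundary — such
configurations are recognition errors far more often than biology.
The cutoff is configurable; note it also censors genuinely
far-separated broken ends, so the measured broken fraction is a lower
bound near the cutoff.

**Signed territory distance.** Boundary voxels are object voxels with
at least one non-member *face* (6-)neighbour. Face connectivity keeps
the crust one axis-step thick; a diagonal (26-neighbour) definition
interacts badly with anisotropic voxels — a member whose z-diagonal
neighbour pokes out can sit a full voxel diagonal inside the surface —
and biases inside distances low by several hundred nm. The distance is
measured to the plane through the three nearest boundary-voxel centres;
the sign is negative iff the rounded voxel index of the point belongs
to the territory (membership, robust to concave territories). The
plane is a refinement of the nearest-boundary-point distance (it
removes the lateral quantization offset); it is trusted only when it
agrees with that distance within 0.25 voxel diagonals, otherwise the
triple is a quantization artifact (collinear, lattice-plane, or secant
through a curved surface) and the nearest-point distance — itself
accurate to ~0.5 diagonals — is used. With this guard the measured
distance stays within one voxel diagonal of the analytic value on
voxelized spheres at the default geometry. When a cell has two
territories, each locus is scored against the nearest one.

## 3. Break statistics

* **Threshold**: linear-interpolation quantile (the common default
  estimator) of the control pair distances, q = 0.99. At least 10
  control values are required.
* **Call**: broken iff distance strictly exceeds the threshold;
  boundary equality is intact (the threshold is itself a control
  value).
* **Tail test**: plug-in σ = √(P\*(1−P\*)), x = kσ/√n with k = 3
  (confidence 0.997); significant iff P\* − x > 0. The margin is
  strictly increasing in n for fixed P\* > 0.
* **Territory association**: Pearson chi-square on the 2×2
  broken/intact × outside/inside table, df = 1, no Yates correction
  (sample sizes are large; the correction is available via
  `scipy.stats.chi2_contingency(correction=True)` if wanted). An
  allele counts as "outside" when either of its two signals has a
  positive signed territory distance. The fold is the ratio of
  outside proportions between the two rows.
* **Mann–Whitney**: exact null distribution for tie-free samples with
  min group size ≤ 8, tie-corrected normal approximation otherwise.

## 4. 4C-seq computation

Coordinates are 0-based half-open throughout; BED is native, 1-based
appears only in report formatting.

* **Digestion**: cut at `site start + offset` for every (possibly
  overlapping) motif occurrence; HindIII A^AGCTT → offset 1, DpnII
  ^GATC → offset 0. Fragments tile each chromosome exactly (asserted
  on every counting run). DpnII is only the circularization point of
  the synthetic read generator; counting is HindIII-fragment based.
* **Demultiplexing**: a read is kept iff the ligation-site motif occurs
  at position ≥ 1 and the prefix before the first occurrence begins
  with exactly one anchor primer (primers must be mutually non-prefix);
  rejections are logged as no-site / unknown-anchor / ambiguous, and
  classified + rejected = total (read conservation, asserted in tests).
* **Mapping**: a capture maps iff its 20-bp prefix occurs exactly once
  genome-wide over both strands (a packed 2-bit k-mer index backs the
  search). The reported position is the capture's 5′ base on the plus
  strand; minus-strand hits therefore report the right edge of the
  match. This emulates "uniquely mapped reads" for synthetic genomes;
  externally produced alignments can be imported as
  (chrom, position, strand) triples instead.
* **Counting**: plus-strand positions within 4 bp of a fragment start
  and minus-strand positions within 4 bp of `end − 1` increment the
  fragment; left- and right-end counts sum into the raw signal;
  everything else is an end-miss (logged). The bait fragment and one
  neighbour on each side are masked by default (self-ligation and
  undigested products dominate them); `mask_flank=-1` disables masking.
* **Profiles**: non-overlapping windows (500 kb) from coordinate 0;
  a fragment belongs to the window containing its midpoint and
  contributes 1 when raw ≥ 1. Fragment-level counting (not read-level)
  de-weights PCR amplification of single ligation products.
* **Merging**: each replicate scaled to 10⁶ assigned reads, merged
  normalized signal is the mean; the merged raw count is the pooled sum
  so that contact-bearing status reflects the union of replicates.
  The reported replicate correlation is the Pearson r of per-window
  profiles (mean over pairs if > 2 replicates; degenerate
  constant/single-window profiles compare by equality).
* **Trans fraction**: share of contact-bearing *fragments* on non-bait
  chromosomes, consistent with the window definition. Note this is a
  fragment-level quantity: with a cis-concentrated decay profile it is
  much larger than the read-level trans share.
* **Enrichment**: per-gene signal is the sum of window values over
  windows overlapping the gene (window level, default) or the count of
  contact-bearing fragments with midpoint inside the gene
  (`level="fragment"`); partner genes vs all other non-bait genes by
  Mann–Whitney, two-sided by default.

## 5. Synthetic data: what it emulates and what it does not

The generator renders the acquisition geometry of the imaging protocol
at a scaled-down default of 256×256×20 voxels, (dz, dy, dx) =
(400, 200, 200) nm — full 1024×1024 fields and 400–800 nm z-steps are
supported via the geometry config. Per stack: 10 nuclei as bright
cylinders (radius 3 µm, height 4.8 µm, brightness 1000), two alleles
per nucleus, two spherical territories (radius 1.4 µm, amplitude 600,
rendered then blurred 1.5 voxels; centres ≥ 1.2 µm apart, so
territories often merge — as real paint signals do). Spots are
isotropic Gaussians of σ = 250 nm and amplitude 8000. σ was chosen so
that a spot spans at least two z-planes at the default z-step: a
single-plane spot is indistinguishable from the very speckles the
1×1×3 median filter is designed to remove, and σ = 250 nm is within
the size range of BAC-probe signals under a confocal PSF. Noise is a
background offset of 100 plus Gaussian noise (sd 50, "moderate noise")
plus Bernoulli single-voxel speckles (rate 10⁻⁴, amplitude 4000) that
specifically exercise the despeckler.

Intact intra-allele separations are gamma(k = 4, θ = 75) nm (mean
300 nm, a realistic inter-probe distance for probes flanking a ~0.5 Mb
region), truncated at the generator's break distance of 1000 nm;
broken alleles add a 1500 nm shift. Break flags are Bernoulli draws per
allele; a locus is planted outside the territories (but always inside
the nucleus) with probability `outside_fraction`. Placement constraints
(anchors ≥ 2 µm apart, same-channel signals ≥ 1.5 µm apart, 3-voxel
lateral margins) are satisfied by seeded rejection sampling with
whole-set retries, so generation is deterministic per seed.

The 4C generator draws 3 random chromosomes of 1 Mb (natural HindIII
density ≈ 1 site / 4 kb), designs a 20-bp anchor primer immediately
upstream of a HindIII site near the middle of the bait chromosome
(unique genome-wide, no site overlap at the junction), and emits reads
`primer + AAGCTT + 40 bp fragment-end prefix`. Targets follow
cis-decay (1 + d)^(−α), α = 1, with a uniform trans floor of 0.05;
10% junk reads (constructed to fail parsing) are appended, and reads
are shuffled per replicate (2 replicates by default). Only fragments
whose end prefixes are unique genome-wide are sampled, so the counting
path can be held to *exact* recovery of the planted counts.

**Not emulated**: PSF anisotropy and photobleaching, chromatic
aberration, nucleus shape irregularity, autofluorescence structure;
sequencing errors, PCR duplicates, undigested/self-ligated products
(the generator never plants reads on the bait or its neighbours), and
the biological contact structure of a real genome (domains,
compartments). Passing benchmarks therefore demonstrate the
correctness and calibration of the *computation* — detection, pairing,
distances, counting, statistics — under the stated image and read
models, not detection performance on real microscopes or aligners.

## 6. Problem sizes used by the test suite and reproduction script

Detection recovery runs 20 noisy stacks (plus 3 noise-free) at the
default geometry — 800 planted loci; the signed-distance check uses 500
points against a voxelized sphere; break calling uses cohorts of 2000
alleles with a planted 3% break rate; 4C exactness uses the default
3 × 1 Mb genome with 10⁴ reads per replicate; the enrichment
calibration runs 500 null simulations (120 genes, 20 random partners,
i.i.d. fragment contacts, exchangeable labels). These sizes give
tight-enough Monte-Carlo error for every asserted tolerance while the
whole suite stays in the one-minute range.

## 7. Known limitations

* Mutual-NN pairing can cross-pair doubly-broken nuclei (§2).
* The 2000 nm cutoff censors extreme break separations.
* Fixed top-k selection assumes approximately known signal size; a
  grossly mis-set k either splits signals or admits noise components
  (mitigated, not eliminated, by the size filter).
* The cylinder model under-fits lobed or tilted nuclei.
* The exact mapper is for synthetic genomes; real data should be
  aligned externally and imported.
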