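# breakfish

Quantification of double-strand-break mobility from **break-apart 3D FISH**
z-stacks, and genome-wide contact profiling of the broken loci by
**viewpoint-based 4C-seq** — the two measurements used to ask whether
recurrent leukemia translocations arise from pre-existing spatial proximity
of the partner genes or from the wandering of broken DNA ends.

## Who this is for

Groups doing confocal 3D-FISH on interphase nuclei with a dual-color
break-apart probe (two fluorophores flanking a gene of interest, e.g.
*AML1*/*RUNX1*) plus a whole-chromosome paint, who want automated,
reproducible detection and distance statistics instead of manual scoring;
and groups running 4C-seq who need the fragment-level counting path
(digestion → demultiplexing → fragment-end counts → windowed profiles →
partner-gene enrichment). Every stage is exercised end to end on synthetic
data with known ground truth, so the whole chain is testable without any
microscope or sequencer.

## The measurements

**Break calling.** Each nucleus is detected as a cylinder (axis along the
optical axis) fitted to the DNA counterstain by maximizing in-cylinder
brightness density. Within each nucleus, the top-*k* brightest voxels of
each probe channel form connected components — the FISH signals — and each
signal is reduced to its brightness-weighted centroid
*c* = Σᵢ wᵢ xᵢ / Σᵢ wᵢ in physical nm. Signals of the two colors are paired
into alleles by mutual nearest neighbors. With control (untreated) cells
defining the distribution of intra-allele pair distances *d*, the break
threshold is the 99th quantile *q₀.₉₉(d_control)*; an allele in a treated
cohort is called **broken** when *d > q₀.₉₉*. By construction ~1% of control
alleles exceed the threshold, so the quantity of interest is the excess over
that floor.

**Tail significance.** For an observed tail proportion *P\** out of *n*
alleles, σ = √(P\*(1−P\*)) and x = 3σ/√n; the tail carries strictly positive
probability mass (confidence 0.997) when *P\** − x > 0.

**Territory localization.** The signed distance from a locus centroid to the
chromosome-territory boundary is the distance to the plane through the three
nearest territory boundary voxels, positive outside the territory and
negative inside. A 2×2 chi-square (no continuity correction) tests whether
broken alleles sit outside the territory more often than intact ones.

**4C-seq.** The genome is digested in silico at HindIII sites (A^AGCTT);
reads of the form `primer + AAGCTT + capture` are demultiplexed by anchor
primer, captures are mapped by unique exact occurrence, and a read within
4 bp of a fragment end increments that fragment. Profiles count fragments
with ≥ 1 contact per 500-kb window; replicates are normalized to a common
library size and merged; the trans-contact fraction and a Mann–Whitney
enrichment test over translocation-partner genes complete the analysis.

## Worked example

```python
from breakfish.synth import FishLayout, make_fish_stack
from breakfish.pipeline import run_fish_pipeline
from breakfish.config import RunConfig

control = FishLayout(n_nuclei=10)
treated = FishLayout(n_nuclei=10, broken_fraction=0.05, outside_fraction=0.1)
sets  = [("control",   make_fish_stack(layout=control, seed=s)[0]) for s in range(3)]
sets += [("etoposide", make_fish_stack(layout=treated, seed=100 + s)[0]) for s in range(3)]
result = run_fish_pipeline(sets, RunConfig())
print(round(result.threshold_nm, 1))
print(result.stats["conditions"])
```

prints (60 control and 60 treated alleles, all 60 cells passing QC):

```
815.9
{'control':   {'n_alleles': 60, 'broken_fraction': 0.0167, 'tail_margin': -0.0329, 'tail_significant': False},
 'etoposide': {'n_alleles': 60, 'broken_fraction': 0.05,   'tail_margin': -0.0344, 'tail_significant': False}}
```

The break threshold (815.9 nm) is the 99th quantile of the 60 control pair
distances. The treated cohort shows 5% broken alleles versus 1.7% in the
control — the planted 5% break rate is recovered on top of the ~1% false
positive floor — but at n = 60 the three-sigma tail margin is still
negative: a cohort this small cannot certify the tail, which is exactly why
the assay needs thousands of alleles (at n = 2000 the same proportions are
highly significant; see `breakfish.break_stats.tail_test`).

Command-line equivalents: `breakfish simulate|segment|measure|stats` and
`fourc simulate|digest|demux|count|profile|enrich` (see `--help` on each).

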