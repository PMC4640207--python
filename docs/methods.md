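# Methods

This note documents the models, parameter choices and numerical conventions
behind `famcna`, and what the synthetic-data experiments do and do not show.

## Admixture model

A specimen is a mixture of tumour cells (fraction `purity`) and diploid
non-tumour cells, a configurable share of which are lymphocytes
(`til_fraction`, the lymphocyte fraction of the *non-tumour* compartment; a
sample is "high TIL" when it exceeds 0.5).  For a locus with `c` copies in
the tumour cells,

* population copy number: `purity·c + (1−purity)·2`; noise-free log2 ratio
  `log2(mix/2)`;
* B-allele frequency with `b` tumour B copies and germline B count
  `g ∈ {0,1,2}`: `(purity·b + (1−purity)·g) / (purity·c + (1−purity)·2)`.
  A zero denominator (pure tumour over a homozygous deletion) carries no
  DNA; the observed BAF is resampled uniformly on [0, 1].

Two closed-form consequences anchor the test suite: the diploid state is a
fixed point of the mixing at any purity, and a noise-free hemizygous
deletion at a germline-het marker has mBAF `1/(2−p)`, which crosses the LOH
threshold 0.76 exactly at `p = 2 − 1/0.76 ≈ 0.6842`.

## Synthetic cohort

The generator emulates the study design end to end.  Defaults (all
configurable):

| parameter | default | rationale |
|---|---|---|
| markers per chromosome (1–22, X) | 500 | whole-chromosome events carry ≥ 100 informative het markers for the LOH window; desk-scale runtime |
| reference cohort | 90 diploid females | baseline size used for the log2-ratio denominator |
| group sizes | 14+3 CHEK2, 34+15 BRCAX, 47 BRCA1, 7 BRCA2 | 120-sample cohort; 14/17 and 34/49 low/high-TIL splits in the two compared classes |
| log2-ratio noise sd | 0.15 | typical SNP-array marker noise |
| BAF noise sd | 0.03 | keeps the het band well separated from homozygotes |
| het fraction | 0.30 | marker informativeness (free parameter; arrays vary) |
| GC / fragment-length wave sd | 0.2 / 0.1 | per-sample covariate waves for the correction step to remove |
| purity | U(0.5, 0.9) low-TIL, U(0.2, 0.5) high-TIL | TIL-rich specimens are impurer |
| til_fraction | U(0.05, 0.45) low, U(0.55, 0.95) high | two strata around the 0.5 cutoff |

Planted events are whole-arm gains (3 copies) and losses (1 copy, B lost)
plus one focal high-level amplification (10 copies, 10 % of chromosome 17).
Luminal tumours carry the classic 1q+/8q+/16p+/8p−/16q− profile with
probability 0.5 (0.3 if high-TIL); basal-like tumours carry 3q+/5q−.
Class-differential events are planted at fixed counts among low-TIL tumours:
1p loss in 6/14 CHEK2 vs 2/34 BRCAX, chromosome-22 loss in 1/2 vs 1/4, and
the focal 17q amplification in 6/14 CHEK2 only.  Chromosome X is simulated
diploid (female cohort).  Events of one sample never overlap; every event,
purity and TIL fraction is recorded as ground truth.

The expression matrix (default 2000 genes, noise sd 0.25 log2 units) has
three planted layers: 100 immune-signature genes shifted by
`3.0 · til_fraction · sd` — per-gene effects vary (× U(0.5, 1.5)) and half
the genes move *down* with infiltration, because a correlation distance
between gene-standardized sample profiles is blind to a signature whose
genes all shift identically (the shift is a per-sample constant that the
correlation removes); with the default TIL strata the realised
between-stratum contrast is 1.5 sd.  100 intrinsic genes separate luminal
from basal (±0.5 log2); 6 genes are shifted up in CHEK2 by 1.26 log2
(linear fold-change 2.4, the largest planted difference).

## Copy-number pipeline

Log2 ratios use the per-marker **median** of the reference cohort (robust
to outlying reference samples).  Covariate correction is a per-sample OLS of
the ratio on GC fraction and log fragment length; the fitted component is
subtracted and the pre-fit mean restored, so only covariate-tracking
variation is removed.  The model form is a pragmatic choice; wave artefacts
in real arrays can be non-linear.

Segmentation is recursive binary splitting: the split maximising the
two-sample pooled-variance *t* statistic is accepted iff (a) two-sided
*p* < 1e−4, (b) both sides hold ≥ 20 markers (100 for mBAF), and
(c) |Δmean| / pooled within-segment SD ≥ 0.45; accepted splits recurse.
Ties in the *t* landscape break to the lowest index.  Differences and pooled
variances below `1e−10 · max(1, max|x|)` are treated as exactly zero —
without this guard, rounding noise in cumulative sums manufactures
"significant" splits inside constant (e.g. mean-substituted) segments.
With the guard, re-segmenting the fitted step signal reproduces the same
breakpoints.

State calls: copy number `2·2^m` from the segment mean `m`; neutral on the
inclusive band [1.75, 2.25], amplification strictly above 6, loss below
1.75, gain otherwise.  The estimate is rounded at 1e−9 copies before
thresholding so printed boundary values survive the log2/exp2 round trip.

**Power limits.** Changepoint localisation within ±2 markers requires a
jump-to-noise ratio ≥ ~2; at ratio 1 the argmax error distribution of any
estimator puts only ~60–75 % of mass within ±2 markers.  Likewise an
interior low-amplitude event occupying a small fraction of a chromosome
dilutes the first binary split below the *p* < 1e−4 bar.  The cohort's own
events — arm-level (telomeric) at purity ≥ 0.5, hence ratio ≥ 2.1, and
high-amplitude focal amplifications — are recovered in ≥ 95 % (measured
98.5–100 %) of replicates; short subtle interior events are outside this
detector's power and would need a circular (two-changepoint) statistic.

## LOH

mBAF = max(BAF, 1−BAF).  Unpaired informative-marker selection drops
mBAF > 0.95 as germline-homozygous; when germline heterozygosity is known, a
mask replaces the cutoff.  This matters in one corner: copy-neutral LOH at
purity 1 yields mBAF 1.0 at het markers, indistinguishable from homozygotes
without germline information; at purity ≤ ~0.9 the folded BAF stays below
the cutoff and the unpaired path calls it.  The segment test is a one-sided
one-sample *t*-test against the heterozygous mean 0.5 — an explicit,
overridable choice of what the "*p* < 0.01" rule tests — combined
with the fixed mean-mBAF threshold 0.76.  The threshold, not the test, is
what rejects pure-noise segments: folding het noise inflates the mean above
0.5 with trivially small *p* at 100+ markers, so the conjunction is
essential.  Segments under 100 informative markers are reported but forced
non-LOH with a reason code.

## Class comparison

Region grid = sorted union of every sample's segment boundaries per
chromosome, so each sample is constant on each region and every segment is a
union of regions.  The 3×2 Fisher test (gained / lost / unchanged, with
amplification collapsed into gained; amplification stays distinct for
clustering and display) is computed by full conditional enumeration of r×2
tables with fixed margins, summing multivariate-hypergeometric probabilities
of tables no more probable than the observed one (tolerance 1e−9 on the
log-probability comparison).  p-values are reported uncorrected, mirroring
the reporting convention; a BH column is available but off by default.
Ward clustering runs on marker-level states encoded amplification = 2,
gain = 1, neutral = 0, loss = −1 (a documented, configurable convention).

## Expression

One-way ANOVA with a two-level factor is the classical F test
(F = t² of the pooled-variance t).  Genes with zero pooled within-class
variance get p = 1 when the class means agree and p = 0 (infinite F,
flagged) otherwise.  BH step-up comes from
`statsmodels.stats.multitest.multipletests`; the suite verifies it against
the direct min-over-tail formula.  Median-split ties go to the low-TIL
group.  Fold-changes are signed linear ratios with magnitude ≥ 1 (negative
= lower in the first class).  "Most variable" intrinsic genes = top 50 % by
variance (configurable); the two-branch cut of a dendrogram is its final
merge; branches are named by correlating branch-mean profiles with the
luminal/basal archetype means.  Signature construction intersects the
per-stratum FDR < 0.05 gene sets: at the default effect size this recovers
most (not all) planted genes with ≥ 90 % purity — full recovery is a power
question, not a correctness one.

## What the synthetic experiments show — and do not

Passing tests demonstrate that the pipeline recovers what was planted under
its own generative model: Gaussian marker noise, linear admixture,
independent markers, i.i.d. genotypes, clean two-stratum TIL structure.
Real arrays add wavy autocorrelated noise, allele-specific hybridisation
bias, subclonality (per-event cell fractions), and immune signatures
entangled with subtype.  None of these are modelled, so the measured
operating characteristics (gate sensitivity/specificity ≈ 1, Spearman
≈ 0.97, full DE power at fold-change 2.4) are upper bounds on real-data
performance, not forecasts.  The analytic anchors (mixing conservation, the
0.684 LOH purity boundary, state-call boundaries, exactness of the Fisher
enumeration and of BH) are model-free and transfer as-is.

## Reproducibility

All randomness flows through `numpy.random.Generator` seeded from one
integer; stage substreams are spawned with fixed keys, so identical
configurations are bit-identical, which the end-to-end checksum test
asserts.  Internally all coordinates are 0-based half-open; exported tables
are 1-based inclusive and carry a header comment saying so.
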