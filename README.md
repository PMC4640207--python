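# famcna

Copy-number, LOH and gene-expression profiling of familial breast-tumour
cohorts from SNP-array signal, with a matched synthetic-data generator that
plants known events under tumour purity and lymphocyte admixture.

## The problem

Familial breast carcinomas carrying moderate-risk germline variants (e.g. a
truncating *CHEK2* allele) are profiled for somatic copy-number aberrations
(CNAs) and loss of heterozygosity (LOH) to ask whether the mutation class
leaves a characteristic genomic footprint, as *BRCA1* does.  Two practical
obstacles dominate this kind of analysis:

1. **Tumour-infiltrating lymphocytes (TILs)** are diploid cells admixed into
   the specimen.  They dilute the tumour signal — a hemizygous deletion in a
   tumour of purity *p* shows a log2 ratio of `log2((p·1 + (1−p)·2)/2)`
   instead of −1 — and can erase CNA/LOH profiles entirely.  Samples rich in
   TILs must be identified (here from an mRNA immune signature) and excluded
   from supervised comparisons.
2. **Class comparisons are underpowered**: with ~14 vs ~34 tumours per class,
   region-level differences are tested with an exact 3×2 Fisher test
   (gained / lost / unchanged × class), reported without multiple-testing
   correction.

`famcna` implements the full pipeline and a generator that emulates its
inputs so every step can be validated against planted ground truth.

## Methods at a glance

* **Log2 ratios** against the per-marker median of a diploid reference
  cohort (default 90 females), corrected per sample for GC content and
  log fragment length by OLS.
* **Segmentation**: recursive binary splitting; a split must pass a
  two-sample *t*-test at *p* < 1e−4, leave ≥ 20 markers on both sides, and
  have |Δmean| / pooled SD ≥ 0.45.
* **State calls** from the segment mean: copy number `2·2^m`; loss < 1.75,
  neutral in [1.75, 2.25], amplification > 6, gain otherwise.
* **LOH** from mirrored B-allele frequency mBAF = max(BAF, 1−BAF) over
  informative markers, segmented with a 100-marker window; a segment is LOH
  iff mean mBAF ≥ 0.76 and a one-sided *t*-test against 0.5 gives
  *p* < 0.01.  On a noise-free hemizygous deletion this flips exactly at
  purity `p` solving `1/(2−p) = 0.76`, i.e. `p ≈ 0.684`.
* **Class comparison** on a region grid (union of all samples' breakpoints):
  exact 3×2 Fisher test by full conditional enumeration; per-class gain/loss
  frequency tracks; Ward clustering of encoded state profiles.
* **Expression**: immune signature = per-subtype-stratum median split on TIL
  percentage → one-way ANOVA → Benjamini–Hochberg step-up FDR < 0.05 →
  intersection of strata; TIL gate by average-linkage clustering
  (correlation distance) of the standardized signature submatrix;
  differential expression by one-way ANOVA with step-up FDR and signed
  linear fold-changes.

## Worked example

```python
from famcna import interface

config = interface.load_config(overrides={"seed": "1"})
run = interface.PipelineRun(config, "famcna_out")
run.run()          # simulate -> gate -> cnloh -> compare -> de
```

or, equivalently, from the shell:

```sh
famcna all --seed 1 --out-dir famcna_out
```

On the default 120-tumour cohort (14+3 CHEK2, 34+15 BRCAX, 47 BRCA1,
7 BRCA2; 500 markers per chromosome) this logs

```
signature size=69; Spearman score~TIL rho=0.971 p=8.1e-75
class comparison on 47 samples (CHEK2 vs BRCAX)
8 genes at FDR < 0.05
```

meaning: 69 immune-signature genes were recovered and their per-sample score
tracks the planted TIL fraction (ρ = 0.97); 14 CHEK2 and 33 BRCAX low-TIL
luminal tumours pass the gate and enter the supervised comparison; all 6
planted expression differences (linear fold-change up to 2.4, higher in
CHEK2) are recovered at FDR < 0.05, alongside two false discoveries — the
expected behaviour of FDR control at this scale.  `region_tests.tsv` shows the planted
chromosome-1p loss difference (6/14 vs 2/34 tumours) at Fisher
*p* ≈ 0.002, and `loh_segments.tsv` contains chromosome-22 LOH calls only
in tumours whose purity exceeds the analytic 0.684 boundary.

Outputs are tab-delimited tables (segments, LOH segments, region tests,
frequency tracks, DE results), a Newick dendrogram of CNA state profiles,
and `manifest.json` with all parameters and output checksums.  Exported
coordinates are 1-based inclusive; each table says so in its header comment.

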