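# Methods

## Data model and coordinates

All coordinates are 0-based half-open `[start, end)` (BED convention),
including windows. The genome is partitioned into fixed-width windows
(default 500 bp) tiling each chromosome from position 0; the last window
of a chromosome is truncated. An interval belongs to a window iff it
overlaps it by at least one base. Strand is carried on intervals but
ignored by all overlap logic, since every analysis here is
strand-agnostic. Chromosome names are matched literally; readers accept
an optional alias map for naming-scheme mismatches. Readers reject
malformed coordinates (non-integer, `start >= end`) with the offending
line number rather than clamping.

## The window-level differential test

Published integrative MeDIP+MRE DMR callers rest on a likelihood model
whose details live outside this package's sources; we therefore implement
a fully specified stand-in that preserves the same decision surface —
500 bp windows, two assays in, one two-sided q-value and a direction out,
q < 1e-5 cutoff — and is verifiable by brute force:

* **Per assay, a conditional binomial.** For MeDIP counts `x_n, x_t` with
  exposures `s_n, s_t`, condition on `T = x_n + x_t`; under the null
  `x_t ~ Binomial(T, p₀)` with `p₀ = s_t/(s_n + s_t)`. The one-sided tail
  in the direction of the observed deviation (inclusive of the observed
  count) maps through the inverse standard normal to a signed score `z`
  (positive = tumor-enriched). When the two tails are exactly equal the
  observation sits at the null center and `z = 0`. Tails are floored at
  1e-300 before inversion to avoid infinities. The same construction on
  MRE counts yields `z_R`.
* **Combination.** `Z = (z_M − z_R)/√2` — a Stouffer combination with the
  MRE sign flipped, because MRE reads mark unmethylated CpGs. If one
  assay has a zero per-window margin, `Z` is the other's score alone; if
  both are zero, `Z = 0` and `p = 1`. The two-sided p-value is
  `2·Φ(−|Z|)` capped at 1; direction is hyper when `Z > 0`.
* **Exposures and CNV.** The effective exposure of a window is
  `library_total × cnv_factor`. Tumor copy-number gains therefore raise
  the null proportion `p₀` instead of rescaling observed counts — a gain
  of 2 explains away a 2:1 count excess. When per-enzyme MRE counts are
  available, each enzyme's track is rescaled to the mean per-enzyme total
  before pooling, compensating for unequal enzyme efficiency.
* **Family and correction.** Windows without CpGs are excluded from
  testing *and* from the multiple-testing family (both assays are
  CpG-conditional, so such windows carry no evidence). Benjamini–Hochberg
  is applied per pairwise comparison (step-up with enforced monotonicity).

The test is discrete and slightly conservative: measured size at the
default depth is ≈ 0.03 at nominal 0.05 (checked in the suite against a
binomial tolerance band).

## Consensus rules

* Type consensus: same direction in ≥ 2 of 3 comparisons (configurable).
  A 2-vs-1 direction conflict resolves to the majority direction; exact
  ties yield no call.
* EC-shared: window is consensus in both cancer types with identical
  direction.
* Type-preferred: called with one direction in all three comparisons of
  one type and in *no* comparison of the other (either direction),
  applied literally. Type-preferred sets are subsets of the type
  consensus sets and disjoint from the shared set; the suite verifies the
  full rule algebra by exhaustive enumeration of all 3 × 3 call
  configurations.

DMRs are reported at window resolution. Merging adjacent significant
windows into multi-window regions is deliberately not performed: counts
and downstream fractions are per-window units.

## Annotation conventions

* **Exclusive context label**: priority promoter > exon/UTR > intron >
  intergenic; CGI, shore, and TE membership are carried as independent
  boolean flags (a DMR can be counted in several features for enrichment
  while keeping one exclusive context label).
* **Shores** are the 1 kb flanks of each CpG island, clipped to the
  chromosome and minus any overlapping CGI body, paired to their island.
  Island/shore change patterns per direction are the three-way partition
  CGI-only / CGI+shore / shore-only (else none).
* **Enrichment score**: `ES = (n_hit/n_DMR)/(N_hit/N_all)` on the window
  frame. The score itself carries no test; we attach a one-sided binomial
  p (success probability = the feature's genome-wide window rate over
  n_DMR trials) with BH across the feature batch, and flag subfamilies
  with ES > 5 and significant q — keeping effect size and significance
  separate. Features present in zero windows are reported undefined
  rather than zero.
* **chromHMM merging**: the dominant state of a window in one cell line
  is the state covering > 50 % of its bases (an exact 50/50 tie has no
  dominant state). Across cell lines, promoter wins if any line's
  dominant state maps to promoter; else enhancer if any maps to enhancer;
  else other. The label → class map is configuration, not code.
* **Methylation-state words**: combining the cancer-vs-normal direction
  with the H1-vs-normal call at the same window forces the mapping
  hypo+none → MMU, hypo+NE-higher → UMU, hyper+none → UUM,
  hyper+NE-lower → MUM (a hyper window implies the normal tissue is
  unmethylated there, and conversely). The two contradictory combinations
  (e.g. hyper where normal is already the methylated side) fall outside
  the four canonical words and are reported undefined.
* **Profiles**: RPKM = count/(bin_kb × library_millions) at 500 kb bins;
  tumor/normal fold changes are averaged across same-type samples before
  the log2 transform; bins with zero normal RPKM are missing. The global
  5 kb density scan compares library-normalized MeDIP densities over bins
  with non-zero normal signal; a bin is hypo-/hypermethylated when the
  ratio crosses 1/f or f. The fold cutoff f is not dictated by the
  statistic; the default is 2.0. Note a uniform count doubling is
  absorbed by library normalization — only *relative* density shifts are
  labeled.

## Cohort validation

Per DMR: `w` = probes with position in `[start, end)`;
`aML = mean of all non-missing beta values` in the group × probe block;
`DMC = aML_cancer − aML_normal`. The Mann–Whitney U test runs on
per-sample mean betas by default so n equals the number of biological
samples (probe-level pooling inflates n by treating probes as
replicates; it remains available as `mode="probe"`). Exact two-sided
p-values for combined n ≤ 12 come from full enumeration of group
assignments (a permutation test on U, valid under ties); larger samples
use the tie-corrected normal approximation. BH is applied across all
testable DMRs of the run (class-wise families are a configuration
option). A DMR validates iff q < 0.05, |DMC| > 0.05 strictly, and the
observed sign matches the predicted direction. DMRs without probes, or
without at least one non-missing value per group, are untestable and
excluded from the BH family.

Quantile normalization maps each sample's sorted non-missing values onto
the average of the per-sample quantile profiles (interpolated onto a
common grid so samples with different missingness remain comparable);
ties receive the mean of their mapped values; missing entries stay
missing. With complete equal-length columns this is classic quantile
normalization.

## The synthetic generator

The generator's defaults *are* the study conditions the pipeline is
tested under; they are fixed, not tuning knobs.

* **Genome**: 2 chromosomes × 2 Mb (one flagged X-like), 500 bp windows
  (8,000 windows). CpGs follow a two-rate clustered process: a high
  homogeneous rate (0.06/bp) inside ~60 CpG islands per chromosome, and a
  clustered background (cluster centers at 6e-4/bp, ~18 CpGs per cluster,
  150 bp Gaussian scatter) elsewhere — ~45,000 CpGs in total. Real CpGs
  aggregate rather than scatter uniformly, and the clustering gives the
  toy genome the CpG-dense non-island loci where hypomethylation events
  occur. A fixed random 25 % of CpGs are MRE sites (a stand-in for
  enzyme recognition sites; per-enzyme structure is not modeled). Genes
  (~30/chromosome with exons), 1 kb core promoters (TSS ± 500 bp), four
  TE subfamilies (two designated enhancer-like), and miRNA/lncRNA TSS
  lists complete the annotation.
* **Methylomes**: baseline normal methylation ~0.1 in CGI/promoter
  windows and ~0.8 elsewhere, with 0.02 window jitter and 0.01
  per-tumor-sample jitter. Planted classes: 60 shared, 60 EAC-only, 60
  UPSC-only windows (half hyper, half hypo, effect size Δm = 0.6), plus a
  contiguous UPSC-only hypomethylated block covering half the X-like
  chromosome (Δ = 0.3). Hyper windows are drawn from CGI/promoter
  windows, hypo windows from CpG-dense background windows (CpG count
  ≥ 2 × the genome mean): both assays are CpG-conditional, so a
  differential window is only meaningful where CpGs exist, and real
  methylation changes concentrate at CpG-dense regulatory loci. The H1
  profile equals the baseline except at designated planted windows,
  producing all four methylation words by construction. Tumor samples
  carry two CNV blocks each (factors 1.5 and 0.75) to exercise the
  exposure normalization.
* **Counts**: Poisson, MeDIP rate `depth × cnv × m × cpg/cpḡ` and MRE
  rate `depth × cnv × (1−m) × mre/mrē`, depth 30 reads/window/assay at
  reference density — the simplest generative model consistent with the
  assays' semantics (linear methylation response for MeDIP,
  complementary for MRE, multiplicative CNV).
* **Cohort**: 20 samples per group (normal / EAC-like / UPSC-like),
  probes at 0.5/kb with a 3× placement bias toward CGI/promoter windows,
  betas Beta-distributed around the group's latent methylation
  (concentration 50), and 30 % of planted DMR windows deliberately left
  probe-free to exercise the coverage reporting.
* **Chromatin states**: per cell line, geometric-length background
  segments at 50 bp resolution with promoter states planted at TSSs
  (per-line probability 0.9) and enhancer states at enhancer-designated
  TE copies (probability 0.7) plus random intergenic patches.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (GC/CpG-coupling bias,
mappability, fragment-size effects), inter-individual variation within
the pooled normal (only a jitter parameter; the pooling makes it
unidentifiable), realistic genome composition (repeat landscape, CpG
island length distribution), probe cross-reactivity and array batch
effects, and any coupling between methylation and expression. Recovery
rates measured here characterize the algorithmic pipeline under its own
generative assumptions, not field performance.

## Numerical choices and degenerate inputs

Two-sided binomial p-values use the doubled-smaller-tail convention
capped at 1; tails are floored at 1e-300 before normal inversion; exactly
central observations score 0. Consensus direction ties yield no call.
`q_cutoff = 0` is legal and produces empty downstream tables. Empty
feature sets give undefined (not zero) enrichment. Windows lacking CpGs,
DMRs lacking probes, and all-missing beta blocks are excluded rather than
imputed. All generators and the pipeline are deterministic under a fixed
seed; stage seeds are derived from the run seed by fixed offsets.

## Problem sizes

The default configuration (8,000 windows, 7 methylomes + H1, 60 samples
in the cohort, 20-seed null series) was chosen so the entire suite and
the acceptance script complete in a few minutes on one CPU while keeping
every per-window test at realistic per-window depth.

## Known limitations

The window test is a documented stand-in, not a reimplementation of any
published likelihood; absolute q-values will differ from other callers
even where decisions agree. Window-resolution DMRs are not merged into
regions, so region counts are not comparable to region-merged callers.
The enrichment test treats DMR windows as independent draws, ignoring
spatial autocorrelation; its p-values are anti-conservative for clustered
DMRs (the effect-size ES and the >5-fold flag do not suffer from this).
Validation assumes probe positions map cleanly onto the discovery
genome's coordinates.
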