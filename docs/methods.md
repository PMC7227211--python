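# Methods

## Overview

`chromlasso` prioritizes regulatory GWAS variants for a quantitative trait
by (1) selecting matched control SNPs for each trait-associated sentinel,
(2) building a binary SNP × chromatin-feature overlap design, (3) fitting
an L1-penalized logistic regression whose background covariates are forced
into the model, (4) carrying the selected chromatin features and
coefficients forward as a genome-wide scoring function, and (5) filtering
LD-block members by dual top-percentile scores, eQTL evidence and
allele-level GATA-motif overlap. The package is organised one module per
stage; a synthetic-cohort generator supplies all inputs so every stage is
testable at desk scale.

## The penalized model

For labels y (1 = trait-associated SNP, 0 = matched control) and design
columns standardized to zero mean / unit variance, the solver minimizes

    f(b0, β) = −(1/n) Σᵢ [yᵢηᵢ − log(1 + exp ηᵢ)] + λ Σⱼ wⱼ|βⱼ|

with ηᵢ = b0 + xᵢᵀβ and penalty factors w = 0 for the three background
covariates (distance to nearest gene in bp, count of LD partners with
r² ≥ 0.8, minor allele frequency) and w = 1 for chromatin features.
Forcing the background in means a chromatin feature earns a nonzero
coefficient only if it separates cases from controls *beyond* what genomic
context explains — the matched-control design leaves residual covariate
signal (training-set background-only AUC can reach ~0.85 on synthetic
cohorts), which is precisely why the covariates are forced rather than
ignored.

Fitting is iteratively reweighted least squares with cyclic coordinate
descent on the working response, warm starts down a λ grid of 100
log-spaced values spanning four decades below λ_max (the smallest λ at
which every penalized coefficient is zero, computed at the
background-only optimum). A sequential strong rule screens the penalized
columns at each λ; screened-out columns are re-checked against the KKT
conditions after convergence, so screening never changes the solution.
Convergence is declared when the maximum weighted squared coefficient
update falls below 1e-8; probabilities are clipped to [1e-5, 1−1e-5] and
linear predictors to ±30, so perfectly separable designs converge to a
bounded, tolerance-accurate optimum with a warning rather than failing.
Coefficients are mapped back to the original column scale for reporting;
penalized coefficients whose standardized magnitude is below 1e-4 are
clamped to exactly zero — such values are soft-threshold boundary dust
(genuinely selected features carry standardized coefficients of ~0.05 and
above), and the clamp reproduces the exact zeros that the standard
coordinate-descent implementation of this model reports. The in-house
solver exists because no installed Python package offers per-coefficient
penalty factors together with an AUC-based CV path; its solutions are
cross-checked in the test suite against an independent FISTA minimizer of
the same objective (coefficients to 1e-3, objective values to 1e-7).

Model selection: stratified 10-fold CV (stratification keeps both labels
in every fold under ~1:100 imbalance); per λ, the fold-out AUC of the full
linear predictor is averaged and its standard error taken as the
across-fold SD divided by √k. λ_min maximizes mean CV AUC; **λ_se** is the
largest λ with mean CV AUC ≥ (maximum − SE at λ_min). The genome-wide
scoring model keeps only the nonzero chromatin coefficients at λ_se;
background coefficients and the intercept are logged as provenance.

## Scoring and percentiles

score(s) = Σⱼ βⱼ·1[s overlaps feature j], with SNP position p treated as
the half-open interval [p−1, p) against 0-based BED intervals. Percentiles
use the strictly-smaller-count convention, 100·#{score < s}/N, so tied
SNPs share a percentile and the zero-score mass never enters "top 5 %"
sets (percentile ≥ 95) — a conservative, deterministic tie policy. The
top-1 % selection used for pathway enrichment instead takes the highest
⌈0.01·N⌉ scores extended across boundary ties, after excluding known
trait loci; with heavy ties the percentile rule can select nothing, which
is the wrong behavior for an enrichment input set.

## Matched controls

Covariates are matched with explicit calipers: |Δmaf| ≤ 0.05,
|Δlog10(dist+1)| ≤ 0.25, |Δ#proxies| ≤ max(2, 25 % of the case's count).
When a case's eligible pool is smaller than the requested control count
the calipers double, up to 5 times, and the realized relaxation level is
recorded. The pool always excludes case SNPs and their r² ≥ 0.8 proxies
(label-leakage guard) and respects MAF > 0.10. Controls may repeat across
cases but are deduplicated into a single row when the design matrix is
assembled. The caliper widths approximate bin-based matching tools; exact
reproduction of any specific binning scheme is a non-goal.

## Candidate stratification

LD blocks are expanded around sentinels at r² strictly > 0.7 with
symmetric pair lookup. A block member becomes a candidate iff it is in the
genome-wide top 5 % under both scoring schemes (the trait model plus a
second model or external score table), has ≥ 1 eQTL target gene, and
carries one of the eight GATA motifs (AGATAA, TTATCA, AATAGA, TTATCT;
GATAA, AATAG, CTATT, TTATC) overlapping the SNP base under at least one
allele. Motif matching is exact substring search on the given window
orientation only — the eight strings already cover both orientations, and
no degenerate-position expansion is applied, keeping the otherwise
manual curation step reproducible. A hit must overlap the SNP base itself
because the interpretation is allele-level (disruption/creation). The
within-block top-scorer is flagged (`block_top`) but not used as a hard
filter, since "scores highly within its block" is ambiguous as a
criterion; the flag lets users apply it themselves. Members lacking a
secondary score are skipped with a warning, mirroring the per-method
coverage gaps of external score tables.

## Pathway enrichment

Top-scoring SNPs (exclusion-first) are assigned their nearest gene on the
same chromosome, ties broken toward the lower start coordinate and
flagged. Enrichment per gene set is the binomial upper tail
P(X ≥ k), X ~ Binomial(n, K/N) — binomial rather than hypergeometric to
match the GO-style web-tool convention the workflow replaces — with
Benjamini–Hochberg adjustment across sets and a default FDR < 0.05 report
threshold. The background defaults to all genes in the annotation and is
configurable, since the "correct" universe (all annotated vs all testable
genes) is a genuinely open choice.

## The synthetic cohort

The generator emulates the joint structure the method consumes, not
chromatin biology:

- **SNPs** are laid out in genome order, partitioned into consecutive LD
  blocks of `ld_block_size + 1` members; a configurable number of full
  blocks per trait become case blocks. Sentinel p-values are log-uniform
  below 5e-8; a rank-k proxy's r² is `r2_decay^k` plus ±0.05 jitter
  (spanning the 0.8 and 0.7 thresholds at defaults), and its p-value
  follows the sentinel on the −log10 scale scaled by r², creating the
  monotone score–significance gradient that the p-value-stratification
  analysis probes. All other SNPs draw p ~ Uniform(0,1). LD is an
  explicit pair table (direction randomized; lookups are symmetric), not
  simulated genotypes, because the method consumes precomputed LD.
- **Tracks**: the first `n_enriched_features` tracks cover sentinels with
  probability `p_overlap_case` (0.8), everything else at `p_overlap_null`
  (0.05); LD proxies are covered at the r²-interpolated rate
  `p_null + r²(p_case − p_null)`, so marginally associated variants
  inherit part of the planted signal — without this, sub-significant SNPs
  could not score above background and the stratification analysis would
  have nothing to detect. Intervals are short (≤ ~100 bp) boxes around
  the covered SNP, written as 0-based half-open BED.
- **eQTLs** cover a configurable fraction of SNPs with 1–3 same-chromosome
  genes; designated validated candidates (high-r² proxies) always get at
  least one row, so multi-gene loci arise naturally.
- **Sequence windows** (default 41 bp) around candidates carry a planted
  GATA motif overlapping the SNP base under exactly one allele (two
  disrupted-by-alt for every created-by-alt), re-drawn until the scanner
  confirms the truth label; background windows are rejection-sampled to
  be motif-free under both alleles. Planting can rewrite a candidate's
  ref/alt alleles, so the SNP table is re-emitted afterwards.
- **Region sets**: an "enhancer" set built around case-block SNPs and a
  control set around null SNPs; **gene sets**: one set of genes nearest
  to sentinels plus size-matched random sets.

Every random stream derives from `(seed, per-function salt)`, so outputs
are bit-identical for a fixed seed regardless of call order, and the full
pipeline reproduces byte-identical artifacts on re-runs (verified by
checksum in the tests).

What the generator does *not* emulate: correlated chromatin marks (all
tracks are independent; real assays are strongly collinear, which is what
makes feature selection on real panels hard), realistic MAF/LD spectra,
gene structure, or hg19 coordinates. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted signal under
clean conditions — not expected field performance on real cohorts, where
the planted 0.8-vs-0.05 contrast would be far weaker and features far
more redundant. At the default configuration the case/control classes are
nearly separable and training AUC ≈ 0.99; real-data AUCs near 0.8 reflect
the much noisier real feature panel.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `proxy_r2` | 0.8 | r² defining LD proxies for covariates/exclusion |
| `block_r2` | 0.7 | strict lower bound for LD-block expansion |
| `top_fraction` | 0.05 | dual-model candidate percentile filter |
| `top1_fraction` | 0.01 | enrichment input selection |
| `maf_min` | 0.10 | control MAF floor |
| `n_controls` | 100 | matched controls per case |
| `folds` | 10 | CV folds |
| `fdr` | 0.05 | reported enrichment threshold |
| `motif_window` | 41 bp | sequence context scanned around a SNP |

Simulation defaults (200 tracks, 20 planted at 0.8 vs 0.05, 500 cases,
20 000 SNPs over 4 × 10 Mb chromosomes, blocks of 5 proxies with
r²-decay 0.9) define the package's reference planted-signal condition;
the test suite and acceptance script use scaled-down variants of the same
generator (1 200–3 000 SNPs, 15–30 tracks) for everything except the
reference recovery experiment.

## Known limitations

- LASSO with CV-based λ_se does not control the false-selection rate: on
  no-signal cohorts a chromatin feature whose overlaps fluke toward the
  cases (a property of the realized universe that every CV fold shares)
  is retained in roughly 15 % of replicates. The reference
  coordinate-descent implementation selects the same features when given
  the same fold assignments; its default *unstratified* folds are
  effectively more conservative only because their noisier per-fold AUCs
  inflate the one-SE buffer. We keep stratified folds (required under
  real 1:100 imbalance) and report the calibration rate honestly.
- Matching leaves residual background-covariate signal (by design it is
  absorbed by the forced covariates, not eliminated).
- Motif scanning is exact-match over eight strings; no PWM scoring.
- Single-position variants only; indels and structural variants are out
  of scope.
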