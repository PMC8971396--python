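# Methods

## Model

A gene's score is the count of satisfied binary evidence flags among five
metrics chosen for their association with CNS disease genes: de novo variant
burden (count ≥ 10), exon-index membership (≥ 1 flagged exon promotes the
gene), critical coding constraint (max CCR percentile ≥ 99, inclusive),
brain expression (median over the 13 brain-tissue medians ≥ 10 TPM,
inclusive; an even-length median is the mean of the two middle values), and
loss-of-function constraint (o/e LOF upper bound strictly < 0.345 — 0.35
with rounding from the thousandths place). Flags are deliberately
unweighted: the five fitted odds ratios sit in a narrow band (≈1.4–2.2), so
one point per metric keeps the score interpretable without letting any
metric dominate. Audit flags for the four rejected candidates (CCR-95,
missense constraint, and two CNV-burden cutoffs) are carried for screening
but never scored.

Missing-metric semantics are strict by default: a gene absent from any of
the five sources is unscorable (NA), is never high scoring, and is excluded
from medians and means. A lenient mode (missing = false) exists but is off;
silently under-scoring a gene with one missing source would bias CNV
summaries downward. Scores supplied in input files are recomputed from
flags at load time; a mismatch is a hard error rather than a warning.

Harmonization across sources matches by stable identifier first, then by
current symbol, then through a supplied alias map; a symbol claimed by two
identifiers is reported unresolved, never merged. Non-coding, RNA,
mitochondrial and pseudogene biotypes are excluded when a biotype column is
present; otherwise exclusion is the caller's responsibility.

## Statistics

* **Screen:** Pearson chi-squared (no continuity correction) of each
  candidate flag against the binary CNS outcome; candidates pass at
  p < 0.05.
* **Model:** multiple logistic regression with a constant. Metrics with
  variance-inflation factor > 5 are dropped first (the threshold is
  configurable; 5 is the usual rule-of-thumb boundary), then the metric
  with the largest Wald p ≥ 0.05 is removed and the model refit until all
  retained coefficients are significant. Perfect separation is detected
  (non-finite standard errors or a failed fit) and the offending metric is
  dropped with an explicit reason.
* **Odds ratios:** cross-product estimate with Woolf CI
  (log OR ± z·SE, SE² = Σ 1/cell). Any zero cell triggers the
  Haldane–Anscombe 0.5 correction, noted in the result. This equals the
  exponentiated coefficient of a one-predictor logistic fit, which the test
  suite verifies against statsmodels on expanded data.
* **Fisher exact test:** two-sided by the minimum-likelihood definition
  (sum of hypergeometric point probabilities ≤ the observed table's);
  verified exhaustively against direct enumeration for every 2×2 table
  with all margins ≤ 12.
* **Score-level odds ratios** compare each level (and the pooled ≥3 level)
  with score-0 genes; the gene universe is whatever labeled records are
  passed in, so the caller controls whether unlabeled genes count as
  non-CNS. The negative control relabels the outcome as non-CNS vs rest
  and measures score-0 membership.
* **Probability transform:** OR × baseline odds mapped through
  odds/(1+odds). The baseline odds are an explicit argument because no
  single universal baseline exists; the symmetry
  p(1/OR, 1/odds) = 1 − p(OR, odds) is property-tested.
* **Power:** the minimum detectable OR solves, by bisection, for the OR at
  which a two-proportion normal test reaches the requested power; verified
  against a Monte-Carlo power estimate.

## CNV analysis

Coordinates are 0-based half-open internally; BED input is taken as-is and
1-based TSV is converted on load. A gene belongs to a CNV iff ≥ 1 bp of one
of its exons overlaps the call; a `gene_body` fallback exists for inputs
without exon models and is flagged in output. Per-CNV summaries count genes,
scorable ("scored") genes, high-scoring genes, the maximum level, and the
median/mean score percent over non-NA genes. CNVs whose genes are all
unscorable are dropped before cohort statistics, and calls covering > 90% of
a chromosome are excluded as aneuploidy-scale.

Cohort contrasts are Welch two-sided t-tests (the pooled-variance choice is
not defensible with cohorts this unbalanced) on five per-CNV measures per
loss/gain stratum, Bonferroni α = 0.05/10 = 0.005. The maximum-score
distribution is tested per level (5,4,3,2,1,0,NA) and stratum — 14 tests,
α = 0.004 — using Fisher when any observed cell is ≤ 5 (an expected-count
rule is available) and chi-squared otherwise. The headline enrichment is the
pooled 2×2 odds ratio for case CNVs carrying ≥ 1 high-scoring gene.
Pathogenicity regressions are OLS of gene-content measures on the 1–4
classification code with CNV size as covariate. Region reports profile a
recurrent region and its breakpoint segments with the same gene-set summary
used genome-wide.

## Synthetic data

`simulate_genome` draws the five flags by thresholding an equicorrelated
latent Gaussian (pairwise correlation defaults to 0) at the quantiles of
the source-database marginal frequencies (487, 4636, 1444, 6069, 2896 of
19,601 genes), draws the CNS label from a logistic model with per-metric
odds ratios defaulting to 2.2/1.9/1.8/1.7/1.4 and a score-0 baseline CNS
rate of 715/10461, and back-fills raw metric values uniformly inside the
region consistent with each flag so the binarizers round-trip exactly.
Brain-expression vectors are lognormal draws rescaled so their median hits
the target exactly. The four audit metrics are marginally but not
conditionally informative — CCR-95 contains CCR-99, the missense flag is
nested in the LOF flag, the stricter burden cutoff overlaps the index flag
while the looser cutoff's extra genes avoid it — so the screen usually
passes them and backward elimination removes them, reproducing the
screen-then-prune shape of model construction. 842 genes (4.3%) lose one
random metric to emulate incomplete source coverage. Non-CNS genes with no
flag at all carry 1.7-fold odds of a non-CNS (vs no/absent) label, which is
what the negative control is designed to detect.

`simulate_gene_models` lays non-overlapping genes (exponential sizes, mean
30 kb, mean gap 70 kb) with 2–10 exons whose first and last touch the gene
boundaries, across 20 chromosomes. `simulate_cnv_cohorts` places log-normal
CNVs (case losses/gains mean 344/419 kb, controls 104/244 kb; σ = 0.8,
matching the cohorts' mean sizes) that must hit ≥ 1 exon. Because case
calls are larger, placement alone enriches them for high-scoring genes; a
pilot batch of untilted case draws (3× oversampled) estimates that
baseline, and candidate case calls are then accepted with probabilities
that set the case/control high-gene odds ratio to the configured value
(default 9) against the realized control odds. Cohort sizes default to
835/1357 case and 2547/1862 control loss/gain calls.

The ortholog generator emits 1:1 human–mouse pairs with 27 high-level
phenotype flags, either with per-term enrichment (seven terms at OR 1.6 by
default) or with exact class-level odds ratios via a latent class indicator
whose firing activates a nonempty random subset of member terms; genes with
no abnormal term carry the class-free "normal" flag so the ≥1-phenotype
rule never distorts class odds.

What the generators do not emulate: linkage/clustering of constrained genes
along the genome, recurrent breakpoints and segmental duplications, shared
CNVs within families, correlated metric noise from shared underlying
sequencing data, and OMIM's ascertainment bias. Passing recovery tests
therefore demonstrates correctness of the estimators under the modeled
sampling process, not robustness to those real-data artifacts.

## Packaged fixtures

Two count fixtures freeze the per-score-level gene table (with its
outcome-category decomposition; totals sum to 18,759 = 19,601 − 842 NA) and
the per-level maximum-score CNV counts (cohort totals 835/1357/2547/1862).
Two region fixtures (7q11.23/Williams–Beuren and 22q11.2 with A–B/B–D/D–F
segments) list real gene symbols with synthetic per-gene score stand-ins;
only their summary counts (25/15/6 and 64/38/8, MAPK1 = 4) are meaningful,
as flagged in the files. Fixture files are SHA-256 checksummed at load.

## Numerical choices and degenerate inputs

Ties at every cutoff are resolved as stated above (≥ for CCR/TPM/de novo,
strict < for o/e). Even-length medians average the two middle values
everywhere (gene sets, CNV summaries), so summaries are reproducible to the
digit. Empty score levels yield NA association rows rather than errors;
degenerate 2×2 margins raise for chi-squared, are skipped with a reason in
per-level tables, and zero cells in ORs are corrected as noted. Backward
elimination from an empty or fully eliminated candidate set returns an
intercept-only fit with an empty retained list.

## Problem sizes used in validation

The recovery batteries run 100 replicates at 15,000 genes (metric
retention; chosen so the weakest metric, OR 1.4 at 14.8% prevalence, is
comfortably powered) and 100 replicate CNV cohorts at the default cohort
sizes (enrichment-OR coverage). The Fisher equivalence sweep covers all
5,238 nondegenerate 2×2 tables with margins ≤ 12.

## Known limitations

The score is a gene-level prior, blind to variant-level evidence, non-coding
mechanisms and recessive architecture. The logistic validation inherits the
label quality of the clinical database the outcome is drawn from. The
backward-elimination driver refits from scratch each round (no score tests),
which is faithful but O(rounds × fit). The CNV annotator assumes a single
assembly; no liftover is provided. The exact outcome universe behind the
published per-level odds ratios is not recoverable from printed counts, so
those ORs are treated as directional, not as point targets.
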