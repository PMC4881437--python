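# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `crcmet`.

## Coordinate and data conventions

All genomic intervals are 0-based half-open (BED convention), which makes
overlap and union arithmetic exact integer operations. Copy-number calls
are direction-typed (`gain`/`loss`); downstream statistics treat the two
directions as distinct events and never pool them. Expression matrices are
genes × samples DataFrames; clinical tables carry DFS/OS time (years),
event indicators, and group/MSI/stage/grade labels.

## Sample quality: DLRS

The derivative log-ratio spread is IQR(d)/(1.349·√2), where d are
differences of consecutive probe log₂ ratios *within* chromosomes. For
i.i.d. probe noise with SD σ the differences have SD σ√2, and IQR/1.349
estimates their SD robustly, so the statistic estimates σ while ignoring
the (sparse) segment boundaries. The robust IQR form resists outlier
probes; a plain SD/√2 variant is a one-line swap for users who prefer it.
Samples with DLRS ≥ 0.5 are flagged ineligible.

## Segmentation and calling

The proprietary segmenter used on the original arrays is not available;
calls here come from recursive binary segmentation: per chromosome, the
split that most reduces within-segment squared error is accepted while the
reduction exceeds `penalty · σ̂² · log n` (BIC-style; `penalty` defaults to
3, σ̂ from DLRS), recursing into both halves. Segment means at or beyond
±0.25 are called gains/losses — a deliberately loose bound on the ±0.58
single-copy log-ratio of a diploid genome, attenuated by tumor-cell
fraction — and abutting same-direction calls merge with probe-weighted
means. The segmenter sits behind the call-table contract: pre-segmented
SEG input (`cna.read_seg`) bypasses it entirely, so any external segmenter
can be substituted. Downstream statistics consume only binary occupancy,
which is why a simple, testable segmenter suffices. Segmentation is
idempotent on its own fitted means (verified by test), and on noise-free
input the binarized calls equal the binarized planted truth.

## Recurrence testing (frequency-statistic permutation test)

Per arm and direction, sample × bin occupancy is 1 iff a same-direction
call overlaps the bin (bins tile the arm; the last may be short; 1 Mb
default). The null hypothesis is random within-arm placement: per sample
and permutation, each maximal aberrant run is relocated to a uniform start
(count and lengths preserved, no wraparound; runs that collide after
relocation merge through the OR). The per-bin p-value is

p(b) = (1 + #{permutations: max_b' f*(b') ≥ f(b)}) / (1 + n_perm),

a max-statistic calibration that is family-wise valid across the arm and
monotone in f. The “+1” correction keeps p > 0 and valid. Of the original
method's two statistics (frequency and footprint), only the frequency
statistic is implemented — it is the one the analysis uses; the footprint
is a straightforward extension point. Gains and losses are tested
separately because they are biologically distinct events. Default
n_perm = 999. Significant regions are maximal runs of bins with f ≥ 0.35
and p < 0.05, the stringent thresholds of the study design.

In the pipeline the recurrence map is computed **within the metastatic
group**: the scientific question is which aberrations stack in metastatic
tumors beyond chance; the disease-free group enters through the survival
scan, making the two maps complementary rather than nested.

## Survival statistics and SPPS

Kaplan-Meier estimation, the two-group log-rank test and univariate Cox
proportional-hazards fits are delegated to `lifelines`; Cox uses Efron tie
handling, which is markedly more accurate than Breslow for the heavily
tied quartile covariates. Tests cross-check the log-rank statistic against
a hand-built risk table and against the Cox partial-likelihood score test
at β = 0 (an exact equivalence on tie-free two-group data), and verify
nominal type-I error by simulation.

SPPS scans cohort-wide recurrent regions (frequency floor 10%, so an
In-Group of useful size exists): the In-Group is samples whose
same-direction calls cover ≥ `min_cover` = 0.5 of the region — the
operationalization of "samples with similar CNA regions", configurable
because the original grouping rule is not fully specified — and DFS is
compared by log-rank. "Mean survival" is reported as the restricted mean
survival time up to the last observed time, the only well-defined mean
under censoring. Regions with an empty In- or Out-Group are skipped with a
warning rather than failing the run.

## Gene funnel

The recurrence and survival maps intersect base-pair-wise within matching
directions (commutative, idempotent; both p-values carried). Genes map to
regions on ≥ 1 bp overlap; a gene hitting both a gain and a loss region is
kept in both with an `ambiguous` flag. The normal-CNV exclusion computes
the fraction of each *region* covered by the union of catalog intervals
(union first — splitting a catalog interval into abutting pieces cannot
change the answer) and removes genes whose region overlap is ≥ 5%, unless
whitelisted; gene-body overlap is also reported for the candidate table.
The whitelist exists because the published candidate list retains one gene
(SPAG11A, 68.65% overlap) despite the stated rule; exceptions must
therefore be explicit, never silent. By default the exclusion applies to
both directions; a flag restricts it to gains for users who read the rule
literally.

## Expression meta-cohort and screening

Datasets merge on their common genes and are standardized per dataset and
gene to mean 0 / unit variance (ddof = 1). This exact location/scale
correction replaces empirical-Bayes batch adjustment deliberately: it is
simpler, fully testable (per-batch mean |·| < 1e-8, variance within 1e-6
of 1), and sufficient because every downstream statistic is rank- or
regression-based.

Each candidate gene is screened by univariate Cox OS and DFS fits on
standardized continuous expression (a single coefficient per
gene-endpoint; quartiles are display/grouping devices only). The primary
screen requires some endpoint to have p < 0.05 *and* a
direction-consistent coefficient: loss → negative (worse prognosis when
the tumor underexpresses the gene), gain → positive. The stringent filter
keeps genes with min(p_OS, p_DFS) < 0.005. Mann-Whitney (exact enumeration
for tie-free combined n < 20, tie-corrected normal approximation
otherwise) and Kruskal-Wallis record tumor-vs-normal and
clinicopathological associations.

Quartiles cut at the 25th/50th/75th linear-interpolation percentiles;
boundary ties go to the lower quartile (deterministic). The combination
analysis takes a list of deleted genes: group A is samples with *every*
listed gene in its own Q1, group B samples with every gene in Q2–Q4, mixed
samples are excluded, and the groups are compared by log-rank with KM
curves emitted.

## EMT score

The published procedure seeds sample ordering with a Bayesian probit
meta-gene classifier; here that step is a rank-enrichment pre-score
(es_mesenchymal − es_epithelial from the curated sets, rank-scaled to
[0, 1]). The pre-score's only job is to *order* samples for extreme-tail
selection, for which a deterministic, dependency-free rank statistic is
well suited; this is the package's one prominent methodological deviation.

Signature refinement labels the top/bottom 25% of samples by pre-score
(≥ 8 per tail required) and keeps genes that (a) beat all 1000
label-permutation between-tail mean differences in magnitude — the
per-gene empirical q = 0 criterion — and (b) have tail-membership ROC
AUC ≥ 0.85 (or ≤ 0.15 for the epithelial side); sign of the difference
assigns the list. Under pure noise this returns an error or near-empty
sets (verified by test): q = 0 against 1000 permutations admits no false
signature.

The enrichment statistic is the ssGSEA running sum: genes ranked by
descending within-sample expression; in-set ECDF weighted by
(rank/N)^0.25 minus unweighted out-of-set ECDF, summed over all ranks
(the integral form, not the max-deviation KS form; both the exponent and
the form are arguments). With exponent 0 the statistic is a pure rank
statistic, invariant to monotone transforms of the sample. The final
score is minmax(ES_M) − minmax(ES_E) across the cohort, guaranteed in
[−1, +1] and exactly antisymmetric under exchanging the signatures. The
source description of the subtraction's direction conflicts with its own
sign convention (−1 epithelial, +1 mesenchymal); the sign convention wins.
Cohort min-max is one reasonable reading of "normalized subtraction" (no
formula is given); it is isolated in one helper should a different
normalization be preferred.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults mirror the emulated study's design: 78
disease-free, 11 metastatic, 7 local-recurrence samples (the
local-recurrence cases are generated and flagged for exclusion, as in the
study); ~8000 uniformly spaced probes over a compact 8-arm synthetic
genome (the real array layout is irrelevant to the statistics); three
planted driver regions (two losses, one gain) carried with penetrance 0.8
(one at 0.7) in the metastatic group and background rate 0.05 in the
disease-free group; Poisson(2) passenger aberrations per sample at
2–15% arm length; segment amplitude ±0.8 log₂ (single-copy change
attenuated by tumor-cell fraction); probe noise SD 0.15, typical of good
FFPE hybridizations and comfortably under the 0.5 DLRS gate.

Survival is exponential with proportional hazards — the simplest model
satisfying the assumptions the Cox/log-rank analyses exercise — with
baseline DFS hazard 0.08/yr (disease-free mean DFS near the ~10-year
follow-up horizon), hazard ratio 3 per driver carried, and 30% uniform
censoring. The expression meta-cohort spreads 4 × 60 tumors over batches
with N(0, 0.5) location shifts and log-normal scale (SD 0.1 on the log),
couples driver-resident genes at 1 expression unit per copy, shifts a
15-gene mesenchymal block up and a 15-gene epithelial block down by 1.5
units in mesenchymal-phenotype tumors (25% of tumors), and appends 40
diploid epithelial normals. Where the emulated study states no value,
these are one-time choices for statistical realism, not fidelity.

Not emulated: FFPE/wave/GC artifacts, probe-level microarray chemistry and
RMA preprocessing (the simulator emits gene-level expression directly),
MSI biology (MSI enters only as a label), allele-specific copy number,
purity/ploidy. Passing tests therefore demonstrate the *statistical
machinery* — calibration, recovery, bookkeeping — under a clean generative
model, not robustness to real-array artifacts.

## Problem sizes and numerical choices

The default test suite and the acceptance script use: 999 permutations per
arm in single analyses and 499 inside the end-to-end pipeline run; 1000
replicate null datasets (10 samples × 20 bins, 199 permutations) for
p-value validity; 2000 replicates for log-rank type-I error; 10 × n = 500
replicates for Cox recovery; 50 replicate profiles at 2000 probes for
segmentation recovery — sizes chosen so the whole suite completes in a few
minutes on one core while keeping Monte-Carlo error well below the asserted
tolerances. One global seed fans out to per-stage seeds by fixed strides
(mod 2³¹) so any stage can be re-run in isolation and reproduce its
manifest hash. All simulator output uses fixed float formatting, making
repeated runs byte-identical.

## Known limitations

- The binary segmenter has no explicit significance model per breakpoint;
  very short or very shallow segments below the BIC threshold are missed
  by design.
- The permutation null relocates runs independently per sample; correlated
  co-occurrence of aberrations across samples (e.g. whole-genome doubling)
  is outside the null family.
- SPPS p-values are not corrected across regions; they are filtered again
  by the intersection with the permutation-calibrated recurrence map.
- The 42-gene candidate list itself is consumed as a published fixture:
  the exact Boolean rule that produced it from the 958-gene pool is not
  fully specified in the source and is not re-derived here; the package's
  explicit screen (primary pass OR EMT association) is configurable.
- The EMT pre-score replaces a trained probit classifier; rank agreement
  with that classifier on real compendia is untested by construction.
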