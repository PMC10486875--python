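# Methods

This note documents the models behind each pipeline stage, the synthetic
cohort generator that stands in for study data, the numerical choices, and
the limits of what the tests demonstrate.

## Study design assumed throughout

Each patient contributes one pre-treatment and one post-treatment blood
sample; every sample is measured on two targeted count panels ("IP" and
"MII", each with endogenous, housekeeping and negative-control probes,
sharing a subset of endogenous genes) and, optionally, on an 18-population
flow-cytometry panel with absolute counts plus CBC values. All inference is
paired: tests compare within-patient differences, and the differential
expression model encodes the pairing as patient fixed effects.

## Normalization chain

1. **geNorm ranking.** For housekeeping candidates j, k the pairwise
   variation V_jk is the sample SD (n−1 denominator) of
   log2(a_j/a_k) across samples; the stability measure M_j is the mean of
   V_jk over k ≠ j. The gene with the highest M is eliminated and M is
   recomputed until two genes remain. Ties at the maximum break to the
   first gene in candidate order (deterministic). The selected set is
   either the top-n requested (default 19 in the full pipeline; the
   scaled-down runs use the panel's candidate count) or the smallest n with
   V(n/n+1) < 0.15, where V(n/n+1) is the SD of the log2 ratio of
   normalization factors (geometric means of the n and n+1 most stable
   genes). geNorm runs **per panel** and the selections are pooled —
   whether the reference study pooled candidates across panels is not
   stated, so this is configurable at the library level.
2. **Housekeeping scaling.** Each sample is multiplied by
   (cohort mean of housekeeping geometric means) / (its own geometric
   mean). Zeros are floored at 0.5 before any log or geometric mean — only
   zero cells are modified, so exact-scaling relations between positive
   samples are preserved exactly.
3. **Cross-panel merge.** Per biological sample, panel B is rescaled by
   the ratio of the two panels' arithmetic-mean normalized counts over the
   shared genes (geometric mean available via the library); shared genes
   are then reported once as the average of the two rescaled measurements.
   The source (panel A / panel B / both) is kept per gene.
4. **log2 transform** with offset 1.
5. **Limit of detection.** Negative-control probes pass through the same
   scaling and log2 transform; the threshold is their pooled mean + 2·SD
   (sample SD) on that scale, matching the convention of stating the LOD in
   log2 units. A gene is "detected" only if it exceeds the threshold in
   strictly more than 50% of profiles; exactly half fails.

## Marker validation and abundance scores

Pairwise similarity is the Pearson correlation of log2 expression across
**all** samples (both time points pooled — selection happens once, not per
time point); Spearman is available via an argument. Within each cell type a
candidate is retained iff it is unique to that type, detected, has finite
variance, and correlates > 0.6 (strict) with at least one other surviving
same-type candidate; a type is scorable with ≥ 2 retained markers. The
abundance score is the unweighted mean log2 expression of retained markers,
so it always lies between the markers' min and max for that sample. The
total-leukocyte score defaults to the single CD45 gene (PTPRC) and is
configurable; relative scores are type score − total-leukocyte score
(log2). Paired two-sided t-tests per type, BH-corrected across types;
zero-variance differences with a nonzero shift are reported as p = 0 with a
`degenerate` flag rather than NaN.

## Paired differential expression

The primary model per gene is a negative-binomial (NB2) GLM on raw counts
with log link: intercept, a post-treatment indicator (the effect of
interest), patient fixed-effect dummies (the paired design), and a
per-sample offset equal to −log(normalization factor). The dispersion α
(variance = μ + αμ²) is estimated per gene by profile maximum likelihood: a
Poisson fit initializes the coefficients and a moment estimate of α centers
a bounded search of the profile log-likelihood over log α (floor 1e−8,
ceiling 20, tolerance 0.03 on log α, warm-started IRLS with tolerance 1e−8
and at most 100 iterations). The reported FOC is the treatment coefficient
divided by ln 2; p-values are Wald tests on that coefficient.

Fallback chain: a gene falls back to a Gaussian linear model on
log2-normalized values ("log-linear") when the NB fit fails, does not
converge, has a degenerate standard error, or diverges (|FOC| > 25 log2
units, which catches perfect separation such as all-zero pre samples).
An optional third branch — a two-component NB mixture sharing regression
coefficients, fit by EM — can be enabled per run for bimodal genes but is
off by default; the default chain covers convergence failures. All-zero
genes are skipped with a flag.

DEG calling uses |log2 FC| ≥ 0.5 and BH p ≤ 0.05 with **inclusive**
boundaries by default (configurable to strict): the inclusive convention
follows the phrasing used where headline DEG counts are typically reported.
BH adjustment is the standard step-up (statsmodels) and is checked in the
tests against an independent brute-force implementation. Tukey outlier
removal for heatmap input drops genes whose summary (default: mean log2
expression) falls outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; the rule is applied
in a single pass and is not idempotent by design.

## Pathway scores

Member genes are standardized (zero mean, unit variance across samples;
zero-variance genes get unit divisor) and the score is the sample
projection on the first right singular vector of the gene × sample
z-matrix. The axis sign is flipped if negative loadings outnumber positive
ones (ties break on the loading sum), so scores rise when the pathway's
genes rise and the orientation is deterministic. Single-gene sets reduce to
the standardized expression. Scores of one set never depend on other sets.

## Flow concordance

Gated absolute counts are log2(x+1)-transformed before paired t-tests and
correlations (counts are strongly right-skewed; the transform is
configurable). Leukocyte fractions divide each population by either a named
total column or the sum of the top-level populations (granulocytes,
monocytes, lymphocytes, dendritic cells, MDSC). Cross-modality concordance
correlates, per time point separately, each population's log2 count with
its matched cell-type score across patients (Pearson and Spearman both
reported); rows with fewer than 3 matched patients are omitted. A hierarchy
validator rejects tables where a child population exceeds its parent.

The 18-population panel, its parent links, and the population → cell-type
mapping ship as editable CSVs under `immunopair/data/`, as does an
illustrative marker map (13 cell types, 61 genes) and a set of six pathway
gene sets (leukocyte functions; myeloid differentiation and maintenance;
T, B and NK cell functions; MHC class II antigen presentation). These are
synthetic stand-ins assembled from standard immunology marker knowledge —
the candidate marker list and the vendor's pathway memberships are not
published in machine-readable form — so analyses on real data should
replace them with the user's own definitions.

## Synthetic cohort generator

`simulate_cohort` draws counts probe-by-probe from
NB(mean = baseline · scale · 2^(bio + fc·post), dispersion α), with:

- **baseline**: log2 means ~ N(7.5, 0.8) for marker/pathway genes,
  N(7, 1.5) for anonymous filler genes, 10% of fillers planted near
  background (N(1, 1)) so the LOD filter has work to do; housekeeping
  baselines ~ N(9, 0.8).
- **scale**: per-(sample, panel) log-normal library factor
  (ln-SD 0.25 by default).
- **bio**: log2-scale biological variation. Markers of cell type c share a
  latent per-sample abundance factor f_{c,s} ~ N(0,1):
  bio = σ_m(√ρ·f + √(1−ρ)·ε) with σ_m = 1.0 log2 and ρ = 0.9, which is
  what makes within-type marker correlation detectable (~0.8 observed
  after count noise) while cross-type correlation stays near 0 after
  normalization. Other endogenous genes get independent N(0, 0.35²);
  housekeeping genes get per-gene SDs drawn from U(0.02, 0.25) with a few
  deliberately noisy ones (U(0.5, 1.0)) so the geNorm ranking is
  non-trivial.
- **fc**: planted group fold changes, defaults
  myeloid +1.5, lymphocyte −0.6, MHC-II −0.7, pan-leukocyte +0.4, rest 0 —
  the direction pattern of a G-CSF-supported chemotherapy cycle. Dispersion
  defaults to α = 0.05 (moderate overdispersion typical of targeted
  counting); the DE simulation studies use α = 0.1 as their stated
  condition. Negative controls are Poisson(5), independent of time point.

`simulate_flow_counts` draws leaf populations log-normal around typical
absolute counts (cells/µL; e.g. mature neutrophils 3500, CD4 T 800) with a
shared per-patient factor (ln-SD 0.3), within-sample noise (ln-SD 0.25),
planted log2 post effects per leaf (defaults: neutrophil/monocyte surge,
+0.5 lymphocyte rise, CD16+ NK flat, thrombocytes −0.3), and an optional
coupling κ·f_{c,s} − κ²/2 to the expression latent factors (κ = 0.6 pre,
0.15 post by default — centering keeps E[count] independent of κ, so
trajectories and coupling are separately controllable). Parents are sums of
their leaves, so the gating hierarchy holds by construction. The default
configuration therefore plants the signature discordance: lymphocyte counts
rise while lymphocyte gene expression falls, and the granulocyte surge
shrinks the lymphocyte share of leukocytes.

What the generator does **not** emulate: probe-level sequence effects and
positive-control drift, RNA degradation, batch/cartridge structure, heavy-
tailed patient outliers, and any realistic inter-patient variance
components (none are published for this design); passing tests demonstrate
the pipeline's correctness and operating characteristics under this model,
not performance on real cohorts.

## Simulation study sizes

Chosen for a single desktop CPU: effect recovery uses 200 replicates of one
NB gene at 40 pairs (true log2 FC 1, α 0.1, per-patient baseline shifts
absorbed by the blocking covariates); sensitivity/FDR uses 200 replicates
of 30 genes with 10% planted effects at |log2 FC| = 1; type-I error uses
200 scaled-down null cohorts (12 patients, 120 genes/panel) through the
full normalize → select → score chain plus flow tests; marker recovery and
the discordance study use single cohorts (12 and 40 patients).

## Known limitations

- With ~40 patient fixed effects for 80 observations, profile-ML dispersion
  is biased downward (incidental-parameters effect; α̂ ≈ 0.05 at true 0.1),
  which makes per-gene Wald p-values slightly anticonservative; the effect
  estimate itself is unbiased, and the empirical FDR of DEG calling stays
  well controlled in the simulation study. Empirical-Bayes dispersion
  shrinkage is deliberately out of scope.
- The paired-NB effect estimator sits at the efficiency bound
  (SD = √(2α/n)/ln 2 ≈ 0.102 log2 at the study conditions), so its
  recovery coverage in a ±0.2 band is 95.0% in expectation and a 200-
  replicate measurement fluctuates around that value by ±1.5% across seeds.
- Tukey outlier removal is single-pass, not iterated.
- The mixture branch is a pragmatic two-component EM, not a full mixture-
  model selection procedure, and is off by default.
- No claim of numerical identity with any vendor software is made; the
  pathway gene sets and marker map are illustrative.
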