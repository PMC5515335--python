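# Methods

This note records the statistical models the package implements, the
modelling choices made where the underlying procedures were open, and what
the synthetic benchmark does and does not demonstrate.

## Detection-rate QC

A probe-count sample carries eight negative-control probes measuring
non-specific background. The detection threshold is the upper limit of a
normal-theory 99.5% *prediction* interval on the control counts,

    t = mean + t_{(1+0.995)/2, n-1} · sd · sqrt(1 + 1/n),

chosen over a confidence interval of the control mean because the question
asked of each endogenous count is "could background alone have produced
this single value?", not "where is the mean of background?". The CI-of-mean
and mean + k·sd variants are available (`method=` in
`detection_threshold`) for sensitivity analysis. The threshold is computed
per sample, since the controls are per-sample measurements; a pooled global
threshold is available (`per_sample=False`). A sample passes at detection
rate ≥ 0.75 (inclusive). Zero-variance controls collapse the threshold to
the control mean and are flagged.

## Housekeeping normalization

Expression values are `log2(count + 1)`; each sample is shifted so that its
mean housekeeping log2 value equals the cohort anchor (the grand mean of
those per-sample means). Subtracting the mean of logs is equivalent to
dividing raw counts by the geometric mean of the housekeeping genes — the
arithmetic-vs-geometric question on the raw scale is resolved in favour of
the geometric mean, the standard choice for count panels. The pseudocount
of 1 guards zero counts; scale invariance therefore holds exactly only in
the no-pseudocount limit and approximately (quantization-level error) at
counts ≫ 1.

## Intrinsic subtyping

Nearest-centroid calls use Spearman correlation between a sample's profile
and each subtype centroid after per-gene median centering across samples.
Spearman (rather than Pearson) makes the call invariant to monotone
per-sample distortions, and median centering removes per-gene platform
offsets; both are standard for cross-platform 50-gene subtyping. Pearson is
selectable. Four subtypes (LumA, LumB, Her2E, Basal) are called by default;
a normal-like centroid can be supplied but is off by default because that
group largely reflects stromal contamination rather than a tumor state.

Consensus training labels require agreement between the nearest-centroid
call and the name of the sample's cluster under Ward linkage on Pearson
correlation distance (the same metric pair used for TNBC subtyping, for
internal consistency; clusters are named by their majority nearest-centroid
call, ties alphabetical). Disagreeing samples are `unassigned` and excluded
from training. The classifier is a 1000-tree random forest with sqrt(p)
features per split and a fixed seed; out-of-bag misclassification is the
reported training error, and the prediction probability of a call is the
forest's vote fraction, gated at a strict > 0.4 for a "confident" call. All
ties everywhere break by fixed alphabetical subtype order with an explicit
flag.

## Copy number from qPCR Ct

One PCR cycle is one log2 unit of template. The additive two-way model
`Ct(s,a) = μ + sample(s) + assay(a) + ε(s,a)` is fitted by least squares
over the observed cells (missing wells excluded, not imputed); "two-way
ANOVA normalization" is implemented as exactly this effect removal, and the
negated residual is the copy-number log2 signal. Identifiability of the
effects requires the bipartite graph of observed (sample, assay) cells to
be connected; disconnected patterns raise an error naming the blocks.
Per-gene signals are the mean over the gene's assays. Linear copy numbers
are rescaled multiplicatively so the global median over all genes and
samples equals 2 *exactly* (the median is scale-equivariant, so the anchor
is applied on the linear scale rather than as a log-scale shift, which
would be off by the even-count median interpolation). The amplification
cut-off is a parameter with default 4 copies (two-fold over diploid);
published amplification cut-offs vary by platform and cohort, so no single
value is privileged.

## TNBC subtyping and ssGSEA

Triple-negative samples (ER−/PR−/HER2− by IHC; missing status excludes a
sample with a logged warning) are clustered on the TNBC signature genes
with distance `1 − Pearson(x, y)` and Ward linkage, and the tree is cut
into six clusters (k is a parameter). Each cluster's per-gene mean log2
profile is scored against each subtype gene set with a single-sample GSEA
running sum: genes ordered by decreasing expression (ties broken by gene
name for determinism), in-set positions gain `rank^0.25` normalized over
in-set genes, out-of-set positions lose `1/(N−m)`, and the score is the sum
of the running sum over all positions (integral form). The exponent and
normalization are configurable; 0.25 is the conventional rank-weighting
exponent for single-sample scoring. The cluster takes the argmax subtype;
several clusters may share one, and the handling of unassignable samples
is a reporting-level parameter.

## Survival analysis

DFS is time-to-first-event with right censoring; no competing-risks
machinery. Cox fits use the Efron tie approximation and report Wald 95%
CIs and p-values (HR + CI + P is the display convention served); the
partial-likelihood score test at β = 0 is exposed separately and equals
the log-rank chi-square for two untied groups, which the tests exploit as
a cross-check. Zero events or non-convergence (monotone likelihood /
complete separation) raise explicit errors rather than returning divergent
estimates. Pooled-arm analysis ignores the randomized arm for prognostic
questions, then fits arm contrasts within subtype for interaction-style
questions.

## Immune stratification and per-gene association

Ward clustering on Manhattan distance over the immune panel, cut at 2; the
cluster with the higher panel-mean expression is `immune-high` — the
labelling depends only on expression, never on cluster ids or sample
order. Per-gene Cox models use standardized continuous log2 expression
(HR per SD), adjusted for treatment arm, with BH across the panel; a
median-split dichotomized variant is available; either convention is
defensible for panel-scale data.

## Discovery of recurrence genes

Early = DFS event at ≤ 5 years; late = event-free beyond 5 years; patients
censored at or before the horizon are excluded as unclassifiable (a choice
— such patients are simply unlabelled). Pooled-variance two-sample t-tests
on log2 expression (Welch optional), fold change oriented late/early so
protective genes have FC > 1, compound significance rule FC > 1.5 or
FC < 1/1.5 *and* BH q < 0.05. The printed lower cut "0.67" is treated as
1/1.5 exactly so that swapping group labels maps FC → 1/FC with an
unchanged significance flag; the literal 0.67 is an option. Validation
re-tests only the discovered genes (BH over that set) and additionally
requires direction concordance (toggleable).

## The synthetic cohort

Defaults are the study conditions: 600 samples (the benchmark size), an
800-gene endogenous panel (50 classifier + 88 immune + 150 TNBC-signature
+ background genes), 10 housekeeping probes, 8 negative controls; subtype
proportions 327/124/69/296 over 816 (luminal A/B, HER2-enriched,
basal-like); PIK3CA prevalence 46/26/35/3% by subtype; centroid separation
2 log2 units with within-subtype noise SD 1; per-sample log2 scale SD 0.5;
Poisson(10) control background; IHC labels from a confusion process
(92.4% of luminal tumors labelled HR+, 86.8% of basal labelled TNBC,
59.4% of HER2-enriched labelled HER2+); planted hazard ratios 2.07
(LumB vs LumA), 0.66 (PIK3CA mutant within HR+), 0.59 (immune-high within
TNBC) on an exponential baseline of 0.04 events/year with ~20% independent
censoring truncated at 10 years of follow-up. Expression counts are
rounded (not floored) after exponentiation, for unbiasedness at low
counts. Event times are exponential by default because the Cox HR then
equals the planted ratio exactly; a Weibull proportional-hazards law is
available.

Panel-level properties — per-gene baseline levels, centroid shifts,
housekeeping means — are drawn from a *fixed* stream independent of the
cohort seed: two cohorts simulated with different seeds share the same
panel, the way a training and a study cohort profiled on one assay design
would. All cohort-level randomness (labels, noise, survival, degradation)
derives from a single seed through a hierarchy of per-stage
`SeedSequence` streams, so runs are byte-reproducible and stages can be
re-drawn independently.

The recurrence-discovery generator (`simulate_recurrence_cohort`) plants a
12.5% early-recurrence fraction (the observed HR+ proportion, 49/391) and
shifts 35 prognostic genes one log2 unit higher in long-term event-free
patients — all protective, matching the observed predominance of
protective discovery genes.

What the generator does **not** emulate: optical or lane artifacts, FFPE
degradation chemistry beyond a scalar shrink-toward-background factor,
assay efficiency variation, correlated gene-gene structure beyond the
planted blocks, non-proportional hazards, or informative censoring.
Passing tests therefore demonstrate that the *procedures* are implemented
correctly and recover planted structure under their own assumptions — not
that the pipeline would achieve comparable accuracy on real FFPE NanoString
data, where block structure is weaker and noise is not i.i.d. Gaussian.

## Numerical choices and problem sizes

Degenerate inputs have defined behaviour throughout: zero-variance
controls flag and collapse to the mean; constant genes are skipped with
warnings (per-gene Cox, correlations) or flagged (t-tests); all-identical
samples refuse a 2-cut; empty groups and event-free fits raise.

Monte-Carlo checks in the test suite use: 200 replicates at n = 500 for
hazard-ratio CI coverage, 1000 replicates at n = 200 for log-rank type-I
error, 60 replicates of the 400 × 400 discovery pipeline for FDR and
sensitivity, and smaller replicate counts (8–40) for module-level
variance-reduction and power properties. These sizes give the assertions
comfortable statistical margins while keeping the default suite fast; the
single-draw assertions use multiplicity-adjusted binomial bounds rather
than nominal ones so a correct generator passes with overwhelming
probability.
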