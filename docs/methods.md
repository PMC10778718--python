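# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## CBC dynamics

For cell type c ∈ {ANC, PLT, Hb, ALC, Mo} (units: cells/µL for ANC, ALC,
Mo; 10³ cells/µL for PLT; g/dL for Hb):

* c0 — pre-treatment value; min c — minimum over **all** on-treatment
  panels, the week-2 draw included (the nadir window has no stated edges,
  so the widest on-treatment window is used);
* c1 = √(c0 · min c); c2 — week-2 value; c3 = log(c2 / c0).

The log base for c3 is natural by default and configurable. Every
downstream use of c3 is sign- or correlation-based, hence base-invariant;
only absolute magnitudes change with the base. Ratios NLR = ANC/ALC,
PLR = PLT/ALC, LMR = ALC/Mo are formed at the 0-level (baselines) and
1-level (geometric means). All CBC values must be positive (geometric means
and log ratios are undefined otherwise); nonpositive inputs are rejected at
record construction.

Outcome groups: group 1 (early death, ED) — progression ≤ 12 months and
disease-specific death ≤ 15 months; group 2 (progression) — progression
observed with overall survival > 30 months; group 3 (non-progression) — no
recurrence, follow-up > 60 months. Early progression (EP) is progression
≤ 12 months regardless of survival. Patients fitting no rule stay
unassigned.

## Propensity matching and group tests

Propensity scores come from a logistic regression of arm on the requested
covariates (categorical covariates one-hot encoded); matching is greedy
1:1 or 1:2 nearest-neighbor without replacement on the logit scale, treated
patients processed in patient-id order with ties broken by control id for
determinism. A caliper (×SD of the logit propensity) is available but off
by default, since the matched design being mirrored states none. On
(quasi-)separation the matcher falls back to exact-stratum matching with a
warning. Balance is reported as standardized mean differences before and
after (categoricals: max over level indicators).

Group comparisons: Shapiro–Wilk on both arms at α = 0.05 decides between
Welch's t (both normal) and the Wilcoxon rank-sum (normal approximation,
no tie correction — so identical samples give p = 1 exactly); categorical
variables use chi-square without Yates correction. Flags mark p < 0.05 and
p < 0.1.

## Expression processing

Detection filter: an RNA is kept only if it has a positive count in
strictly more than 50% of all samples ("undetected in at least half"
excludes, so detection in exactly half is removed). Removals are logged per
biotype with detection fractions.

TMM normalization is implemented in-package (no installed Python library
provides it): reference sample = the one whose 75th count percentile
(scaled by library size) is closest to the mean across samples; per-sample
factors are inverse-variance-weighted means of M-values after symmetric
trimming of 30% on M and 5% on A (the reference defaults of the published
algorithm); factors are rescaled to geometric mean 1. The implementation is
validated in the test suite against frozen factors from the reference
implementation (edgeR 4.0.16) on a 5×3 toy matrix and a 200×6
negative-binomial matrix, agreeing to ≈5·10⁻¹¹.

Per-patient log₂FC: with effective library size L·f (library size ×
TMM factor), abundance a = count/(L·f) and
log₂FC = log₂((a_post + pc) / (a_pre + pc)). The pseudocount pc defaults to
0.5/mean(L) — half a read at average depth on the abundance scale — applied
identically to both samples so the pre/post swap antisymmetry is exact.
Normalization is joint across all samples by default (per-pair available
by subsetting); joint normalization keeps per-patient fold changes on one
common scale, which the cross-patient correlation analysis requires.

## Association screen

Pairwise-complete Pearson correlations of each RNA's per-patient log₂FC
against every CBC feature and the binary ED / EP indicators, with two-sided
t-distributed p-values; constant columns give missing entries, never 0.
"Significant" means p < 0.05 with **no** multiple-testing correction
throughout the screening stages — the procedure mirrors a screening design
that deliberately trades specificity for recall ahead of the network and
regression stages, and the null calibration tests verify the 5% rate.

Link-flag variants: for network admission a cell type is "linked" through
{c0, min c, c1}; for node annotation and the coverage criterion through
{c0, c1, c2, c3, min c}. Ratio groups always use the 0/1 pair.

Homeostasis screen: for cell type c and baseline b ∈ {c0, c1}, an RNA is
flagged when (i) the cohort-level corr(b, c3) is negative, (ii) the RNA is
significantly correlated with both b and c3, and (iii) with opposite signs.
This operationalizes "the RNA explains the negative baseline–recovery
relation" as the minimal opposite-sign reading; a leave-one-RNA-out change
in the cohort correlation would be an alternative reading and is not
implemented. Quadrant classes follow the plotting convention: color by ED
sign (red positive, blue negative), line style by cell type (solid for
ANC/PLT, dashed for Hb/Mo/ALC). RNA–outcome correlations use the binary ED
indicator rather than survival time.

## Network

Admission: (1) ≥ 3 of the 8 hematological link groups **and** significant
vs both ED and EP, or (2) |R vs ED| > 0.5. Edges connect admitted RNAs with
pairwise |R| above the threshold (0.5 and 0.6 networks are both built);
"R > t" is read as |R| > t so that anti-correlated ED-relevant RNAs stay
connected, with the signed R kept as an edge attribute. Isolated admitted
nodes are dropped, so reported node counts describe the connected graph —
which is why one admitted pool yields different node counts at the two
thresholds. Edge significance is not additionally required (magnitude
only). Export: GraphML (lossless round-trip) and TSV edge list.

## Key-RNA selection

All-subsets regression: OLS of the binary ED indicator (linear probability
model) on every subset of network-RNA log₂FC profiles up to max_k
predictors, centered, predictors standardized. The response is not named by
the design being mirrored; ED is the outcome the selected RNAs are
validated against, so it is the default and configurable. Retained models =
the best model per size k by adjusted R² (plain R² is monotone in k,
adjusted R² need not be; both are stored). Inclusion frequency = fraction
of retained models containing the RNA. max_k defaults to
min(10, n/4, p), reduced when complete enumeration up to that depth would
exceed ~4·10⁶ models — enumeration stays exact per size, only the depth
shrinks. Ties in adjusted R² break lexicographically on sorted member ids;
exactly collinear predictors are dropped with a warning. Key ncRNAs need
inclusion frequency strictly > 0.5, key mRNAs strictly > 0.6, as the union
over the two networks' searches.

A caveat the test suite makes explicit: under the per-size-best retained
rule the *maximum* inclusion frequency is high even for pure-noise
predictors (the chance-best predictor persists across per-size champions);
what the null does guarantee is that no *particular* RNA is crowned
consistently across replicates. The frequency thresholds therefore act as a
within-network ranking device, not an error-rate control — the composite
triple additionally requires the coverage criterion and ED-sign structure.

All-CBC coverage: RNAs in the |R| > 0.5 network linked (annotation
variant) to all five cell types. The final signed triple = strongest
ED-positive key ncRNA (+), strongest ED-negative key ncRNA (−), and the
all-CBC mRNA with the strongest ED correlation (its own ED sign); slots
without a qualifying RNA stay empty and the score uses the components that
exist.

## Composite score and survival

Score = Σ ed_sign(r) · log₂FC(r) over the triple, i.e.
+positive-ncRNA − negative-ncRNA − negative-mRNA in the canonical case;
this is the only sign assignment under which "score < 0 ⇒ favorable
survival" is coherent with the components' ED-correlation signs. The
dichotomy is at absolute zero (not shift-invariant — asserted by a negative
test). Disease-specific survival: disease deaths are events; other-cause
deaths and living patients are censored at their last time. Kaplan–Meier
per score group (lifelines), log-rank over the full follow-up (the
30-month rates are reported descriptively off the curves,
right-continuous convention S(t) = P(T > t)), Wilcoxon rank-sum of the
score by ED status, and median follow-up by reverse Kaplan–Meier.

The over-representation test is a local one-sided Fisher/hypergeometric
test per GMT term with Benjamini–Hochberg FDR — a deliberate, offline
replacement for web-based enrichment services; ranked enrichment is out of
scope.

## Synthetic cohorts

The generator emulates the data layout of a single-institution CCRT
biomarker study with paired pre/week-2 plasma RNA samples and weekly CBC
panels. One per-patient latent severity u ties the layers together:

* **ED subgroup**: a random `ed_fraction` (default 0.2) of patients form
  the ED group and carry a latent shift of `ed_latent_shift` (default 2.5)
  standard deviations; u is standardized before use. Early death is
  modelled as a distinct fragile subgroup rather than the tail of one
  Gaussian — a thresholded continuum caps the achievable point-biserial
  RNA–ED correlation near 0.45, too weak for the |R| > 0.5 admission route
  that a real discovery cohort exercises.
* **Counts**: negative binomial (gamma–Poisson; variance μ + αμ², α =
  `dispersion`, default 0.15) with lognormal per-sample size factors
  (SD 0.3 on the log scale) and a lognormal abundance spectrum (median
  ≈ `baseline_mean_counts`/e, log-SD 1.5) that leaves a small tail of
  undetectable RNAs for the detection filter. Planted drivers are
  biomarker-grade abundant and shift their post/pre log₂ ratio by
  `driver_effect` · sign · u (canonical roles: ED-positive miRNA,
  ED-negative lncRNA, ED-negative mRNA).
* **CBC coupling**: baselines load on u with weight `cbc_coupling`
  (positively for ANC/PLT/Mo, negatively for Hb/ALC — the adverse
  hematology profile), and the week-2 log-ratios load with the opposite
  sign, which plants both the driver–CBC correlations and the cohort-level
  negative baseline–recovery correlation that the homeostasis screen
  targets. Weekly panels follow a multiplicative myelosuppression decline
  with nadir around week 4 plus lognormal noise.
* **Survival**: ED — progression U(2, 12), disease death ≤ 15 months;
  progression group — progression U(3, 30) with 40% late disease deaths,
  the rest censored; non-progression — censored at U(61, 96) months.
  Within-group times are simple uniforms because only group membership and
  the 30-month horizon matter downstream.

Defaults describe a 40-patient cohort with ~2000 RNAs across eight
biotypes — deliberately smaller than a full transcriptome so that complete
pipeline replicates stay cheap; the association, admission and selection
stages are all per-RNA, so the scale enters only through the
multiple-screening burden. What the generator does **not** emulate:
sequencing-run batch effects, biotype-specific noise, correlated non-driver
RNA modules, informative censoring, or covariate-outcome confounding —
passing tests show the pipeline recovers planted structure under its own
assumptions, not that real cohorts behave this way.

## Numerical and testing notes

* Determinism: one `numpy` Generator per simulation seed; identical
  configs are bit-identical. Greedy matching and subset ties are broken by
  id order.
* The null-calibration tests check the screening rate against the 99%
  binomial band for a 2000-RNA panel around 0.05 (pooled over replicates),
  and homeostasis flags against a bivariate-normal Monte-Carlo oracle
  (observed/expected within a factor of two) — the bands were fixed from
  the sampling model before inspection, with the panel-level width
  retained to absorb the asymptotic t-approximation on fold-change data.
* The subset search is validated against a direct statsmodels OLS
  enumeration (≤ 12 predictors); KM curves against the empirical survival
  function in the censoring-free case; the ORA p-value against a direct
  hypergeometric tail sum; TMM against frozen reference factors.
* Reference replicate conditions for recovery statistics: 20 seeds,
  n = 40, driver_effect = 1.5, cbc_coupling = 0.7, three planted drivers.

## Known limitations

* The screening threshold (uncorrected p < 0.05) is inherited from the
  mirrored design; the package reports it as a screen and provides the
  null-calibration machinery to quantify it, but offers no FDR-controlled
  alternative.
* The linear-probability subset regression ignores the binary nature of
  the ED outcome; with collinear drivers the inclusion-frequency criterion
  can miss redundant true drivers (the triple's other two routes mitigate
  this).
* Exact reproduction of any specific cohort's selected RNA identities
  depends on unstated upstream choices (response variable, retained-model
  pool, PSM algorithm details) documented above as configurable defaults.
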