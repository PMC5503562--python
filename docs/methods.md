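# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, the synthetic data model behind the test
suite, and the numerical conventions that matter at the edges.

## Proliferative index

A sample's PI is the **median** normalized expression of a proliferation gene
set — by default a 131-gene PCNA meta-gene list supplied by the user as a
plain text file. Genes of the set absent from the matrix are dropped (their
number is reported as `n_genes_used`); the median is robust to that
shrinkage, and erroring would make cross-platform use impractical. A
zero-overlap set is an error. Medians over an even number of genes are the
mean of the two central values (numpy convention).

Two normalizations feed the PI:

* **CPM** for cross-cohort comparisons: each sample scaled to one million
  counts. PI on CPM is invariant to per-sample rescaling of raw counts.
* **VST** for within-cancer survival work. The reference transformation in
  the field fits a dispersion trend before stabilizing; re-implementing that
  fit is out of scope, so the documented stand-in is
  `log2(count / size_factor + 1)` with DESeq-style median-of-ratios size
  factors computed over genes with all-positive counts. It is monotone per
  sample and variance-stabilizing for negative-binomial counts at moderate
  means, which is all the downstream rank- and regression-based statistics
  need. When no gene has all-positive counts the library-size factors are
  used with a warning. `expression_from_table` is the adapter seam for
  substituting an externally computed VST matrix.

Cohorts from different sources (tumor vs normal compendia) are normalized
independently; the package does not attempt co-normalization, and the
tumor-vs-normal comparisons are rank-based for that reason.

Group comparisons of PI (tumor vs adjacent normal, stage T1 vs T4, N0 vs N1,
M0 vs M1, subtype contrasts) use the two-sided Wilcoxon rank-sum test: exact
null when the pooled n is at most 20 with no ties, normal approximation with
continuity correction otherwise. PCA–PI correlations center genes across
samples, take sample scores from the SVD, and report Spearman rho per
component; Spearman uses average ranks for ties throughout.

## Survival association and PICs

All survival fits are **univariate** Cox proportional-hazards models
(survival time = days to death or last follow-up, whichever is larger;
event = death observed). The partial likelihood uses the **Efron tie
correction** and is maximized by Newton's method (step tolerance 1e-9, at
most 50 iterations). The per-transcript scan runs the same iteration batched
across genes: risk-set sums are suffix cumulative sums over the time-sorted
samples, so one cancer's whole transcriptome costs a few vector operations
per Newton step.

Non-convergence — iteration cap, non-positive information, or the
coefficient magnitude exceeding 15 on the VST scale (the "estimate nearing
infinity" seen under monotone separation) — yields `converged=False` and
**p = 1**. This failure convention keeps the cancers × transcripts p-value
matrix complete, which the downstream selection relies on. Constant
covariates and cohorts with fewer than two events get the same treatment.
Wald p-values are reported; the test suite cross-checks coefficients and
standard errors against an independent implementation on tied data and
against brute-force partial-likelihood maximization on small untied data.

A **PIC** (proliferation-informative cancer) is a cancer whose PI Cox
p-value, Bonferroni-corrected by the number of cancers passing the cohort
filter (at least 50 patients, at least 25 deaths), is strictly below 0.05.
The correction factor is the cancer count, not the transcript count, because
the family of tests being corrected is the per-cancer PI scan.

**Shared survival transcripts** are those with uncorrected Cox p < 0.05 in
at least 9 of the (19) cancers; the boundary is strict. Cancers are
clustered on the −log10 p rows restricted to those transcripts with
Euclidean distance and Ward linkage (the Ward.D2 variant scipy implements),
and the 2-cluster cut is compared to the PIC labels. Identical rows merge at
height zero; the cluster count is configurable but 2 is the documented
default since the dichotomy of interest is PIC vs non-PIC.

Kaplan-Meier quartile tests stratify at the 25th/75th percentiles of a score
(PI or a model's predictions); samples exactly on a boundary go to the
extreme group (configurable to `exclude`). The two-group log-rank test and
KM estimators come from lifelines.

## Cross-cancer extreme-survivor models

Per cancer, outcome 0 is the k = 18 *uncensored* shortest-surviving patients
and outcome 1 the 18 longest-surviving patients; censored patients are
eligible for the long-survival group because long follow-up while alive is a
good outcome, and restricting to deaths would exclude exactly the best
outcomes (k = 18 matches the smallest cohort's quartile in the motivating
data). Ties at the k-th position keep the lexicographically smaller sample
id, making the design reproducible. Genes are z-scaled within each cancer
over the design samples (zero-variance genes map to 0 with a warning), the
cohorts are concatenated, and a 70/30 split stratified by outcome (ceiling
convention on the training side) separates training from testing.

* **LASSO / ridge**: penalized binomial regression over a 30-point lambda
  path (from the data-derived maximum down three decades), 5-fold
  outcome-stratified cross-validation, and the **one-standard-error rule**:
  the strongest penalty whose mean CV loss is within one SE of the minimum.
  The CV loss is binomial deviance by default (mean squared error available
  via `cv_loss="mse"`). On weak-signal designs the 1-SE rule can defensibly
  return the empty (intercept-only) model; its constant scores evaluate to
  AUC 0.5.
* **Random forest**: 500 trees, `max_features` capped at 1000.
* **Linear SVM**: cost grid 1e-5 … 1e4 in decade steps, chosen by 5-fold CV
  squared error on class predictions.

Evaluation is the empirical ROC and trapezoid AUC on the held-out test
partition; AUC is invariant to monotone transforms of the scores and equals
the Mann-Whitney U statistic divided by n1·n0. Two models' correlated AUCs
on the same test set are compared with **DeLong's paired test** (midrank
implementation).

The **permutation null** redraws `set_size = 7` distinct cancers
(`n_draws = 1000` by default; scaled down in the test suite), reruns
dichotomization → scaling → split → fit → evaluation per draw, and records
the test AUC with the number of PICs in the draw; draws that fail a
precondition are redrawn and counted. Summaries are the Spearman correlation
between PIC count and AUC and the empirical exceedance p of a reference
(PIC-only) AUC, computed as (1 + #{draws ≥ ref}) / (n + 1).

**Full-cohort assessment** scores every patient of each PIC with the fitted
model (per-cancer z-scaling recomputed over the full cohort); cancers with
more than 25 uncensored patients outside the training set are evaluated on
non-training patients only (flag `held_out`), the rest on the full cohort
(flag `includes_training`, reported so the optimism is visible); top vs
bottom predicted quartiles are compared by log-rank.

## Mutation and drug associations

Somatic variant classifications map to a closed vocabulary: missense,
nonsense, synonymous (Silent), everything else `other` with a logged
warning. **Burden** is the log10 of each patient's total mutation count
across all classes, with a +1 pseudocount so zero-mutation patients are
retained as the lowest ranks (Spearman only sees ranks, so any monotone
zero-handling is equivalent); the association with PI is Spearman, pooled or
per cancer (pooled uses raw PI without per-cancer re-centering; per-cancer
z-scoring is available via the per-cancer scope).

The **per-gene scan** contrasts PI between carriers of at least one
missense/nonsense mutation in the gene and patients with only synonymous or
no mutation in it; patients whose only variants in the gene are class
`other` are excluded from both groups (they are neither protein-altered nor
clean controls). Genes need at least 5 qualifying carriers in a cancer to be
tested there ("at least 5 mutations" read as carriers; a raw-count reading
is configurable), and cancers with fewer than 100 eligible genes are skipped
entirely. Genes tested in at least 2 cancers are combined with **Fisher's
method** (χ² = −2Σln p, df = 2k; p = 0 inputs are an error) and controlled
with Benjamini-Hochberg FDR.

A caveat the synthetic experiments make explicit: when total mutation burden
rises with proliferation, the carriers of *any* gene are a burden-selected,
higher-PI subset, so per-gene p-values are globally inflated — the q-q
inflation familiar from real tumor data. Interpret the scan's tail genes,
not its bulk.

Cell-line PI is the median expression over probes mapping to PI-set genes
(all probes of a gene contribute); per-drug Spearman correlations with EC50
require at least 10 lines and are BH-adjusted across drugs. Treatment rank
matrices (probe × treatment, each column a permutation of 1..P, rank 1 = the
strongest expression increase after treatment) are scored by the median rank
of PI probes; a treatment's **activation percentile** is the fraction of
treatments with a numerically larger median rank, so growth-promoting
treatments score near 1 ("top") and strongly anti-proliferative ones near 0
("bottom decile"). Two treatments' full PI-probe rank distributions are
compared with a Kolmogorov-Smirnov test.

## Synthetic cohort model

The generator exists so that every downstream stage has ground truth. Per
patient *i* of cancer *c*:

* latent proliferation `z_i ~ N(mu_c, 1)` with per-cancer shifts
  `mu_c ~ N(0, 0.5²)`;
* an auxiliary program value `w_i ~ N(0, 1)`, independent of `z`;
* library size factors `s_i ~ LogNormal(0, 0.25²)`;
* counts `x_gi ~ NB(mean = s_i q_g exp(L_gi), dispersion phi_g)` via the
  gamma-Poisson mixture, with baselines `q_g ~ LogNormal(ln 30, 1)` and
  `phi_g ~ U(0.05, 0.4)` (variance = m + phi·m²);
* loadings: `beta_g ~ U(0.5, 1)` on the 131 PI genes, zero elsewhere; a
  disjoint 60-gene auxiliary block is sliced per cancer, each slice loading
  on its own cancer's `w` with random-sign magnitudes `U(0.5, 1)`; and every
  gene carries a weak pleiotropic coupling `eps_{g,c} ~ N(0, 0.15²)` to the
  cancer's auxiliary program. The random signs matter: one-signed blocks
  would shift the median-of-ratios size factors with the factor itself and
  leak it into the PI (a compositional artifact this design eliminates), and
  the weak pleiotropy is what lets individual transcripts carry partial
  prognostic signal in non-PICs — the regime in which a shared survival
  signature restricted to ≥9-of-19 significance is non-empty and stable;
* survival `T_i ~ Exp(h0 exp(gamma_c z_i + eta_c w*_i))` with
  `h0 = 1e-3/day`, `gamma_c = 0.8` exactly in the planted PICs (0
  elsewhere; a gamma = 0 configuration plants no PICs), and
  `eta_c = ±0.8` (random sign) in non-PICs acting on
  `w*_i = 0.6 w_i + 0.8 xi_i`: the survival-relevant facet of the auxiliary
  program is only partially transcriptional (fidelity 0.6), reflecting that
  immune/stromal outcome drivers are incompletely observed in expression —
  without this, extreme-survivor outcomes in non-PICs are almost perfectly
  learnable and random cancer subsets rival the PIC-only model, inverting
  the qualitative structure the generator is meant to emulate;
* censoring: independent exponential whose per-cancer rate is root-found so
  the expected censoring fraction equals the configured 0.35;
* pathologic T/N/M stage follows `z` plus unit noise in PICs and is pure
  noise in non-PICs;
* mutations: per-patient totals `Poisson(exp(ln 30 + 0.5 z))` scattered
  uniformly over the gene universe with class frequencies missense .5 /
  nonsense .1 / synonymous .3 / other .1; three designated driver genes are
  additionally mutated with probability logistic in `z` (intercept −1,
  slope 2);
* drug panels: 486 cell lines with their own proliferation surrogates; 4 of
  24 drugs are proliferation-targeting with log-EC50 slope −1 per unit of
  the surrogate (noise SD 1); the rank matrix has 60 treatments of which 5
  anti-proliferative (PI probes shifted −3 SD in differential score before
  ranking) and 3 growth-promoting (+3 SD).

Everything is deterministic given the seed; the three generators draw from
independent child streams of it.

**What a green test does and does not establish.** The generator emulates
the statistical skeleton of the motivating multi-cancer analyses: a
continuous proliferation axis expressed in a gene block, survival coupled to
it in a subset of cancers only, cancer-unique auxiliary survival programs,
burden and driver-gene coupling, and drug effects. It does *not* emulate
batch effects, gene-length or GC bias, subtype taxonomies, tumor purity,
correlated gene-gene noise beyond the planted factors, non-proportional
hazards, informative censoring, or integer-day survival ties. Green
recovery tests therefore establish that the pipeline's statistics recover
the parameters of this stated world, not that they are robust to everything
real cohorts contain.

## Numerical conventions and degenerate inputs

* Duplicate expression rows collapse by summation (counts are additive);
  composite `symbol|entrez` ids keep the symbol.
* Stage strings reduce to whole-stage ordinals (T1a/T1b → T1); unparseable
  stages are missing, never errors.
* Zero-total expression columns are errors under CPM; zero survival days are
  allowed but logged.
* Exact Wilcoxon only without ties and pooled n ≤ 20; otherwise normal
  approximation with continuity correction.
* Quartile ties go to the extreme group by default.
* The Cox divergence bound (|coefficient| > 15) is calibrated to the VST
  scale; on that scale a genuine hazard ratio of e¹⁵ per unit is
  unattainable, so the bound only triggers under separation.
* Empirical permutation p-values use the add-one convention, so they are
  never zero.
* All random procedures (simulation, CV folds, splits, permutation draws)
  take explicit seeds; derived seeds stay below 2³¹.

## Known limitations

* The VST stand-in is not the reference dispersion-trend transformation;
  rank-based downstream statistics are insensitive to the difference, but
  absolute transformed values differ.
* Cox fits are univariate by design; no clinical-covariate adjustment.
* The per-gene mutation scan inherits the burden-selection inflation
  described above; its FDR is controlled against the wrong (uniform) null
  whenever burden correlates with PI — as in the data that motivated it.
* The dichotomized classifier discards the middle of the survival
  distribution; its AUC is not an estimate of full-cohort discrimination
  (the full-cohort KM assessment exists for that reason).
* Synthetic drug/rank data use normal approximations for microarray-scale
  expression rather than count models.
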