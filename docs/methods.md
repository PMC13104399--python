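# Methods

## Scope and data model

The package analyses a proteins × samples abundance matrix with a
three-group design (N/P/D; defaults 11/6/9 = 26 samples). Abundances are
iBAQ-style linear intensities on input; a cell is *missing* when the source
table holds 0 or an empty field, because MaxQuant writes 0 for non-detected
iBAQ values and log2(0) is undefined. Protein identity is the full
semicolon-joined accession group; the matrix keeps proteins as rows and
samples as columns, matching the proteinGroups orientation.

## Synthetic data generator

The generator emulates the statistical structure a label-free experiment
hands to this analysis; it is the basis of all tests and of the acceptance
run.

* **Intensities.** Protein baselines are `b_i ~ N(base_mu, base_sigma²)` in
  log2 units (defaults 25 and 2, typical of log2 iBAQ ranges); cell values
  are `b_i + effect + N(0, noise_sd²)` with `noise_sd = 0.5`.
* **Planted effects.** `n_differential` proteins (default 23) carry a log2
  mean shift in one group; the default panel alternates a +2.5 shift in P
  with a −2.5 shift in D, mirroring a mix of pre-disease increases and
  disease decreases. Planted baselines are drawn at `base_mu + base_sigma`
  with SD `base_sigma/4`: high enough that the panel survives the validity
  filter, but not so abundant that the planted shifts move the per-sample
  intensity totals that column normalization divides by (at the +2σ
  abundance tier a single planted protein can be several percent of a
  column total, and sum-normalization then smears its group shift onto
  every other protein — a real hazard of total-intensity normalization that
  the generator deliberately avoids building into its null).
* **Missingness.** Each cell is detected with probability
  `expit(missing_slope · (x − missing_mid))` of its latent log2 value, so
  dropout is left-censored (missing-not-at-random). Defaults
  `slope = 1.0`, `mid = 23.5` were calibrated once so that the 90%
  group-validity filter retains ≈52% of 3963 proteins (≈2076), the
  attrition regime the pipeline targets; under these defaults ~85% of
  proteins carry at least one missing cell. Setting
  `missing_mid = −inf` switches dropout off entirely.
* **Ground truth.** The pre-missingness latent matrix, planted ids, true
  group means and per-contrast directions are returned alongside the
  matrix, enabling oracle tests (effect recovery, monotone missingness).

What the generator does **not** emulate: correlated protein modules
(background proteins are independent), peptide-level effects, batch or
acquisition drift, FFPE chemistry, and abundance-dependent noise. Passing
tests therefore demonstrate correctness of the pipeline's computations and
its behaviour under the assumed LFQ missingness model — not performance on
any particular real tissue dataset.

## Preprocessing

Stage order is fixed: flag removal → normalization/log2 → validity filter →
imputation. Consequences of that order: normalization totals are computed
on the flag-cleaned matrix, and imputed values can never rescue a protein
past the filter.

* **Normalization** divides each column by (its non-missing sum / 10¹¹), so
  every sample's non-missing linear total equals `scale_total = 1e11`
  afterwards (checked to relative 1e-9). The alternative reading "divide by
  10¹¹ only" was rejected because it would not equalize loading between
  samples.
* **Validity filter** keeps a protein iff some group g has
  `valid ≥ ceil(min_valid_fraction · n_g)`; "at least 90%" is a lower bound
  on the observed fraction, hence the ceiling. For (11, 6, 9) at 0.90 the
  thresholds are (10, 6, 9).
* **Imputation** draws each missing cell of sample *s* independently from
  `N(m_s − downshift·σ_s, (width·σ_s)²)` with the long-standing defaults
  `downshift = 1.8`, `width = 0.3` (in units of the sample's observed log2
  SD). Both are exposed as parameters. A sample needs ≥2 observed values;
  all draws derive from one seed (per-sample substreams), so reruns are
  bit-identical.

Known artifact, documented rather than hidden: on a *null* matrix with
MNAR dropout, proteins that pass the filter through one well-detected group
receive downshifted imputations in their other groups, which manufactures
group differences; the selection rate on an imputed null sits near the
nominal α, while on a complete null it is clearly below α (the test suite
checks the latter). On real data this is indistinguishable from genuine
presence/absence signal, which is exactly why downshifted imputation is
used.

## Differential testing

Decision tree per protein (α = 0.05 throughout):

* all three groups pass Shapiro–Wilk (p > α) **and** Levene (Brown–Forsythe
  variant, median-centred) p > α → Fisher one-way ANOVA + pooled-variance
  Student t pairwise;
* all normal, Levene p ≤ α → Welch ANOVA + Games–Howell pairwise (both via
  pingouin);
* any group non-normal → Kruskal–Wallis + Dunn pairwise (rank z statistic
  with tie correction, implemented here).

The normality gate requires *all* groups to pass — the aggregation rule is
a choice, made once. A constant group is treated as maximally non-normal
(Shapiro–Wilk is undefined on it). Proteins constant across all samples are
excluded and logged, not given NaN p-values.

Holm adjustment is applied within each protein across its three contrasts
(m = 3), implemented directly (sorted pᵢ · (m−i), running maximum, cap at
1) and verified against statsmodels' step-down in the tests. No
protein-level FDR is applied: volcano exports carry raw p-values, and the
selection rule is omnibus p < α plus ≥1 Holm pairwise p < α. Note that the
decision tree itself consumes the data, so the Fisher branch is taken on
~0.95³·0.95 ≈ 81% of truly normal homoscedastic proteins — an inherent
property of test-then-test procedures.

Log2 fold change for contrast A_vs_B is mean(B) − mean(A) on the log2
scale (disease minus control for the standard contrasts).

## LDA subset search

The classifier is classical multi-class LDA: Gaussian classes, pooled
within-class covariance with divisor n − g (the MASS convention — note
scikit-learn pools with divisor n, which shifts knife-edge decisions when
priors are unequal), priors equal to class proportions. Accuracy is
resubstitution (the model scored on its own training samples): no holdout
exists at this stage, by design, and the cross-validation module is the
counterweight. "% separation by LD1" is the first eigenvalue of the
between/within generalized eigenproblem over the eigenvalue sum.

The search enumerates all C(n,k) subsets for k in the requested range
(default 2–5), lexicographically over the stable candidate order, recording
every subset's accuracy. A singular within-class scatter (possible for
near-collinear proteins at n = 26) is ridge-regularized with
1e-8 · trace(W) and flagged, so the enumeration never aborts. Frequency
ranking counts how often each protein occurs among the perfect subsets at
the minimal size; ties break by ascending omnibus p, then name, making the
ranking deterministic.

The candidate panel is the significant set capped at the 23 smallest
omnibus p-values (`max_candidates`), the panel size this analysis is
designed around; C(23,5) = 33,649 subsets evaluate in seconds.

## Screening

ROC AUC uses the rank statistic (ties one half) and equals the probability
that a random disease-group sample outranks a random control. Orientation
is fixed — positive class = disease, score = abundance — and never flipped
to max(AUC, 1−AUC): proteins that fall with disease genuinely score below
0.5, which preserves direction information. "Accuracy" for a single protein
is the best confusion-matrix accuracy over all midpoint thresholds, both
orientations — an interpretation, since no threshold rule is canonical for
single-feature screening; a single-feature LDA accuracy gives nearly
identical values on separable data. Pearson correlations are computed over
the pooled 26 imputed samples; the strong-pair threshold (default 0.6) is
applied to signed r. With planted group effects, panel proteins shifted in
the same group are strongly correlated in the pooled view — pooled
correlation mixes within-group covariance with between-group structure,
which is worth remembering when reading the strong-pair count on synthetic
data.

## Cross-validation

Per feature set and partitioning seed: a stratified 70/30 split (per class
round-half-up of 0.7·n_g, at least one sample per class on each side; for
(11, 6, 9) this is (8, 4, 6) train / (3, 2, 3) test), repeated (3×)
stratified 4-fold CV on the train side (reported; nothing is tuned), refit
on the full train side, scored on the untouched test side. Ten consecutive
seeds from the pipeline's base seed drive the partitions. A pair is
*perfect* when its test accuracy is 1 for **every** seed; an averaged rule
is available (`perfect_rule="mean"`) since "accuracy of 1 across seeds"
admits both readings — the all-seeds reading treats it as an exact
criterion, which is this package's default.

The model is multinomial (softmax) logistic regression with mild L2
(inverse strength C = 100, intercepts unpenalized). The penalty is
necessary: an unpenalized multinomial likelihood diverges on linearly
separable data, and separable pairs are precisely the interesting ones on
~18 training samples. It is fitted by a compact damped-Newton solver (the
enumeration performs ~33,000 fits on matrices of ≤26 rows), with a 1e-10
Hessian ridge absorbing the softmax gauge direction; the solver is verified
prediction-for-prediction against scikit-learn's LogisticRegression at
matched regularization in the test suite.

## qPCR (2^−ΔΔCt)

Technical replicates are averaged before differencing. ΔCt = mean target Ct
− mean reference Ct per sample; the calibrator is the arithmetic mean ΔCt
of the control group (a group-design convention, rather than a single
calibrator sample), so the control group's geometric mean fold change is
exactly 1. Fold changes are invariant to any global Ct shift. Ct values
outside (0, 45) are rejected; samples lacking a reference reading are
excluded with a warning. Group comparisons reuse the two-sample branch of
the differential decision tree (pooled t / Welch t / Mann–Whitney).
Amplification-efficiency correction is out of scope.

## Numerical and reproducibility choices

* One global seed per run; stage sub-seeds derive deterministically
  (SeedSequence spawning for the generator and imputation, consecutive
  integers for CV partitions, kept well below 2³¹).
* Tables are written as TSV with `NA` for missing and 6 significant digits;
  round trips preserve the missingness mask exactly and values to that
  precision.
* Degenerate inputs fail loudly and early: all-missing columns, samples
  with <2 observed values, single-class ROC labels, classes too small to
  split, empty perfect-subset lists for ranking.
* The acceptance script runs the full pipeline at study scale (3963
  proteins, 23 planted, 26 samples, 253 CV pairs × 10 seeds) in roughly a
  minute on one CPU; the test suite uses smaller problem sizes (hundreds to
  ~2000 proteins) chosen to keep each statistical check well-powered.

## Limitations

* Resubstitution LDA on 26 samples overfits by construction; minimal
  perfect-subset sizes on strongly separated synthetic data (often 2) are
  smaller than what weakly separated real data yields, and should be read
  together with the held-out CV counts.
* The generator's independence between background proteins understates the
  correlation structure of real proteomes; the strong-pair count on
  synthetic data reflects planted group structure, not co-regulation.
* Type-I control of the full preprocess-plus-test chain under MNAR
  imputation is approximate (see Preprocessing); only the complete-data
  null is strictly below α.
* Games–Howell and Welch ANOVA come from pingouin and inherit its small-n
  behaviour; Dunn p-values use the normal approximation with tie
  correction, without exact small-sample tables.
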