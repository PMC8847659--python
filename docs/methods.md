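# Methods

## The signature and its groups

Patients are stratified by comparing two discrete copy-number (CN) levels
in the cBioPortal convention (−2 deep loss, −1 shallow loss, 0 diploid,
1 low-level gain, 2 high-level amplification): FZR1 (the APC/C co-activator
that directs SKP2 ubiquitination) against a deubiquitinase of SKP2, USP10
by default (USP13 and the negative-control USP14 are selectable).
FZR1 > USP means "high SKP2 ubiquitination" (hence low SKP2 activity, high
p27, expected better outcome), equality "intermediate", FZR1 < USP "low".
Missing CN on either gene yields "unclassified"; such rows are retained,
counted in the run manifest, and excluded from group contrasts — the choice
of exclusion over imputation is deliberate, since the discrete levels admit
no obvious imputation model. For expression-only datasets a median-split
variant is used: FZR1 ≤ its dataset median with USP10 above its median is
"low", the mirror image "high", everything else — including patients
exactly at both medians, because the rule is "≤ median" taken literally —
"intermediate".

Throughout the package the group *step* is numbered high = 0,
intermediate = 1, low = 2, so that "high" is the baseline level of every
regression and the step counts progressively *more* SKP2 activity.

## Synthetic cohort generator

The generator is first-class, tested code: it produces cohorts with the
statistical structure the analyses assume, so that calibration and
parameter-recovery claims are measurable.

* **CN levels** are drawn independently per gene from configurable
  marginals. The default marginal (0.02, 0.13, 0.70, 0.13, 0.02) is
  symmetric, so the signature splits roughly 24/52/24 high/intermediate/low
  (P(equal) = Σp² ≈ 0.52 under independence). Real cohorts do not publish
  these marginals for the signature genes; the defaults are a documented
  convention, not an estimate. Joint CN dependence between genes is not
  modelled.
* **Subtypes** default to proportions 0.75/0.07/0.16 luminal/HER2/TNBC
  (remainder "other"), the mixture seen in large breast-cancer registries;
  receptor statuses are then set consistently with the IHC definitions.
* **Clinical effects are luminal-only by default** (`luminal_only=False`
  applies them cohort-wide), mirroring the luminal-specific associations
  the signature is designed around.
* **p27** (RPPA-like, arbitrary units) decreases by `p27_effect` (default
  0.3) per group step with noise SD `p27_sd` = 1.
* **Survival** is exponential with baseline hazard 0.006/month; the low
  group's hazard is multiplied by `hazard_ratio_low_vs_high` (default 1.8).
  Censoring is uniform on [0, T]; T is found by bisection on the analytic
  mixture censoring probability E[(1 − e^{−hT})/(hT)] so the realized
  censor fraction lands within a few percent of the target (default 30%).
  A uniform window is the simplest mechanism independent of group.
* **Stage (I–IV) and grade (1–3)** follow proportional-odds models:
  logit P(Y ≤ j) = α_j − shift·step with baseline category probabilities
  (0.18, 0.55, 0.22, 0.05) and (0.20, 0.45, 0.35) and default shift 0.5
  log-odds per step, so lower-ubiquitination patients skew to higher
  stage/grade.
* **Positive lymph nodes** are NB2: log μ = β₀ + β₁·[intermediate] +
  β₂·[low] with default β = (0.43, 0.29, 0.58) and dispersion θ = 0.25
  (var = μ + μ²/θ); draws use the gamma–Poisson mixture.
* **Expression** (log2 scale) ties to a single latent SKP2-activity factor
  `latent_skp2` = (step − 1) + SKP2 CN level + N(0, 1). A `frac_responsive`
  fraction of genes (default 20%) loads on it with weights
  N(0, `expr_effect_sd`²); the SKP2 row tracks the factor directly and
  FZR1/USP10/USP13 rows increase with their own CN (slope 0.5 per level).
  Using one shared factor is what makes the two validation contrasts
  (signature groups, SKP2 CN) concordant, as they are hypothesized to be in
  real tumors.
* **Reference perturbation profiles** are random permutations of the gene
  universe, except for planted "reversers" that rank the query's down-genes
  at the very top and up-genes at the very bottom.

Determinism: each `simulate_*` call seeds one `numpy` Generator from the
config seed (expression uses seed + 1), so identical configs give
bit-identical tables.

What the generator does **not** emulate: microarray preprocessing, probe
mapping, RPPA normalization, correlated CN segments, subtype-specific
expression programs, non-exponential hazards, or informative censoring.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated model, not robustness to the messier
structure of real cohort data.

## Statistical components

* **ANOVA / t tests.** Classical one-way decomposition; F = 0 (p = 1) when
  both between- and within-group sums of squares vanish. The high-vs-low
  p27 comparison uses Welch's t with Satterthwaite df by default for
  robustness to unequal variances; a `--pooled` flag restores the
  pooled-variance form.
* **Moderated t.** Per-gene two-group fits give (lfc, s², df) with pooled
  residual variance. The variance prior (d₀, s₀²) is estimated by method
  of moments on log s²: e_g = log s²_g − ψ(df/2) + log(df/2) has variance
  ψ′(d₀/2) + ψ′(df/2) under the scaled-F marginal, so d₀ solves a trigamma
  equation (Newton inverse) and s₀² follows from the mean. Posterior
  variance s̃² = (d₀s₀² + df·s²)/(d₀ + df); t = lfc/√(s̃²·v_c) on df + d₀
  degrees of freedom (normal when d₀ = ∞, which is the correct limit when
  the observed variances are exchangeable). s² is floored at 1e−12 before
  taking logs. FDR is Benjamini–Hochberg step-up.
* **Concordance.** Two genome-wide LFC vectors — signature low-vs-high and
  SKP2-CN (level ≥ 1) vs (level ≤ 0) — are compared by Spearman ρ over all
  genes, no significance filtering. Both are oriented along increasing
  SKP2 activity (the signature's low-ubiquitination group is its SKP2-high
  state), so a signature that tracks SKP2 yields ρ > 0. The "CN high"
  threshold at level ≥ 1 treats any gain as high and diploid-or-loss as
  normal/low.
* **Survival.** Product-limit estimator with censored ties processed after
  deaths; k-group log-rank with hypergeometric expectations and the
  covariance form d(n−d)/(n−1)·(δ·n_g/n − n_g n_h/n²), quadratic form via
  a generalized inverse on k−1 components. The default two-group analysis
  compares high vs low with intermediate excluded (a three-group flag keeps
  it as its own stratum); the excluded-intermediate default keeps the
  contrast between the two biologically opposite states.
* **NB2 GLM.** Log link. β given θ by Fisher-scoring IRLS (weights
  μ/(1 + μ/θ)); θ given β by Newton in log θ with backtracking so the
  likelihood never decreases; outer alternation until |Δloglik| < 1e−8
  (≤ 100 iterations). θ initialized by method of moments from the Pearson
  residuals of a Poisson fit; equi-/under-dispersed data cap θ at 1e6 (the
  Poisson limit) with a warning rather than an error. Standard errors from
  (XᵀWX)⁻¹ at convergence, Wald z with the normal reference — matching the
  conventional glm.nb-style summary, not a t reference. Note that the
  intercept's Wald test (β₀ = 0, i.e. mean count 1 in the high group) is
  reported for completeness but is not a scientifically meaningful null.
* **Connectivity.** Per-set signed sup-norm KS statistic over list
  positions (d⁺ if it dominates, −d⁻ otherwise, 0 on an exact tie, with
  the tie comparison done in integer arithmetic). The bidirectional raw
  score is ks_up − ks_down when the two disagree in sign and 0 otherwise;
  normalization by the attainable extreme 2 − (t_up + t_down)/n maps it to
  [−1, 1]. This symmetric form is exactly antisymmetric under reversal of
  the reference ranking and under swapping the up/down sets — properties
  the classical one-sided max formulation only satisfies approximately.
  Permutation p-values draw random position sets of the observed sizes
  (two-sided on |score|, +1 pseudo-count); since all profiles rank the same
  universe, one shared null sample serves every profile. "Recommended"
  requires score < 0 and BH FDR < 0.05. IC50 comparisons run on the
  natural-log scale, ANOVA across drugs plus Welch t per drug against the
  reference, with the star convention *** p < 0.001, ** p < 0.01,
  * p < 0.05.

## Problem sizes used in tests and the acceptance script

Parameter recovery refits 1000 simulated cohorts of n = 1500 per stratum;
log-rank calibration uses 2000 null cohorts of n = 200 with ~30% censoring
and 300 powered cohorts of 400 per arm; the expression suites use 1500–5000
genes; the connectivity screen uses a 600-gene universe, 50 profiles and
1000 permutations. These sizes put Monte-Carlo error comfortably inside
each check's tolerance while keeping the full suite around a minute.

## Known limitations

* The signature compares only two genes; no multivariable or Cox
  adjustment is provided (none is part of the analysis design).
* DrInsight-style connectivity internals are not reproduced; the screen
  uses the classical bidirectional KS statistic, and the validated claim is
  planted-reverser recovery, not equality with any external tool.
* The generator's independence assumptions (CN across genes, censoring
  mechanism) are simplifications; see above.
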