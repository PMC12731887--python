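# Methods

## The model

`clpn` estimates a **cross-lagged panel network (CLPN)** over 11
psychological subscales measured at two waves: four death-anxiety (DA)
dimensions (D1 Cognition, D2 Emotion, D3 Time awareness, D4 Stress and
pain) and seven fear-of-cancer-recurrence (FCR) dimensions (F1 Triggers …
F7 Coping strategies).  The directed edge *i → j* is the coefficient of
variable *i* at baseline (T1) predicting variable *j* at follow-up (T2),
controlling for **all** other T1 variables and for demographic covariates.
Formally, one penalized regression per outcome node *j*:

    z(Y_j^{T2}) ~ Σ_i β_{ij} z(Y_i^{T1}) + γ_j' C + ε_j,

with an L1 (LASSO) penalty on the 11 lagged coefficients β_{·j} only.
The 11 fitted coefficient vectors are assembled into an 11×11 adjacency
matrix (rows = predictors, columns = outcomes); the diagonal carries the
autoregressive paths, which are stripped for display and excluded from all
centrality sums.  Edge weights are also reported as "odds ratios"
OR = exp(β), the reporting transform used in this literature; OR = 1 is an
absent edge.

### Model family: Gaussian default, logistic option

The subscale scores are continuous sums, so the default model is a
Gaussian linear LASSO on z-scored outcomes; coefficients are then
standardized effects, which makes edge weights comparable across nodes and
makes centrality sums meaningful.  Because parts of this literature phrase
the estimator as logistic regression without stating a dichotomization, a
**logistic mode** is provided as a sensitivity analysis: each T2 outcome is
median-split and an L1 logistic regression is fitted; exponentiated
coefficients are then true odds ratios.  The exponentiation transform is
applied to whichever coefficient the chosen mode produces.

### Covariates

Age, education, marital status, occupation and income are adjustment
terms, not network candidates, so they are left **unpenalized** in
Gaussian mode.  scikit-learn's lasso has no glmnet-style penalty factors,
so this is implemented by exact Frisch–Waugh partialling: the outcome and
all lagged predictors are residualized on the covariate design (intercept,
z-scored age, dummy-coded categoricals with missing values as an explicit
"unknown" level) before the lasso; this yields the identical solution to
the joint problem with unpenalized covariate columns.  Covariate
coefficients are profiled back out and reported.  In logistic mode no
exact partialling exists, so covariates are penalized along with the
predictors (documented limitation of that mode).

### Penalty selection

λ is chosen per node by K-fold cross-validation (default K = 10, folds
seeded and shared across nodes) over a 60-point geometric path from the
null penalty λ_max = max|X'y|/n down to 10⁻³ λ_max, using the
minimum-CV-error rule; the sparser one-standard-error rule is available
(`lambda_rule="1se"`).  CV-min deliberately trades a few spurious small
edges for sensitivity; on structure-free data it still zeroes ≥ 80% of
cross-lagged entries, and the 1-SE rule zeroes essentially all of them.
A forced penalty (`fixed_lambda`) supports the analytic limits (0 = OLS,
∞ = empty network) and the frozen-λ resampling mode below.

### The solver

Because the pipeline solves hundreds of thousands of small lasso problems
(11 predictors × CV path × bootstrap/case-dropping resamples), the
Gaussian solver is a Gram-matrix coordinate-descent path solver
(`clpn._solver`, JIT-compiled with numba): each sweep costs O(p²)
regardless of sample size, with warm starts down the penalty path and a
coefficient-change stopping tolerance of 10⁻⁸.  It is pinned in the test
suite against scikit-learn's independent coordinate-descent implementation
and a proximal-gradient (ISTA) oracle to 10⁻⁶, and against closed-form
least squares at λ = 0.

## Centrality

Expected influence (EI) keeps edge signs.  Out-EI(i) = Σ_{j≠i} w_{ij}
(predictive force), In-EI(j) = Σ_{i≠j} w_{ij} (predictability);
one-step bridge EI restricts the sums to edges crossing the DA/FCR
partition.  Two weight scales are computed and always labeled: `coeff`
(log-OR, natural for freshly estimated networks) and `or_minus_1`
(natural when working from a printed OR table).  Published centrality
magnitudes in this literature are not exactly reproducible from rounded
adjacency tables on either scale, so rank orders — which agree across the
two scales except for near-ties of order ~0.01 — are the meaningful
output; near-ties are genuinely undecidable from 3-decimal tables.
Ties in ranked-edge reports break lexicographically in fixed node order,
for determinism.

## Stability and inference

* **Edge CIs**: nonparametric bootstrap of subjects (default 1000
  resamples), percentile 2.5/97.5 intervals on the coefficient scale.
  Percentile rather than BCa intervals match the convention of the
  stability framework this literature cites and are adequate for edge
  weights.  By default λ is re-selected inside every resample
  (full-pipeline uncertainty); `EstimationSettings.frozen_at` freezes the
  full-sample penalties for large calibration experiments.  Resample
  estimation failures are recorded and skipped; more than 10% aborts.
* **CS coefficient**: case-dropping subset bootstrap over drop proportions
  0.05–0.75 (step 0.05; proportions leaving < 30 subjects are infeasible
  and excluded).  CS is the largest proportion at which ≥ 95% of
  subsamples keep a Pearson correlation ≥ 0.7 with the full-sample
  centrality, required cumulatively from 0.05 upward.  The 0.7/95%
  constants follow the cited stability convention and are configurable.
  CS ≥ 0.25 is conventionally acceptable, ≥ 0.50 strong.
* **Difference tests**: percentile bootstrap of the difference between two
  edge weights or two nodes' centralities; significant iff the 95% CI
  excludes 0.  Because lasso point masses at zero make these intervals
  conservative, realized false-positive rates sit at or below the nominal
  5%.
* Every resampling routine maps resample index → seed substream
  explicitly (`SeedSequence.spawn`), so results are reproducible and
  independent of execution order.

## Subgroup comparison

Early stage (I/II) vs advanced stage (III/IV).  Each subgroup network is
estimated with the same settings; the λ *selection procedure*, not the
selected value, is shared, so sparsity adapts to each group's n.  Primary
outputs are descriptive: per-group networks, centralities, block extrema
and the elementwise coefficient difference.  An optional permutation test
(max |edge difference| and global-strength difference; p = fraction of
permuted statistics ≥ observed) is provided as an explicitly labeled
inferential extension beyond the descriptive comparison.

## Missing data

The targeted study design loses subjects only by wave-2 dropout, handled
by listwise deletion with the retention fraction reported.  Little's MCAR
test is implemented in full generality: EM (multivariate normal,
pattern-grouped) pooled mean/covariance estimates, then the pattern-wise
chi-square statistic with df = Σ_p k_p − k.  With whole-wave dropout this
reduces to a two-pattern test with df = 11.  Monte-Carlo calibration in
the test suite shows type-I error within [0.02, 0.09] at nominal 0.05
(n = 400, 300 replicates) and essentially full power against dropout
triggered by a high baseline score.

## The synthetic cohort generator

The questionnaire data behind the published analysis are not publicly
available, so the generator emulates the study conditions and provides
known ground truth:

* **T1**: multivariate normal with block-exchangeable correlation
  (within-construct 0.4, between-construct 0.2), rescaled to the published
  T1 means/SDs and truncated at 0.
* **T2**: standardized structural model `auto + cross + covariate effects
  + noise`; residual SDs default to completing each outcome to unit
  variance, so the stored truth is **exactly** the estimand of the
  node-wise standardized regressions.  T2 is rescaled to the published
  follow-up means/SDs and truncated at 0.
* **Defaults** (chosen once as the package's reference conditions):
  autoregression 0.45 everywhere; sparse cross structure with strong
  positive paths D2→D1 0.30, D3→F3 0.30, D1→F2 0.25, D3→D4 0.25, D1→F4
  0.20, D1→F7 0.20, F2→F1 0.20, F1→F6 0.18 and weak negatives out of the
  coping node (F7→F1/F3/F4 −0.08, F6→D1 −0.05, F2→F7 −0.06) — the
  qualitative pattern of the published network, with the smallest
  "meaningful" effect placed at 0.18 because effects below ~0.15 are
  treated as negligible in this design.  Covariates: age ~ N(47.3,
  11.27²) truncated to [18, 90] with a small planted effect (0.05 on D1
  and D3); categoricals multinomial at the published cohort proportions;
  stage mix 0.103/0.406/0.394/0.096; whole-wave MCAR dropout at 0.0467.
* **Subgroups**: an optional replacement cross-lagged matrix for stages
  III/IV plants stage-specific structure.
* **Truncation at 0** (scores are non-negative sums) mildly distorts the
  linear model; the distortion is closed-form bounded in the tests
  (largest for D3, whose mean sits 1.7 SD above zero) and is well inside
  estimation noise at all sample sizes used.

What the generator does **not** emulate: item-level response processes,
ordinal score granularity, MNAR dropout, or floor effects beyond simple
truncation.  Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the stated generative model, not
robustness to every feature of real questionnaire data.

## Problem sizes used in the shipped experiments

Chosen as the package's reference experiment scales: ground-truth sign
recovery uses 50 replicates at n = 426 (the analysed sample size) with
error decay checked at n ∈ {200, 426, 2000}; stability uses 100
case-dropping subsamples per proportion at n = 2000 (strong signal) and
n = 100 (pure noise); difference-test calibration uses 100-resample
bootstraps with per-replicate frozen penalties over 40 null and 20
power replicates at n = 2000; subgroup recovery uses 20 replicates at
n ≈ 2000 per group.  The acceptance script re-runs the same experiments
at modestly reduced replicate counts and records the sizes alongside each
value.

## Known limitations

* Two waves only; no ≥3-wave dynamics, no cross-sectional (EBICglasso)
  networks, no global fit indices (deliberately out of scope).
* The logistic mode penalizes covariates and discards information through
  the median split; it is a sensitivity check, not the primary analysis.
* CS values depend on the centrality correlation convention; alternative
  correlation measures (e.g. Spearman) are not implemented.
* The permutation comparison assumes exchangeability of subjects across
  stage groups under the null, which ignores possible covariate imbalance
  between stages.
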