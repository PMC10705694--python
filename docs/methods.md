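# Methods

This note documents the models, conventions and numerical choices behind
`paiselect`, in the order the pipeline runs them.

## Synthetic cohort model

The generator emulates a naturalistic two-arm depression cohort (ECT vs
ketamine) at the level of its statistical structure, not its clinical
detail. Per patient it draws:

- **clinical scales**: baseline QIDS (integer, truncated normal, mean 17.5,
  SD 3.4, floored at the inclusion threshold 10), five BASIS-24 subscales
  (normals clipped to [0, 4] with subscale-specific means/SDs), MoCA
  (integer, clipped to [0, 30]), age (integer years, 18–90);
- **binary indicators**: sex, inpatient status, and `p_binary` generic
  history/diagnosis indicators with prevalences drawn uniformly from
  `prevalence_range` (default 1–30%, so many fall under the
  near-zero-variance filter, as in real medication-history data).

Potential outcomes follow a linear model with a treatment interaction:

    y(t | x) = b0 + Σ_j prog_j x_j + 1[t = ECT] · τ(x) + ε
    τ(x)     = c0 + Σ_j presc_j x_j,    ε ~ N(0, noise_sd²)

Both arms share one noise draw; outcomes are rounded half-away-from-zero
and clipped to [0, 27] (QIDS is an integer scale). The ground-truth table
stores the noise-free expectations, both potential outcomes pre- and
post-rounding, the propensity, `true_advantage = |τ(x)|` and the true
optimal arm (`indifferent` on ties). The observed outcome always equals
the assigned arm's potential outcome, row-wise.

**Treatment assignment.** Confounding is a logistic model on covariates
(`confounding_coefs` are log-odds of ECT; defaults put weight on baseline
QIDS, inpatient status, BASIS psychosis and age — the variables a
naturalistic service would select on). Because study conditions fix exact
arm sizes, assignment is drawn by Gumbel top-k (softmax sampling without
replacement) on the centered confounding logit: the `n_ect` highest
perturbed logits receive ECT. This keeps the propensity structure while
making arm counts deterministic. `ect_pool_multiplier` (default 1) scales
the ECT pool relative to the ketamine arm; the naturalistic setting this
emulates had an ECT pool an order of magnitude larger than the ketamine
arm, which is what makes 1:1 matching meaningful (with equal arms and no
caliper, matching is vacuous).

**Named conditions.** `SimConfig.strong_interaction()` plants
τ(x) = 17.22 − 0.8·QIDS − 1.8·self-harm − 0.9·emotional-lability (SD ≈ 3.4
QIDS points, sign flips near the center of the severity distribution, so
severe presentations favor ECT, milder ones ketamine), noise SD 2 and a
4× ECT pool: a condition under which allocation is learnable and over half
the cohort has a true advantage ≥ 2 points. `SimConfig.null()` zeroes the
prescriptive coefficients: nobody has a true advantage, the reference
condition for false-discovery calibration.

**Missingness** is injected MCAR per column: MoCA at per-arm rates
(defaults 3% ECT / 29% ketamine) and each BASIS subscale at ~2.5%. The
generator makes no attempt at MNAR mechanisms, per-visit trajectories,
dropout or dose effects — so passing tests certify the estimation
machinery under the stated assumptions, not robustness to informative
missingness or model misspecification on real records.

## Matching and preprocessing

- **Propensity** is a maximum-likelihood logistic regression of treatment
  on the matching covariates (constant-value covariates are dropped;
  non-overlapping per-arm ranges raise a separation error naming the
  covariate).
- **Matching** is greedy 1:1 nearest neighbor without replacement on the
  logit of the propensity, the conventional distance scale. The smaller
  arm's patients are processed in seed-randomized order; with no caliper
  (the default) the smaller arm is fully matched. A caliper, when set, is
  expressed in SDs of the logit. Balance is reported as standardized mean
  differences before/after. Presets mirror the sensitivity structure of
  the analysis: `full` (baseline QIDS, age, inpatient, BASIS psychosis),
  `qids_only`, `qids_age`, `qids_age_inpatient`.
- **Order of operations**: rows missing a matching covariate are excluded
  (with a logged count) before matching; imputation runs *after* matching
  so fill values are computed on the analysis sample. Consequently the
  matched size can fall slightly below `n_per_arm` when matching
  covariates are missing.
- **Imputation** is within treatment class: mode (ties → smallest value)
  for skewed scores (MoCA, BASIS psychosis, BASIS substance abuse), mean
  for the roughly normal/uniform ones (BASIS emotional lability,
  relationships, self-harm). Imputation is idempotent.
- **Near-zero-variance filter**: a column is dropped if it has a single
  unique value or if the count ratio of its most to second-most frequent
  value exceeds 19 (the 95:5 rule; exactly 19 is kept — the boundary is
  "strictly greater", chosen because the rule is quoted as a ratio without
  boundary semantics). The treatment column is always exempt.

## The outcome learner

Random-forest regression with the treatment label as an ordinary feature.
`splitrule` "variance" is CART variance reduction
(`RandomForestRegressor`); "extratrees" draws random split thresholds
(`ExtraTreesRegressor`, bootstrap kept on). `min_node_size` is the minimum
node size eligible for further splitting, mapped to sklearn's
`min_samples_split` with a floor of 2. Default ensemble size is 1000
trees; desk-scale grids use 100 (estimates stabilize well below 1000 at
these n, and the acceptance-scale runs fit several hundred forests).

**Nested tuning**, per training partition only: (1) near-zero-variance
filter; (2) a ranking forest (mtry = √p) scores features by permutation
importance (mean MSE increase over repeats); (3) retained-feature count =
min(#positive importances, ⌈0.7·p⌉) — `ceil` because "upper 70%" states no
rounding rule — with a fallback to the top ⌈0.7·p⌉ when no importance is
positive, and explicit `n_filter` candidates tunable in the grid; (4) an
inner 10-fold grid search over mtry / splitrule / min-node-size /
n_filter scored by mean held-fold RMSE (the conventional regression
default; no metric is otherwise implied); (5) refit on the full partition.
A single-point grid skips the inner search. Grid points whose mtry exceeds
the retained feature count are skipped with a log line; all-skipped is an
error.

Two conventions worth stating because they are design choices, not forced:

- the **treatment column always survives** the filter and the selection —
  counterfactual flipping is meaningless if the learner discards it;
- **columns are canonicalized to lexicographic order** before fitting, so
  results are invariant to the caller's column order; selection ties break
  by that canonical order. One global seed expands deterministically into
  per-stage child seeds (simulation, assignment, folds, fits, matching
  order, permutations) via `SeedSequence` on (seed, stage label).

## PAI and the threshold sweep

Predictions for held-out patients are made under the received and flipped
treatment label; the smaller prediction defines the predicted-optimal arm
and the absolute difference is the PAI. **Tie rule** (isolated in
`compute_pai`): equal predictions count the received arm as optimal with
PAI 0 — no disadvantage is predicted either way. The full-scale outer loop
is leave-one-out; k-fold (default 10) is the desk-scale surrogate and the
output metadata records which was used.

The sweep subsets patients with PAI ≥ θ (≥, so θ = 0 reproduces the whole
sample) for θ on the grid {0, 0.1, …, max PAI}, splits each subset by
received-optimal status and applies a one-sided Welch t-test with the
direction fixed a priori: the optimal group is hypothesized to have the
*lower* mean min-QIDS. Welch rather than pooled-variance is the robust
default where the test form is unspecified; Cohen's d keeps the pooled-SD
convention. Rows with fewer than two patients in either group carry
undefined statistics and are excluded from the Benjamini–Hochberg
adjustment, which runs across the remaining sweep rows. Two groups with
zero variance and equal means yield p = 0.5 by convention.

## Evaluation

- **R²** is the sum-of-squares coefficient of determination (can be
  negative). The pipeline reports it on held-out factual predictions.
- **Permutation test**: the outcome column alone is reshuffled and the
  *entire* modeling procedure re-runs per replicate; p = (1 + #{R²_perm ≥
  R²_obs}) / (B + 1) — the add-one convention keeps p > 0 at finite B.
  Failed replicates are logged and redrawn (capped at B).
- **Power**: minimum detectable Cohen's d for a one-sided two-sample
  t-test, solved by bisection (tolerance 1e-6) on the noncentral t
  distribution; cross-checked against the statsmodels power solver and a
  normal approximation in the tests. At 235 per arm: d ≈ 0.230.

## TreeSHAP

Attributions use the **path-dependent** value function (splits on features
in the conditioning set are followed; others cover-average the children),
implemented with the polynomial path-weight bookkeeping that avoids
enumerating feature subsets, in numba-compiled kernels. Interaction values
condition the traversal on each feature j being known vs unknown:
`Φ[i,j] = (φ_i|j known − φ_i|j unknown)/2`, diagonal = residual main
effect; matrices are symmetric and rows sum to the SHAP values. Both
routines are verified against exhaustive Shapley enumeration (tolerance
1e-6; observed agreement is at machine precision) on random small forests.

The **baseline** is the forest's cover-weighted expected prediction —
the quantity that makes local accuracy (baseline + Σφ = prediction) an
exact identity. With bootstrap resampling on the analysis cohort it
estimates the sample-average predicted min-QIDS, which is how waterfall
plots anchor. **Prescriptive profiles** report each patient's doubled
off-diagonal interaction entry between a feature and the treatment label
(positive = the ECT label raises predicted min-QIDS = ketamine favored).
Because a patient's interaction value flips sign with their own arm, the
segment-level direction summary uses the ECT-minus-KET contrast of mean
interaction values below/above the feature median. Plot rendering is out
of scope; the canonical outputs are tables.

## Study conditions and problem sizes

The validation suite runs five named conditions (`paiselect.studies`),
sized for a single CPU:

- *oracle allocation*: strong-interaction cohort, 235 per matched arm,
  true expected outcomes plugged in as the model — allocation agreement
  must be exact and the optimal-vs-non-optimal outcome gap equals the mean
  simulated advantage within Monte-Carlo error;
- *fitted recovery*: same cohorts, 10-fold outer CV, a reduced two-point
  grid (mtry = p/3; min-node-size 5 vs 20; importance-based retention;
  100 trees) — top-PAI-quartile directional agreement and effect-size
  amplification along the sweep;
- *null calibration*: 50 replicates at 100 per arm with a single-point
  grid — the fraction of replicates with any BH q < 0.05 stays within the
  nominal FDR's reach;
- *permutation calibration*: outcome-independent cohorts (30 per arm),
  B = 99, 20 seeds — p approximately uniform, never zero;
- *matching improvement*: confounded cohorts with a 3× ECT pool — mean
  |SMD| strictly decreases, matched arms exactly equal.

## Known limitations

- The simulator's outcome model is linear-with-interaction plus Gaussian
  noise; it does not probe forest behavior under non-additive prognostic
  structure beyond the planted terms, heteroscedasticity, or informative
  missingness.
- Greedy nearest-neighbor matching is order-dependent by construction; the
  seed-randomized order makes this explicit rather than hiding it. Optimal
  matching, matching with replacement and IPW are out of scope.
- Individual PAI scores carry no uncertainty intervals; bootstrap
  stability of the predicted-optimal labels is noted as future work.
- The LOO outer loop is available but the shipped study conditions use
  10-fold outer CV; at these sample sizes the two give closely similar
  PAI distributions while differing hundredfold in cost.
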