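# Methods

`cateselect` studies a model-selection problem: given a family of candidate
outcome models f(x, a) for an observed triplet (covariates X, binary
treatment A, outcome Y), which selection criterion picks the candidate whose
induced treatment-effect estimate is most trustworthy?  This note records
the models, the estimators, the synthetic data-generating process, and the
numerical choices behind the package's defaults.

## Causal framing

Within the potential-outcomes framework with consistency, unconfoundedness
and overlap, the conditional average treatment effect (CATE) is
`tau(x) = mu1(x) - mu0(x)`, with `mu_a(x) = E[Y | X = x, A = a]` the
response surfaces.  Any outcome model f induces a plug-in CATE
`tau_f(x) = f(x, 1) - f(x, 0)` and, averaged, an ATE.  The ideal selection
criterion is the CATE mean squared error (PEHE),
`tau-risk(f) = E[(tau(X) - tau_f(X))^2]`, but it is infeasible on real data
because `tau` is unobserved.  The package therefore implements the feasible
surrogates built from two nuisance functions — the propensity
`e(x) = P(A = 1 | X = x)` and the conditional mean outcome
`m(x) = E[Y | X = x]`:

| risk | per-observation loss |
|---|---|
| `mu_risk` | `(y - f(x; a))^2` |
| `mu_risk_ipw` | `(a/e + (1-a)/(1-e)) (y - f(x; a))^2` |
| `tau_risk_ipw` | `(y (a/e - (1-a)/(1-e)) - tau_f)^2` |
| `u_risk` | `((y - m)/(a - e) - tau_f)^2` |
| `r_risk` | `((y - m) - (a - e) tau_f)^2` |

Each nuisance-dependent risk exists in a *semi-oracle* flavour (true
simulated nuisances) and a *feasible* flavour (estimated nuisances).  All
estimators are plain sample means over the evaluation rows.

The `r_risk` rests on the decomposition
`y = m(x) + (a - e(x)) tau(x) + eps`, `E[eps | X, A] = 0`.  In population it
equals an overlap-weighted CATE error,
`∫ e(1-e) (tau - tau_f)^2 p(x) dx` plus candidate-independent
propensity-weighted Bayes residual terms (`reweighted_tau_risk` implements
the finite-sample right-hand side).  The finite-sample gap between the two
sides is the Bernoulli-assignment Monte-Carlo term
`mean[((a-e)^2 - e(1-e)) (tau - tau_f)^2]`, whose per-candidate standard
deviation scales as `sqrt(E[e(1-e)(1-2e)^2]/n) / E[e(1-e)]` — roughly 1-3%
relative at n = 2000 away from the randomized-trial regime.  Tests of the
identity therefore use the absolute sampling bound
`5/sqrt(n) * mean((tau - tau_f)^2)`; with constant `e = 1/2` the identity is
exact (`(a - e)^2 = 1/4` pointwise) and is asserted exactly.

## Synthetic data generator

Surfaces are random expansions over Gaussian kernels:
`mu0 = Phi w0`, `mu1 = Phi w1`, with `Phi_ij = exp(-||x_i - k_j||^2 / (2 h^2))`.
Defaults, fixed once as the package's study conditions:

- **Covariates**: uniform on `[-2, 2]^d`, `d = 2`.  Bounded support keeps
  every kernel informative; two dimensions keep visual diagnostics and
  runtime manageable while already producing strongly nonlinear surfaces.
- **Knots**: 5 per basis, uniform on the same hypercube; candidate
  featurizations use only 2 knots, so the candidate family is deliberately
  misspecified relative to the truth.
- **Bandwidth** `h = 1.0`: about a quarter of the domain diagonal — smooth
  surfaces with visible local structure.
- **Coefficients**: `w0, w_e ~ N(0, I)`; `w1 = w0 + effect_scale * delta`,
  `delta ~ N(0, I)`.  `effect_scale = 1` makes effect heterogeneity
  comparable to baseline heterogeneity.
- **Propensity**: `e(x) = sigmoid(lambda * z(x))` where `z` is the kernel
  score standardized against a frozen 2048-point reference draw from the
  covariate law (stored in the basis, so `e` stays a deterministic function
  of x).  The overlap knob `lambda` is the logit standard deviation:
  `lambda = 0` is a randomized trial; benchmark runs draw
  `lambda ~ U(0.3, 3)`, spanning realized NTV roughly 0.1-0.75.  The logit
  is clamped at ±8, so `e` is strictly interior (weakest allowed overlap
  ~3.4e-4).
- **Outcome noise**: additive Gaussian, `noise_sd = 0.2` (surface sd is
  ~O(1), i.e. a signal-to-noise ratio a working epidemiologist would call
  comfortable but not clean).
- **Randomness**: one integer seed spawns independent substreams for basis,
  covariates, assignment and noise, so the surfaces are invariant to the
  sample size and the leading rows of a larger sample extend a smaller one.
- By default the propensity basis is sampled independently of the outcome
  basis; `share_propensity_basis=True` routes confounding through the same
  nonlinearities.

What the generator does *not* emulate: discrete/mixed covariates,
heavy-tailed or heteroscedastic noise, high-dimensional confounding, and
treatment effects correlated with measurement artifacts.  Passing benchmarks
here shows the selection machinery behaves as the theory predicts under
smooth low-dimensional confounding; it does not certify performance on,
e.g., registry data with hundreds of covariates.

## Candidate families

- **Ridge on random kernel features** (120 members): 2 knots drawn from the
  training rows per featurization seed, bandwidth from the median pairwise
  distance heuristic on a ≤200-row subsample, features standardized, ridge
  intercept unpenalized; penalties {1e-3 … 1e2} × meta-learners
  {TLearner, SftLearner} × 10 featurization seeds.  The SftLearner shares
  one featurization between arms with separate regressors (the same penalty
  in both arms); the TLearner draws separate featurizations from each arm's
  rows.
- **Gradient boosting SLearner** (18 members): histogram gradient-boosted
  trees on (x, a), learning rate {0.01, 0.1, 1} × max leaf nodes
  {25, 27, 30, 32, 35, 40}, early stopping disabled so the grid is the only
  hyperparameter axis.

## Nuisance estimation

Both nuisances use a two-member stack: a penalized linear model (logistic
for `e`, ridge for `m`) and histogram gradient-boosted trees.  Member
hyperparameters are chosen by a 3-fold grid search on the training set
(Brier score for the propensity — minimized by the true conditional
probability — and MSE for the outcome); the tuned members are cross-fitted
over 5 folds and a linear combiner (logistic, or nonnegative least squares
for the regression) is trained on the out-of-fold predictions, after which
the members are refitted on the full training set.  Grids are deliberately
small ({C: 0.01-10}, {alpha: 0.01-100}, boosting learning rate {0.05, 0.3} ×
leaves {15, 31}): the stack's flexibility comes from combining a linear and
a tree member, not from a wide search.  `m` regresses y on x only (not on
a), matching its definition as the factual conditional mean.

Estimated propensities are kept strictly inside (0, 1).  A flooring helper
(`bound_propensity`, default eta 1e-3) exists for the risks that divide by
`e` or `1-e`, but is **off by default**: the variance inflation of the IPW
and U risks under weak overlap is part of what the benchmark measures, not a
numerical accident to be hidden.  The `r_risk` never needs clipping (no
division).

## Selection procedure and benchmark

One stratified train/test split per dataset (default 90/10); candidates and
nuisances fitted on the training side (optionally on disjoint halves of it
with `nuisance_set="separate"`); every risk computed for every candidate on
the test side; the configured risk's argmin returned, ties broken by
identifier.  Candidates carry their training-row fingerprint and the risk
table refuses evaluation rows they have seen.

The benchmark simulates many datasets, runs the procedure once per dataset,
and scores each risk column against the oracle `tau_risk` column by
tie-adjusted Kendall correlation (tau-b, since degenerate candidates can
produce tied risks), its per-dataset mean-centered version, and the excess
CATE error of the risk's selection (percent above the best candidate).
Overlap is summarized by the normalized total variation
`NTV = mean 0.5 |e/p - (1-e)/(1-p)|` (p = treated prevalence), a plug-in
estimate of the total-variation distance between treated and control
covariate densities, and effect size by the mean absolute ratio of the
effect to the mean-centered baseline (near-zero denominators excluded).
Overlap/effect strata are tertiles of the *realized* distribution of each
run — cut points from any one run do not transfer to another generator
configuration.

## Problem sizes and numerical choices

Default experiment scales, chosen to make each benchmark claim measurable
with bounded Monte-Carlo error on a single CPU: 150 datasets of n = 1000
for the overlap benchmark (50 per tertile), 40 paired datasets per train
fraction for the split sweep, 20 for the shared-versus-separate nuisance
comparison.  The per-dataset excess-risk distributions are heavy-tailed
(many exact zeros next to occasional multi-hundred-percent values), so
tertile medians still carry noticeable seed-to-seed variability; Kendall
means are considerably more stable.

Degenerate inputs: constant-prediction candidates are legal everywhere
(ties broken lexicographically); a `u_risk` denominator below 1e-12 raises
rather than returning an astronomical number; `effect_ratio` with a flat
baseline and a null effect returns 0 by convention; tertile bins are
half-open and lower-inclusive, so a value sitting exactly on a cut point
joins the stratum above it.

## Known limitations

- The feasible-risk findings are demonstrated on the built-in generator
  only; loaders accept external tabular datasets with the same schema, but
  no external benchmark ships with the package.
- The train-fraction trade-off is condition-dependent: with low-dimensional
  covariates the nuisances are easy to estimate, so the dominant error is
  test-set risk noise and smaller training fractions can score slightly
  higher Kendall agreement than 90/10 (see the split-sweep records a
  benchmark run emits).
- Bayes residual terms of the reweighting identity are only available in
  the simulator context (from the configured noise), never estimated from
  data; they are candidate-independent and cancel in comparisons.
- No confidence intervals on risk estimates: selection compares point
  rankings, as the procedure would in practice.
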