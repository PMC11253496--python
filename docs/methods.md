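# Methods

## The problem

One research question — *does intra-operative arterial oxygen pressure
(paO2) affect the risk of a post-operative complication?* — admits many
defensible analysis pipelines. The analyst must decide how to handle
missing proxy readings, which surrogate model fills in the sparsely
measured paO2, whether that model is tuned, how repeated measurements are
aggregated per surgery, and how the aggregated exposure is coded and
tested. Running several of these *specifications* and reporting the
smallest p-value p\_(1) is multiple testing in disguise: even when every
null hypothesis is true, P(p\_(1) ≤ α) can be far above α.

`minpverse` treats the declared specification grid as a test family of
size m and adjusts p\_(1) for the selection. The recommended correction is
the single-step **minP** procedure:

p̃\_i = P( min\_{1≤ℓ≤m} P\_ℓ ≤ p\_i | ∩\_i H\_0^i ),

estimated as the proportion of outcome-permuted datasets whose minimal
p-value is lower than or equal to p\_i (ties count). Because the
permutation distribution of min P\_ℓ inherits the dependence between the
strategies, minP loses far less power than Bonferroni (p̃\_i = min(m p\_i,
1)) when the strategies largely agree, while still controlling the
family-wise error rate in the weak sense — which is the relevant sense
here: all m hypotheses formalize the *same* vague research claim, so the
case to protect against is the one where all of them are true. Holm is
included for completeness but adjusts p\_(1) exactly as Bonferroni does,
so it adds nothing for selective reporting; the report says so.

## The strategy grid

Five axes, crossed into 2·2·2·2·3 = 48 strategies:

| axis | options | default notes |
| --- | --- | --- |
| missing_handling | drop, impute | drop removes measurement rows with any missing proxy; impute = chained-equations regression imputation (scikit-learn `IterativeImputer`, 10 iterations) on the proxy columns only |
| surrogate_model | random_forest, regularized_glm | tree ensemble = LightGBM in random-forest mode (bagging fraction 0.632 without boosting); GLM = elastic net behind a standard scaler |
| tuning | default, random_search | see below |
| aggregation | mean, median | per surgery, over observed + predicted paO2 |
| exposure_coding_and_test | continuous_logistic, binary_200_fisher, ternary_200_250_fisher | Wald z on the logistic slope; Fisher exact at 200 mmHg; Freeman–Halton exact at 200/250 mmHg |

Grid order is fixed (axes nested in the order above, rightmost fastest) so
that column ℓ of every permutation matrix always refers to the same
strategy. Stage seeds derive from the master seed plus the axis values the
stage depends on, so strategies sharing a preprocessing path share its
randomness bitwise — this is what makes cached execution provably
equivalent to strategy-by-strategy execution (asserted in the tests) —
and adding a strategy never perturbs the others.

**Tuning.** `default` uses fixed documented hyperparameters (100 trees,
full feature fraction, min leaf 5 for the forest; α = 1.0, l1_ratio = 0.5
for the elastic net). `random_search` scores 10 candidates — the default
configuration always enters as candidate 0 — by RMSE on a single 25%
holdout and refits the winner on all rows. Search spaces: trees ∈ [50,
200], feature fraction ∈ [0.2, 1.0], min leaf ∈ [1, 20]; penalty strength
log-uniform on [1e-4, 1e2], mixing ∈ [0, 1]. A compact holdout-scored
search was chosen over k-fold cross-validation deliberately: the
simulation studies refit 8 surrogate models per replicate across hundreds
of replicates, and the tuning budget is the dominant cost of the whole
procedure. With the default included among the candidates, the selected
configuration never scores worse than the default on the search's own
criterion (asserted in the tests).

**Failure policy.** A strategy that cannot produce a p-value (constant
coded exposure, constant outcome, logistic separation or non-convergence,
too few training rows) is flagged with a reason, carries NaN, and is
excluded from the family; adjustments use the effective m. An empty
ternary category is *not* a failure: the Freeman–Halton test collapses to
the 2×2 test on the remaining categories, which is the statistically
correct behaviour. Surrogate predictions are clamped to [20, 600] mmHg so
degenerate extrapolations cannot break the codings.

## The permutation null

Permuted datasets mimic the global null by shuffling the **outcome**
across surgeries. Shuffling the outcome rather than the exposure leaves
every exposure-side stage untouched, which preserves the full dependence
structure among the m tests and allows one preprocessing pass (16 exposure
vectors, 8 surrogate fits) to serve all B permutations — only the coding +
test stage reruns. One shared shuffle per permutation is applied jointly
to all strategies; drop-path strategies see the shared permuted outcome
restricted to their own analysis set. No preprocessing stage (including
imputation, which deliberately excludes the outcome from its model) ever
reads the outcome, so this caching is exact, not an approximation; the
test suite asserts bitwise equality against full per-permutation
re-execution. Whether one *should* re-run imputation and surrogate
training per permutation is a modelling choice; here the exposure pipeline
is defined as outcome-blind, which makes the answer "no" by construction.

The per-permutation test stage is vectorized: for a fixed exposure coding,
a permuted outcome only moves the contingency table within fixed category
margins, so exact-test p-values are read from a lookup table built once
per distinct event margin (hypergeometric/multivariate-hypergeometric
enumeration with the "probability ≤ observed, relative tie tolerance
1e-7" criterion); logistic Wald p-values come from a damped Newton solver
batched across permutations, with per-row convergence (gradient norm <
1e-8) and separation detection (|standardized slope| > 15 or singular
information). Row-wise reductions are used instead of BLAS matrix-vector
products so that results are bitwise independent of batch composition.

Adjusted p-values use the plain proportion #/B; the validity-preserving
variant (count+1)/(B+1) is available behind `smoothed=True` (off by
default). Significance decisions follow the adjusted-p-value convention:
reject iff p̃ ≤ α.

## The synthetic generator

The motivating clinical dataset is not publicly available, so the
generator emulates its *structure* with invented, configurable marginals;
every default is overridable.

* **Latent paO2**: per surgery, a stationary Gaussian AR(1) over 10–40
  timepoints, marginal N(200, 40) mmHg clipped to [50, 450],
  autocorrelation 0.8. The autocorrelation makes the within-surgery series
  drift, so mean and median aggregation genuinely differ; the marginal
  places the clinical cut points 200/250 mmHg inside the support so all
  three codings are live.
* **Proxies**: k = 5 linear maps of latent paO2 (coefficients 1.0, 0.8,
  0.6, −0.5, 0.4; one negative, as for inversely related vitals) plus
  independent N(0, 40) noise — individually weak predictors, as routine
  vitals are. 5% of proxy entries are MCAR-missing.
* **Observation**: paO2 is revealed on a random 10% of timepoints
  (surgeries with no revealed value are predicted end to end).
* **Outcome**: Bernoulli with logit β0 + β1 (mean latent paO2 − 200)/50;
  defaults β0 = −1.1 (≈25% complication prevalence), β1 = 0. The part-1
  null study sets β0 = β1 = 0, i.e. an exact fair-coin outcome independent
  of everything; the part-2 study plants β1 = 1, which gives the logistic
  strategy ≈0.8 power at n = 300 (measured in the tests) and an unsaturated
  power curve over n = 50…300.

What the generator does **not** emulate: correlated proxy noise (shared
physiology), non-linear proxy–paO2 relationships (e.g. the sigmoidal
SpO2 curve), informative missingness, case-mix heterogeneity, or the
marginals of the real data. One consequence matters for interpreting the
studies: the 16 preprocessing paths produce exposure vectors that
correlate at 0.9+ here, so the 48 tests are *more* dependent than the
analogous real-data family appears to be. The family-wise error of the
*unadjusted* minimum is therefore substantially lower on synthetic data
(≈15–20% at n = 100) than the ≈70% reported for the real data — the
qualitative inflation is reproduced, the magnitude is not. The minP and
Bonferroni guarantees are dependence-adaptive and dependence-free
respectively, so those conclusions transfer unchanged; passing tests here
demonstrate control and ordering, not the real-data effect sizes.

## Simulation studies

* **Part 1 (FWER)**: for each n, R global-null datasets; per dataset the
  48 raw p-values, the B-permutation minP adjustment and the Bonferroni
  adjustment; a family-wise error is "any (adjusted) p ≤ α". Estimates are
  reported with 95% Wilson score intervals (the single-proportion interval
  underlying Newcombe's recommendations). Reference scale R = B = 1000,
  n ∈ {100, 200, 300, 500, 2000, 3000}; the shipped studies and the
  acceptance script run R = 200, B = 150, n = 100 — chosen as the package's
  desk-scale default so the whole experiment completes in minutes on one
  core while keeping the Wilson interval at ±3 percentage points around
  5%.
* **Part 2 (significant fraction)**: planted effect β1 = 1, fraction of
  the 48 specifications significant at α ∈ {0.01, 0.05, 0.1}, averaged
  over R replicates. Reference sizes n ∈ {50, …, 300}; the shipped reduced
  study uses n ∈ {50, 150, 300}, R = 200, B = 100. The expected ordering
  unadjusted ≥ minP ≥ Bonferroni holds at every (n, α) up to a Monte-Carlo
  tolerance of 0.01 (it is not a pointwise algebraic identity: with finite
  B the empirical minP count can sit a hair above or below its analytic
  counterpart).

## Numerical and design notes

* Exact-test tie handling uses a relative tolerance of 1e-7 when comparing
  table probabilities, and the minP counting uses exact ≤ on the observed
  p-value.
* Exact-test p-values are discrete and conservative, with an atom at
  p = 1; under the null their empirical CDF stays *below* the diagonal.
  Calibration tests therefore check two-sided uniformity (KS) for the
  continuous logistic test but one-sided validity (no anti-conservative
  deviation) for the exact tests.
* The Wilson interval is snapped to exactly 0/1 at the boundary counts.
* Degenerate inputs fail loudly: < 30 surrogate training rows, < 10
  surgeries after dropping, all-constant proxies, empty profiles. A
  strategy failing on more than half of the permutations aborts the null
  construction with a diagnostic.
* Known limitations: single imputation (no pooling across multiple
  imputations); no confounder adjustment, and consequently no claim that
  outcome permutation is the right null in confounded regressions; no
  effect-size or confidence-interval multiplicity adjustment; permutation
  p-values are granular at 1/B, so B must be large for stable decisions
  near α.
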