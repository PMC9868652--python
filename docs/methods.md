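# Methods

## The structured deep embedding model

The model constrains a feed-forward network to a three-level variable
taxonomy. For patient `i`, variable `v` with binned series
`x_{iv} ∈ R^B`:

* **Per-variable embedding.** `e_{iv} = w_v^T tanh(W_v x_{iv} + b_v) +
  c_v`, an independent two-layer perceptron (`B → H → 1`, default
  `H = 8`) per variable. The output is one scalar so every intermediate
  quantity is readable as an index.
* **Grouping layers.** Combo embedding `e_{ic} = tanh(Σ_{v∈c} a_{cv}
  e_{iv} + b_c)`; composite embedding `e_{ik} = tanh(Σ_{c∈k} g_{kc}
  e_{ic} + b_k)`. These are dense layers under a hard 0/1 membership
  mask applied to both weights and gradients, so cross-group weights are
  exactly zero at every step of training — equivalent to independent
  per-group subnetworks but vectorizable in one matrix product. The
  masking contract is tested by finite differences: perturbing a
  variable never moves a non-member combo or composite embedding, not
  even in the last bit.
* **Prediction head.** A single linear map from the final embedding
  vector to two outputs under log-softmax; training minimizes the mean
  negative log-likelihood.

The **base**, **combo** and **composite** variants attach the head after
level 1, 2 or 3 respectively; on the packaged panel their final widths
are 206, 32 and 5/3/7 (strategies g1/g2/g3).

### Initialization: a composite-index prior

All weights start at their positive mean-pooling value (1/fan-in)
perturbed by 50% multiplicative Gaussian noise; biases start at zero.
Every embedding therefore begins as approximately the mean of its
standardized children — the hierarchy carries the intended clinical
meaning ("a composite index summarizes its members") from epoch 0.
Zero-mean random initialization was rejected after diagnosis: the
arbitrary signs it assigns to each 1-D bottleneck make the deep masked
stack align slowly, while the (much larger) per-variable subnets
memorize the training set through non-signal composites; best-held-out
checkpoints then systematically under-use the informative composite.
With the mean-path prior and `H = 8`, base/combo/composite reach
statistically indistinguishable discrimination on the synthetic study
conditions, which is the behaviour the repeated protocol is designed to
measure.

### Grouping-layer weight decay

An L2 penalty (`group_decay`, default 0.1) applies to the two grouping
layers only — not the per-variable subnets or the head. Redundant group
members otherwise go "lazy" (one member absorbs all weight while the
rest idle at their initial values), which distorts per-member
attribution; penalizing only the grouping weights spreads credit across
members and suppresses co-adapted noise pathways without limiting what
the per-variable encoders can express. Empirically it also improves
held-out discrimination of the composite model.

### Training protocol

Per repeat (default 10): a fresh stratified 80/20 split, fresh seeded
initialization, Adam (lr 1e-3, batch 32) for up to 50 epochs with early
stopping (patience 5) monitored on the *test* loss, restoring the best
epoch's weights. Monitoring the test set for stopping is statistically
improper but is the stated protocol this package reproduces; a
three-way-split mode (validation carved out of the training fold) is
available and off by default. Metrics are AUROC and AUPRC on the test
fold; summaries are means with normal-theory 95% CIs across repeats.
Splits are pure functions of `(seed, repeat)`.

## Tensorization

Records are averaged into fixed-width bins of months before the index
date (month = 30.4375 days, removing calendar ambiguity); bin `b`
covers months-before-index `[b·w, (b+1)·w)` with the most recent bin
first, matching the convention that a measurement exactly one month
before the index lands in bin 1. Empty bins hold exactly 0, and values
are z-scored per variable before binning (so 0 doubles as "population
mean"); the scaler learned on a training cohort can be applied to
censored evaluation sets. Records at or after the index, or beyond the
last bin, are dropped with a logged count.

## Synthetic cohorts

The generator emulates the structure of a hospital-warehouse lab
extract, not its content:

* visit times: homogeneous Poisson process per patient (default 12
  visits/year over a 60-month lookback; the desk-scale studies in the
  tests and the acceptance script use 24 months as their stated problem
  size);
* missingness: each variable measured per visit with probability
  `1 − missingness` (default 0.6 missing);
* values: variable baseline = midpoint of its normal range, noise sd =
  (high − low)/4; control trajectories stationary;
* signal: case values of variables inside `signal_groups` shift by
  `drift_per_month × sd × (ramp − months-before-index)` over the final
  `ramp_months` (default 18), strongest at the index date — the
  "biomarker rising toward diagnosis" pattern;
* covariates: age and smoking (plus sex, obesity) are shifted for cases
  so that covariates alone separate the classes at ≈70% accuracy — by
  Bayes' rule an equal-variance Gaussian shift is exactly a logistic
  link — giving propensity matching measurable work;
* control index dates: drawn by jittering the span quantile `1 − f` of
  each control's record span, where `f` is the cases' mean per-variable
  fractional measurement loss under truncation; with Poisson-uniform
  visits the expected realized reduction equals `f`. The distributional
  form (uniform jitter) is a choice; only the expectation is pinned
  down by the calibration target.

What the generator does **not** emulate: inter-variable correlation
beyond the injected group drift, demographic realism, calendar-time or
assay drift, informative visit scheduling, and code/diagnosis
sequences. Passing tests therefore demonstrate that the machinery
recovers known structure under controlled conditions, not that it will
perform equivalently on real EHR data.

## Cluster purity

Embeddings are clustered by a Gaussian mixture (full covariance,
`reg_covar = 1e-6`) initialized from seeded K-means centroids, with hard
assignment by maximum responsibility and a re-seeded retry if a
component empties. Purity is the size-weighted total entropy
`Σ_i (n_i/N) Σ_j −(n_ij/n_i) ln(n_ij/n_i)`: 0 iff every cluster is
class-pure, at most `ln`(number of classes). The per-(i,j) weight is
taken as the cluster weight `n_i/N` (the standard convention); an
alternative `n_ij/N` weighting is exposed. The sign is chosen so that
lower = purer on a nonnegative scale, and logs are natural. Two mixture
components (case/control subgrouping) is the default. t-SNE is provided
strictly as a plotting aid and never feeds the score.

## Attribution

Shapley values are computed against the game `v(S) = E_b[f(x_S,
b_{−S})]` with a seeded background sample of patients (≤100). For ≤10
features (the composite layer) the exact subset enumeration is used;
beyond that, antithetic permutation sampling — whose telescoping
marginal contributions make the additivity identity `Σ φ = f(x) −
E_b[f(b)]` hold to float precision at any number of permutations. Each
hierarchy level is explained through the model's *own* downstream
layers (level 2 through composite + head, level 1 through combo +
composite + head), with the explained output being the case-class
log-probability. Reported values are means of |φ| over patients with
SDs, keyed by the unit's parent for the cross-layer linked view.
Because attributions depend on the architecture they flow through, the
roll-up of base-model per-variable values into composites
(`accumulated_shap`, which conserves the grand sum exactly) is provided
for contrast with the composite model's own level-3 report.

Composite importance rankings use four off-the-shelf classifiers on the
level-3 embeddings: logistic regression (absolute standardized
coefficients) and decision tree / random forest / xgboost
(split-criterion impurity reduction), each refit on seeded bootstrap
resamples, scores normalized to sum to 1 per fit.

## Propensity matching

Separability is the mean held-out accuracy of logistic fits on balanced
case/control resamples (70/30 split per fit, up to `n_iterations = 100`
fits, stopping once the running mean settles within tolerance of 0.5 —
the "indistinguishable populations" target). Matching is 1:1 nearest
neighbor without replacement on the logit of the propensity score, no
caliper; non-overlapping supports degrade to a best-effort match with a
warning. Both held-out and in-sample separabilities are reported, as
the two can differ noticeably at small n.

## Temporal trends

At anchors 0/3/6/12 months before the index, a patient's value is the
mean of measurements within ±2 months (inclusive; adjacent windows
overlap by design, and the anchor-0 window is truncated at the index).
The trend is an OLS slope of the per-anchor group means with the time
axis oriented so that values rising toward diagnosis give a positive
coefficient; per-patient regression is available as an option. The
adjusted slope divides by the normal-range diagonal `(high −
low)/anchor span`, so a series climbing exactly from the lower to the
upper normal limit across the span scores 1, and the statistic is
invariant under joint affine rescaling of values and range.

## Numerical conventions and edge cases

* Records exactly at the index date are removed by the pre-diagnosis
  filter ("at or after"); censoring at `k` months keeps strictly more
  than `k` months before the index, so `k = 0` coincides with the
  pre-diagnosis filter and a record at exactly −k months is removed.
* Constant embedding columns: zero importance (with a warning);
  constant combo columns in correlation grouping are treated as
  uncorrelated (undefined correlations replaced by 0, with a warning).
* Correlation grouping uses absolute Pearson correlation and connected
  components (the weakest closure consistent with transitive
  bundling); components of size ≥2 become composites, all isolated
  combos pool into one residual composite. Whether negative
  correlations should bundle is genuinely open; absolute value is the
  default here.
* AUROC with a constant score (e.g. fully censored inputs) is 0.5.
* Checkpoints embed the taxonomy hash and refuse to load against a
  different taxonomy.
* Stage seeds in the pipeline are derived by hashing (global seed,
  stage name), so stages can be re-run independently of order.

## Problem sizes

Desk-scale study conditions used throughout the tests and the
acceptance script: 200 cases + 200 controls, 24-month lookback, monthly
bins, 12 visits/patient-year, 60% missingness, drift 0.15 sd/month over
an 18-month ramp confined to the liver function group (strategy g1);
10-repeat evaluation protocol; Shapley backgrounds of 15–60 patients
with 4–32 permutations. The drift-recovery study uses a 36-variable
panel with 100 cases over 5 seeds; the matching study uses 100 cases
against 300 controls.

## Known limitations

* The per-variable encoder is a small static perceptron on binned
  means; no recurrent or attention-based sequence modelling.
* Zero-filling is the only missing-data strategy (by design, to match
  the reproduced protocol); no multiple imputation.
* Grouping strategies are fixed partitions; no learned or overlapping
  group structure.
* The synthetic generator's simplifications (above) bound what the test
  suite can certify about real clinical data.
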