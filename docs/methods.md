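# Methods

## Model

The regressor is a single-hidden-layer feed-forward network.  Inputs are
coded to [0, 1] by min–max scaling, `μ(x) = (x − x_min)/(x_max − x_min)`,
with `x_min`/`x_max` taken from the observed data range; out-of-range
values at prediction time are clipped after coding.  Decoding is the exact
algebraic inverse `x_min + μ·(x_max − x_min)`, so decode∘encode is the
identity on the in-range domain (to floating-point conditioning: the
round-trip error scales with the interval magnitude, and the inverse
direction with `|x_min|/width`).

Hidden node `j` computes `σ(Σ_i x_i · W_{(i−1)h+j})` — no hidden bias —
and the single output node computes `σ(Σ_j Y_j · W_{mh+j} + W_P)` with a
fixed +1 bias input.  The flat weight layout (input-major across hidden
nodes, then output weights, then bias) is what ties each weight to one
column of the training plan.  The logistic function is evaluated in its
numerically stable two-branch form.

With `h` hidden nodes the network is invariant under permuting hidden
units together with their output weights; "recovering" a generating
network therefore means recovering its *function*, and the fitted weight
vector may be a hidden-unit permutation of the generating one.

## Experiment plans

Three plans are shipped in two forms.  The `printed` plans are verbatim
transcriptions of the published run tables.  Balance checking
(`balance_report`) shows that the printed 27-run, 13-factor, 3-level plan
is not a strength-2 orthogonal array (57 column pairs have unequal joint
level counts), and the printed 16-run plan has 14 unbalanced pairs; the
printed 12-run plan is a valid Plackett–Burman array.  The `canonical`
plans are algebraic constructions that always pass strength-2 balance —
Plackett–Burman for 12 runs, a regular 2^(15−11) fraction for 16 runs, and
a regular 3^(13−10) fraction over GF(3) for 27 runs — and are the training
default.  Both forms are first-class: the printed plans preserve fidelity
to the source tables, and the balance report surfaces their imbalance
rather than silently repairing it.

## Training loop

* **Run cost**: `Σ_subjects |a − e| / max(|a|, ε)` with `ε = 1e−8`
  guarding zero targets.  MRE is the cohort mean of per-subject errors;
  MMRE the mean of MREs (for a single cohort the two coincide).
* **Cost–effect table**: per (weight, level), the sum of run costs over
  the runs holding that weight at that level; memberships are derived
  from the plan matrix, never from a hard-coded index list.
* **Level selection**: per-weight argmin of the accumulated cost (worst =
  argmax); ties break toward the lowest level index for determinism.
* **Incumbent retention**: the returned model is the best candidate
  evaluated *anywhere* so far — each plan run is itself a complete weight
  vector, and the marginal best-levels network is evaluated as one more
  candidate.  This makes the MMRE history non-increasing by construction
  and makes the search exact whenever the generating point is itself a
  plan run.
* **Interval halving**: each weight's new interval is centered on its
  best level's value with half the old width, translated (not clipped)
  back inside the old interval when it overhangs an endpoint — so widths
  halve exactly each iteration.  The worst level's value is excluded from
  the new interval; in the one corner where it would survive as an
  endpoint (3-level grid, best at an endpoint, worst at mid) the
  offending endpoint is pulled to the best/worst midpoint, relaxing exact
  halving for that weight in that iteration only.
* **Stopping**: `MMRE_{k−1} − MMRE_k < tol` with `tol = 0.01` on the
  fraction scale (an absolute difference, the plain reading of the
  stopping rule), or `max_iter = 10`.  Because of incumbent retention the
  difference is never negative, so the first non-improving iteration
  stops training.
* **Convergence support**: the per-iteration risk step
  `δ_k = (risk_k − risk_{k−1})/m` is recorded; a shrinking |δ| sequence
  corroborates convergence but does not gate it.

Training is fully deterministic given (cohort, config); no randomness
enters the loop.

## Factor effects and risk shares

`δ_j` is the raw ablation difference in mean output when coded factor `j`
is forced to 0 (ablation on the coded scale, matching the coded pipeline).
No per-factor divisor is applied; normalization happens in `risk_shares`,
which scales `|δ_j|/Σ|δ|` to `100 − other_share` percentage points.  The
"other factors" residual (default 6.7 %) is an input mirroring the
published report layout, not an estimate.  Report percentages are rounded
to one decimal for presentation only; invariants are checked on the
unrounded values (shares + residual sum to 100 within 1e−9).

Baseline shares use scikit-learn learners fitted to (coded factors →
target) and seeded permutation importance (20 shuffles), normalized the
same way.  Gaussian naive Bayes is a classifier, so the continuous target
is binarized at its median for that fit and scored through the class-1
probability.  Shares are flagged unstable when no factor's mean importance
clears twice its across-shuffle spread.  Hyperparameters are the
scikit-learn defaults (echoed into the run log by the pipeline).

## Synthetic cohorts

The generator emulates the *structure* of the study data, not its joint
distribution: two groups (default 224 experimental / 448 control, the
totals used throughout the published results), truncated-normal continuous
variables at the published group means ± SD (BMI 27.1 ± 4.3 vs 22.7 ± 1.2
kg/m², cholesterol pooled over gender strata to 7.7 ± 4.8 vs 6.0 ± 4.0
mmol/L, OGTT glucose/insulin at five timepoints), Bernoulli binary factors
at the published prevalences (family history 49.1 %/41.5 %, psychoactive
substances 38.4 %/34.8 %), and continuous 0–1 "poor-behaviour" scores for
physical activity and nutrition whose group means equal the published
prevalences of the binarized variables (0.696/0.607 and 0.580/0.456, SD
0.15) — the published tables print only the binarized prevalences, and a
continuous score is what the coded pipeline expects.  Factors are drawn
independently; real risk factors are correlated, so passing recovery tests
demonstrates correctness of the estimation machinery, not robustness to
confounding.  HOMA-IR is computed, not drawn.

The default risk target is generated by a known 6-input network whose
weights lie on the initial search grid and coincide with one row of the
canonical 16-run plan, so a noise-free target is exactly recoverable in
one iteration — the plan evaluates the generating point directly.  This
makes parameter recovery a sharp test rather than an approximate one.
Gaussian noise (default SD 0.01 on the [0, 1] output scale) is added and
the target clipped to [0, 1].  All randomness flows from a single seeded
generator, so identical seeds give bitwise-identical cohorts.

## Problem sizes

The test suite trains on down-scaled cohorts (40/80 to 56/112 subjects)
for the multi-seed sweeps and on the full default 224/448 cohort for the
single convergence check; the acceptance script uses 224/448 for the
training run and 20 replicates of 56/112 for recovery.  These sizes give
standard errors small enough for the 3-standard-error sampling checks
while keeping the whole suite in the tens of seconds.

## Limitations

* The published per-factor share percentages and the 0.5 % MMRE headline
  were computed on the restricted clinical cohort and are not reproducible
  here; synthetic-cohort shares reflect the generating network, not
  clinical reality.
* Marginal (per-level) selection on a 12–27-run plan estimates main
  effects confounded with interactions; for targets not generated on the
  search grid the first iteration is a coarse screen and the final model
  a local refinement, with no global-optimality guarantee.
* One hidden layer, logistic activations, continuous targets only; no
  cross-validation or held-out evaluation (matching the method's design),
  and no mixed-level or D-optimal designs.
* The optional factor-correlation (copula) structure is not implemented;
  factors are independent by construction.
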