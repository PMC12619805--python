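# Methods

`biochemom` implements a fractionation-free biochemometric workflow: given
aligned untargeted LC-MS peak areas for a panel of botanical extracts and a
cell-viability readout per extract, it ranks the metabolite features most
associated with shifts in bioactivity. The chain is

```
viability plates ──4PL──► IC50 ──ln──► y
feature table ──zero handling──► blank filter ──► source-presence filter
             ──Hellinger──► balanced 80:20 split ──► auto-scale (train-fit)
             ──LASSO (LOO-CV λ)──► PLS1 (LOO-CV components)
             ──VIP ∪ Selectivity Ratio──► candidates + direction of effect
             ──cosine library match──► annotations
```

## Dose-response model and IC50

Viability is modeled with the four-parameter logistic

y(x) = lower + (upper − lower) / (1 + (x / c)^b),

with `b` the Hill slope and `c` the inflection (µg/ml). Zero-dose wells
anchor the upper asymptote: the power term is evaluated only for x > 0 and
y(0) := upper, the b > 0 limit. Fitting is multi-start nonlinear least
squares (`scipy.optimize.least_squares`), slopes starting at
{0.5, 1, 2, 4}, inflection at the geometric mean of the positive doses,
asymptotes at the observed viability extremes; the best-SSE converged start
wins. IC50 is defined as the *absolute* 50%-viability crossing, solved from
the fitted parameters, and reported only when 50% lies strictly between
the asymptotes — a flat or non-crossing curve yields a flagged, undefined
IC50 rather than an extrapolation. Replicate IC50s (one per plating
replicate by default; a pooled-well fit is available) are summarized as
mean ± sd (n−1), and the natural log of the mean is the modeling target.
Natural log is used because the downstream validation metrics are quoted
on that scale (ln 57.21 = 4.05, ln 116.16 = 4.75, range ≈ 0.71 for the
motivating cohort).

## Preprocessing

Missing measurements are encoded as zero peak area. Zeros are replaced by
ε = 0.001 (raw-area units) before any transform; zero-variance features are
then removed. The working transform is **Hellinger** — the square root of
the within-sample relative abundance, h_ij = √(a_ij / Σ_j a_ij) — which
places each sample on the unit sphere and damps the dominance of large
peaks, followed by **auto-scaling** (per-feature centering and unit
variance, n−1 denominator) fitted on the training samples only and applied
frozen to test data. A normality screen ranks transform/scaling candidates
(Hellinger or ln(x+ε); auto or Pareto) by the median per-feature
Shapiro-Wilk W; per-feature testing with a median summary is one of several
defensible readings and is the implemented one. Note that W is invariant to
affine transformations, so the screen genuinely discriminates the
*transform* (Hellinger vs log) only — auto and Pareto scaling of the same
transform share identical W by construction, and the scaling choice must
rest on modeling grounds instead. PCA (SVD on the centered
matrix) runs on the full transformed dataset before any filtration, as an
unsupervised look at cohort structure.

## Feature filters

Both filters act on **raw** areas — fold-change and presence thresholds are
meaningless after row normalization.

* **Blank filter**: keep a feature only if its area exceeds `fold` (default
  5) times the per-feature mean over all blank injections in at least
  `min_samples` non-blank samples; `min_samples` defaults to half
  (ceiling) of the smaller source group. A feature absent from the blanks
  has blank mean 0, so any positive area counts.
* **Source-presence filter**: keep a feature present (area strictly above
  ε) in every sample, or present in at least ⌈half⌉ of *each* source group.
  The "each group" conjunction is the default because the alternative
  "at least one group" reading defeats the filter's purpose of focusing on
  features shared across material sources; both modes are exposed
  (`each-group` / `any-group`).
* **Audit**: every removed feature's raw areas are correlated (Pearson)
  with ln IC50; |r| ≥ 0.5 triggers a "possibly discarded active" warning.
  Constant vectors have undefined r and are reported as such.

The filters are order-dependent by design; the pipeline fixes
blank → source and records a stepwise `FilterTrace` ledger (counts,
per-feature reasons, parameters).

## Balanced splitting

Samples are stratified above/below the mean ln IC50 and test members drawn
uniformly at random (seeded) within each stratum. Per-stratum test counts
start at ⌊fraction × stratum size⌋ and the remainder needed to reach
round(fraction × n) goes to the stratum with the largest fractional part
(ties: larger stratum, then label order). A stratum smaller than 2 is an
error.

## LASSO preselection

The LASSO objective (1/2n)‖y − Xβ‖² + λ‖β‖₁ is minimized by cyclic
coordinate descent with soft-thresholding, warm-started along a descending
λ path (100 log-spaced values from λ_max = max_j |x_j'y|/n down to
10⁻⁴ λ_max), converged when no coefficient moves more than 10⁻⁷ in a full
sweep. The solver works on the Gram form with an active-set strategy
(converge on the active set, then a full KKT sweep admits violators); the
kernel is numba-compiled with a pure-Python fallback.

λ is chosen by leave-one-out CV over the shared grid (argmin MSE; ties go
to the larger λ, the sparser model), then the model is refit on the full
training set at λ* and its nonzero features proceed to PLS. **The scaler
and response centering are refit inside every CV fold.** This is essential,
not stylistic: when p ≥ n, columns standardized on the full training set
satisfy sum-to-zero constraints that make each held-out sample an exact
linear combination of its fold, so an interpolating small-λ fit "predicts"
even pure noise perfectly and CV then favors dense models. With per-fold
standardization the null behavior is correct (pure-noise targets select
near-empty models). If the refit at λ* is empty, the nearest λ with a
nonzero coefficient is used, with a warning.

## PLS regression

PLS1 via NIPALS with deflation: per component, w = X'y/‖X'y‖, t = Xw,
p = X't/(t't), q = y't/(t't), then X ← X − tp', y ← y − qt. The regression
vector is b = W(P'W)⁻¹q, so predictions from b match the deflation-based
predictions identically. Extraction stops early (with a warning) if y
becomes numerically orthogonal to X. The component count is chosen by
leave-one-out CV with a full per-fold refit of both the scaler and the
decomposition (no leakage); the LOO RMSE curve's argmin wins, ties to the
smaller count. Test-set RMSE is also expressed as CV% = 100 × RMSE /
(max − min of observed ln IC50 over the modeled cohort). An optional stage
ledger refits and validates the PLS model after each filtration stage
(unfiltered, post-blank, post-source, LASSO-direct, sparse PLS) so the
incremental value of each step is visible as a train-CV/test RMSE pair.
Stage models exclude features observed in fewer than two training samples:
such features cannot be cross-validated (some LOO folds see only replaced
zeros, whose near-zero variance explodes auto-scaled held-out values).

## Feature importance and direction

* **VIP**: VIP_j = √( p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ) with
  SSY_a = q_a²(t_a't_a); mean squared VIP is 1 and the conventional
  influence cut is VIP > 1.
* **Selectivity Ratio**: the scaled training matrix is projected on the
  normalized regression vector (target projection, t_TP = Xb/‖b‖,
  p_TP = X't_TP/(t_TP't_TP)); SR_j is explained over residual variance of
  column j under the rank-one reconstruction. Columns proportional to the
  target-projection score have zero residual; their SR is capped at 10⁶
  and flagged. The default SR cut of 0.5 is descriptive, not canonical,
  and exposed as configuration.
* **Candidates**: default selection is the union of {SR > 0.5} and
  {VIP > 1}; intersection and single-score modes are available.
* **Direction**: each candidate's *raw* mean peak area is compared between
  the k = 5 most-active (lowest IC50) and k least-active samples;
  higher area among the most active ⇒ `positive_activity`. Ties go to
  `negative_activity` with a warning.

## Annotation

Library candidates within a precursor-m/z tolerance are scored by cosine
similarity of square-root-scaled intensities under greedy one-to-one peak
matching within a fragment tolerance (best pair first). Square-root
weighting de-emphasizes base peaks, a common spectral-matching choice.
A mirror-plot export (query up, library negated, base peak normalized to
100) supports the manual comparison that any putative identification
requires. No modified/neutral-loss cosine is attempted, and the package
never asserts compound identity — only similarity.

## Synthetic data generator

The generator emulates a two-source extract panel with the structure the
workflow assumes; its defaults are the study conditions the package
targets: 24 + 16 samples in two source groups, 3 blank injections, 1600
features, IC50 uniform on ln scale over 57–117 µg/ml, 5-dose viability
plates (0/25/50/100/200 µg/ml, 3 plate replicates, 2% viability noise,
true 4PL lower 0 / upper 100 / slope 2 with inflection = IC50).

* **Background** features are log-normal (baseline ln-mean 13, ln-sd 1.2;
  within-feature ln-sd 0.8) with a per-feature multiplicative group offset
  (ln-sd 0.7) that makes the two sources separate in PCA. 80% of
  background features are "rare" with per-feature, per-group missingness
  uniform on (0.65, 0.95) — exercising the each-group presence logic —
  and 20% are "common" (5% missingness), which leaves roughly 300 features
  after the two filters. Background features are absent from blanks.
* **Active spikes** (4) are built with *exactly* the target Pearson
  correlation (|r| = 0.8, negative against ln IC50 by default, i.e.
  associated with increased activity) by combining the standardized
  ln-IC50 vector with an orthogonalized noise vector; amplitude is ±20%
  around a log-normal baseline.
* **Contaminants** (30) have comparable abundance in blanks and samples,
  so they fail the 5-fold blank rule essentially always.

What the generator does *not* emulate: correlated metabolite modules,
retention-time or batch drift, censored (non-crossing) dose-response
curves, heteroscedastic intensity-dependent noise, isotopes/adducts.
Passing benchmarks therefore demonstrate that the chain recovers planted
univariate associations under realistic compositional noise and
missingness — not performance on any real cohort.

A consequence worth stating: because all four spikes are correlated with
the same response at |r| = 0.8, they are mutually correlated (~0.64), and
after the Hellinger transform the observable correlation attenuates to
~0.6–0.7 through row-sum variability. An L1 selector given a correlated
block keeps a subset of representatives — so end-to-end spike recovery of
≥ 3 of 4 spikes succeeds in roughly 60–70% of seeds rather than always,
with a median candidate set around 7–11 features. This is a property of
LASSO under exchangeable predictors, not an implementation artifact, and
is measured (never asserted away) by the benchmark.

## Numerical choices and degenerate inputs

* Standard deviations use the n−1 denominator throughout.
* ε-replacement happens on the raw-area scale before any transform;
  "present" always means strictly above ε.
* 4PL slope is bounded to (10⁻⁶, 50); non-convergence of every start
  returns a flagged unconverged fit, never an exception.
* LASSO convergence tolerance 10⁻⁷ (max coefficient change); PLS deflation
  stops at weight norms ≤ 10⁻¹²; SR residuals ≤ 10⁻¹² × the largest
  explained variance count as zero.
* Ties: λ → larger (sparser); components → fewer; direction → negative;
  report ordering → SR desc, VIP desc, feature id.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical seeds give bit-identical splits, paths, candidate
  sets and reports.

## Problem sizes used in the shipped benchmarks

The test suite and the acceptance script run the full chain on the default
scenario (40 samples × 1600 features) across 20 generator seeds, the
dose-response recovery simulations at the assay's 18-well replication, and
the algebraic oracles on small instances (6×3 to 40×53) where closed forms
or naive refit loops are exact. One full pipeline run takes a few seconds
on a single CPU.
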