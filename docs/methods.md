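# Methods

This note documents the models, estimation procedures, defaults, and design
choices behind `cdmcompare`, and what the simulation-based tests do and do
not establish.

## Models

**Rasch / CML.**  The Rasch model gives
`P(X_ij = 1) = logistic(θ_i − σ_j)`.  Item difficulties are estimated by
conditional maximum likelihood: conditioning on each person's raw score `r`
removes `θ_i`, leaving a likelihood that depends on the elementary symmetric
functions `γ_r` of the item easiness values `ε_j = exp(−σ_j)`.  We evaluate
`γ_r` with the standard summation algorithm and its single-item deletions by
recomputation (O(J³), numerically robust; J ≤ ~30 in all intended uses).
The likelihood is invariant to a common shift of all difficulties, so the
sum-zero normalization is imposed after optimization (L-BFGS with analytic
gradient).  Persons with all-0 or all-1 scores carry no conditional
information; they are excluded from estimation and counted.  CML makes the
difficulty estimates independent of the ability distribution, which the test
suite checks directly by duplicating high scorers.

**2PL / MML.**  `P(X_ij = 1) = logistic(a_j (θ_i − b_j))` with ability fixed
at N(0, 1) (the usual identification constraint).  Estimation is EM over a
Gauss–Hermite quadrature rescaled to the standard normal (21 nodes by
default); the M-step is a per-item weighted logistic Newton iteration.
Slopes are kept in [0.05, 6]; an estimate hitting the bound (a Guttman-like
item) produces a warning and is listed in `bounded_items_`.

**Rasch-vs-2PL comparison.**  The likelihood-ratio test needs both models on
the same likelihood scale, so the Rasch model is re-fitted *marginally* with
the same quadrature.  Free parameters: J (marginal Rasch) vs 2J (2PL), hence
df = J.  ΔAIC/ΔBIC/ΔCAIC (2PL minus Rasch) use the person count as sample
size; CAIC penalizes `k (ln N + 1)`.

**Item-fit screen.**  The conventional "Q-item" style screen is not uniquely
defined; we use a score-group Pearson chi-square.  Persons are grouped by
raw score (adjacent scores merged until ≥ 30 persons per group; at least 3
groups required).  The expected proportion correct per group uses the
*exact* conditional probability `P(X_j = 1 | r) = ε_j γ_{r−1}^{(j)} / γ_r`,
so no ability point estimates enter.  The statistic sums squared
standardized group residuals with df = G − 1; items with p < α (default .05)
are flagged.  Simulation under Rasch-true data shows a type-I flag rate of
about 0.05 with this df, and near-certain detection of a slope-3 item at
n = 1000.  Infit/outfit mean squares are reported for inspection but do not
drive flags.

**LLTM.**  Difficulties are constrained to `σ = Q η + c`.  Estimation is the
same conditional likelihood, optimized over `η` (chain rule through `Q`).
`c` is not separately identified under CML and is computed analytically from
the sum-zero constraint (`c = −mean(Q η)`).  Standard errors come from the
observed information (finite differences of the analytic gradient; a
pseudo-inverse handles the one flat direction that appears in saturated
designs, where `η` is identified only up to a constant).  On an identity
Q-matrix the LLTM reproduces the Rasch fit to optimizer precision, and its
conditional likelihood can never exceed the unconstrained Rasch likelihood —
both are regression tests.

**LSDM.**  Given source ICCs `P_j(θ)` (Rasch or 2PL) on an ability grid, the
conjunctive model `P_j(θ) = Π_k P(A_k|θ)^{q_jk}` becomes, after taking logs,
an independent linear system `ln P(θ) = Q x(θ)` per grid point.  The default
solver enforces `x ≤ 0` (attribute probabilities ≤ 1) via non-negative least
squares on the negated system; plain least squares is available by flag, in
which case implied probabilities above 1 are clipped and counted.  Source
probabilities are *not* ε-clipped inside the solver — `ICCTable` already
guarantees values strictly inside (0, 1), and any clipping belongs to the
upstream ICC evaluation (`evaluate_iccs`, ε = 1e−6 by default).  This
preserves the defining property of the method: ICCs constructed as exact
conjunctive products of attribute curves on a full-column-rank Q-matrix are
recovered with zero residual, zero MAD, and exact attribute probabilities
(to ~1e−14 in practice).

LSDM-implied item difficulties are the grid locations where the
reconstructed curve first crosses probability 0.5 (linear interpolation
between bracketing grid points; rows never reaching 0.5 are flagged
`extrapolated` and reported at the grid boundary).  Attribute summaries
regress `logit P(A_k|θ)` on θ over grid points with the probability inside
(ε, 1−ε): the slope is the component discrimination, `−intercept/slope` its
difficulty; components with fewer than 3 usable points are flagged unfit.
Mean-centered difficulties are reported for cross-model comparison.

**MAD.**  Reconstruction quality is the mean absolute distance between
source and reconstructed ICC rows over the grid; < 0.05 is labeled good,
< 0.10 satisfactory, otherwise poor.  MAD values are grid-dependent; the
default grid is 61 equally spaced points on [−4, 4].

## Comparison harness

`run_full_comparison` executes calibration (with optional item screening on
the fit sample; if the retained subset would lose Q-matrix column rank, the
full set is kept with a warning), the three reconstructions (LLTM,
LSDM-on-Rasch, LSDM-on-2PL), and the evaluation battery.  Conventions:

* Predictive and cross-validation correlations for **all three** model rows
  are computed against the *Rasch* empirical difficulties of the respective
  sample, so that Steiger's Z — which requires the two compared correlations
  to share one variable — is well-defined for every pairing.  (Empirical
  Rasch and 2PL difficulties are nearly collinear in practice.)
* Cross-validation direction: parameters fitted on sample A predict
  difficulties *independently estimated* on sample B; no pooling.
* Steiger's Z uses the overlapping dependent-correlations form with the
  mean-correlation substitution in the covariance term.  Null simulations
  (trivariate normal, equal dependent correlations, n = 100) give a
  rejection rate of ~0.05 at α = .05.
* Cohen's d for the paired MAD tests is `mean(diff) / sd(diff)`.
  The rendered comparison table reports, per row, the d of the
  comparison-model-minus-row-model convention (negative = the comparison
  model reconstructs better).
* The regression robustness check selects the two most difficult change
  rules and two most difficult design principles from the LLTM η ranking
  (overridable), regresses empirical difficulties on those main effects,
  then adds all rule × principle products; collinear products are dropped
  with a warning, and the hierarchical F-test on ΔR² is reported.  Tests are
  unadjusted for multiplicity by design.

## Synthetic data generator

The generator emulates the structure of a two-sample validation study of
rule-based figural matrices: ~600 examinees per sample with abilities drawn
N(0, 1), 18–26 binary items built from the nine-component taxonomy, with
integer Q-matrix weights in [0, 2] (one or two change rules plus one or two
design principles per item; full column rank enforced with bounded retries).
Both sample sizes are free parameters.  Each dataset derives independent
ability and response substreams from one seed, so regeneration is exact and
the stored abilities are reusable.

Generating worlds:

* **additive** — `σ = Q η + c`; default `η` is the published set of
  mean-centered component base-parameter estimates for this taxonomy, i.e.
  an empirically realistic additive world.
* **conjunctive** — `P_ij = Π_k P(A_k|θ_i)^{q_jk}` with logistic mastery
  curves.  Defaults: discrimination 3 for every component, difficulties
  spread over [−2.5, 1].  The steep slopes embody the multiplicative
  hypothesis's all-or-nothing reading of components; with shallow curves
  `ln P` is nearly linear in θ and the conjunctive world becomes empirically
  indistinguishable from the additive one, which would defeat the
  generator's purpose of providing a discriminable alternative world.
* **twopl** — unstructured `logistic(a_j (θ − b_j))`, used for slope
  recovery and misfit scenarios.

What the generator does **not** emulate: administration-mode effects between
the two samples (they are parallel by construction), missing responses,
guessing on distractor-based response formats, local item dependence, and
ability distributions other than the standard normal.  Passing tests
therefore show that the estimators and the comparison logic behave correctly
under clean versions of the study's assumptions — not that any substantive
conclusion transfers to a particular empirical dataset.

## Numerical choices and degenerate inputs

* Probability clipping in ICC evaluation: ε = 1e−6; reconstructed LSDM
  probabilities are kept strictly inside (0, 1) at machine-level bounds.
* CML/LLTM optimization: L-BFGS with analytic gradients, ftol 1e−12/1e−10;
  2PL EM stops when the marginal log-likelihood changes by < 1e−7.
* Items with no variance among non-extreme scorers, all-zero Q rows or
  columns, rank-deficient Q-matrices (for the LLTM), constant vectors in
  correlations, and |r| = 1 inputs to Steiger's Z all raise named errors.
* 0.5-crossing interpolation is linear in probability space; on
  non-monotone reconstructed rows the first upward crossing wins.
* No isotonic smoothing is applied to attribute curves.

## Scale of the simulation-based checks

Simulation tests run at deliberately modest sizes chosen to make their
expected behavior unambiguous: 600 persons per sample and 18 items for
model-discrimination replicates (50 per world), 2000–3000 persons for
single-fit parameter recovery, 100 replicates for item-fit type-I rates,
and 2000 replicates for Steiger-Z calibration.  These sizes keep the full
suite fast while leaving wide margins to each test's threshold.

## Known limitations

* The LSDM solves each grid point independently; nothing enforces
  monotone attribute curves, and noisy source ICCs can produce locally
  non-monotone reconstructions (visible in the attribute-summary R²).
* MAD comparisons measure distance to the *fitted* source ICCs, not to the
  unknown true curves; with weakly conjunctive data this metric has little
  power to prefer the LSDM, which is a property of the methodology, not an
  implementation artifact.
* The item-fit screen's df = G − 1 calibration was verified for the default
  grouping (≥ 30 persons per group) at J ≈ 18, n ≈ 600; very different
  designs may need re-checking.
* CAIC and BIC use the person count as N; other conventions exist.
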