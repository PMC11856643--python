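# cdmcompare

Do the components of a rule-based reasoning item combine **additively** or
**multiplicatively**?  When a figural-matrix item requires several change
rules and design principles at once, does each unmastered component subtract
a fixed amount from the log-odds of success (additive hypothesis), or does
failing any single component make the item unsolvable, so that the success
probability is a *product* of component mastery probabilities (multiplicative
hypothesis)?

`cdmcompare` is a Python toolkit for psychometricians who want to put these
two effect assumptions head to head with cognitive diagnostic models (CDMs).
It implements:

* **Rasch calibration by conditional maximum likelihood** (elementary
  symmetric functions) and **2PL calibration by marginal ML** (EM over a
  fixed N(0, 1) quadrature), with a score-group chi-square item-fit screen
  and a Rasch-vs-2PL likelihood-ratio / information-criterion comparison.
* The **linear logistic test model (LLTM)** — the additive CDM.  Item
  difficulty is constrained to `σ_j = Σ_k q_jk η_k + c`, where `q_jk` is the
  items × components Q-matrix weight, `η_k` the base parameter of component
  `k`, and `c` the sum-zero normalization constant, so that
  `P(X_ij = 1) = logistic(θ_i − σ_j)`.
* The **least squares distance method (LSDM)** — the multiplicative CDM.
  Starting from externally calibrated item characteristic curves (ICCs), it
  assumes `P_j(θ) = Π_k P(A_k = 1 | θ)^{q_jk}` and solves the log-linear
  system `ln P(θ) = Q x(θ)` by (non-negativity-constrained) least squares at
  every ability level, yielding attribute mastery curves and reconstructed
  ICCs.
* A **model-comparison harness**: mean absolute distance (MAD) between
  source and reconstructed ICCs (< .05 good, < .10 satisfactory), paired
  t-tests on item-level MADs, predictive and cross-validated correlations
  with empirical difficulties, Steiger's Z for dependent overlapping
  correlations, Spearman rank agreement of component parameters, and a
  multiple-regression robustness check with rule × design-principle
  interaction terms.
* A **synthetic-data generator** for the nine-component taxonomy of
  difficult figural matrices (five change rules: ADD, ANE, COM, CQ, SS;
  four design principles: DP, VOS, MR, DRA), producing additive-true,
  conjunctive-true, or 2PL-true response matrices with known ground truth.

The estimators follow scikit-learn conventions (`fit`, `get_params`,
trailing-underscore fitted attributes); module-level functions
(`fit_rasch`, `fit_lltm`, `solve_attribute_logprobs`, ...) are thin wrappers.

## Worked example

```python
from cdmcompare import (make_taxonomy_qmatrix, simulate_additive,
                        run_full_comparison)

q = make_taxonomy_qmatrix(n_items=18, rng_seed=42)
fit = simulate_additive(q, n_persons=600, rng_seed=1)   # additive-true world
cv = simulate_additive(q, n_persons=600, rng_seed=2)    # parallel sample

report = run_full_comparison(fit.responses, cv.responses, q)
print(report.render_text())
t = report.mad_tests["lltm_vs_lsdm_rasch"]
z = report.steiger_tests["lltm_vs_lsdm_rasch_fit"]
print(f"paired t({t.df}) = {t.t:.2f}, p = {t.p:.3f}, d = {t.d:.2f}")
print(f"Steiger Z = {z.z:.2f}, p = {z.p:.3f}")
```

prints

```
Model  IRT-Model  MAD     Difference (Cohen's d)  Predictive r  Cross-Validation r
1. LLTM  rasch     0.006           -              1.00          1.00
2. LSDM  rasch     0.048       -1.84              0.95          0.94
3. LSDM  twopl     0.055       -0.57              0.96          0.95
paired t(15) = -7.35, p = 0.000, d = -1.84
Steiger Z = 7.13, p = 0.000
```

Because this world is additive by construction, the LLTM reconstructs the
Rasch ICCs almost perfectly (mean MAD 0.006, "good" on the conventional
scale), while the conjunctive LSDM is left with a systematic reconstruction
gap (0.048); the paired t on item-level MADs and Steiger's Z on the
predictive correlations both reject equality of the two reconstructions.
On conjunctive-true data (see `examples/conjunctive_demo.yaml`) the ordering
reverses.

A command-line interface drives the same stages from YAML configs:

```bash
cdmcompare pipeline --config examples/additive_demo.yaml
cdmcompare calibrate --config my_study.yaml     # also: simulate, lltm, lsdm, compare
```

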