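"""Comparing additive and multiplicative reconstructions.

This module evaluates how well each cognitive diagnostic model (LLTM with
additive effects; LSDM with multiplicative effects, sourced from Rasch or 2PL
ICCs) reproduces empirical item characteristics, and tests the differences:

* paired t-tests on item-level MAD values,
* Steiger's Z for dependent overlapping correlations (both model predictions
  correlate with the same empirical difficulty vector),
* Spearman rank agreement between component-parameter vectors,
* a multiple-regression robustness check asking whether rule x design-principle
  interaction terms add explained variance beyond additive main effects,
* and the end-to-end harness :func:`run_full_comparison` producing a
  comparison table with one row per model / IRT-source combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ResponseMatrix, ThetaGrid
from .irt import ModelFitComparison, RaschCML, TwoPLMML, compare_model_fit, item_fit_screen
from .lltm import LLTM
from .lsdm import LSDM, mad_diagnostics
from .taxonomy import CHANGE_RULE, DESIGN_PRINCIPLE, QMatrix

__all__ = [
    "PairedTResult",
    "CorrelationResult",
    "SteigerResult",
    "RegressionRobustness",
    "ComparisonReport",
    "paired_mad_test",
    "difficulty_agreement",
    "steiger_z",
    "rank_agreement",
    "regression_robustness",
    "select_top_components",
    "run_full_comparison",
]


# ---------------------------------------------------------------------------
# Elementary statistical comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    d: float          # Cohen's d for paired data: mean(diff) / sd(diff)
    mean_diff: float


def paired_mad_test(mads_a: pd.Series | np.ndarray,
                    mads_b: pd.Series | np.ndarray) -> PairedTResult:
    """Paired t-test on matched per-item MAD values (a minus b)."""
    a = np.asarray(pd.Series(mads_a), float)
    b = np.asarray(pd.Series(mads_b), float)
    if isinstance(mads_a, pd.Series) and isinstance(mads_b, pd.Series):
        if list(mads_a.index) != list(mads_b.index):
            raise ValueError("MAD vectors are not matched by item id")
    if a.size != b.size or a.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if np.all(diff == diff[0]):     # constant differences: sd is exactly zero
        sd = 0.0
        mean = float(diff[0])
    if sd == 0:
        if mean == 0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, d=0.0, mean_diff=0.0)
        t = np.inf if mean > 0 else -np.inf
        return PairedTResult(t=float(t), df=n - 1, p=0.0,
                             d=float(np.sign(mean) * np.inf), mean_diff=float(mean))
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), d=float(mean / sd),
                         mean_diff=float(mean))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float


def difficulty_agreement(sigma_model, sigma_empirical,
                         conf: float = 0.95) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(pd.Series(sigma_model), float)
    y = np.asarray(pd.Series(sigma_empirical), float)
    if isinstance(sigma_model, pd.Series) and isinstance(sigma_empirical, pd.Series):
        if list(sigma_model.index) != list(sigma_empirical.index):
            raise ValueError("difficulty vectors are not matched by item id")
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched vectors of length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zc = stats.norm.ppf(0.5 + conf / 2)
    return CorrelationResult(r=r, n=x.size,
                             ci_low=float(np.tanh(z - zc * se)),
                             ci_high=float(np.tanh(z + zc * se)))


@dataclass(frozen=True)
class SteigerResult:
    z: float
    p: float
    r_a: float
    r_b: float
    r_ab: float
    n: int


def steiger_z(r_a: float, r_b: float, r_ab: float, n: int) -> SteigerResult:
    """Steiger's test for two dependent correlations sharing one variable.

    ``r_a`` and ``r_b`` both involve the shared variable (here: the empirical
    difficulty vector); ``r_ab`` is the correlation between the two other
    variables (the two model predictions).  Uses the Fisher-z form with the
    mean-correlation substitution in the covariance term.
    """
    for name, r in (("r_a", r_a), ("r_b", r_b), ("r_ab", r_ab)):
        if not -1 < r < 1:
            raise ValueError(f"{name}={r} outside (-1, 1): Fisher transform undefined")
    if n < 10:
        raise ValueError("n must be >= 10")
    z_a, z_b = np.arctanh(r_a), np.arctanh(r_b)
    rbar = 0.5 * (r_a + r_b)
    rbar2 = rbar * rbar
    psi = r_ab * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r_ab ** 2)
    cov = psi / (1 - rbar2) ** 2
    z = (z_a - z_b) * np.sqrt((n - 3) / (2 - 2 * cov))
    p = 2 * stats.norm.sf(abs(z))
    return SteigerResult(z=float(z), p=float(p), r_a=float(r_a), r_b=float(r_b),
                         r_ab=float(r_ab), n=int(n))


def rank_agreement(params_a, params_b) -> float:
    """Spearman rank correlation between matched component-parameter vectors."""
    a = np.asarray(pd.Series(params_a), float)
    b = np.asarray(pd.Series(params_b), float)
    if isinstance(params_a, pd.Series) and isinstance(params_b, pd.Series):
        if list(params_a.index) != list(params_b.index):
            raise ValueError("parameter vectors are not matched by component id")
    if a.size != b.size or a.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(a, b).statistic)


# ---------------------------------------------------------------------------
# Regression robustness check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionRobustness:
    r2_main: float
    r2_interaction: float
    delta_r2: float
    f: float
    df_num: int
    df_den: int
    p: float
    predictors: tuple[str, ...]
    interactions: tuple[str, ...]
    dropped: tuple[str, ...]


def select_top_components(lltm_fit: LLTM, n_per_kind: int = 2) -> list[str]:
    """The most difficult change rules and design principles by LLTM eta."""
    eta = lltm_fit.eta_series_
    tax = lltm_fit.taxonomy_
    out: list[str] = []
    for kind in (CHANGE_RULE, DESIGN_PRINCIPLE):
        members = [c for c, k in zip(tax.component_ids, tax.kinds) if k == kind]
        ranked = eta[members].sort_values(ascending=False)
        out.extend(ranked.index[:n_per_kind])
    return out


def regression_robustness(difficulties, q: QMatrix,
                          selected_components: list[str]) -> RegressionRobustness:
    """Hierarchical OLS: main component effects, then rule x principle products.

    Interaction columns that are collinear with the already-included design
    are dropped with a warning and listed in ``dropped``.
    """
    y = np.asarray(pd.Series(difficulties), float)
    if y.size != q.n_items:
        raise ValueError("difficulty vector does not match Q-matrix items")
    missing = [c for c in selected_components if c not in q.components]
    if missing:
        raise ValueError(f"selected components not in Q-matrix: {missing}")
    qf = q.to_frame().astype(float)
    x_main = qf[selected_components]
    if q.n_items < len(selected_components) + 2:
        raise ValueError("too few items for the selected predictor count")

    rules = [c for c in selected_components if q.taxonomy.kind_of(c) == CHANGE_RULE]
    principles = [c for c in selected_components
                  if q.taxonomy.kind_of(c) == DESIGN_PRINCIPLE]
    inter_cols = {}
    for r, p_ in product(rules, principles):
        inter_cols[f"{r}x{p_}"] = qf[r] * qf[p_]
    x_inter_all = pd.DataFrame(inter_cols, index=qf.index)

    # drop collinear interaction columns greedily
    base = sm.add_constant(x_main)
    kept, dropped = [], []
    current = base.to_numpy()
    rank = np.linalg.matrix_rank(current)
    for name in x_inter_all.columns:
        cand = np.column_stack([current, x_inter_all[name].to_numpy()])
        if np.linalg.matrix_rank(cand) > rank:
            kept.append(name)
            current = cand
            rank += 1
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropped collinear interaction terms: {dropped}", RuntimeWarning)

    model_main = sm.OLS(y, base).fit()
    x_full = pd.concat([base, x_inter_all[kept]], axis=1)
    model_full = sm.OLS(y, x_full).fit()
    if kept:
        f, p, df_num = model_full.compare_f_test(model_main)
        df_den = int(model_full.df_resid)
    else:
        f, p, df_num, df_den = 0.0, 1.0, 0, int(model_main.df_resid)
    return RegressionRobustness(
        r2_main=float(model_main.rsquared),
        r2_interaction=float(model_full.rsquared),
        delta_r2=float(model_full.rsquared - model_main.rsquared),
        f=float(f), df_num=int(df_num), df_den=df_den, p=float(p),
        predictors=tuple(selected_components), interactions=tuple(kept),
        dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# Full comparison harness
# ---------------------------------------------------------------------------

@dataclass
class ModelRow:
    model: str            # "LLTM" or "LSDM"
    irt_source: str       # "rasch" or "twopl"
    mean_mad: float
    median_mad: float
    predictive: CorrelationResult
    cross_validation: CorrelationResult


@dataclass
class ComparisonReport:
    """Structured output of the full additive-vs-multiplicative comparison."""

    rows: list[ModelRow]
    mad_tests: dict[str, PairedTResult]
    steiger_tests: dict[str, SteigerResult]
    rank_agreement: dict[str, float]
    regression: dict[str, RegressionRobustness]
    component_table: pd.DataFrame = field(repr=False)
    retained_items: list[str] = field(default_factory=list)
    flagged_items: list[str] = field(default_factory=list)
    calibration: dict[str, ModelFitComparison] = field(default_factory=dict)
    item_mads: pd.DataFrame | None = field(default=None, repr=False)

    def row(self, model: str, irt_source: str) -> ModelRow:
        for r in self.rows:
            if r.model == model and r.irt_source == irt_source:
                return r
        raise KeyError((model, irt_source))

    def to_dict(self) -> dict:
        def cr(c: CorrelationResult) -> dict:
            return {"r": c.r, "n": c.n, "ci": [c.ci_low, c.ci_high]}

        return {
            "rows": [
                {"model": r.model, "irt_source": r.irt_source,
                 "mean_mad": r.mean_mad, "median_mad": r.median_mad,
                 "predictive": cr(r.predictive),
                 "cross_validation": cr(r.cross_validation)}
                for r in self.rows
            ],
            "mad_tests": {k: vars(v) for k, v in self.mad_tests.items()},
            "steiger_tests": {k: vars(v) for k, v in self.steiger_tests.items()},
            "rank_agreement": self.rank_agreement,
            "regression": {k: {**vars(v),
                               "predictors": list(v.predictors),
                               "interactions": list(v.interactions),
                               "dropped": list(v.dropped)}
                           for k, v in self.regression.items()},
            "component_table": self.component_table.reset_index().to_dict("records"),
            "retained_items": self.retained_items,
            "flagged_items": self.flagged_items,
            "calibration": {k: vars(v) for k, v in self.calibration.items()},
        }

    def render_text(self) -> str:
        lines = ["Model  IRT-Model  MAD     Difference (Cohen's d)  Predictive r  Cross-Validation r"]
        d_by_row = {"LSDM/rasch": self.mad_tests.get("lsdm_rasch_vs_lltm"),
                    "LSDM/twopl": self.mad_tests.get("lsdm_twopl_vs_lsdm_rasch")}
        for i, r in enumerate(self.rows, 1):
            test = d_by_row.get(f"{r.model}/{r.irt_source}")
            diff = f"{-test.d:+.2f}" if test is not None else "-"
            lines.append(
                f"{i}. {r.model:<5} {r.irt_source:<9} {r.mean_mad:.3f}  "
                f"{diff:>10}              {r.predictive.r:.2f}          "
                f"{r.cross_validation.r:.2f}")
        return "\n".join(lines)


def run_full_comparison(
    responses_fit: ResponseMatrix,
    responses_cv: ResponseMatrix,
    q: QMatrix,
    grid: ThetaGrid | None = None,
    alpha: float = 0.05,
    quad_nodes: int = 21,
    constrained: bool = True,
    eps: float = 1e-6,
    screen_items: bool = True,
    min_group: int = 30,
    n_top_components: int = 2,
) -> ComparisonReport:
    """Run the four-step comparison pipeline on two parallel samples.

    Steps: (1) Rasch/2PL calibration of the fit sample with item screening
    and Rasch-vs-2PL likelihood-ratio comparison in both samples; (2) LLTM
    fit to the raw responses and LSDM decompositions of the Rasch and 2PL
    ICCs; (3) MAD diagnostics, predictive and cross-validation correlations,
    paired t and Steiger Z tests, regression robustness check; (4) component
    parameter table and rank agreements.
    """
    if list(responses_fit.items) != list(responses_cv.items):
        raise ValueError("fit and cross-validation samples cover different items")
    if list(q.items) != list(responses_fit.items):
        raise ValueError("Q-matrix does not match response items")
    grid = grid if grid is not None else ThetaGrid.make()

    # --- step 1: calibration and screening on the full item set -------------
    rasch_full = RaschCML().fit(responses_fit)
    flagged: list[str] = []
    retained = list(responses_fit.items)
    if screen_items:
        screen = item_fit_screen(rasch_full, responses_fit, alpha=alpha,
                                 min_group=min_group)
        if len(screen.retained_items) >= 2:
            q_try = q.subset(screen.retained_items)
            if q_try.full_column_rank:
                retained = screen.retained_items
                flagged = screen.flagged_items
            else:
                warnings.warn(
                    "screened item subset loses Q-matrix column rank; "
                    "keeping the full item set", RuntimeWarning)

    q_r = q.subset(retained)
    fit_r = responses_fit.subset_items(retained)
    cv_r = responses_cv.subset_items(retained)

    rasch_a = RaschCML().fit(fit_r)
    rasch_b = RaschCML().fit(cv_r)
    twopl_a = TwoPLMML(quad_nodes=quad_nodes).fit(fit_r)
    twopl_b = TwoPLMML(quad_nodes=quad_nodes).fit(cv_r)
    calibration = {
        "fit_sample": compare_model_fit(fit_r, twopl_a),
        "cv_sample": compare_model_fit(cv_r, twopl_b),
    }

    rasch_icc = rasch_a.icc_table(grid, eps=eps)
    twopl_icc = twopl_a.icc_table(grid, eps=eps)
    sigma_emp_a = rasch_a.difficulty_series_
    sigma_emp_b = rasch_b.difficulty_series_

    # --- step 2: reconstructions --------------------------------------------
    lltm = LLTM().fit(fit_r, q_r)
    lltm_icc = lltm.icc_table(grid, eps=eps)
    lltm_mad = mad_diagnostics(rasch_icc, lltm_icc)
    lltm_sigma = pd.Series(lltm.difficulties_, index=lltm.items_)

    lsdm_rasch = LSDM(constrained=constrained, eps=eps).fit(rasch_icc, q_r)
    lsdm_twopl = LSDM(constrained=constrained, eps=eps).fit(twopl_icc, q_r)
    lsdm_rasch_sigma = lsdm_rasch.implied_difficulties()["difficulty"]
    lsdm_twopl_sigma = lsdm_twopl.implied_difficulties()["difficulty"]

    # --- step 3: evaluation and tests ---------------------------------------
    def row(model, source, mad, sigma_model):
        return ModelRow(
            model=model, irt_source=source,
            mean_mad=mad.mean, median_mad=mad.median,
            predictive=difficulty_agreement(sigma_model, sigma_emp_a),
            cross_validation=difficulty_agreement(sigma_model, sigma_emp_b))

    rows = [
        row("LLTM", "rasch", lltm_mad, lltm_sigma),
        row("LSDM", "rasch", lsdm_rasch.mad_, lsdm_rasch_sigma),
        row("LSDM", "twopl", lsdm_twopl.mad_, lsdm_twopl_sigma),
    ]

    mad_tests = {
        "lltm_vs_lsdm_rasch": paired_mad_test(lltm_mad.per_item, lsdm_rasch.mad_.per_item),
        "lsdm_rasch_vs_lltm": paired_mad_test(lsdm_rasch.mad_.per_item, lltm_mad.per_item),
        "lsdm_twopl_vs_lsdm_rasch": paired_mad_test(lsdm_twopl.mad_.per_item,
                                                    lsdm_rasch.mad_.per_item),
    }

    n_items = len(retained)

    def steiger_pair(sig_a, sig_b, emp):
        r_a = difficulty_agreement(sig_a, emp).r
        r_b = difficulty_agreement(sig_b, emp).r
        r_ab = float(stats.pearsonr(np.asarray(sig_a, float),
                                    np.asarray(sig_b, float)).statistic)
        return steiger_z(r_a, r_b, r_ab, n_items)

    steiger_tests = {
        "lltm_vs_lsdm_rasch_fit": steiger_pair(lltm_sigma, lsdm_rasch_sigma, sigma_emp_a),
        "lltm_vs_lsdm_rasch_cv": steiger_pair(lltm_sigma, lsdm_rasch_sigma, sigma_emp_b),
        "lsdm_rasch_vs_lsdm_twopl_fit": steiger_pair(lsdm_rasch_sigma, lsdm_twopl_sigma,
                                                     sigma_emp_a),
        "lsdm_rasch_vs_lsdm_twopl_cv": steiger_pair(lsdm_rasch_sigma, lsdm_twopl_sigma,
                                                    sigma_emp_b),
    }

    # --- step 4: parameter inspection ---------------------------------------
    sum_rasch = lsdm_rasch.attribute_summary().table
    sum_twopl = lsdm_twopl.attribute_summary().table
    component_table = pd.DataFrame({
        "kind": list(q.taxonomy.kinds),
        "bp_lltm_rasch": lltm.eta_centered_,
        "sigma_lsdm_rasch": sum_rasch["difficulty_centered"],
        "sigma_lsdm_twopl": sum_twopl["difficulty_centered"],
        "beta_lsdm_twopl": sum_twopl["discrimination"],
    }, index=pd.Index(q.taxonomy.component_ids, name="component"))

    def safe_rank(a, b):
        mask = np.isfinite(np.asarray(a, float)) & np.isfinite(np.asarray(b, float))
        a_, b_ = np.asarray(a, float)[mask], np.asarray(b, float)[mask]
        try:
            return rank_agreement(a_, b_)
        except ValueError:
            return float("nan")

    ranks = {
        "lltm_vs_lsdm_rasch": safe_rank(component_table["bp_lltm_rasch"],
                                        component_table["sigma_lsdm_rasch"]),
        "lltm_vs_lsdm_twopl": safe_rank(component_table["bp_lltm_rasch"],
                                        component_table["sigma_lsdm_twopl"]),
        "lsdm_rasch_vs_lsdm_twopl": safe_rank(component_table["sigma_lsdm_rasch"],
                                              component_table["sigma_lsdm_twopl"]),
    }

    top = select_top_components(lltm, n_per_kind=n_top_components)
    regression = {
        "rasch": regression_robustness(sigma_emp_a, q_r, top),
        "twopl": regression_robustness(
            pd.Series(twopl_a.difficulties_, index=twopl_a.items_), q_r, top),
    }

    item_mads = pd.DataFrame({
        "lltm": lltm_mad.per_item,
        "lsdm_rasch": lsdm_rasch.mad_.per_item,
        "lsdm_twopl": lsdm_twopl.mad_.per_item,
    })

    return ComparisonReport(
        rows=rows, mad_tests=mad_tests, steiger_tests=steiger_tests,
        rank_agreement=ranks, regression=regression,
        component_table=component_table, retained_items=retained,
        flagged_items=flagged, calibration=calibration, item_mads=item_mads)
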