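"""Rasch and 2PL calibration, item-fit screening and model-fit comparison.

Two estimation routes are provided, mirroring standard practice:

* :class:`RaschCML` — conditional maximum likelihood (CML).  Conditioning on
  the raw score eliminates the person parameters, so the item difficulty
  estimates do not depend on the ability distribution.  Estimation works
  through the elementary symmetric functions of the item easiness values.
* :class:`TwoPLMML` (and the internal marginal Rasch used for likelihood
  ratio tests) — marginal maximum likelihood via EM over a fixed N(0, 1)
  Gauss-Hermite quadrature.  Rasch and 2PL marginal likelihoods live on the
  same scale, which is what the nested model comparison requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from ._esf import conditional_item_probs, esf, esf_deleted
from .containers import ICCTable, ResponseMatrix, ThetaGrid

__all__ = [
    "RaschCML",
    "TwoPLMML",
    "ItemFitReport",
    "ModelFitComparison",
    "fit_rasch",
    "fit_2pl",
    "item_fit_screen",
    "compare_model_fit",
    "evaluate_iccs",
    "gauss_hermite_normal",
    "marginal_rasch_loglik",
]

PROB_EPS = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit does not converge."""


def _validate_responses(responses: ResponseMatrix) -> None:
    if responses.n_items < 2:
        raise ValueError("need at least 2 items")
    raw = responses.raw_scores
    nonextreme = (raw > 0) & (raw < responses.n_items)
    sub = responses.scores[nonextreme]
    if sub.shape[0] == 0:
        raise ValueError("no persons with non-extreme raw scores")
    totals = sub.sum(axis=0)
    dead = [responses.items[j] for j in range(responses.n_items)
            if totals[j] == 0 or totals[j] == sub.shape[0]]
    if dead:
        raise ValueError(f"items without response variance among non-extreme persons: {dead}")


def _cml_neg_loglik_grad(beta: np.ndarray, item_totals: np.ndarray,
                         score_counts: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative conditional log-likelihood and gradient in easiness-log space.

    ``beta_j = -sigma_j``; ``score_counts[r]`` counts non-extreme persons with
    raw score r (entries 0 and n are ignored).
    """
    eps = np.exp(beta)
    n = beta.size
    g = esf(eps)
    g_del = esf_deleted(eps)
    ll = float(item_totals @ beta)
    grad = item_totals.astype(float).copy()
    for r in range(1, n):
        nr = score_counts[r]
        if nr == 0:
            continue
        ll -= nr * np.log(g[r])
        grad -= nr * eps * g_del[:, r - 1] / g[r]
    return -ll, -grad


@dataclass
class RaschFitResult:
    difficulties: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    score_theta: pd.Series
    n_excluded_persons: int


class RaschCML:
    """Rasch model fitted by conditional maximum likelihood.

    Item difficulties are identified only up to a constant under CML; the
    sum-zero normalization is applied after optimization.  Persons with
    all-0 or all-1 raw scores carry no conditional information and are
    excluded from estimation (but counted and reported).

    Attributes (after ``fit``)
    --------------------------
    items_ : list of item ids
    difficulties_ : ndarray, sum-zero normalized item difficulties (logits)
    loglik_ : float, conditional log-likelihood at the optimum
    score_theta_ : pd.Series mapping each non-extreme raw score to its ML
        ability estimate (NaN for extreme scores)
    n_excluded_persons_ : int, persons with extreme raw scores
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-12):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "RaschCML":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, responses: ResponseMatrix) -> "RaschCML":
        _validate_responses(responses)
        n_items = responses.n_items
        raw = responses.raw_scores
        nonextreme = (raw > 0) & (raw < n_items)
        sub = responses.scores[nonextreme]
        item_totals = sub.sum(axis=0)
        score_counts = np.bincount(raw[nonextreme], minlength=n_items + 1)

        # start at centered log-odds of item proportions
        p = item_totals / sub.shape[0]
        beta0 = np.log(p / (1 - p))
        beta0 -= beta0.mean()

        res = optimize.minimize(
            _cml_neg_loglik_grad, beta0, args=(item_totals, score_counts),
            jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
        )
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            raise ConvergenceError(f"CML optimization failed: {res.message}")
        beta = res.x - res.x.mean()          # location fixed by sum-zero constraint
        sigma = -beta

        self.items_ = list(responses.items)
        self.difficulties_ = sigma
        self.loglik_ = float(-_cml_neg_loglik_grad(beta, item_totals, score_counts)[0])
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.n_excluded_persons_ = int((~nonextreme).sum())
        self.score_theta_ = self._score_theta_table(sigma)
        return self

    def _score_theta_table(self, sigma: np.ndarray) -> pd.Series:
        """ML ability per raw score (extreme scores get NaN)."""
        n = sigma.size
        thetas = {}
        for r in range(n + 1):
            if r == 0 or r == n:
                thetas[r] = np.nan
                continue
            f = lambda t: expit(t - sigma).sum() - r
            thetas[r] = optimize.brentq(f, -30.0, 30.0)
        s = pd.Series(thetas)
        s.index.name = "raw_score"
        return s

    @property
    def difficulty_series_(self) -> pd.Series:
        return pd.Series(self.difficulties_, index=self.items_, name="sigma")

    def icc_table(self, grid: ThetaGrid, eps: float = PROB_EPS) -> ICCTable:
        return evaluate_iccs(self, grid, eps=eps)


def gauss_hermite_normal(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled to integrate against N(0, 1)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _em_marginal(scores: np.ndarray, n_nodes: int, estimate_slopes: bool,
                 max_iter: int, tol: float, slope_bounds: tuple[float, float]):
    """EM for the marginal 1PL/2PL with ability fixed at N(0, 1).

    Returns (a, b, loglik, n_iter, converged, bounded_items).
    """
    n_persons, n_items = scores.shape
    nodes, weights = gauss_hermite_normal(n_nodes)
    x = scores.astype(float)

    a = np.ones(n_items)
    p_obs = np.clip(x.mean(axis=0), 0.05, 0.95)
    d = np.log(p_obs / (1 - p_obs))          # intercept in logit p = a*node + d
    lo, hi = slope_bounds

    def marginal_ll(a, d):
        logit = a[:, None] * nodes[None, :] + d[:, None]
        logp = -np.logaddexp(0.0, -logit)
        log1mp = -np.logaddexp(0.0, logit)
        ll_in = x @ logp + (1 - x) @ log1mp          # persons x nodes
        return ll_in, float(logsumexp(ll_in + np.log(weights)[None, :], axis=1).sum())

    ll_in, ll = marginal_ll(a, d)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior node weights per person
        post = np.exp(ll_in + np.log(weights)[None, :]
                      - logsumexp(ll_in + np.log(weights)[None, :], axis=1, keepdims=True))
        nbar = post.sum(axis=0)                      # nodes
        rbar = x.T @ post                            # items x nodes

        # M-step: per-item weighted logistic Newton iterations
        for j in range(n_items):
            aj, dj = a[j], d[j]
            for _ in range(25):
                p = expit(aj * nodes + dj)
                resid = rbar[j] - nbar * p
                w2 = nbar * p * (1 - p)
                if estimate_slopes:
                    g = np.array([resid @ nodes, resid.sum()])
                    h = np.array([[w2 @ (nodes ** 2), w2 @ nodes],
                                  [w2 @ nodes, w2.sum()]])
                    try:
                        step = np.linalg.solve(h, g)
                    except np.linalg.LinAlgError:
                        break
                    aj, dj = aj + step[0], dj + step[1]
                    aj = float(np.clip(aj, lo, hi))
                else:
                    g = resid.sum()
                    h = w2.sum()
                    dj = dj + g / h
                    step = np.array([g / h])
                if np.max(np.abs(step)) < 1e-9:
                    break
            a[j], d[j] = aj, dj

        ll_in, ll_new = marginal_ll(a, d)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    bounded = [j for j in range(n_items) if estimate_slopes and (a[j] <= lo or a[j] >= hi)]
    b = -d / a
    return a, b, ll, it, converged, bounded


class TwoPLMML:
    """Two-parameter logistic model fitted by marginal ML (EM, N(0,1) ability).

    Attributes (after ``fit``)
    --------------------------
    items_ : list of item ids
    discriminations_ : ndarray of slopes beta_j (> 0)
    difficulties_ : ndarray of locations b_j
    loglik_ : float, marginal log-likelihood
    bounded_items_ : items whose slope hit the bound (Heywood-type divergence)
    """

    def __init__(self, quad_nodes: int = 21, max_iter: int = 500, tol: float = 1e-7,
                 slope_bounds: tuple[float, float] = (0.05, 6.0)):
        self.quad_nodes = quad_nodes
        self.max_iter = max_iter
        self.tol = tol
        self.slope_bounds = slope_bounds

    def get_params(self, deep: bool = True) -> dict:
        return {"quad_nodes": self.quad_nodes, "max_iter": self.max_iter,
                "tol": self.tol, "slope_bounds": self.slope_bounds}

    def set_params(self, **params) -> "TwoPLMML":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, responses: ResponseMatrix) -> "TwoPLMML":
        _validate_responses(responses)
        a, b, ll, it, conv, bounded = _em_marginal(
            responses.scores, self.quad_nodes, True, self.max_iter, self.tol,
            self.slope_bounds)
        if bounded:
            warnings.warn(
                f"slopes bounded at {self.slope_bounds} for items "
                f"{[responses.items[j] for j in bounded]}", RuntimeWarning)
        self.items_ = list(responses.items)
        self.discriminations_ = a
        self.difficulties_ = b
        self.loglik_ = ll
        self.n_iter_ = it
        self.converged_ = conv
        self.bounded_items_ = [responses.items[j] for j in bounded]
        return self

    def icc_table(self, grid: ThetaGrid, eps: float = PROB_EPS) -> ICCTable:
        return evaluate_iccs(self, grid, eps=eps)


def marginal_rasch_loglik(responses: ResponseMatrix, quad_nodes: int = 21,
                          max_iter: int = 500, tol: float = 1e-7) -> tuple[float, np.ndarray]:
    """Marginal (N(0,1)) Rasch fit; returns (loglik, difficulties).

    Used so that likelihood-ratio and information-criterion comparisons with
    the 2PL are made on the same (marginal) likelihood scale.
    """
    _validate_responses(responses)
    a, b, ll, _, _, _ = _em_marginal(responses.scores, quad_nodes, False,
                                     max_iter, tol, (1.0, 1.0))
    return ll, b


def evaluate_iccs(fit: "RaschCML | TwoPLMML", grid: ThetaGrid,
                  eps: float = PROB_EPS) -> ICCTable:
    """Model ICCs on an ability grid, clipped to ``(eps, 1 - eps)``."""
    if isinstance(fit, TwoPLMML):
        a = fit.discriminations_
        provenance = "twopl"
    else:
        a = np.ones(len(fit.items_))
        provenance = "rasch"
    b = fit.difficulties_
    probs = expit(a[:, None] * (grid.points[None, :] - b[:, None]))
    probs = np.clip(probs, eps, 1 - eps)
    return ICCTable(items=list(fit.items_), grid=grid, probs=probs, provenance=provenance)


# ---------------------------------------------------------------------------
# Item fit screening
# ---------------------------------------------------------------------------

@dataclass
class ItemFitReport:
    """Per-item score-group chi-square fit screen with infit/outfit."""

    table: pd.DataFrame = field(repr=False)   # statistic, df, p, infit, outfit, flagged
    alpha: float = 0.05
    n_groups: int = 0

    @property
    def flagged_items(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])

    @property
    def retained_items(self) -> list[str]:
        return list(self.table.index[~self.table["flagged"]])


def _score_groups(raw: np.ndarray, n_items: int, min_count: int) -> list[np.ndarray]:
    """Merge adjacent non-extreme raw scores into groups of >= min_count persons."""
    groups: list[np.ndarray] = []
    current: list[int] = []
    count = 0
    for r in range(1, n_items):
        nr = int((raw == r).sum())
        if nr == 0 and not current:
            continue
        current.append(r)
        count += nr
        if count >= min_count:
            groups.append(np.array(current))
            current, count = [], 0
    if current:
        if groups:
            groups[-1] = np.concatenate([groups[-1], np.array(current)])
        else:
            groups.append(np.array(current))
    return groups


def item_fit_screen(fit: RaschCML, responses: ResponseMatrix, alpha: float = 0.05,
                    min_group: int = 30) -> ItemFitReport:
    """Score-group chi-square item-fit screen for a CML Rasch fit.

    Persons are grouped by raw score (adjacent scores merged until each group
    holds at least ``min_group`` persons).  The expected proportion correct in
    a group is the *exact* conditional probability ``P(X_j = 1 | r)`` implied
    by the fitted easiness parameters (elementary-symmetric-function form),
    so no ability estimates enter the screen.  The per-item statistic is a
    Pearson chi-square over groups with ``df = G - 1``; items with
    ``p < alpha`` are flagged.  Infit/outfit mean squares are reported
    alongside.
    """
    if fit.items_ != list(responses.items):
        raise ValueError("fit and responses cover different item sets")
    n_items = responses.n_items
    raw = responses.raw_scores
    groups = _score_groups(raw, n_items, min_group)
    if len(groups) < 3:
        raise ValueError(
            f"only {len(groups)} score groups of >= {min_group} persons; "
            "need at least 3 for the chi-square screen")

    eps_item = np.exp(-fit.difficulties_)
    cond = conditional_item_probs(eps_item)          # items x (n_items + 1)
    scores = responses.scores.astype(float)

    stat = np.zeros(n_items)
    n_g = len(groups)
    # infit/outfit accumulate over all non-extreme persons
    nonextreme = (raw > 0) & (raw < n_items)
    p_person = cond[:, raw[nonextreme]].T            # persons x items
    x_person = scores[nonextreme]
    resid2 = (x_person - p_person) ** 2
    var = p_person * (1 - p_person)
    outfit = (resid2 / var).mean(axis=0)
    infit = resid2.sum(axis=0) / var.sum(axis=0)

    for g in groups:
        in_g = np.isin(raw, g)
        obs = scores[in_g].sum(axis=0)
        p_g = cond[:, raw[in_g]]                     # items x persons-in-group
        exp_g = p_g.sum(axis=1)
        var_g = (p_g * (1 - p_g)).sum(axis=1)
        stat += (obs - exp_g) ** 2 / var_g

    df = n_g - 1
    pvals = stats.chi2.sf(stat, df)
    table = pd.DataFrame({
        "statistic": stat,
        "df": df,
        "p": pvals,
        "infit": infit,
        "outfit": outfit,
        "flagged": pvals < alpha,
    }, index=pd.Index(responses.items, name="item"))
    return ItemFitReport(table=table, alpha=alpha, n_groups=n_g)


# ---------------------------------------------------------------------------
# Model fit comparison (Rasch vs 2PL)
# ---------------------------------------------------------------------------

@dataclass
class ModelFitComparison:
    """Likelihood-ratio test and information-criterion deltas (2PL minus Rasch)."""

    chi2: float
    df: int
    p: float
    delta_aic: float
    delta_bic: float
    delta_caic: float
    loglik_rasch: float
    loglik_twopl: float
    n_persons: int

    @classmethod
    def from_loglik(cls, loglik_rasch: float, k_rasch: int, loglik_twopl: float,
                    k_twopl: int, n_persons: int) -> "ModelFitComparison":
        chi2 = 2.0 * (loglik_twopl - loglik_rasch)
        df = k_twopl - k_rasch
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else (0.0 if chi2 > 0 else 1.0)
        ln_n = np.log(n_persons)

        def aic(ll, k):
            return -2 * ll + 2 * k

        def bic(ll, k):
            return -2 * ll + k * ln_n

        def caic(ll, k):
            return -2 * ll + k * (ln_n + 1)

        return cls(
            chi2=chi2, df=df, p=p,
            delta_aic=aic(loglik_twopl, k_twopl) - aic(loglik_rasch, k_rasch),
            delta_bic=bic(loglik_twopl, k_twopl) - bic(loglik_rasch, k_rasch),
            delta_caic=caic(loglik_twopl, k_twopl) - caic(loglik_rasch, k_rasch),
            loglik_rasch=loglik_rasch, loglik_twopl=loglik_twopl, n_persons=n_persons,
        )


def compare_model_fit(responses: ResponseMatrix, twopl: TwoPLMML,
                      quad_nodes: int | None = None) -> ModelFitComparison:
    """Nested Rasch-vs-2PL comparison on the marginal likelihood scale.

    The Rasch likelihood is recomputed marginally (same quadrature as the
    2PL fit) so both models are scored on the same likelihood type.  Free
    parameter counts: J for the marginal Rasch, 2J for the 2PL, so df = J.
    """
    if twopl.items_ != list(responses.items):
        raise ValueError("2PL fit and responses cover different item sets")
    nodes = quad_nodes if quad_nodes is not None else twopl.quad_nodes
    ll_rasch, _ = marginal_rasch_loglik(responses, quad_nodes=nodes)
    n_items = responses.n_items
    return ModelFitComparison.from_loglik(
        loglik_rasch=ll_rasch, k_rasch=n_items,
        loglik_twopl=twopl.loglik_, k_twopl=2 * n_items,
        n_persons=responses.n_persons)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_rasch(responses: ResponseMatrix, **kwargs) -> RaschCML:
    return RaschCML(**kwargs).fit(responses)


def fit_2pl(responses: ResponseMatrix, quad_nodes: int = 21, **kwargs) -> TwoPLMML:
    return TwoPLMML(quad_nodes=quad_nodes, **kwargs).fit(responses)
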