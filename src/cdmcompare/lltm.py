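"""Linear logistic test model (LLTM): additive component decomposition.

The LLTM constrains Rasch item difficulties to the additive structure
``sigma_j = sum_k q_jk eta_k + c``: each component contributes a fixed shift
``eta_k`` (its *base parameter*) for every unit of Q-matrix weight, and the
constant ``c`` normalizes the difficulties to sum to zero.  Estimation is by
conditional maximum likelihood, exactly as for the unconstrained Rasch model,
so on a saturated (identity) Q-matrix the LLTM reproduces the Rasch fit.

Because the conditional likelihood is invariant to a common shift of all item
difficulties, ``c`` is not a free parameter: it is computed analytically from
the sum-zero constraint after ``eta`` is estimated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ICCTable, ResponseMatrix, ThetaGrid
from .irt import PROB_EPS, ConvergenceError, _cml_neg_loglik_grad, _validate_responses
from .taxonomy import QMatrix
from scipy.special import expit

__all__ = ["LLTM", "fit_lltm", "lltm_reconstructed_difficulties", "lltm_icc_table"]


def _neg_loglik_grad_eta(eta: np.ndarray, q_w: np.ndarray, item_totals: np.ndarray,
                         score_counts: np.ndarray) -> tuple[float, np.ndarray]:
    # beta (easiness log) = -sigma = -(Q @ eta); chain rule through -Q
    beta = -(q_w @ eta)
    nll, g_beta = _cml_neg_loglik_grad(beta, item_totals, score_counts)
    return nll, -(q_w.T @ g_beta)


class LLTM:
    """LLTM fitted by conditional maximum likelihood.

    Attributes (after ``fit``)
    --------------------------
    components_ : component ids (taxonomy order)
    eta_ : ndarray, base parameters (logit difficulty contributions)
    eta_se_ : ndarray, asymptotic standard errors (observed-information based)
    eta_centered_ : ndarray, mean-centered base parameters for reporting
    c_ : float, normalization constant from the sum-zero constraint
    difficulties_ : ndarray, reconstructed item difficulties Q @ eta + c
    loglik_ : float, conditional log-likelihood
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "LLTM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, responses: ResponseMatrix, q: QMatrix) -> "LLTM":
        if list(q.items) != list(responses.items):
            raise ValueError("Q-matrix items do not match response items")
        if not q.full_column_rank:
            raise ValueError(
                "Q-matrix is rank deficient; eta unidentified "
                f"(dependent columns: {q.dependent_columns()})")
        _validate_responses(responses)

        n_items = responses.n_items
        raw = responses.raw_scores
        nonextreme = (raw > 0) & (raw < n_items)
        sub = responses.scores[nonextreme]
        item_totals = sub.sum(axis=0)
        score_counts = np.bincount(raw[nonextreme], minlength=n_items + 1)
        q_w = q.weights.astype(float)

        eta0 = np.zeros(len(q.taxonomy))
        res = optimize.minimize(
            _neg_loglik_grad_eta, eta0, args=(q_w, item_totals, score_counts),
            jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9},
        )
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            raise ConvergenceError(f"LLTM optimization failed: {res.message}")
        eta = res.x

        hess = self._numeric_hessian(eta, q_w, item_totals, score_counts)
        # pinv: on saturated designs eta is identified only up to a constant
        cov = np.linalg.pinv(hess, hermitian=True)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))

        sigma_raw = q_w @ eta
        c = -float(sigma_raw.mean())

        self.components_ = list(q.taxonomy.component_ids)
        self.items_ = list(q.items)
        self.taxonomy_ = q.taxonomy
        self.eta_ = eta
        self.eta_se_ = se
        self.eta_centered_ = eta - eta.mean()
        self.c_ = c
        self.difficulties_ = sigma_raw + c
        self.loglik_ = float(-res.fun)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        return self

    @staticmethod
    def _numeric_hessian(eta, q_w, item_totals, score_counts, h: float = 1e-5) -> np.ndarray:
        k = eta.size
        hess = np.zeros((k, k))
        for i in range(k):
            e = np.zeros(k)
            e[i] = h
            _, gp = _neg_loglik_grad_eta(eta + e, q_w, item_totals, score_counts)
            _, gm = _neg_loglik_grad_eta(eta - e, q_w, item_totals, score_counts)
            hess[i] = (gp - gm) / (2 * h)
        return 0.5 * (hess + hess.T)

    @property
    def eta_series_(self) -> pd.Series:
        return pd.Series(self.eta_, index=self.components_, name="eta")

    def component_table(self) -> pd.DataFrame:
        """Component report: kind, base parameter, SE, mean-centered value."""
        return pd.DataFrame({
            "kind": list(self.taxonomy_.kinds),
            "eta": self.eta_,
            "se": self.eta_se_,
            "eta_centered": self.eta_centered_,
        }, index=pd.Index(self.components_, name="component"))

    def reconstruct_difficulties(self, q: QMatrix) -> pd.Series:
        """``Q @ eta + c`` for an arbitrary (possibly subset) Q-matrix."""
        if tuple(q.taxonomy.component_ids) != tuple(self.components_):
            raise ValueError("Q-matrix components do not match the fitted taxonomy")
        return pd.Series(q.weights @ self.eta_ + self.c_, index=q.items, name="sigma_hat")

    def icc_table(self, grid: ThetaGrid, eps: float = PROB_EPS) -> ICCTable:
        probs = expit(grid.points[None, :] - self.difficulties_[:, None])
        return ICCTable(items=list(self.items_), grid=grid,
                        probs=np.clip(probs, eps, 1 - eps), provenance="lltm")


def fit_lltm(responses: ResponseMatrix, q: QMatrix, **kwargs) -> LLTM:
    return LLTM(**kwargs).fit(responses, q)


def lltm_reconstructed_difficulties(fit: LLTM, q: QMatrix) -> pd.Series:
    return fit.reconstruct_difficulties(q)


def lltm_icc_table(fit: LLTM, grid: ThetaGrid, eps: float = PROB_EPS) -> ICCTable:
    return fit.icc_table(grid, eps=eps)
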