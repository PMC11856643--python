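"""Least squares distance method (LSDM): multiplicative component decomposition.

The LSDM takes item characteristic curves from an already-fitted IRT model
and decomposes them along the Q-matrix under a conjunctive assumption: the
probability of solving an item is the product of the mastery probabilities of
its components, ``P_j(theta) = prod_k P(A_k=1 | theta)^{q_jk}``.  Taking
logs turns this into a linear system per ability level,

    ln P(theta) = Q x(theta),      x_k(theta) = ln P(A_k=1 | theta),

which is solved independently at each grid point by least squares.  Because
component probabilities cannot exceed 1, the default solver constrains
``x <= 0`` (a non-negative least squares problem on the negated system); the
unconstrained literal least-squares solution is available by flag, with
above-1 probabilities clipped and counted.

Reconstruction quality is summarized by the mean absolute distance (MAD)
between source and reconstructed ICCs over the grid, with the conventional
reading: MAD < 0.05 good, < 0.10 satisfactory, else poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import logit

from .containers import ICCTable
from .taxonomy import QMatrix

__all__ = [
    "LSDM",
    "MADReport",
    "AttributeSummary",
    "solve_attribute_logprobs",
    "reconstruct_iccs",
    "mad_diagnostics",
    "implied_item_difficulty",
    "attribute_curve_summary",
    "mad_label",
]

PROB_EPS = 1e-6

MAD_GOOD = 0.05
MAD_SATISFACTORY = 0.10


def mad_label(mad: float) -> str:
    """Conventional reconstruction-quality label for a MAD value."""
    if mad < MAD_GOOD:
        return "good"
    if mad < MAD_SATISFACTORY:
        return "satisfactory"
    return "poor"


@dataclass
class MADReport:
    """Per-item and scale-level mean absolute ICC reconstruction distance."""

    per_item: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if (self.per_item < 0).any():
            raise ValueError("MAD values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.per_item.mean())

    @property
    def median(self) -> float:
        return float(self.per_item.median())

    @property
    def labels(self) -> pd.Series:
        return self.per_item.map(mad_label).rename("label")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mad": self.per_item, "label": self.labels})


@dataclass
class AttributeSummary:
    """Logistic summaries of the recovered attribute characteristic curves."""

    table: pd.DataFrame = field(repr=False)
    # columns: difficulty, discrimination, difficulty_centered, r2,
    #          extrapolated (bool), unfit (bool)


class LSDM:
    """Least squares distance decomposition of ICCs along a Q-matrix.

    Parameters
    ----------
    constrained : bool, default True
        Enforce ``ln P(A_k|theta) <= 0`` (attribute probabilities <= 1) via
        non-negative least squares on the negated system.  When False, plain
        least squares is used and any cell with probability > 1 is clipped to
        ``1 - eps`` and counted in ``n_clipped_``.
    eps : float
        Probability clip applied before logarithms.

    Attributes (after ``fit``)
    --------------------------
    components_, items_, grid_ : problem layout
    attribute_logprobs_ : ndarray, components x grid-points matrix X of
        ``ln P(A_k=1 | theta)`` (all entries <= 0 in constrained mode)
    residual_norms_ : ndarray, per-theta Euclidean residual of ``Q x - ln P``
    reconstructed_ : ICCTable with provenance ``lsdm-reconstructed``
    mad_ : MADReport against the source table
    source_provenance_ : provenance tag of the source ICCs
    n_clipped_ : int, cells clipped in unconstrained mode
    """

    def __init__(self, constrained: bool = True, eps: float = PROB_EPS):
        self.constrained = constrained
        self.eps = eps

    def get_params(self, deep: bool = True) -> dict:
        return {"constrained": self.constrained, "eps": self.eps}

    def set_params(self, **params) -> "LSDM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, source: ICCTable, q: QMatrix) -> "LSDM":
        if list(q.items) != list(source.items):
            raise ValueError("Q-matrix items do not match ICC table items")
        dead_cols = [c for c, s in zip(q.components, q.weights.sum(axis=0)) if s == 0]
        if dead_cols:
            raise ValueError(f"components with all-zero Q columns are unidentified: {dead_cols}")

        qw = q.weights.astype(float)
        n_comp = qw.shape[1]
        n_grid = len(source.grid)
        # ICCTable guarantees probabilities strictly in (0, 1); any eps
        # clipping belongs upstream (evaluate_iccs), so exact conjunctive
        # sources decompose exactly here.
        log_p = np.log(source.probs)                                   # items x grid

        x = np.empty((n_comp, n_grid))
        resid = np.empty(n_grid)
        n_clipped = 0
        for t in range(n_grid):
            col = log_p[:, t]
            if self.constrained:
                # min ||Q(-y) - col|| with y >= 0  <=>  nnls(Q, -col)
                y, rnorm = nnls(qw, -col)
                x[:, t] = -y
                resid[t] = rnorm
            else:
                sol, *_ = np.linalg.lstsq(qw, col, rcond=None)
                over = sol > 0
                n_clipped += int(over.sum())
                x[:, t] = sol
                resid[t] = float(np.linalg.norm(qw @ sol - col))

        self.components_ = list(q.components)
        self.items_ = list(q.items)
        self.grid_ = source.grid
        self.taxonomy_ = q.taxonomy
        self.attribute_logprobs_ = x
        self.residual_norms_ = resid
        self.n_clipped_ = n_clipped
        self.source_provenance_ = source.provenance
        self.reconstructed_ = self.reconstruct(q)
        self.mad_ = mad_diagnostics(source, self.reconstructed_)
        return self

    def reconstruct(self, q: QMatrix) -> ICCTable:
        """Rebuild item ICCs from the attribute log-probabilities."""
        if list(q.components) != list(self.components_):
            raise ValueError("Q-matrix components do not match the fitted decomposition")
        x = self.attribute_logprobs_
        if not self.constrained:
            # unconstrained solutions may imply attribute probabilities > 1
            x = np.minimum(x, np.log(1 - self.eps))
        probs = np.exp(q.weights.astype(float) @ x)
        # keep strictly inside (0, 1) without disturbing exact reconstructions
        probs = np.clip(probs, 1e-300, 1.0 - 1e-12)
        return ICCTable(items=list(q.items), grid=self.grid_, probs=probs,
                        provenance="lsdm-reconstructed")

    def attribute_probs(self) -> pd.DataFrame:
        """Components x grid table of attribute mastery probabilities."""
        return pd.DataFrame(np.exp(self.attribute_logprobs_),
                            index=pd.Index(self.components_, name="component"),
                            columns=self.grid_.points)

    def implied_difficulties(self) -> pd.DataFrame:
        return implied_item_difficulty(self.reconstructed_)

    def attribute_summary(self, eps: float | None = None) -> AttributeSummary:
        return attribute_curve_summary(self, eps=eps)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def mad_diagnostics(source: ICCTable, reconstructed: ICCTable) -> MADReport:
    """Mean absolute distance between source and reconstructed ICC rows."""
    if list(source.items) != list(reconstructed.items):
        raise ValueError("item sets differ between source and reconstruction")
    if not np.array_equal(source.grid.points, reconstructed.grid.points):
        raise ValueError("theta grids differ between source and reconstruction")
    mad = np.abs(source.probs - reconstructed.probs).mean(axis=1)
    return MADReport(per_item=pd.Series(mad, index=source.items, name="mad"))


def implied_item_difficulty(reconstructed: ICCTable) -> pd.DataFrame:
    """Ability at the 0.50 solution probability, per item.

    Linear interpolation between the grid points bracketing the first upward
    crossing of 0.5.  Rows that never reach 0.5 inside the grid are flagged
    ``extrapolated`` and reported at the nearer grid boundary.
    """
    probs = reconstructed.probs
    if not np.all(np.isfinite(probs)):
        raise ValueError("non-finite probabilities in reconstructed ICCs")
    theta = reconstructed.grid.points
    out_difficulty = np.empty(len(reconstructed.items))
    out_flag = np.zeros(len(reconstructed.items), dtype=bool)
    for j, row in enumerate(probs):
        above = row >= 0.5
        if above.all():
            out_difficulty[j] = theta[0]
            out_flag[j] = True
            continue
        if not above.any():
            out_difficulty[j] = theta[-1]
            out_flag[j] = True
            continue
        # first upward crossing: first t with row[t] < 0.5 <= row[t+1]
        crossing = None
        for t in range(len(theta) - 1):
            if row[t] < 0.5 <= row[t + 1]:
                crossing = t
                break
        if crossing is None:        # starts above 0.5 and only decreases
            out_difficulty[j] = theta[0]
            out_flag[j] = True
            continue
        p0, p1 = row[crossing], row[crossing + 1]
        frac = (0.5 - p0) / (p1 - p0)
        out_difficulty[j] = theta[crossing] + frac * (theta[crossing + 1] - theta[crossing])
    return pd.DataFrame({"difficulty": out_difficulty, "extrapolated": out_flag},
                        index=pd.Index(reconstructed.items, name="item"))


def attribute_curve_summary(fit: LSDM, eps: float | None = None) -> AttributeSummary:
    """Logistic fits to the recovered attribute characteristic curves.

    For each component, ``logit(P(A_k|theta))`` is regressed on theta over
    grid points where the probability is inside ``(eps, 1 - eps)``; the slope
    is the component discrimination and ``-intercept/slope`` its difficulty.
    Components whose fitted difficulty falls outside the grid are flagged
    ``extrapolated``; components with fewer than 3 usable grid points are
    flagged ``unfit``.
    """
    if eps is None:
        eps = max(fit.eps, 1e-6)
    theta = fit.grid_.points
    rows = []
    for k, comp in enumerate(fit.components_):
        p = np.exp(fit.attribute_logprobs_[k])
        usable = (p > eps) & (p < 1 - eps)
        if usable.sum() < 3:
            rows.append({"difficulty": np.nan, "discrimination": np.nan,
                         "r2": np.nan, "extrapolated": True, "unfit": True})
            continue
        y = logit(p[usable])
        x = theta[usable]
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        if abs(slope) < 1e-12:
            difficulty = np.nan
            extrapolated = True
        else:
            difficulty = -intercept / slope
            extrapolated = not (theta[0] <= difficulty <= theta[-1])
        rows.append({"difficulty": difficulty, "discrimination": slope, "r2": r2,
                     "extrapolated": extrapolated, "unfit": False})
    table = pd.DataFrame(rows, index=pd.Index(fit.components_, name="component"))
    table["difficulty_centered"] = table["difficulty"] - table["difficulty"].mean()
    return AttributeSummary(table=table)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def solve_attribute_logprobs(source: ICCTable, q: QMatrix,
                             constrained: bool = True, eps: float = PROB_EPS) -> LSDM:
    return LSDM(constrained=constrained, eps=eps).fit(source, q)


def reconstruct_iccs(fit: LSDM, q: QMatrix) -> ICCTable:
    return fit.reconstruct(q)
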