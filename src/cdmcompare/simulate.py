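"""Synthetic response-data generators.

The raw responses behind the reference study are not publicly deposited, so
every downstream stage here is exercised on simulated data that emulates the
study's structure: ~600 examinees per sample with abilities drawn from a
standard normal, 18-26 binary rule-based items whose difficulties are either
additive combinations of nine component parameters (the additive / LLTM-true
world), conjunctive products of component success curves (the multiplicative
/ LSDM-true world), or a plain two-parameter logistic model.

Each generator derives two independent substreams from its single seed: one
for person abilities and one for response noise, so the truth-block abilities
are reusable and regenerating from ``(seed, parameters)`` reproduces the
identical score grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit

from .containers import ResponseMatrix
from .taxonomy import DEFAULT_TAXONOMY, ComponentTaxonomy, QMatrix

__all__ = [
    "AttributeCurveParams",
    "SimulatedDataset",
    "make_taxonomy_qmatrix",
    "simulate_additive",
    "simulate_conjunctive",
    "simulate_2pl",
    "DEFAULT_ETA",
    "DEFAULT_CURVES",
]

#: Default additive component difficulties (logit units) for the nine default
#: taxonomy components, in taxonomy order ADD, ANE, COM, CQ, SS, DP, VOS, MR,
#: DRA.  These are the published mean-centered LLTM base-parameter estimates
#: for the taxonomy, i.e. the empirically realistic additive world.
DEFAULT_ETA = np.array([-0.366, -0.218, -0.395, 0.407, 0.187, 1.109, -0.135, -0.314, -0.101])


@dataclass
class AttributeCurveParams:
    """Logistic mastery curves P(A_k = 1 | theta) per component.

    ``pinned`` entries (non-NaN) fix a component's curve at a constant
    probability, which covers the zero-discrimination limit cleanly.
    """

    difficulty: np.ndarray
    discrimination: np.ndarray
    pinned: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.difficulty = np.asarray(self.difficulty, float)
        self.discrimination = np.asarray(self.discrimination, float)
        if self.difficulty.shape != self.discrimination.shape:
            raise ValueError("difficulty and discrimination must have equal length")
        if self.pinned is None:
            self.pinned = np.full_like(self.difficulty, np.nan)
        else:
            self.pinned = np.asarray(self.pinned, float)
            if self.pinned.shape != self.difficulty.shape:
                raise ValueError("pinned must match component count")
        free = np.isnan(self.pinned)
        if np.any(self.discrimination[free] <= 0):
            raise ValueError("discrimination must be > 0 for non-pinned components")

    def __len__(self) -> int:
        return len(self.difficulty)

    def probs(self, theta: np.ndarray) -> np.ndarray:
        """Components x theta matrix of mastery probabilities."""
        theta = np.asarray(theta, float)
        p = expit(self.discrimination[:, None] * (theta[None, :] - self.difficulty[:, None]))
        fixed = ~np.isnan(self.pinned)
        if fixed.any():
            p[fixed, :] = self.pinned[fixed, None]
        return p


#: Default conjunctive world: steep mastery curves (discrimination 3) with
#: component difficulties spread across the ability range.  The multiplicative
#: hypothesis treats each component as an all-or-nothing gate -- failing any
#: one makes the item unsolvable -- which corresponds to sharply rising
#: mastery curves.  Shallow curves would make ``ln P`` nearly linear in theta
#: and the conjunctive world empirically indistinguishable from the additive
#: one.
DEFAULT_CURVES = AttributeCurveParams(
    difficulty=np.linspace(-2.5, 1.0, len(DEFAULT_TAXONOMY)),
    discrimination=np.full(len(DEFAULT_TAXONOMY), 3.0),
)


@dataclass
class SimulatedDataset:
    """A simulated response matrix together with its generating truth."""

    responses: ResponseMatrix
    q: QMatrix | None
    truth: dict[str, Any] = field(repr=False)
    seed: int = 0

    @property
    def model(self) -> str:
        return self.truth["model"]


def _substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent (ability, response) generators derived from one seed."""
    ss = np.random.SeedSequence(seed)
    ability_ss, response_ss = ss.spawn(2)
    return np.random.default_rng(ability_ss), np.random.default_rng(response_ss)


def _draw_responses(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(prob.shape) < prob).astype(np.int8)


def _response_matrix(scores: np.ndarray, items: list[str]) -> ResponseMatrix:
    persons = [f"p{i + 1}" for i in range(scores.shape[0])]
    return ResponseMatrix(persons=persons, items=items, scores=scores)


def make_taxonomy_qmatrix(
    n_items: int,
    taxonomy: ComponentTaxonomy = DEFAULT_TAXONOMY,
    max_weight: int = 2,
    rng_seed: int = 0,
    diagonal_augmented: bool = False,
    max_retries: int = 200,
) -> QMatrix:
    """Draw a random full-column-rank Q-matrix emulating the study design.

    Each item receives one or two change rules and one or two design
    principles, with integer weights in ``[1, max_weight]``; all other cells
    are zero.  With ``diagonal_augmented`` the first ``K`` items are
    single-component (identity-like) rows, guaranteeing full column rank.

    Raises
    ------
    ValueError
        If ``n_items`` is smaller than the component count, or no
        full-column-rank draw is found within ``max_retries`` attempts.
    """
    n_comp = len(taxonomy)
    if n_items < n_comp:
        raise ValueError(
            f"n_items={n_items} < {n_comp} components: full column rank impossible"
        )
    if max_weight < 1:
        raise ValueError("max_weight must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rules = [taxonomy.component_ids.index(c) for c in taxonomy.change_rules]
    principles = [taxonomy.component_ids.index(c) for c in taxonomy.design_principles]

    last: QMatrix | None = None
    for _ in range(max_retries):
        w = np.zeros((n_items, n_comp), dtype=int)
        start = 0
        if diagonal_augmented:
            for k in range(n_comp):
                w[k, k] = 1
            start = n_comp
        for j in range(start, n_items):
            chosen: list[int] = []
            if rules:
                chosen += list(rng.choice(rules, size=rng.integers(1, min(2, len(rules)) + 1),
                                          replace=False))
            if principles:
                chosen += list(rng.choice(principles,
                                          size=rng.integers(1, min(2, len(principles)) + 1),
                                          replace=False))
            if not chosen:  # degenerate taxonomy: pick any component
                chosen = [int(rng.integers(n_comp))]
            for k in chosen:
                w[j, k] = int(rng.integers(1, max_weight + 1))
        q = QMatrix(items=[f"i{j + 1}" for j in range(n_items)], taxonomy=taxonomy, weights=w)
        if q.full_column_rank:
            return q
        last = q
    dep = last.dependent_columns() if last is not None else []
    raise ValueError(
        f"no full-column-rank Q-matrix found in {max_retries} draws; "
        f"dependent columns in last draw: {dep}"
    )


def simulate_additive(
    q: QMatrix,
    eta: np.ndarray = DEFAULT_ETA,
    c: float = 0.0,
    n_persons: int = 600,
    rng_seed: int = 0,
) -> SimulatedDataset:
    """Simulate responses with additively composed item difficulties.

    Item difficulty is ``sigma_j = sum_k q_jk * eta_k + c``; a person with
    ability ``theta ~ N(0, 1)`` solves item ``j`` with probability
    ``logistic(theta - sigma_j)``.
    """
    eta = np.asarray(eta, float)
    if eta.shape != (len(q.taxonomy),):
        raise ValueError(f"eta length {eta.size} != {len(q.taxonomy)} components")
    if n_persons < 2:
        raise ValueError("n_persons must be >= 2")
    sigma = q.weights @ eta + c
    ability_rng, response_rng = _substreams(rng_seed)
    theta = ability_rng.standard_normal(n_persons)
    prob = expit(theta[:, None] - sigma[None, :])
    scores = _draw_responses(prob, response_rng)
    truth = {
        "model": "additive",
        "eta": eta.copy(),
        "c": float(c),
        "sigma": sigma,
        "theta": theta,
    }
    return SimulatedDataset(responses=_response_matrix(scores, list(q.items)),
                            q=q, truth=truth, seed=rng_seed)


def simulate_conjunctive(
    q: QMatrix,
    curves: AttributeCurveParams = DEFAULT_CURVES,
    n_persons: int = 600,
    rng_seed: int = 0,
) -> SimulatedDataset:
    """Simulate responses under the conjunctive (multiplicative) world.

    Solving item ``j`` requires every component it involves:
    ``P_ij = prod_k P(A_k=1 | theta_i) ** q_jk``.
    """
    if len(curves) != len(q.taxonomy):
        raise ValueError(f"curves cover {len(curves)} components, Q has {len(q.taxonomy)}")
    if n_persons < 2:
        raise ValueError("n_persons must be >= 2")
    ability_rng, response_rng = _substreams(rng_seed)
    theta = ability_rng.standard_normal(n_persons)
    comp_probs = curves.probs(theta)                       # K x N
    log_p = q.weights @ np.log(comp_probs)                 # J x N
    prob = np.exp(log_p).T                                 # N x J
    scores = _draw_responses(prob, response_rng)
    truth = {
        "model": "conjunctive",
        "curves": curves,
        "theta": theta,
    }
    return SimulatedDataset(responses=_response_matrix(scores, list(q.items)),
                            q=q, truth=truth, seed=rng_seed)


def simulate_2pl(
    a: np.ndarray,
    b: np.ndarray,
    n_persons: int = 600,
    rng_seed: int = 0,
    item_ids: list[str] | None = None,
) -> SimulatedDataset:
    """Simulate two-parameter logistic responses: ``P = logistic(a_j (theta - b_j))``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"slope vector length {a.size} != difficulty vector length {b.size}")
    if np.any(a <= 0):
        raise ValueError("all slopes must be > 0")
    if n_persons < 2:
        raise ValueError("n_persons must be >= 2")
    ability_rng, response_rng = _substreams(rng_seed)
    theta = ability_rng.standard_normal(n_persons)
    prob = expit(a[None, :] * (theta[:, None] - b[None, :]))
    scores = _draw_responses(prob, response_rng)
    items = item_ids if item_ids is not None else [f"i{j + 1}" for j in range(a.size)]
    truth = {"model": "twopl", "a": a.copy(), "b": b.copy(), "theta": theta}
    return SimulatedDataset(responses=_response_matrix(scores, items), q=None,
                            truth=truth, seed=rng_seed)
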