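"""Response-matrix, ability-grid and ICC-table containers shared by all models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import expit

__all__ = ["ResponseMatrix", "ThetaGrid", "ICCTable", "PROVENANCES"]

PROVENANCES = ("rasch", "twopl", "lltm", "lsdm-reconstructed")


@dataclass
class ResponseMatrix:
    """Persons x items binary score matrix (complete data).

    Missing values are handled at the I/O boundary (rejected, or removed by
    listwise deletion); the in-memory container is always complete.
    """

    persons: list[str]
    items: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (len(self.persons), len(self.items)):
            raise ValueError(
                f"scores shape {s.shape} != {len(self.persons)} persons x {len(self.items)} items"
            )
        if len(set(self.persons)) != len(self.persons):
            raise ValueError("person ids must be unique")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item ids must be unique")
        if not np.isin(s, (0, 1)).all():
            raise ValueError("scores must be 0 or 1")
        self.scores = s.astype(np.int8)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def raw_scores(self) -> np.ndarray:
        return self.scores.sum(axis=1)

    @property
    def item_totals(self) -> np.ndarray:
        return self.scores.sum(axis=0)

    def subset_items(self, items: list[str]) -> "ResponseMatrix":
        idx = [self.items.index(i) for i in items]
        return ResponseMatrix(persons=list(self.persons), items=list(items),
                              scores=self.scores[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=pd.Index(self.persons, name="person"),
                            columns=list(self.items))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResponseMatrix":
        return cls(persons=[str(p) for p in frame.index],
                   items=[str(i) for i in frame.columns],
                   scores=frame.to_numpy())


@dataclass(frozen=True)
class ThetaGrid:
    """Ordered ability evaluation points (logit units)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("grid must be a non-empty 1-d array")
        if not np.all(np.diff(p) > 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", p)

    @classmethod
    def make(cls, lo: float = -4.0, hi: float = 4.0, count: int = 61) -> "ThetaGrid":
        if count < 2:
            raise ValueError("grid needs at least 2 points")
        return cls(np.linspace(lo, hi, count))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ICCTable:
    """Items x grid-points matrix of model solution probabilities."""

    items: list[str]
    grid: ThetaGrid
    probs: np.ndarray = field(repr=False)
    provenance: str = "rasch"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.items), len(self.grid)):
            raise ValueError(f"probs shape {p.shape} != items x grid points")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("ICC probabilities must lie strictly in (0, 1)")
        self.probs = p

    def subset_items(self, items: list[str]) -> "ICCTable":
        idx = [self.items.index(i) for i in items]
        return ICCTable(items=list(items), grid=self.grid, probs=self.probs[idx],
                        provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=pd.Index(self.items, name="item"),
                            columns=self.grid.points)


def logistic_icc(theta: np.ndarray, difficulty: np.ndarray,
                 discrimination: np.ndarray | float = 1.0) -> np.ndarray:
    """Item response surface ``logistic(a_j * (theta - b_j))`` as items x theta."""
    theta = np.asarray(theta, float)
    b = np.atleast_1d(np.asarray(difficulty, float))
    a = np.broadcast_to(np.asarray(discrimination, float), b.shape)
    return expit(a[:, None] * (theta[None, :] - b[:, None]))
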