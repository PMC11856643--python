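"""Component taxonomy and Q-matrix containers.

A *component taxonomy* lists the elementary demands (change rules and design
principles) that rule-based items are constructed from.  The *Q-matrix* maps
that taxonomy onto a set of items: entry ``q[j, k]`` is a non-negative integer
giving how strongly (or how often) component ``k`` is involved in item ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComponentTaxonomy",
    "QMatrix",
    "DEFAULT_TAXONOMY",
    "CHANGE_RULE",
    "DESIGN_PRINCIPLE",
]

CHANGE_RULE = "change_rule"
DESIGN_PRINCIPLE = "design_principle"


@dataclass(frozen=True)
class ComponentTaxonomy:
    """Ordered list of item components with their kind.

    Parameters
    ----------
    component_ids : tuple of str
        Short labels, e.g. ``("ADD", "ANE", ...)``.  The order is canonical:
        every Q-matrix built from this taxonomy uses it as column order.
    kinds : tuple of str
        One of ``"change_rule"`` / ``"design_principle"`` per component.
    """

    component_ids: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.component_ids) != len(self.kinds):
            raise ValueError("component_ids and kinds must have equal length")
        if len(set(self.component_ids)) != len(self.component_ids):
            raise ValueError("component ids must be unique")
        bad = set(self.kinds) - {CHANGE_RULE, DESIGN_PRINCIPLE}
        if bad:
            raise ValueError(f"unknown component kinds: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.component_ids)

    @property
    def change_rules(self) -> tuple[str, ...]:
        return tuple(c for c, k in zip(self.component_ids, self.kinds) if k == CHANGE_RULE)

    @property
    def design_principles(self) -> tuple[str, ...]:
        return tuple(c for c, k in zip(self.component_ids, self.kinds) if k == DESIGN_PRINCIPLE)

    def kind_of(self, component_id: str) -> str:
        return self.kinds[self.component_ids.index(component_id)]


#: The nine-component taxonomy for difficult figural matrices: five change
#: rules (addition; addition with null element; completeness; cutting
#: quantities; successive sequences) and four design principles (drawing
#: principles; variation of open shapes; multiple relations; direction of
#: rule application).
DEFAULT_TAXONOMY = ComponentTaxonomy(
    component_ids=("ADD", "ANE", "COM", "CQ", "SS", "DP", "VOS", "MR", "DRA"),
    kinds=(
        CHANGE_RULE,
        CHANGE_RULE,
        CHANGE_RULE,
        CHANGE_RULE,
        CHANGE_RULE,
        DESIGN_PRINCIPLE,
        DESIGN_PRINCIPLE,
        DESIGN_PRINCIPLE,
        DESIGN_PRINCIPLE,
    ),
)


@dataclass
class QMatrix:
    """Items x components weight matrix with non-negative integer entries."""

    items: list[str]
    taxonomy: ComponentTaxonomy
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape != (len(self.items), len(self.taxonomy)):
            raise ValueError(
                f"weights shape {w.shape} does not match "
                f"{len(self.items)} items x {len(self.taxonomy)} components"
            )
        if len(set(self.items)) != len(self.items):
            raise ValueError("item ids must be unique")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0) or np.any(w != np.round(w)):
            raise ValueError("weights must be non-negative integers")
        self.weights = w.astype(int)
        zero_rows = [self.items[j] for j in np.flatnonzero(self.weights.sum(axis=1) == 0)]
        if zero_rows:
            raise ValueError(f"items with all-zero Q rows: {zero_rows}")

    @property
    def components(self) -> tuple[str, ...]:
        return self.taxonomy.component_ids

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.weights))

    @property
    def full_column_rank(self) -> bool:
        return self.rank == len(self.taxonomy)

    def dependent_columns(self) -> list[str]:
        """Components whose columns are linearly dependent on the others.

        Identified greedily: a column is flagged when adding it to the span of
        the previously kept columns does not increase matrix rank.
        """
        kept: list[int] = []
        flagged: list[str] = []
        for k in range(self.weights.shape[1]):
            cand = self.weights[:, kept + [k]]
            if np.linalg.matrix_rank(cand) > len(kept):
                kept.append(k)
            else:
                flagged.append(self.components[k])
        return flagged

    def subset(self, items: list[str]) -> "QMatrix":
        idx = [self.items.index(i) for i in items]
        return QMatrix(items=list(items), taxonomy=self.taxonomy, weights=self.weights[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=pd.Index(self.items, name="item"),
                            columns=list(self.components))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, taxonomy: ComponentTaxonomy) -> "QMatrix":
        unknown = set(frame.columns) - set(taxonomy.component_ids)
        if unknown:
            raise ValueError(f"unknown component columns: {sorted(unknown)}")
        missing = set(taxonomy.component_ids) - set(frame.columns)
        if missing:
            raise ValueError(f"missing component columns: {sorted(missing)}")
        frame = frame.loc[:, list(taxonomy.component_ids)]  # canonical order
        return cls(items=[str(i) for i in frame.index], taxonomy=taxonomy,
                   weights=frame.to_numpy())
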