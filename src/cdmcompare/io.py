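"""CSV / JSON readers and writers for the package's data objects.

Dialect: comma-separated UTF-8 with a mandatory header row; ``NA`` is the
only recognized missing token in response files and is rejected unless
listwise deletion is enabled.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ICCTable, ResponseMatrix
from .simulate import AttributeCurveParams, SimulatedDataset
from .taxonomy import ComponentTaxonomy, QMatrix

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_qmatrix",
    "write_qmatrix",
    "write_truth",
    "read_truth",
    "write_icc_table",
]

log = logging.getLogger("cdmcompare")


def write_response_matrix(responses: ResponseMatrix, path: str | Path) -> None:
    responses.to_frame().to_csv(path)


def read_response_matrix(path: str | Path, listwise_deletion: bool = False) -> ResponseMatrix:
    """Read a persons x items CSV (first column person id, cells 0/1/NA).

    ``NA`` cells are rejected unless ``listwise_deletion`` is set, in which
    case affected persons are dropped and the count is logged.
    """
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicate person ids: {dupes}")
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].tolist()
        raise ValueError(f"duplicate item ids: {dupes}")
    valid = {"0", "1", "NA"}
    values = frame.to_numpy()
    bad = np.argwhere(~np.isin(values, list(valid)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-binary cell {values[r, c]!r} at person {frame.index[r]!r}, "
            f"item {frame.columns[c]!r}")
    has_na = values == "NA"
    if has_na.any():
        if not listwise_deletion:
            r, c = np.argwhere(has_na)[0]
            raise ValueError(
                f"missing value at person {frame.index[r]!r}, item {frame.columns[c]!r}; "
                "enable listwise_deletion to drop affected persons")
        keep = ~has_na.any(axis=1)
        log.info("listwise deletion: dropped %d of %d persons with missing responses",
                 int((~keep).sum()), len(frame))
        frame = frame.loc[keep]
    return ResponseMatrix.from_frame(frame.astype(int))


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    q.to_frame().to_csv(path)


def read_qmatrix(path: str | Path, taxonomy: ComponentTaxonomy) -> QMatrix:
    """Read an items x components CSV against a taxonomy.

    Columns permuted relative to the taxonomy are reordered canonically (and
    logged); unknown or missing columns, negative, or non-integer weights are
    errors.
    """
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    if list(frame.columns) != list(taxonomy.component_ids) and \
            set(frame.columns) == set(taxonomy.component_ids):
        log.info("Q-matrix columns reordered to canonical taxonomy order")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric Q-matrix entries: {exc}") from exc
    if np.any(values < 0) or np.any(values != np.round(values)):
        raise ValueError("Q-matrix weights must be non-negative integers")
    q = QMatrix.from_frame(frame, taxonomy)
    log.info("Q-matrix %d items x %d components, rank %d (full column rank: %s)",
             q.n_items, len(q.taxonomy), q.rank, q.full_column_rank)
    return q


def write_icc_table(table: ICCTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.columns = [f"{t:.6g}" for t in table.grid.points]
    frame.to_csv(path)


def write_truth(dataset: SimulatedDataset, path: str | Path) -> None:
    """Serialize a simulated dataset's generating truth as flat JSON."""
    truth = dataset.truth
    payload: dict = {"model": truth["model"], "seed": dataset.seed,
                     "theta": np.asarray(truth["theta"]).tolist()}
    if truth["model"] == "additive":
        payload.update(eta=truth["eta"].tolist(), c=truth["c"],
                       sigma=truth["sigma"].tolist())
    elif truth["model"] == "conjunctive":
        curves: AttributeCurveParams = truth["curves"]
        payload.update(curve_difficulty=curves.difficulty.tolist(),
                       curve_discrimination=curves.discrimination.tolist(),
                       curve_pinned=[None if np.isnan(v) else v for v in curves.pinned])
    elif truth["model"] == "twopl":
        payload.update(a=truth["a"].tolist(), b=truth["b"].tolist())
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
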