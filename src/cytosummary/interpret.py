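"""Per-cell relevance scoring for the trained aggregator.

Two complementary scores are computed for every cell and combined:

* sensitivity analysis (SA) — the feature-summed absolute partial derivatives
  of the contrastive loss with respect to that cell's input values,
  R_m = sum_d |dL/dx_{m,d}|, obtained by backpropagating the loss through the
  network at a loss-bearing batch;
* critical-point analysis (CPA) — the L1 norm of the cell's first
  fully-connected-layer activations, measuring how much the cell contributes
  to the sum-pooled representation.

Both are min-max normalized per well, added, and the sum min-max normalized
again; cells above 0.8 / below 0.2 (strict) are flagged most/least relevant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSet, SingleCellTable
from .model import AggregatorModel, backward_view, forward
from .training import _supcon_core

__all__ = [
    "sensitivity_relevance",
    "cpa_relevance",
    "combined_relevance",
    "flag_cells",
    "correlate_features",
    "score_cells",
]


def sensitivity_relevance(
    model: AggregatorModel,
    batch: list[tuple[SampleSet, str]],
    temperature: float = 0.1,
    variant: str = "supcon_standard",
) -> list[np.ndarray]:
    """SA relevance for every view in a loss-bearing batch.

    ``batch`` pairs each view with its compound label; the SupCon loss over
    the batch is backpropagated to the inputs, and each cell's score is the
    L1 norm of its input gradient. Returns one score vector per view, in
    batch order.
    """
    if not batch:
        raise ValueError("empty batch")
    states = [forward(model, s, keep_state=True) for s, _ in batch]
    V = np.vstack([st.v for st in states])
    labels = np.array([lab for _, lab in batch])
    _, dV = _supcon_core(V, labels, temperature, variant)
    scores = []
    for st, dv in zip(states, dV):
        _, dX = backward_view(model, st, dv)
        scores.append(np.abs(dX).sum(axis=1))
    return scores


def cpa_relevance(
    model: AggregatorModel, X: SampleSet | np.ndarray, post_activation: bool = True
) -> np.ndarray:
    """CPA relevance: per-cell L1 norm of first-layer activations.

    ``post_activation`` (default) uses the values after the leaky ReLU; set it
    False for the raw affine outputs.
    """
    st = forward(model, X, keep_state=True)
    act = st.H1 if post_activation else st.A1
    return np.abs(act).sum(axis=1)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:  # degenerate (constant or single cell) -> zeros, not errors
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def combined_relevance(sa: np.ndarray, cpa: np.ndarray) -> np.ndarray:
    """Min-max both scores within the well, add, min-max the sum again."""
    sa = np.asarray(sa, dtype=np.float64)
    cpa = np.asarray(cpa, dtype=np.float64)
    if sa.shape != cpa.shape:
        raise ValueError("SA and CPA scores cover different cell sets")
    return _minmax(_minmax(sa) + _minmax(cpa))


def flag_cells(relevance: pd.DataFrame, hi: float = 0.8, lo: float = 0.2) -> pd.DataFrame:
    """Label cells by combined relevance: > hi most_relevant, < lo least_relevant."""
    out = relevance.copy()
    score = out["combined_score"].to_numpy()
    flags = np.where(score > hi, "most_relevant",
                     np.where(score < lo, "least_relevant", "neutral"))
    out["flag"] = flags
    return out


def correlate_features(
    relevance: pd.DataFrame, table: SingleCellTable
) -> pd.DataFrame:
    """Pearson r between each input feature and the combined relevance score.

    Rows are aligned by position: the relevance table must score exactly the
    cells of ``table`` in order. Zero-variance features get r = NaN
    (undefined), and the output is sorted by |r| descending.
    """
    if len(relevance) != table.n_cells:
        raise ValueError("relevance rows do not match table cells")
    if table.n_cells < 3:
        raise ValueError("need at least 3 cells for correlation")
    score = relevance["combined_score"].to_numpy()
    rows = []
    for j, name in enumerate(table.features):
        x = table.X[:, j]
        if np.std(x) == 0 or np.std(score) == 0:
            r = np.nan
        else:
            r = stats.pearsonr(x, score).statistic
        rows.append({"feature": name, "pearson_r": r})
    out = pd.DataFrame(rows)
    return out.reindex(
        out["pearson_r"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)


def score_cells(
    model: AggregatorModel,
    table: SingleCellTable,
    temperature: float = 0.1,
    variant: str = "supcon_standard",
) -> pd.DataFrame:
    """Relevance table for every cell of every well.

    The loss-bearing batch is assembled from the full wells of the table
    (labels = compound IDs, no cell sampling), mirroring a training batch at
    inference time. Requires every compound to have >= 2 wells.
    """
    views = [(s, s.well_key.compound_id) for s in table.iter_wells()]
    if len(views) < 4:
        raise ValueError("need at least 4 wells to form a loss-bearing batch")
    sa_all = sensitivity_relevance(model, views, temperature, variant)
    rows = []
    for (s, _), sa in zip(views, sa_all):
        cpa = cpa_relevance(model, s)
        comb = combined_relevance(sa, cpa)
        for m in range(s.n_cells):
            rows.append(
                {
                    "plate_id": s.well_key.plate_id,
                    "well_id": s.well_key.well_id,
                    "compound_id": s.well_key.compound_id,
                    "cell_index": m,
                    "sa_score": sa[m],
                    "cpa_score": cpa[m],
                    "combined_score": comb[m],
                }
            )
    return flag_cells(pd.DataFrame(rows))
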