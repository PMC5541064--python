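"""DTN-T construction and Enrichment Ratio analysis.

The drug-therapeutic-property network DTN-T holds each drug's repositioning
probabilities toward the 14 ATC properties, with the drug's *known* labels
zeroed (a drug cannot be "repositioned" to a property it already has). The
Enrichment Ratio between properties X and Y,

    ER_{X,Y} = (a / b) / (c / d),

measures how over-represented X-labelled drugs are among those whose pruned
DTN-T carries an edge into Y: a = X-labelled drugs with an edge to Y,
b = all drugs with an edge to Y, c = X-labelled drugs with any edge,
d = all drugs with any edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_dtn_t",
    "prune_dtn",
    "enrichment_ratio",
    "ERMatrix",
    "er_matrix",
    "er_threshold_stability",
    "combined_er",
    "top_er_pairs",
]


def build_dtn_t(
    probability_matrix: pd.DataFrame, labels: dict[str, set[str]]
) -> pd.DataFrame:
    """Zero each drug's known-label probabilities; everything else is kept."""
    out = probability_matrix.copy().astype(float)
    for drug in out.index:
        if drug not in labels or not labels[drug]:
            raise ValueError(f"drug {drug!r} has no labels")
        for c in labels[drug]:
            if c in out.columns:
                out.loc[drug, c] = 0.0
    return out


def prune_dtn(dtnt: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Binary edge matrix: edge iff probability >= threshold (closed rule)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return pd.DataFrame(
        (dtnt.to_numpy() >= threshold).astype(int), index=dtnt.index, columns=dtnt.columns
    )


def enrichment_ratio(
    edges: pd.DataFrame, labels: dict[str, set[str]], x: str, y: str
) -> tuple[float, tuple[int, int, int, int]]:
    """ER_{x,y} with its audit counts (a, b, c, d).

    A zero denominator (b = 0 or c = 0) yields ER = 0; callers needing the
    distinction inspect the counts.
    """
    if x == y:
        raise ValueError("ER is undefined on the diagonal (known labels are zeroed)")
    has_x = edges.index.to_series().map(lambda d: x in labels[d]).to_numpy(bool)
    edge_to_y = edges[y].to_numpy() > 0
    any_edge = edges.to_numpy().sum(axis=1) > 0
    a = int(np.sum(has_x & edge_to_y))
    b = int(np.sum(edge_to_y))
    c = int(np.sum(has_x & any_edge))
    d = int(np.sum(any_edge))
    if b == 0 or c == 0 or d == 0:
        return 0.0, (a, b, c, d)
    return (a / b) / (c / d), (a, b, c, d)


@dataclass
class ERMatrix:
    """q x q Enrichment Ratio matrix at one pruning threshold.

    The diagonal is structurally missing (NaN). ``counts`` retains the
    (a, b, c, d) quadruple per ordered pair; ``flagged`` lists the cells
    whose ER was set to 0 by a zero denominator.
    """

    er: pd.DataFrame
    threshold: float | None
    counts: dict[tuple[str, str], tuple[int, int, int, int]] = field(default_factory=dict)
    flagged: set[tuple[str, str]] = field(default_factory=set)


def er_matrix(edges: pd.DataFrame, labels: dict[str, set[str]], threshold: float | None = None) -> ERMatrix:
    """All ordered-pair enrichment ratios for one pruned edge matrix."""
    classes = list(edges.columns)
    er = pd.DataFrame(np.nan, index=classes, columns=classes)
    counts: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    flagged: set[tuple[str, str]] = set()
    for x in classes:
        for y in classes:
            if x == y:
                continue
            val, quad = enrichment_ratio(edges, labels, x, y)
            er.loc[x, y] = val
            counts[(x, y)] = quad
            if quad[1] == 0 or quad[2] == 0 or quad[3] == 0:
                flagged.add((x, y))
    return ERMatrix(er=er, threshold=threshold, counts=counts, flagged=flagged)


def _offdiag_vector(er: pd.DataFrame) -> np.ndarray:
    """Off-diagonal cells flattened in a fixed (row-major) order."""
    mask = ~np.eye(len(er), dtype=bool)
    return er.to_numpy()[mask]


def er_threshold_stability(
    dtnt: pd.DataFrame,
    labels: dict[str, set[str]],
    threshold_grid: tuple[float, ...],
) -> pd.DataFrame:
    """Pearson correlation between ER matrices across pruning thresholds.

    For each threshold pair the correlation is taken over the vectorised
    off-diagonal cells finite in both matrices; fewer than 3 shared finite
    cells, or a constant vector, leaves the entry missing.
    """
    if len(threshold_grid) < 2:
        raise ValueError("need at least 2 thresholds")
    vecs = {}
    for t in threshold_grid:
        em = er_matrix(prune_dtn(dtnt, t), labels, threshold=t)
        vecs[t] = _offdiag_vector(em.er)
    out = pd.DataFrame(np.nan, index=list(threshold_grid), columns=list(threshold_grid))
    for t1 in threshold_grid:
        for t2 in threshold_grid:
            v1, v2 = vecs[t1], vecs[t2]
            ok = np.isfinite(v1) & np.isfinite(v2)
            if ok.sum() < 3:
                continue
            a, b = v1[ok], v2[ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                out.loc[t1, t2] = 1.0 if t1 == t2 else np.nan
                continue
            out.loc[t1, t2] = stats.pearsonr(a, b)[0]
    return out


def combined_er(
    dtnt: pd.DataFrame,
    labels: dict[str, set[str]],
    top_thresholds: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95),
) -> ERMatrix:
    """Cellwise mean of the ER matrices at the highest pruning thresholds.

    Missing (diagonal) cells stay missing; a cell missing at some
    thresholds averages over the thresholds where it is finite.
    """
    mats = [er_matrix(prune_dtn(dtnt, t), labels, threshold=t) for t in top_thresholds]
    stack = np.stack([m.er.to_numpy() for m in mats])
    with warnings.catch_warnings():
        # the diagonal is all-NaN by construction; nanmean keeps it NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    er = pd.DataFrame(mean, index=mats[0].er.index, columns=mats[0].er.columns)
    flagged = set().union(*(m.flagged for m in mats))
    return ERMatrix(er=er, threshold=None, counts={}, flagged=flagged)


def top_er_pairs(er: pd.DataFrame, k: int) -> list[tuple[str, str, float]]:
    """The k largest finite ER cells, descending; ties break lexicographically
    on (X, Y)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = [
        (x, y, float(er.loc[x, y]))
        for x in er.index
        for y in er.columns
        if x != y and np.isfinite(er.loc[x, y])
    ]
    cells.sort(key=lambda t: (-t[2], t[0], t[1]))
    return cells[:k]
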