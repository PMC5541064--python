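"""Side-effect and structure similarity networks and their ATC projections.

Drugs are compared by their side-effect term sets (Jaccard coefficient) or
fingerprint bit sets (Tanimoto coefficient); both metrics take two empty
sets as perfectly similar (coefficient 1). Projecting the similarity
network onto the 14 overlapping ATC communities via node-to-community
coefficients gives each drug a 14-dimensional profile (DTN-SE / DTN-ST)
comparable with its DTN-T row by per-drug Spearman correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "jaccard",
    "tanimoto",
    "similarity_network",
    "atc_communities",
    "node_to_community",
    "cross_network_spearman",
]


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; two empty sets are maximally similar (1)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def tanimoto(a: set, b: set) -> float:
    """|A n B| / (|A| + |B| - |A n B|); empty-vs-empty is 1 for consistency
    with the Jaccard convention. On sets this coincides with Jaccard."""
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


_METRICS = {"jaccard": jaccard, "tanimoto": tanimoto}


def similarity_network(feature_sets: dict[str, set], metric: str = "jaccard") -> pd.DataFrame:
    """Symmetric drugs x drugs similarity matrix with unit diagonal."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    fn = _METRICS[metric]
    drugs = list(feature_sets)
    n = len(drugs)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = fn(feature_sets[drugs[i]], feature_sets[drugs[j]])
    return pd.DataFrame(sim, index=drugs, columns=drugs)


def atc_communities(labels: dict[str, set[str]], classes: list[str]) -> dict[str, set[str]]:
    """ATC letter -> drug community; multi-label drugs join every community
    of their labels, so communities overlap."""
    return {c: {d for d, ls in labels.items() if c in ls} for c in classes}


def node_to_community(
    similarity: pd.DataFrame, partition: dict[str, set[str]]
) -> pd.DataFrame:
    """Drugs x communities node-to-community coefficient matrix.

    The coefficient of drug d toward community C is the mean similarity of
    d to the members of C excluding d itself; a community with no other
    members contributes 0.
    """
    drugs = list(similarity.index)
    classes = list(partition)
    out = pd.DataFrame(0.0, index=drugs, columns=classes)
    for c in classes:
        members = [m for m in partition[c] if m in similarity.index]
        for d in drugs:
            others = [m for m in members if m != d]
            if others:
                out.loc[d, c] = float(similarity.loc[d, others].mean())
    out.index.name = "drug"
    return out


def cross_network_spearman(
    dtn_t: pd.DataFrame, projection: pd.DataFrame
) -> pd.Series:
    """Per-drug Spearman rho between the drug's DTN-T row and its
    node-to-community projection row (average ranks for ties).

    Drugs present in both frames are compared over their shared property
    columns; a zero-variance vector leaves that drug's rho missing.
    """
    shared = [d for d in dtn_t.index if d in projection.index]
    cols = [c for c in dtn_t.columns if c in projection.columns]
    rhos = pd.Series(np.nan, index=shared, name="rho")
    for d in shared:
        u = dtn_t.loc[d, cols].to_numpy(float)
        v = projection.loc[d, cols].to_numpy(float)
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            continue
        rhos[d] = stats.spearmanr(u, v)[0]
    rhos.index.name = "drug"
    return rhos
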