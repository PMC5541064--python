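"""Collapse replicate perturbation trials into per-drug credible sets.

For each drug, trials are k-means clustered, the cluster with the highest
mean intra-cluster Pearson correlation is kept as the representative group
S1, the mean over *all* trials is appended as one extra sample S2, and the
credible set S = S1 + S2 becomes the drug's training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .gctio import ExpressionTable

__all__ = [
    "CredibleSet",
    "trial_correlation_matrix",
    "select_representative_group",
    "credible_set",
    "credible_table",
]


def trial_correlation_matrix(trials: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the rows of ``trials`` (t x genes).

    Zero-variance trials get correlation 0 with every other trial (their
    Pearson coefficient is undefined); the diagonal stays 1.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    t = trials.shape[0]
    centered = trials - trials.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def _group_score(corr: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise correlation inside a group; singletons score -inf."""
    if len(members) < 2:
        return -np.inf
    sub = corr[np.ix_(members, members)]
    m = len(members)
    return float((sub.sum() - m) / (m * (m - 1)))


def select_representative_group(trials: np.ndarray, k: int = 2, seed: int = 0) -> np.ndarray:
    """Indices of the k-means cluster with maximal intra-cluster correlation.

    Clusters trials (rows) into at most ``k`` groups with seeded k-means on
    the raw Z-score vectors, scores each group by its mean pairwise Pearson
    correlation, and returns the winner's trial indices in ascending order.
    Singleton groups cannot be scored and lose to any multi-member group;
    if every group is a singleton, the group holding the lowest trial index
    wins. Ties break toward the group with the lowest member index.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    t = trials.shape[0]
    if not 1 <= k:
        raise ValueError(f"k must be >= 1, got {k}")
    k = min(k, t)
    if t == 1 or k == 1:
        return np.arange(t)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(trials)
    corr = trial_correlation_matrix(trials)
    best: np.ndarray | None = None
    best_key: tuple[float, int] | None = None
    for g in range(k):
        members = np.flatnonzero(assign == g)
        if len(members) == 0:
            continue
        # higher score wins; lower first-member index breaks ties
        key = (_group_score(corr, members), -int(members[0]))
        if best_key is None or key > best_key:
            best_key, best = key, members
    assert best is not None
    if best_key is not None and not np.isfinite(best_key[0]):
        # all groups singletons: fall back to the lowest-index trial
        return np.array([0])
    return np.sort(best)


@dataclass
class CredibleSet:
    """A drug's training samples: representative trials S1 plus the
    mean-of-all-trials sample S2."""

    drug_id: str
    s1_indices: np.ndarray
    s2: np.ndarray
    samples: np.ndarray  # (|S1| + 1) x genes

    def __post_init__(self) -> None:
        assert self.samples.shape[0] == len(self.s1_indices) + 1


def credible_set(trials: np.ndarray, k: int = 2, seed: int = 0, drug_id: str = "") -> CredibleSet:
    """Build the credible set S = S1 (representative group) + S2 (mean of
    all trials) for one drug."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    s1 = select_representative_group(trials, k=k, seed=seed)
    s2 = trials.mean(axis=0)
    samples = np.vstack([trials[s1], s2[None, :]])
    return CredibleSet(drug_id=drug_id, s1_indices=s1, s2=s2, samples=samples)


def credible_table(table: ExpressionTable, k: int = 2, seed: int = 0) -> ExpressionTable:
    """Apply :func:`credible_set` to every drug of a cohort.

    Returns a new samples x genes table whose rows are each drug's S1
    trials (sample ids ``<drug>|s1_<trial>``) followed by its S2 mean
    (``<drug>|s2``), all mapped back to the drug.
    """
    sample_ids: list[str] = []
    drug_of_sample: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for drug in table.drugs:
        idx = table.samples_of(drug)
        cs = credible_set(table.values[idx], k=k, seed=seed, drug_id=drug)
        for local in cs.s1_indices:
            sid = f"{drug}|s1_{table.sample_ids[idx[local]]}"
            sample_ids.append(sid)
            drug_of_sample[sid] = drug
        sid = f"{drug}|s2"
        sample_ids.append(sid)
        drug_of_sample[sid] = drug
        rows.append(cs.samples)
    values = np.vstack(rows) if rows else np.empty((0, len(table.gene_ids)))
    return ExpressionTable(sample_ids, list(table.gene_ids), values, drug_of_sample)
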