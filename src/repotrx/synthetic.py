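"""Synthetic L1000-like cohorts with known ground truth.

Emulates the structure of landmark-gene drug-perturbation data: each drug
is observed in several replicate trials of 978 Z-scored genes, carries one
or two first-level ATC labels, and its trials are the sum of the mean-shift
expression patterns of its labels plus independent Gaussian noise. A
fraction of drugs additionally receive a *planted latent class*: the
expression (and side-effect / fingerprint) signal of a class that is absent
from their label table. Recovering those planted (drug, class) pairs is the
pipeline's parameter-recovery benchmark.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .gctio import ATC_LETTERS, ExpressionTable

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "generate_side_effect_sets",
    "generate_fingerprints",
    "class_names",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    The defaults mirror the real cohort's geometry — 978 landmark genes,
    14 ATC classes, roughly ten trials per drug — at a 200-drug scale.
    """

    n_drugs: int = 200
    n_genes: int = 978
    n_classes: int = 14
    trials_per_drug: tuple[int, int] = (5, 15)   # inclusive range
    multilabel_fraction: float = 0.25            # P(drug carries a second label)
    signal: float = 1.0                          # mean shift on signal genes, Z units
    noise_sd: float = 1.0                        # residual s.d., Z units
    signal_gene_fraction: float = 0.10           # class-characteristic gene share
    planted_fraction: float = 0.20               # P(drug gets a latent extra class)
    sideeffect_pool: int = 20                    # characteristic items per class
    fingerprint_pool: int = 20                   # characteristic bits per class
    background_pool: int = 100                   # shared non-informative items
    background_share: float = 0.05               # P(background item included)
    within_class_share: float = 0.70             # P(class item included)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes > 26:
            raise ValueError(f"n_classes must be <= 26, got {self.n_classes}")
        if self.trials_per_drug[0] < 1 or self.trials_per_drug[0] > self.trials_per_drug[1]:
            raise ValueError(f"invalid trials_per_drug range {self.trials_per_drug}")
        for name in (
            "multilabel_fraction",
            "planted_fraction",
            "within_class_share",
            "background_share",
            "signal_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def class_names(n_classes: int) -> list[str]:
    """Class identifiers: the 14 ATC letters, or A..Z beyond 14 classes."""
    if n_classes <= len(ATC_LETTERS):
        return list(ATC_LETTERS[:n_classes])
    return list(string.ascii_uppercase[:n_classes])


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # counter-based stream per sub-generator: stage-level reproducibility
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def _class_shift_patterns(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-class mean-shift vectors: +-signal on a random 10% gene subset."""
    n_signal = max(1, int(round(spec.signal_gene_fraction * spec.n_genes)))
    patterns = np.zeros((spec.n_classes, spec.n_genes))
    for c in range(spec.n_classes):
        genes = rng.choice(spec.n_genes, size=n_signal, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_signal)
        patterns[c, genes] = spec.signal * signs
    return patterns


def generate_cohort(spec: SyntheticSpec) -> tuple[ExpressionTable, dict[str, set[str]], dict]:
    """Generate (expression table, label table, truth record).

    Each drug's trials are ``sum of its labels' shift patterns (+ latent
    pattern if planted) + N(0, noise_sd)`` per gene. The truth record lists
    the planted (drug, latent class) pairs, which never appear in the label
    table.
    """
    names = class_names(spec.n_classes)
    rng_struct = _rng(spec, 0)
    rng_noise = _rng(spec, 1)
    patterns = _class_shift_patterns(spec, _rng(spec, 2))

    width = len(str(max(spec.n_drugs, 1)))
    drugs = [f"drug{str(i).zfill(width)}" for i in range(spec.n_drugs)]

    labels: dict[str, set[str]] = {}
    planted: dict[str, str] = {}
    sample_ids: list[str] = []
    drug_of_sample: dict[str, str] = {}
    blocks: list[np.ndarray] = []

    for drug in drugs:
        primary = int(rng_struct.integers(spec.n_classes))
        lab = {primary}
        if spec.n_classes > 1 and rng_struct.random() < spec.multilabel_fraction:
            second = int(rng_struct.integers(spec.n_classes - 1))
            if second >= primary:
                second += 1
            lab.add(second)
        latent: int | None = None
        free = sorted(set(range(spec.n_classes)) - lab)
        if free and rng_struct.random() < spec.planted_fraction:
            latent = int(free[rng_struct.integers(len(free))])
            planted[drug] = names[latent]
        labels[drug] = {names[c] for c in lab}

        mean = patterns[sorted(lab)].sum(axis=0)
        if latent is not None:
            mean = mean + patterns[latent]
        t = int(rng_struct.integers(spec.trials_per_drug[0], spec.trials_per_drug[1] + 1))
        noise = rng_noise.normal(0.0, spec.noise_sd, size=(t, spec.n_genes))
        blocks.append(mean[None, :] + noise)
        for i in range(t):
            sid = f"{drug}_t{i}"
            sample_ids.append(sid)
            drug_of_sample[sid] = drug

    values = np.vstack(blocks) if blocks else np.empty((0, spec.n_genes))
    genes = [f"g{j}" for j in range(spec.n_genes)]
    table = ExpressionTable(sample_ids, genes, values, drug_of_sample)
    truth = {"planted": planted, "labels": {d: sorted(labels[d]) for d in labels}}
    return table, labels, truth


def _generate_item_sets(
    labels: dict[str, set[str]],
    spec: SyntheticSpec,
    planted: dict[str, str] | None,
    pool: int,
    prefix: str,
    stream: int,
) -> dict[str, set[str]]:
    rng = _rng(spec, stream)
    names = class_names(spec.n_classes)
    block = {c: [f"{prefix}_{c}_{i}" for i in range(pool)] for c in names}
    background = [f"{prefix}_bg_{i}" for i in range(spec.background_pool)]
    planted = planted or {}
    out: dict[str, set[str]] = {}
    for drug in labels:
        classes = set(labels[drug])
        if drug in planted:
            classes.add(planted[drug])
        items: set[str] = set()
        for c in sorted(classes):
            keep = rng.random(pool) < spec.within_class_share
            items.update(it for it, k in zip(block[c], keep) if k)
        keep_bg = rng.random(spec.background_pool) < spec.background_share
        items.update(it for it, k in zip(background, keep_bg) if k)
        out[drug] = items
    return out


def generate_side_effect_sets(
    labels: dict[str, set[str]],
    spec: SyntheticSpec,
    planted: dict[str, str] | None = None,
) -> dict[str, set[str]]:
    """Label-correlated side-effect term sets.

    Every class owns a characteristic block of ``sideeffect_pool`` terms; a
    drug includes each term of its classes' blocks (and of its planted
    latent class's block) with probability ``within_class_share``, plus
    background terms at ``background_share``.
    """
    return _generate_item_sets(labels, spec, planted, spec.sideeffect_pool, "se", 3)


def generate_fingerprints(
    labels: dict[str, set[str]],
    spec: SyntheticSpec,
    planted: dict[str, str] | None = None,
) -> dict[str, set[str]]:
    """Label-correlated structural fingerprint bit sets (same construction
    as the side-effect sets, over an independent bit pool)."""
    return _generate_item_sets(labels, spec, planted, spec.fingerprint_pool, "fp", 4)
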