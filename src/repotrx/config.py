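"""Pipeline configuration.

Defaults are the hyper-parameters selected by cross-validated learning
curves for the softmax repositioning model: learning rate 0.06, training
threshold 0.30, validation threshold 0.06, regularization weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "DEFAULT_ER_GRID", "DEFAULT_COMBINE_THRESHOLDS"]

# DTN-T pruning grid 0.20-0.95 in steps of 0.05; the six highest values
# (0.70-0.95) are the ones averaged into the combined enrichment-ratio matrix.
DEFAULT_ER_GRID: tuple[float, ...] = tuple(round(0.20 + 0.05 * i, 2) for i in range(16))
DEFAULT_COMBINE_THRESHOLDS: tuple[float, ...] = tuple(t for t in DEFAULT_ER_GRID if t >= 0.70)


@dataclass
class PipelineConfig:
    """Hyper-parameters and file paths for an end-to-end run."""

    learning_rate: float = 0.06
    lam: float = 1.0               # weight of the structural-risk (L2) term
    batch_size: int = 32
    iterations: int = 200          # epochs of mini-batch gradient descent
    averaging_window: int = 100    # final epochs averaged into the probability matrix
    training_threshold: float = 0.30
    validation_threshold: float = 0.06
    k_folds: int = 5
    kmeans_k: int = 2              # trial-clustering k for the credible set
    star_threshold: float = 0.9    # strict ">" cut for star-drug calls
    rho_threshold: float = 0.4     # strict ">" cut for SD2/SD3 membership
    er_threshold_grid: tuple[float, ...] = field(default=DEFAULT_ER_GRID)
    combine_thresholds: tuple[float, ...] = field(default=DEFAULT_COMBINE_THRESHOLDS)
    seed: int = 0
    # synthetic-cohort overrides for the simulate stage (SyntheticSpec fields)
    synthetic: dict | None = None
    # input paths (optional: the simulate stage fills them in)
    expression_path: str | None = None
    label_path: str | None = None
    side_effect_path: str | None = None
    fingerprint_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("training_threshold", "validation_threshold", "star_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.averaging_window > self.iterations:
            raise ValueError(
                f"averaging_window ({self.averaging_window}) exceeds iterations ({self.iterations})"
            )
        if self.averaging_window < 1:
            raise ValueError("averaging_window must be >= 1")
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(not 0.0 <= t <= 1.0 for t in self.er_threshold_grid):
            raise ValueError("er_threshold_grid values must lie in [0, 1]")
        self.er_threshold_grid = tuple(self.er_threshold_grid)
        self.combine_thresholds = tuple(self.combine_thresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["er_threshold_grid"] = list(self.er_threshold_grid)
        d["combine_thresholds"] = list(self.combine_thresholds)
        return d


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    data.update(overrides)
    return PipelineConfig(**data)
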