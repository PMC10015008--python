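"""Pipeline configuration.

All randomness in the pipeline flows from one master seed, split
deterministically per stage with :class:`numpy.random.SeedSequence`, so a
fixed seed reproduces every stochastic step (fold assignment, control
down-sampling, simulation) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

BRIER_SCALE_VARIANTS = ("as_printed", "complement_ratio")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    Attributes
    ----------
    k_folds : int
        Cross-validation folds (default 5).
    knots : int
        Basis dimension per smooth term (default 10).
    downsample_ratio : float
        Controls retained per case when down-sampling (default 10, i.e. a
        fitted case fraction of 1/11 ~ 9.1%).
    target_prevalence : float or None
        True case fraction used for the class adjustment; None means "use
        the observed prevalence of the source data".
    threshold_step : float
        Grid increment for G-mean threshold search (default 0.01).
    selection_tolerance : float
        Scaled-Brier slack (percentage points) within which a variable
        removal is still accepted during backward selection.
    seed : int
        Master seed.
    brier_scale_variant : str
        'as_printed' uses (1 - BS) / BS_max; 'complement_ratio' uses
        1 - BS / BS_max.  Both are monotone decreasing in BS.
    """

    k_folds: int = 5
    knots: int = 10
    downsample_ratio: float = 10.0
    target_prevalence: float | None = None
    threshold_step: float = 0.01
    selection_tolerance: float = 0.05
    seed: int = 0
    brier_scale_variant: str = "as_printed"

    def __post_init__(self):
        if self.k_folds < 2:
            raise ConfigError(f"k_folds must be >= 2, got {self.k_folds}")
        if not (0 < self.threshold_step <= 0.5):
            raise ConfigError(f"threshold_step must be in (0, 0.5], got {self.threshold_step}")
        if self.downsample_ratio < 1:
            raise ConfigError(f"downsample_ratio must be >= 1, got {self.downsample_ratio}")
        if self.brier_scale_variant not in BRIER_SCALE_VARIANTS:
            raise ConfigError(f"unknown brier_scale_variant {self.brier_scale_variant!r}")

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the master seed."""
        h = int.from_bytes(stage.encode("utf-8"), "big") % (2**31)
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(h,))

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.stage_seed(stage))

    def to_dict(self) -> dict:
        return asdict(self)
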