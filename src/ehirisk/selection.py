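"""Cross-validated Brier scoring and backward stepwise model selection.

Candidate models are compared by 5-fold cross-validation: for each fold the
training portion is down-sampled (controls only), the GAMM fitted, the
untouched test fold predicted (random intercepts zero for unseen groups),
the class adjustment applied with the training split's sampling fractions,
and the forecasts scored with the Brier score

    BS = (1/N) sum_t (f_t - o_t)^2

scaled against the score of the no-skill forecast at the test fold's
outcome proportion mean(p),

    BS_max   = mean(p) (1-mean(p))^2 + (1-mean(p)) mean(p)^2
             = mean(p) (1-mean(p))
    BS_scale = (1 - BS) / BS_max        ('as_printed')
    BS_scale = 1 - BS / BS_max          ('complement_ratio')

both reported x100 as percent and both monotone decreasing in BS.  The
as_printed form is the published formula; it cannot be read as a
skill-score fraction (its magnitude is dominated by 1/BS_max), so the
conventional complement form is provided alongside and the choice is a
configuration field.

Backward selection starts from the maximal model and repeatedly removes the
term whose removal gives the best CV scaled score, as long as that score is
not worse than the incumbent's by more than a small slack
(``selection_tolerance``, in scaled-Brier percentage points).  Random-effect
terms are never candidates for removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gamm import (FittedGAMM, ModelSpec, SamplingInfo, adjust_probability,
                   downsample_controls, fit_gamm, predict_probability)

__all__ = [
    "brier_score", "brier_max", "scaled_brier", "kfold_partition",
    "cv_score", "backward_select", "CVResult", "SelectionLedger",
]


def brier_score(f, o) -> float:
    """Mean squared difference between forecasts f and binary outcomes o."""
    f = np.asarray(f, dtype=float)
    o = np.asarray(o, dtype=float)
    if f.shape != o.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {o.shape}")
    if f.size == 0:
        raise ValueError("empty forecast vector")
    return float(np.mean((f - o) ** 2))


def brier_max(mean_p: float) -> float:
    """Brier score of the no-skill forecast at outcome proportion mean_p."""
    if not (0.0 <= mean_p <= 1.0):
        raise ValueError("mean_p must lie in [0, 1]")
    return mean_p * (1 - mean_p) ** 2 + (1 - mean_p) * mean_p ** 2


def scaled_brier(bs: float, bs_max: float, variant: str = "as_printed") -> float:
    """Scaled Brier score (raw ratio; reported x100 as percent elsewhere).

    Higher is better under both variants.
    """
    if bs_max <= 0:
        raise ZeroDivisionError("BS_max is zero: outcome proportion is degenerate")
    if variant == "as_printed":
        return (1.0 - bs) / bs_max
    if variant == "complement_ratio":
        return 1.0 - bs / bs_max
    raise ValueError(f"unknown scaled-Brier variant {variant!r}")


def kfold_partition(n: int, k: int, rng) -> np.ndarray:
    """Uniformly random fold labels 0..k-1 with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer rows than folds")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    labels = np.tile(np.arange(k), n // k + 1)[:n]
    return rng.permutation(labels)


@dataclass
class CVResult:
    fold_bs: list
    fold_bs_max: list
    fold_scaled: list
    variant: str

    @property
    def mean_bs(self) -> float:
        return float(np.mean(self.fold_bs))

    @property
    def sd_bs(self) -> float:
        return float(np.std(self.fold_bs, ddof=1))

    @property
    def mean_scaled(self) -> float:
        return float(np.mean(self.fold_scaled))

    @property
    def sd_scaled(self) -> float:
        return float(np.std(self.fold_scaled, ddof=1))


def cv_score(
    frame: pd.DataFrame,
    spec: ModelSpec,
    config: PipelineConfig,
    rng=None,
    return_predictions: bool = False,
    fit_kwargs: dict | None = None,
):
    """K-fold cross-validated Brier scores for one model specification.

    Test folds are never down-sampled, so they reflect the source
    prevalence; only each fold's training portion has its controls
    down-sampled.  Predictions on the test fold use zero random intercepts
    for unseen groups and are class-adjusted with the training split's
    sampling fractions before scoring.
    """
    if rng is None:
        rng = config.stage_rng("cv")
    fit_kwargs = dict(fit_kwargs or {})
    # train-fold designs carry the whole frame's categorical levels, so a
    # level thinly represented in one fold still predicts (as the reference)
    fit_kwargs.setdefault("cat_levels", {
        var: sorted(frame[var].astype(str).unique()) for var in spec.categorical
    })
    folds = kfold_partition(len(frame), config.k_folds, rng)
    fold_bs, fold_bs_max, fold_scaled = [], [], []
    preds = np.full(len(frame), np.nan)
    for fold in range(config.k_folds):
        test_mask = folds == fold
        train = frame[~test_mask]
        test = frame[test_mask]
        if test["ehi"].sum() == 0:
            import warnings
            warnings.warn(f"fold {fold} contains no cases; scores still computed")
        ds, info = downsample_controls(train, config.downsample_ratio, rng)
        if config.target_prevalence is not None:
            info = SamplingInfo(q=info.q, pi=config.target_prevalence,
                                ratio=info.ratio, seed=info.seed)
        try:
            fitted = fit_gamm(ds, spec, **fit_kwargs)
        except Exception as exc:
            raise RuntimeError(f"fold {fold}: {exc}") from exc
        p_model = predict_probability(fitted, test, include_random=True)
        p_abs = adjust_probability(p_model, info)
        preds[test_mask] = p_abs
        o = test["ehi"].to_numpy(float)
        bs = brier_score(p_abs, o)
        bmax = brier_max(float(o.mean()))
        fold_bs.append(bs)
        fold_bs_max.append(bmax)
        # stored in percent, the scale on which selection_tolerance and the
        # published selection table are expressed
        fold_scaled.append(100.0 * scaled_brier(bs, bmax, config.brier_scale_variant)
                           if bmax > 0 else np.nan)
    result = CVResult(fold_bs, fold_bs_max, fold_scaled, config.brier_scale_variant)
    if return_predictions:
        return result, preds, folds
    return result


@dataclass
class SelectionLedger:
    """Every model evaluated during backward selection, in evaluation order."""

    rows: list = field(default_factory=list)

    def add(self, formula, mean_bs, sd_bs, mean_scaled, sd_scaled, delta, decision):
        self.rows.append(
            {
                "model": formula,
                "mean_brier": mean_bs,
                "sd_brier": sd_bs,
                "mean_scaled_brier": mean_scaled,
                "sd_scaled_brier": sd_scaled,
                "delta_scaled": delta,
                "decision": decision,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def backward_select(
    frame: pd.DataFrame,
    full_spec: ModelSpec,
    config: PipelineConfig,
    fit_kwargs: dict | None = None,
):
    """Backward stepwise selection by cross-validated scaled Brier score.

    At each round every remaining removable term is dropped in turn and the
    reduced model cross-validated (all models in a round share the same fold
    assignment and down-sampling draws via a fresh per-round generator
    seeded from the master seed, so comparisons are paired).  The best
    removal is accepted if its mean scaled score is not worse than the
    incumbent's by more than ``config.selection_tolerance`` percentage
    points.  Selection stops when no removal qualifies.
    """
    ss = config.stage_seed("selection")
    incumbent = full_spec
    inc_result = cv_score(frame, incumbent, config,
                          rng=np.random.default_rng(ss.spawn(1)[0]),
                          fit_kwargs=fit_kwargs)
    ledger = SelectionLedger()
    ledger.add(incumbent.describe(), inc_result.mean_bs, inc_result.sd_bs,
               inc_result.mean_scaled, inc_result.sd_scaled, np.nan, "incumbent")
    round_no = 0
    while incumbent.removable:
        round_no += 1
        round_seed = ss.spawn(1)[0]
        # rescore the incumbent under this round's folds so every Delta is
        # a paired comparison
        inc_result = cv_score(frame, incumbent, config,
                              rng=np.random.default_rng(round_seed),
                              fit_kwargs=fit_kwargs)
        candidates = []
        for name in incumbent.removable:
            cand = incumbent.drop(name)
            # paired comparison: identical folds/down-sampling within a round
            rng = np.random.default_rng(round_seed)
            res = cv_score(frame, cand, config, rng=rng, fit_kwargs=fit_kwargs)
            candidates.append((name, cand, res))
        name, cand, res = max(candidates, key=lambda t: t[2].mean_scaled)
        delta = res.mean_scaled - inc_result.mean_scaled
        accept = delta >= -config.selection_tolerance
        for nm, _, r in candidates:
            ledger.add(f"{incumbent.describe()} - {nm}", r.mean_bs, r.sd_bs,
                       r.mean_scaled, r.sd_scaled,
                       r.mean_scaled - inc_result.mean_scaled,
                       ("drop " + nm) if (accept and nm == name) else "evaluated")
        if not accept:
            break
        incumbent, inc_result = cand, res
    return incumbent, ledger
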