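"""End-to-end pipeline driver.

Stages: read -> preprocess -> backward CV selection -> final down-sampled
fit -> odds-ratio effects -> cross-validated classification.  Produces a
machine-readable report (selected model, CV scores, odds ratios, ROC
summary, exclusion log, seed provenance) and optionally writes it, plus the
selection ledger and effects tables, to an output directory.

Every stochastic step draws from a generator derived deterministically from
the master seed, so a fixed seed reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .effects import effects_table, pairwise_category_or, smooth_interval_or
from .gamm import DEFAULT_SPEC, FULL_SPEC, SamplingInfo, downsample_controls, fit_gamm
from .io import read_runners, read_weather
from .preprocess import build_model_frame, runners_to_frame, weather_to_frame
from .selection import backward_select, cv_score
from .classify import confusion, gmean_threshold, race_level_summary, roc_auc

log = logging.getLogger("ehirisk")

SMOOTH_INTERVALS = {
    "distance": (1760.0, 3520.0),
    "wbgt": (20.0, 30.0),
    "prev5": (15.0, 25.0),
    "age": (2.0, 4.0),
}


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    runners,
    weather,
    out_dir=None,
    select: bool = True,
    fit_kwargs: dict | None = None,
) -> dict:
    """Run the full analysis and return the report dictionary.

    ``runners`` / ``weather`` may be file paths or DataFrames/record lists.
    With ``select=False`` the pre-specified final model is used directly
    instead of running backward selection.
    """
    fit_kwargs = fit_kwargs or {}
    report: dict = {"config": config.to_dict(), "stages": []}

    def stage(name):
        log.info("stage %s (seed %s)", name, config.seed)
        report["stages"].append(name)

    try:
        stage("read")
        if isinstance(runners, (str, Path)):
            runners = read_runners(runners)
        if isinstance(weather, (str, Path)):
            weather = read_weather(weather)
    except Exception as exc:
        raise StageError("read", exc) from exc

    try:
        stage("preprocess")
        frame, excl = build_model_frame(runners, weather)
        report["exclusions"] = excl.to_dict()
        report["n_rows"] = int(len(frame))
        report["n_cases"] = int(frame["ehi"].sum())
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    try:
        if select:
            stage("selection")
            spec, ledger = backward_select(frame, FULL_SPEC(config.knots), config,
                                           fit_kwargs=fit_kwargs)
            report["selection"] = ledger.rows
        else:
            spec, ledger = DEFAULT_SPEC(config.knots), None
        report["selected_model"] = spec.describe()
    except Exception as exc:
        raise StageError("selection", exc) from exc

    try:
        stage("final_fit")
        ds, info = downsample_controls(frame, config.downsample_ratio,
                                       config.stage_rng("downsample"))
        if config.target_prevalence is not None:
            info = SamplingInfo(q=info.q, pi=config.target_prevalence, ratio=info.ratio)
        levels = {var: sorted(frame[var].astype(str).unique())
                  for var in spec.categorical}
        fitted = fit_gamm(ds, spec, cat_levels=levels, **fit_kwargs)
        report["sampling"] = {"q": info.q, "pi": info.pi, "ratio": info.ratio,
                              "n_fitted": int(len(ds))}
        report["edf"] = {k: round(float(v), 4) for k, v in fitted.edf.items()}
        report["convergence"] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in fitted.convergence.items()
        }
    except Exception as exc:
        raise StageError("final_fit", exc) from exc

    try:
        stage("effects")
        est = []
        for term, (a, b) in SMOOTH_INTERVALS.items():
            if f"s({term})" in fitted.design.slices:
                info_s = fitted.design.smooths[term]
                lo = max(a, info_s.xmin)
                hi = min(b, info_s.xmax)
                if lo < hi:
                    est.append(smooth_interval_or(fitted, term, lo, hi))
        for term in spec.categorical:
            est.extend(pairwise_category_or(fitted, term))
        eff = effects_table(est)
        report["effects"] = eff.round(6).to_dict(orient="records")
    except Exception as exc:
        raise StageError("effects", exc) from exc

    try:
        stage("classification")
        cv, preds, folds = cv_score(frame, spec, config, return_predictions=True,
                                    fit_kwargs=fit_kwargs)
        report["cv"] = {
            "mean_brier": cv.mean_bs, "sd_brier": cv.sd_bs,
            "mean_scaled_brier": cv.mean_scaled, "sd_scaled_brier": cv.sd_scaled,
            "variant": cv.variant,
        }
        y = frame["ehi"].to_numpy(int)
        aucs, thresholds = [], []
        for fold in range(config.k_folds):
            m = folds == fold
            if y[m].sum() == 0 or y[m].sum() == m.sum():
                continue
            aucs.append(roc_auc(preds[m], y[m]).auc)
            thresholds.append(gmean_threshold(preds[m], y[m], config.threshold_step))
        thr = float(np.mean(thresholds))
        report["roc"] = {
            "auc_mean": float(np.mean(aucs)),
            "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            "threshold_mean": thr,
            "threshold_sd": float(np.std(thresholds, ddof=1)) if len(thresholds) > 1 else 0.0,
            "confusion_pooled": confusion(preds, y, thr),
            "race_level_pooled": race_level_summary(
                preds, y, frame["race_id"].to_numpy(), thr),
        }
    except Exception as exc:
        raise StageError("classification", exc) from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report_json(report))
        eff.to_csv(out_dir / "effects.csv", index=False)
        if ledger is not None:
            ledger.to_frame().to_csv(out_dir / "selection_ledger.csv", index=False)
        log.info("report written to %s", out_dir)
    return report


def report_json(report: dict) -> str:
    """Deterministic JSON serialisation of a report."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serialisable: {type(o)}")
    return json.dumps(report, indent=1, sort_keys=True, default=default)
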