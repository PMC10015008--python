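"""Brier scoring, cross-validation and backward selection mechanics."""

import numpy as np
import pandas as pd
import pytest

from ehirisk.config import PipelineConfig
from ehirisk.gamm import ModelSpec, SmoothTerm
from ehirisk.selection import (CVResult, backward_select, brier_max, brier_score,
                               cv_score, kfold_partition, scaled_brier)


def brier_loop_oracle(f, o):
    total = 0.0
    for ft, ot in zip(f, o):
        total += (ft - ot) ** 2
    return total / len(f)


class TestBrier:
    def test_perfect_and_worst(self):
        assert brier_score([1, 0, 1], [1, 0, 1]) == 0.0
        assert brier_score([1.0, 0.0], [0, 1]) == 1.0

    def test_hand_value(self):
        assert brier_score([0.9, 0.1], [1, 0]) == pytest.approx(0.01)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        f = rng.random(500)
        o = (rng.random(500) < 0.3).astype(int)
        assert brier_score(f, o) == pytest.approx(brier_loop_oracle(f, o), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            brier_score([0.1], [0, 1])


class TestBrierMax:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.1, 0.09), (0.5, 0.25)])
    def test_values(self, p, expected):
        assert brier_max(p) == pytest.approx(expected)

    def test_equals_p_times_1mp(self):
        for p in np.linspace(0, 1, 21):
            assert brier_max(p) == pytest.approx(p * (1 - p), abs=1e-12)


class TestScaledBrier:
    def test_as_printed(self):
        assert scaled_brier(1.0, 0.09, "as_printed") == pytest.approx(0.0)
        assert scaled_brier(0.01, 0.09, "as_printed") == pytest.approx(11.0, abs=0.01)

    def test_complement_ratio(self):
        assert scaled_brier(0.01, 0.09, "complement_ratio") == pytest.approx(0.8889, abs=1e-4)

    def test_both_monotone_decreasing_in_bs(self):
        for variant in ("as_printed", "complement_ratio"):
            vals = [scaled_brier(bs, 0.09, variant) for bs in np.linspace(0, 1, 30)]
            assert np.all(np.diff(vals) < 0)

    def test_zero_bs_max_error(self):
        with pytest.raises(ZeroDivisionError):
            scaled_brier(0.1, 0.0)


class TestKFold:
    def test_partition_properties(self):
        labels = kfold_partition(103, 5, np.random.default_rng(1))
        sizes = np.bincount(labels, minlength=5)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103

    def test_deterministic_given_seed(self):
        a = kfold_partition(50, 5, np.random.default_rng(7))
        b = kfold_partition(50, 5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_ten_rows_five_folds(self):
        labels = kfold_partition(10, 5, np.random.default_rng(0))
        assert sorted(np.bincount(labels)) == [2, 2, 2, 2, 2]

    def test_errors(self):
        with pytest.raises(ValueError):
            kfold_partition(10, 1, np.random.default_rng(0))
        with pytest.raises(ValueError):
            kfold_partition(3, 5, np.random.default_rng(0))


def _null_frame(n=4000, pi=0.05, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "ehi": (rng.random(n) < pi).astype(int),
        "horse_id": [f"H{i % 800}" for i in range(n)],
        "meet_id": [f"M{i % 200}" for i in range(n)],
    })


def test_cv_null_model_brier_near_analytic():
    """An intercept-only model forecasting the prevalence has expected Brier
    score pi(1-pi)."""
    pi = 0.05
    frame = _null_frame(pi=pi)
    config = PipelineConfig(seed=3, downsample_ratio=5)
    res = cv_score(frame, ModelSpec(), config)
    expected = pi * (1 - pi)
    assert res.mean_bs == pytest.approx(expected, rel=0.15)
    assert res.sd_bs > 0  # fold scores vary on stochastic data


def test_cv_keeps_test_folds_at_source_prevalence(small_frame):
    frame, _, _ = small_frame
    config = PipelineConfig(seed=1)
    res, preds, folds = cv_score(frame, ModelSpec(), config, return_predictions=True)
    # every row predicted exactly once, folds partition the frame
    assert not np.isnan(preds).any()
    assert np.array_equal(np.sort(np.unique(folds)), np.arange(5))
    # intercept-only class-adjusted forecasts sit near the source prevalence,
    # far below the down-sampled case fraction
    assert abs(np.median(preds) - frame["ehi"].mean()) < 0.01
    assert np.median(preds) < 0.02


def test_cv_oracle_forecast_dominates_fitted_model(small_frame):
    """Scoring the generator's true probabilities must beat the fitted
    model's cross-validated Brier score."""
    from scipy.special import expit
    from ehirisk.simulate import true_linear_predictor
    from ehirisk.gamm import DEFAULT_SPEC

    frame, _, truth = small_frame
    config = PipelineConfig(seed=4)
    res = cv_score(frame, DEFAULT_SPEC(10), config, fit_kwargs={"max_outer": 8})
    p_true = expit(true_linear_predictor(truth, frame))
    bs_true = brier_score(p_true, frame["ehi"].to_numpy())
    assert bs_true <= res.mean_bs


def _selection_frame(seed=0, n=5000):
    """Small frame with one strong predictor and one null predictor."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, n)
    noise = rng.choice([f"c{i}" for i in range(8)], n)
    from scipy.special import expit
    y = (rng.random(n) < expit(-2.5 + 1.8 * x)).astype(int)
    return pd.DataFrame({
        "ehi": y, "x": x, "noise_cat": noise,
        "horse_id": [f"H{i % 500}" for i in range(n)],
        "meet_id": [f"M{i % 100}" for i in range(n)],
    })


def test_backward_selection_drops_null_keeps_active():
    frame = _selection_frame()
    spec = ModelSpec(smooth=(SmoothTerm("x", 8),), categorical=("noise_cat",),
                     random=())
    config = PipelineConfig(seed=9, downsample_ratio=10, selection_tolerance=0.05,
                            brier_scale_variant="complement_ratio")
    selected, ledger = backward_select(frame, spec, config,
                                       fit_kwargs={"max_outer": 6})
    assert "noise_cat" not in selected.categorical
    assert any(t.var == "x" for t in selected.smooth)
    led = ledger.to_frame()
    assert (led["decision"] == "incumbent").sum() == 1
    assert led["model"].str.contains("noise_cat").any()


def test_selection_tolerance_zero_accepts_strict_improvement():
    frame = _selection_frame(seed=2)
    spec = ModelSpec(smooth=(SmoothTerm("x", 8),), categorical=("noise_cat",))
    config = PipelineConfig(seed=9, downsample_ratio=10, selection_tolerance=0.0)
    selected, ledger = backward_select(frame, spec, config,
                                       fit_kwargs={"max_outer": 6})
    led = ledger.to_frame()
    dropped = led["decision"].str.startswith("drop")
    # any accepted removal under zero tolerance strictly improved the score
    for _, row in led[dropped].iterrows():
        assert row["delta_scaled"] >= 0.0


def test_random_terms_never_candidates():
    spec = ModelSpec(smooth=(SmoothTerm("x", 8),), categorical=("c",),
                     random=("horse_id",))
    assert "re(horse_id)" not in spec.removable
    assert set(spec.removable) == {"s(x)", "c"}
    with pytest.raises(KeyError):
        spec.drop("horse_id")
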