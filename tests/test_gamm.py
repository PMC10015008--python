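"""Binomial GAMM fitting, prediction, down-sampling and class adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ehirisk.gamm import (DEFAULT_SPEC, FULL_SPEC, ModelSpec, SamplingInfo,
                          SmoothTerm, adjust_probability, downsample_controls,
                          fit_gamm, predict_probability)


@pytest.fixture()
def rng():
    # fresh generator per test: keeps tests order-independent
    return np.random.default_rng(42)


def test_intercept_only_glm_limit(rng):
    y = (rng.random(3000) < 0.08).astype(int)
    f = fit_gamm(pd.DataFrame({"ehi": y}), ModelSpec())
    assert f.beta[0] == pytest.approx(logit(y.mean()), abs=1e-8)


def test_single_linear_effect_recovered_within_2se(rng):
    """On strongly linear truth the smooth's +-1 contrast matches the true
    slope within 2 SE, and stays consistent with an unpenalised logistic
    fit (statsmodels) of the same data."""
    import statsmodels.api as sm

    n = 8000
    x = rng.uniform(-2, 2, n)
    y = (rng.random(n) < expit(-1.0 + 0.8 * x)).astype(int)
    df = pd.DataFrame({"ehi": y, "x": x})
    f = fit_gamm(df, ModelSpec(smooth=(SmoothTerm("x", 10),)))
    s = f.design.smooths["x"]
    sl = f.design.slices["s(x)"]
    X = s.design(np.array([-1.0, 1.0]))
    c = X[1] - X[0]
    slope_half = float(c @ f.beta[sl]) / 2.0
    se_half = float(np.sqrt(c @ f.cov_fixed[sl.start:sl.stop, sl.start:sl.stop] @ c)) / 2.0

    assert abs(slope_half - 0.8) < 2 * se_half
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    assert abs(slope_half - glm.params[1]) < 2 * np.hypot(se_half, glm.bse[1])


def test_pure_noise_smooth_shrinks_to_zero(rng):
    n = 6000
    x = rng.uniform(-2, 2, n)
    z = rng.uniform(0, 1, n)
    y = (rng.random(n) < expit(-1.0 + np.sin(1.5 * x))).astype(int)
    df = pd.DataFrame({"ehi": y, "x": x, "z": z})
    f = fit_gamm(df, ModelSpec(smooth=(SmoothTerm("x", 10), SmoothTerm("z", 10))))
    assert f.edf["s(z)"] < 0.5
    assert f.edf["s(x)"] > 2.0


def test_manual_lambda_override_zeroes_smooth(rng):
    n = 4000
    x = rng.uniform(-2, 2, n)
    y = (rng.random(n) < expit(-0.5 + np.sin(1.5 * x))).astype(int)
    df = pd.DataFrame({"ehi": y, "x": x})
    f = fit_gamm(df, ModelSpec(smooth=(SmoothTerm("x", 10),)),
                 fixed_lambdas={"s(x)": 1e10})
    s = f.design.smooths["x"]
    sl = f.design.slices["s(x)"]
    contrib = s.design(np.linspace(-1.9, 1.9, 50)) @ f.beta[sl]
    assert np.max(np.abs(contrib)) < 0.02
    assert f.edf["s(x)"] < 0.05


def test_random_intercepts_recovered(rng):
    n, g = 6000, 60
    grp = rng.integers(0, g, n)
    b = rng.normal(0, 0.8, g)
    y = (rng.random(n) < expit(-0.5 + b[grp])).astype(int)
    df = pd.DataFrame({"ehi": y, "grp": [f"g{i:02d}" for i in grp]})
    f = fit_gamm(df, ModelSpec(random=("grp",)))
    sigma_hat = 1.0 / np.sqrt(f.lambdas["re(grp)"])
    assert 0.5 < sigma_hat < 1.2
    levels = f.design.random_levels["grp"]
    bh = f.beta[f.design.slices["re(grp)"]]
    aligned = np.array([b[int(l[1:])] for l in levels])
    assert np.corrcoef(bh, aligned)[0, 1] > 0.8


def test_fitted_mean_equals_case_fraction(small_frame):
    frame, _, _ = small_frame
    ds, info = downsample_controls(frame, 10, np.random.default_rng(0))
    f = fit_gamm(ds, DEFAULT_SPEC(10), max_outer=8)
    # IRLS score equation for the unpenalised intercept
    assert f.fitted_values.mean() == pytest.approx(info.q, rel=1e-3)


def test_prediction_identities(small_frame):
    frame, _, _ = small_frame
    ds, _ = downsample_controls(frame, 5, np.random.default_rng(1))
    f = fit_gamm(ds, DEFAULT_SPEC(10), max_outer=8)
    # in-sample predictions reproduce fitted values
    np.testing.assert_allclose(
        predict_probability(f, ds), f.fitted_values, atol=1e-10)
    # unseen meet/horse ids predict identically to include_random=False
    new = ds.head(50).copy()
    new["horse_id"] = "H_unseen"
    new["meet_id"] = "M_unseen"
    np.testing.assert_allclose(
        predict_probability(f, new, include_random=True),
        predict_probability(f, new, include_random=False),
    )
    # unseen categorical level raises
    bad = ds.head(5).copy()
    bad["going5"] = "glue"
    with pytest.raises(ValueError, match="unseen level"):
        predict_probability(f, bad)


def test_eta_zero_maps_to_half():
    s = SamplingInfo(q=0.5, pi=0.5, ratio=1.0)
    assert expit(0.0) == 0.5 and adjust_probability(0.5, s) == pytest.approx(0.5)


class TestDownsample:
    def test_paper_scale_counts(self):
        rng = np.random.default_rng(0)
        n = 200_000
        y = np.zeros(n, dtype=int)
        y[:659] = 1
        frame = pd.DataFrame({"ehi": rng.permutation(y)})
        ds, info = downsample_controls(frame, 10, rng)
        assert len(ds) == 7249          # 659 cases + 6590 controls
        assert int(ds["ehi"].sum()) == 659
        assert info.q == pytest.approx(659 / 7249)

    def test_all_cases_kept_small(self):
        frame = pd.DataFrame({"ehi": [1] * 5 + [0] * 100})
        ds, info = downsample_controls(frame, 2, np.random.default_rng(1))
        assert len(ds) == 15 and ds["ehi"].sum() == 5

    def test_ratio_exceeding_controls_keeps_all(self):
        frame = pd.DataFrame({"ehi": [1] * 5 + [0] * 8})
        with pytest.warns(UserWarning, match="more controls"):
            ds, info = downsample_controls(frame, 10, np.random.default_rng(1))
        assert len(ds) == 13

    def test_no_cases_error(self):
        with pytest.raises(ValueError):
            downsample_controls(pd.DataFrame({"ehi": [0, 0]}), 2,
                                np.random.default_rng(0))


class TestAdjustProbabilityProperties:
    """Property-based checks of the odds-scale prior correction."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        p=st.floats(0.0, 1.0),
        pi=st.floats(1e-6, 0.4),
        ratio=st.floats(0.0, 0.999),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_order_preserved(self, p, pi, ratio):
        # q anywhere in [pi, 1): parametrised as pi + ratio * (1 - pi - eps)
        q = pi + ratio * (0.999 - pi)
        s = SamplingInfo(q=max(q, pi), pi=pi, ratio=10.0)
        out = adjust_probability(p, s)
        assert 0.0 <= out <= 1.0
        # strictly increasing: compare against a nearby larger p
        if p < 0.99:
            assert adjust_probability(p + 0.01, s) >= out

    @given(pi=st.floats(1e-6, 0.4))
    @settings(derandomize=True, max_examples=50)
    def test_identity_when_sampling_matches_source(self, pi):
        s = SamplingInfo(q=pi, pi=pi, ratio=1.0)
        p = np.linspace(0, 1, 11)
        np.testing.assert_allclose(adjust_probability(p, s), p, atol=1e-12)


class TestAdjustProbability:
    def test_identity_when_q_equals_pi(self):
        s = SamplingInfo(q=0.1, pi=0.1, ratio=9.0)
        p = np.linspace(0, 1, 11)
        np.testing.assert_allclose(adjust_probability(p, s), p)

    def test_hand_computed_value(self):
        s = SamplingInfo(q=0.1, pi=0.001, ratio=10.0)
        assert adjust_probability(0.5, s) == pytest.approx(0.008929, abs=1e-6)

    def test_boundaries_and_monotone(self):
        s = SamplingInfo(q=0.0909, pi=0.001, ratio=10.0)
        assert adjust_probability(0.0, s) == 0.0
        assert adjust_probability(1.0, s) == 1.0
        p = np.linspace(0, 1, 201)
        assert np.all(np.diff(adjust_probability(p, s)) > 0)

    def test_inverse_composition(self):
        s = SamplingInfo(q=0.0909, pi=0.001, ratio=10.0)
        p = np.linspace(0.01, 0.99, 50)
        adj = adjust_probability(p, s)
        # analytic inverse of the odds-scale correction
        factor = (s.pi * (1 - s.q)) / (s.q * (1 - s.pi))
        odds_back = adj / (1 - adj) / factor
        np.testing.assert_allclose(odds_back / (1 + odds_back), p, atol=1e-12)

    def test_invariants(self):
        with pytest.raises(ValueError):
            SamplingInfo(q=0.001, pi=0.1, ratio=10.0)  # needs pi <= q


def test_response_validation():
    with pytest.raises(ValueError):
        fit_gamm(pd.DataFrame({"ehi": [0, 0, 0]}), ModelSpec())
    with pytest.raises(ValueError):
        fit_gamm(pd.DataFrame({"ehi": [0, 1, 2]}), ModelSpec())
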