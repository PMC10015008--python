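"""Odds-ratio extraction: interval ORs, pairwise marginal-mean ORs,
probability surfaces."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ehirisk.effects import (pairwise_category_or, probability_surface,
                             smooth_interval_or)
from ehirisk.gamm import (DEFAULT_SPEC, ModelSpec, SamplingInfo, SmoothTerm,
                          downsample_controls, fit_gamm)


@pytest.fixture(scope="module")
def fitted(small_frame):
    frame, _, _ = small_frame
    ds, info = downsample_controls(frame, 10, np.random.default_rng(2))
    return fit_gamm(ds, DEFAULT_SPEC(10), max_outer=12), info


class TestSmoothIntervalOR:
    def test_null_contrast_is_one(self, fitted):
        f, _ = fitted
        est = smooth_interval_or(f, "wbgt", 15.0, 15.0)
        assert est.or_ == pytest.approx(1.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_telescoping(self, fitted):
        f, _ = fitted
        ab = smooth_interval_or(f, "distance", 1800.0, 3000.0).or_
        bc = smooth_interval_or(f, "distance", 3000.0, 4200.0).or_
        ac = smooth_interval_or(f, "distance", 1800.0, 4200.0).or_
        assert np.log(ab) + np.log(bc) == pytest.approx(np.log(ac), abs=1e-10)

    def test_out_of_range_and_non_smooth_errors(self, fitted):
        f, _ = fitted
        with pytest.raises(ValueError, match="training range"):
            smooth_interval_or(f, "wbgt", -50.0, 20.0)
        with pytest.raises(ValueError, match="not a smooth"):
            smooth_interval_or(f, "going5", 0.0, 1.0)


class TestPairwiseCategoryOR:
    def test_contrast_count(self, fitted):
        f, _ = fitted
        ests = pairwise_category_or(f, "going5")
        k = len(f.design.cat_levels["going5"])
        assert len(ests) == k * (k - 1) // 2

    def test_constructed_contrast_value(self, fitted):
        """OR(firm/heavy) must equal exp(beta_firm - beta_heavy) from the
        treatment-coded coefficients."""
        f, _ = fitted
        levels = f.design.cat_levels["going5"]
        sl = f.design.slices["going5"]
        coefs = dict(zip(levels[1:], f.beta[sl]))
        coefs[levels[0]] = 0.0
        ests = {e.comparison: e for e in pairwise_category_or(f, "going5")}
        e = ests["going5 firm/heavy"]
        assert e.or_ == pytest.approx(np.exp(coefs["firm"] - coefs["heavy"]), rel=1e-9)

    def test_hand_constructed_coefficients(self, fitted):
        f, _ = fitted
        import copy

        g = copy.deepcopy(f)
        levels = g.design.cat_levels["going5"]
        sl = g.design.slices["going5"]
        g.beta[sl] = 0.0
        g.beta[sl.start + levels[1:].index("heavy")] = 0.853
        ests = {e.comparison: e for e in pairwise_category_or(g, "going5")}
        assert ests["going5 firm/heavy"].or_ == pytest.approx(np.exp(-0.853), rel=1e-9)
        assert ests["going5 firm/heavy"].or_ == pytest.approx(0.426, abs=5e-4)

    def test_identical_levels_or_one_p_near_one(self, fitted):
        f, _ = fitted
        import copy

        g = copy.deepcopy(f)
        sl = g.design.slices["going5"]
        g.beta[sl] = 0.0
        # zero out the covariance so the contrast statistics are exactly 0
        ests = pairwise_category_or(g, "going5")
        for e in ests:
            assert e.or_ == pytest.approx(1.0)
            assert e.p_adjusted > 0.95

    def test_adjusted_p_at_least_unadjusted(self, fitted):
        from scipy import stats

        f, _ = fitted
        for e in pairwise_category_or(f, "year"):
            raw = 2 * stats.norm.sf(abs(e.statistic))
            assert e.p_adjusted >= raw - 0.01


class TestProbabilitySurface:
    def test_monotone_in_distance_and_prev_shift(self, fitted):
        f, info = fitted
        s = f.design.smooths["distance"]
        grid = {
            "distance": np.linspace(s.xmin, s.xmax, 15),
            "prev_incident": ["0", "1"],
        }
        surf = probability_surface(f, info, grid)
        p0 = surf[surf.prev_incident == "0"].sort_values("distance")["probability"].to_numpy()
        p1 = surf[surf.prev_incident == "1"].sort_values("distance")["probability"].to_numpy()
        # previous-incident surface lies uniformly above (fitted beta_prev > 0)
        assert np.all(p1 > p0)
        # broadly increasing in distance (fitted smooth is monotone at this scale)
        assert p0[-1] > p0[0]

    def test_single_point_matches_mean_contributions(self, fitted):
        from ehirisk.gamm import adjust_probability

        f, info = fitted
        surf = probability_surface(f, info, {})
        eta = sum(f.term_mean_contrib.values())
        assert surf["probability"].iloc[0] == pytest.approx(
            float(adjust_probability(expit(eta), info)), rel=1e-9)

    def test_unknown_term_error(self, fitted):
        f, info = fitted
        with pytest.raises(ValueError, match="not a model term"):
            probability_surface(f, info, {"nope": [1, 2]})
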