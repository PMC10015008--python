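"""Odds-ratio extraction from a fitted GAMM.

Smooth terms have no single odds ratio, so interval odds ratios are
reported: OR(a -> b) = exp(f(b) - f(a)) with a delta-method confidence
interval from the coefficient covariance.  Categorical terms are compared
pairwise on the marginal-means scale (all other model terms held at their
mean fitted contribution over the training data, random effects at zero),
with a single-step multivariate-normal ("Tukey-type") adjustment of the
p-values over each contrast family.  Probability surfaces evaluate the
class-adjusted absolute probability over a covariate grid with non-varied
terms held at their means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .gamm import FittedGAMM, SamplingInfo, adjust_probability

__all__ = ["OREstimate", "smooth_interval_or", "pairwise_category_or",
           "probability_surface"]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class OREstimate:
    comparison: str
    or_: float
    ci_low: float
    ci_high: float
    statistic: float           # z ratio of the log-odds contrast
    p_adjusted: float | None   # multiplicity-adjusted (categorical only)

    def __post_init__(self):
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


def smooth_interval_or(fitted: FittedGAMM, term: str, a: float, b: float) -> OREstimate:
    """Odds ratio exp(f(b) - f(a)) for a smooth term, with 95% CI.

    ``a`` and ``b`` must lie within the term's training range.
    """
    if term not in fitted.design.smooths:
        raise ValueError(f"{term!r} is not a smooth term of this model")
    info = fitted.design.smooths[term]
    for v in (a, b):
        if not (info.xmin <= v <= info.xmax):
            raise ValueError(
                f"{term}={v} outside the training range [{info.xmin:g}, {info.xmax:g}]"
            )
    sl = fitted.design.slices[f"s({term})"]
    X = info.design(np.array([a, b], dtype=float), clamp_warn=False)
    x = X[1] - X[0]
    diff = float(x @ fitted.beta[sl])
    var = float(x @ fitted.cov_fixed[sl.start:sl.stop, sl.start:sl.stop] @ x)
    se = np.sqrt(max(var, 0.0))
    z = diff / se if se > 0 else 0.0
    return OREstimate(
        comparison=f"{term} {b:g} vs {a:g}",
        or_=float(np.exp(diff)),
        ci_low=float(np.exp(diff - _Z95 * se)),
        ci_high=float(np.exp(diff + _Z95 * se)),
        statistic=float(z),
        p_adjusted=None,
    )


def _single_step_adjust(t_obs: np.ndarray, corr: np.ndarray, rng_seed: int = 0,
                        n_draws: int = 200_000) -> np.ndarray:
    """Single-step adjusted p-values from the joint normal of the contrast
    statistics: p_i = P(max_j |Z_j| >= |t_i|).

    The max-|Z| distribution is evaluated by seeded Monte Carlo from the
    contrast correlation matrix (one draw batch serves every contrast), the
    same quantity multcomp/emmeans integrate numerically.
    """
    k = len(t_obs)
    if k == 1:
        return np.array([2 * stats.norm.sf(abs(t_obs[0]))])
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(rng_seed)
    z = rng.standard_normal((n_draws, k)) @ root.T
    maxabs = np.sort(np.abs(z).max(axis=1))
    idx = np.searchsorted(maxabs, np.abs(t_obs), side="left")
    out = 1.0 - idx / n_draws
    return np.clip(out, 0.5 / n_draws, 1.0)


def pairwise_category_or(fitted: FittedGAMM, term: str) -> list[OREstimate]:
    """All pairwise marginal-mean odds ratios for a categorical term.

    Marginal means hold every other model term at its mean fitted
    contribution over the training data and random effects at zero; the
    offsets cancel in the pairwise differences, which therefore reduce to
    contrasts of the term's treatment-coded coefficients.  P-values use the
    single-step multivariate-normal adjustment over the contrast family.
    """
    if term not in fitted.design.cat_levels:
        raise ValueError(f"{term!r} is not a categorical term of this model")
    levels = fitted.design.cat_levels[term]
    if len(levels) < 2:
        return []
    sl = fitted.design.slices[term]
    # coefficient vector on the marginal-mean (link) scale per level:
    # reference level contributes 0
    coefs = np.concatenate([[0.0], fitted.beta[sl]])
    # covariance including the implicit zero row/column of the reference
    V = np.zeros((len(levels), len(levels)))
    V[1:, 1:] = fitted.cov_fixed[sl.start:sl.stop, sl.start:sl.stop]

    pairs = list(combinations(range(len(levels)), 2))
    diffs, ses = [], []
    for i, j in pairs:
        c = np.zeros(len(levels)); c[i] = 1.0; c[j] = -1.0
        diffs.append(float(c @ coefs))
        ses.append(float(np.sqrt(max(c @ V @ c, 1e-300))))
    diffs = np.array(diffs); ses = np.array(ses)
    t = diffs / ses
    # correlation of the contrast statistics for the joint adjustment
    C = np.zeros((len(pairs), len(levels)))
    for r, (i, j) in enumerate(pairs):
        C[r, i] = 1.0; C[r, j] = -1.0
    cov_t = C @ V @ C.T
    d = np.sqrt(np.clip(np.diag(cov_t), 1e-300, None))
    corr = cov_t / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    p_adj = _single_step_adjust(t, corr)

    out = []
    for r, (i, j) in enumerate(pairs):
        out.append(
            OREstimate(
                comparison=f"{term} {levels[i]}/{levels[j]}",
                or_=float(np.exp(diffs[r])),
                ci_low=float(np.exp(diffs[r] - _Z95 * ses[r])),
                ci_high=float(np.exp(diffs[r] + _Z95 * ses[r])),
                statistic=float(t[r]),
                p_adjusted=float(p_adj[r]),
            )
        )
    return out


def effects_table(estimates: list[OREstimate]) -> pd.DataFrame:
    """Long-format effects report (one row per comparison)."""
    return pd.DataFrame(
        {
            "comparison": [e.comparison for e in estimates],
            "or": [e.or_ for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "statistic": [e.statistic for e in estimates],
            "p_adjusted": [e.p_adjusted for e in estimates],
        }
    )


def probability_surface(
    fitted: FittedGAMM,
    sampling: SamplingInfo,
    grid: dict,
) -> pd.DataFrame:
    """Class-adjusted probability over a covariate grid.

    ``grid`` maps a subset of model terms (smooth variable names,
    categorical term names) to the values to vary; all other terms are held
    at their mean fitted contribution over the training data, random
    effects at zero.  Returns a long-format table keyed by the grid
    covariates with a ``probability`` column.
    """
    names = list(grid)
    mesh = [m.ravel() for m in np.meshgrid(*[np.asarray(grid[v]) for v in names],
                                           indexing="ij")]
    n = len(mesh[0]) if mesh else 1
    eta = np.zeros(n)
    varied = set()
    for v, values in zip(names, mesh):
        if v in fitted.design.smooths:
            tname = f"s({v})"
            info = fitted.design.smooths[v]
            sl = fitted.design.slices[tname]
            eta += info.design(values.astype(float)) @ fitted.beta[sl]
            varied.add(tname)
        elif v in fitted.design.cat_levels:
            levels = fitted.design.cat_levels[v]
            sl = fitted.design.slices[v]
            codes = pd.Categorical(pd.Series(values).astype(str), categories=levels).codes
            if np.any(codes < 0):
                raise ValueError(f"unknown level for {v!r} in grid")
            coefs = np.concatenate([[0.0], fitted.beta[sl]])
            eta += coefs[codes]
            varied.add(v)
        else:
            raise ValueError(f"{v!r} is not a model term")
    for tname, contrib in fitted.term_mean_contrib.items():
        if tname not in varied:
            eta += contrib
    p = adjust_probability(expit(eta), sampling)
    out = pd.DataFrame({v: m for v, m in zip(names, mesh)})
    out["probability"] = p
    return out
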