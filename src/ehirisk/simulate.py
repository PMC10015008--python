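"""Synthetic race-population generator with known ground truth.

Emulates the statistical structure the risk-factor analysis assumes:

* a rare binary outcome (~0.1% of runners) driven by smooth covariate
  effects (race distance, WBGT, preceding 5-day temperature average, age),
  categorical effects (going, year, off-time band, previous incident) and
  random intercepts for horse and race meet;
* horses with multi-run careers, so the previous-incident flag evolves
  sequentially as incidents occur;
* runners clustered in race meets that share a course-date weather record
  (seasonal sinusoid + AR(1) noise, humidity negatively correlated with
  temperature);
* structural confounding without direct effects: jump races are longer and
  run by older horses, going follows a rainfall proxy, sex has no effect.

Default true effects are piecewise-linear interpolants (library-independent)
anchored so that the headline contrasts of the real-data analysis hold
exactly on the log-odds scale:

    f_dist(3520) - f_dist(1760) = ln 5.66
    f_wbgt(30)   - f_wbgt(20)   = ln 10.14
    f_prev5(25)  - f_prev5(15)  = ln 0.33
    f_age(4)     - f_age(2)     = ln 1.34
    f_age(6)     - f_age(4)     = ln 0.82
    beta_prev                   = ln 18.59
    beta_off (pre vs post 5pm)  = ln 1.478

The intercept is calibrated by bisection so the expected prevalence matches
``prevalence_target`` (previous-incident state taken at its pre-outcome
value of zero; the realised prevalence runs ~1-2% higher, well inside
sampling noise at the default scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .wbgt import wbgt_from_weather

__all__ = [
    "GeneratorConfig",
    "GeneratorTruth",
    "simulate_weather",
    "simulate_population",
    "true_linear_predictor",
    "DEFAULT_SMOOTH_TRUTHS",
]

def _default_truth_tables() -> dict:
    """Smooth default effect curves tabulated on dense grids.

    The curves are smooth closed forms (so a penalised spline can track them
    without systematic bias) sampled onto dense piecewise-linear tables (so
    the stored truth is library-independent); every anchored contrast point
    lies exactly on its grid.

    * distance: logarithmic, slope fixed so a doubling from 1 to 2 miles
      multiplies the odds by 5.66;
    * WBGT: gentle exponential, scaled so 30 degC vs 20 degC gives 10.14;
    * preceding 5-day average: exactly linear, 25 vs 15 degC giving 0.33;
    * age: concave quadratic peaking near 4.2 years (4 vs 2 -> 1.34,
      6 vs 4 -> 0.82), flattening into a mild rise after age 10.
    """
    d = np.concatenate([np.arange(880.0, 7041.0, 220.0), [1760.0, 3520.0]])
    d = np.unique(d)
    f_d = (np.log(5.66) / np.log(2.0)) * np.log(d / 1760.0)

    w = np.arange(-8.0, 36.5, 0.5)
    # smooth hinge: flat in cold conditions, near-linear rise above ~12 degC,
    # scaled so the 30 vs 20 degC contrast is exactly ln 10.14
    tau, w0 = 4.0, 12.0
    g = tau * np.logaddexp(0.0, (w - w0) / tau)
    g20 = tau * np.logaddexp(0.0, (20.0 - w0) / tau)
    g30 = tau * np.logaddexp(0.0, (30.0 - w0) / tau)
    f_w = (np.log(10.14) / (g30 - g20)) * (g - g20)  # zero at 20 degC

    p5 = np.array([-10.0, 40.0])
    f_p5 = (np.log(0.33) / 10.0) * (p5 - 15.0)

    age = np.arange(1.0, 14.25, 0.25)
    # Gaussian bump peaking in early maturity, flat in the data-sparse old
    # ages; centre and amplitude solved so the two anchored age contrasts
    # (4 vs 2 -> 1.34, 6 vs 4 -> 0.82) hold exactly
    from scipy.optimize import brentq

    s_a = 3.2
    r = np.log(1.34) / np.log(0.82)

    def _g(a, m):
        return np.exp(-(((a - m) / s_a) ** 2))

    def _ratio(m):
        return (_g(4, m) - _g(2, m)) - r * (_g(6, m) - _g(4, m))

    m_a = brentq(_ratio, 3.0, 5.9)
    amp = np.log(1.34) / (_g(4, m_a) - _g(2, m_a))
    f_a = amp * (_g(age, m_a) - _g(2.0, m_a))  # zero at age 2

    return {
        "distance": (d.tolist(), f_d.tolist()),
        "wbgt": (w.tolist(), f_w.tolist()),
        "prev5": (p5.tolist(), f_p5.tolist()),
        "age": (age.tolist(), f_a.tolist()),
    }


DEFAULT_SMOOTH_TRUTHS = _default_truth_tables()

DEFAULT_BETA_GOING = {
    "firm": 0.0,
    "good": 0.529,   # ~ -ln(0.589)
    "soft": 0.753,   # ~ -ln(0.471)
    "heavy": 0.853,  # ~ -ln(0.426)
    "standard": -0.200,  # ~ -ln(1.222)
}

DEFAULT_BETA_YEAR = {
    "2010": 0.10, "2011": 0.15, "2012": 0.0, "2013": 0.0, "2014": 0.0,
    "2015": 0.25, "2016": 0.25, "2017": 0.55, "2018": 0.95,
}

_TURF_GOING = ["hard", "firm", "good to firm", "good", "good to soft", "soft", "heavy"]
_TURF_P = [0.01, 0.07, 0.18, 0.38, 0.20, 0.12, 0.04]
_AW_GOING = ["standard", "standard to slow", "slow", "fast"]
_AW_P = [0.92, 0.05, 0.0296, 0.0004]


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic population."""

    n_runners: int = 620_000
    n_horses: int | None = None  # default: scaled to the runner target
    n_courses: int = 59
    date_start: _date = _date(2010, 7, 1)
    date_end: _date = _date(2018, 4, 30)
    prevalence_target: float = 0.001
    smooth_truths: dict = field(default_factory=lambda: {
        k: (list(x), list(y)) for k, (x, y) in DEFAULT_SMOOTH_TRUTHS.items()
    })
    beta_prev: float = 2.9226   # ln 18.59
    beta_off: float = 0.3907    # pre-5pm vs post-5pm, ln 1.478
    beta_going: dict = field(default_factory=lambda: dict(DEFAULT_BETA_GOING))
    beta_year: dict = field(default_factory=lambda: dict(DEFAULT_BETA_YEAR))
    sigma_horse: float = 0.3
    sigma_meet: float = 0.2
    mean_runs: float = 10.0
    runners_per_meet: float = 85.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence_target < 0.5):
            raise ValueError("prevalence_target must lie in (0, 0.5)")
        if self.sigma_horse < 0 or self.sigma_meet < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if self.date_end <= self.date_start:
            raise ValueError("empty date range")
        if self.n_horses is None:
            # careers lose some runs to calendar clipping; oversample ~15%
            self.n_horses = max(10, int(self.n_runners * 1.15 / self.mean_runs))


@dataclass
class GeneratorTruth:
    """Resolved ground truth of one simulated population."""

    alpha: float
    smooth_truths: dict
    beta_prev: float
    beta_off: float
    beta_going: dict
    beta_year: dict
    b_horse: dict
    b_meet: dict
    eta: np.ndarray  # realised linear predictor per runner, runner order

    def smooth_effect(self, term: str, x) -> np.ndarray:
        """Evaluate a true smooth effect; out-of-support values raise."""
        xs, ys = self.smooth_truths[term]
        x = np.asarray(x, dtype=float)
        if np.any((x < xs[0]) | (x > xs[-1])):
            raise ValueError(f"{term} value outside generator support [{xs[0]}, {xs[-1]}]")
        return np.interp(x, xs, ys)

    def true_or(self, term: str, a: float, b: float) -> float:
        """Ground-truth odds ratio for the contrast ``b`` vs ``a``."""
        return float(np.exp(self.smooth_effect(term, b) - self.smooth_effect(term, a)))


def _seasonal_tmax(doy: np.ndarray) -> np.ndarray:
    # UK-like annual cycle: ~6 degC mean daily max in late January, ~21 in late July
    return 13.5 + 7.5 * np.cos(2 * np.pi * (doy - 205) / 365.25)


def simulate_weather(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily weather per course: seasonal sinusoid + AR(1) noise for tmax,
    humidity drawn with negative correlation to the temperature anomaly."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_days = (config.date_end - config.date_start).days + 1
    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = _seasonal_tmax(doy)

    eps = rng.normal(0.0, 3.5 * np.sqrt(1 - 0.55**2), size=(config.n_courses, n_days))
    anom = lfilter([1.0], [1.0, -0.55], eps, axis=1)
    tmax = np.clip(seasonal[None, :] + anom, -5.0, 38.0)
    rh = np.clip(
        82.0 - 1.1 * anom - 0.9 * (seasonal[None, :] - 13.5) + rng.normal(0, 6.0, size=tmax.shape),
        20.0, 100.0,
    )
    course_ids = np.array([f"C{i:02d}" for i in range(config.n_courses)])
    return pd.DataFrame(
        {
            "course_id": np.repeat(course_ids, n_days),
            "date": np.tile(dates.date, config.n_courses),
            "tmax": np.round(tmax.ravel(), 2),
            "rh": np.round(rh.ravel(), 1),
        }
    )


def _build_meets(config, rng, weather):
    """Race meets: course-dates with surface type, going and race cards."""
    n_meets = max(20, int(round(config.n_runners / config.runners_per_meet)))
    n_aw = max(2, config.n_courses // 10)
    n_flat_turf = max(2, int(0.30 * config.n_courses))
    surface = np.array(
        ["aw"] * n_aw + ["flat"] * n_flat_turf + ["jump"] * (config.n_courses - n_aw - n_flat_turf)
    )

    wb = weather.copy()
    wb["doy"] = pd.DatetimeIndex(pd.to_datetime(wb["date"])).dayofyear
    course_idx = wb["course_id"].str.slice(1).astype(int).to_numpy()
    wb["surface"] = surface[course_idx]

    # seasonal meet weighting: flat racing in summer, jump racing in winter
    summer = 0.5 + 0.5 * np.cos(2 * np.pi * (wb["doy"].to_numpy() - 205) / 365.25)
    weight = np.where(wb["surface"].to_numpy() == "jump", 1.2 - summer, 0.35 + summer)
    weight = np.clip(weight, 0.05, None)
    weight /= weight.sum()
    pick = rng.choice(len(wb), size=min(n_meets, len(wb)), replace=False, p=weight)
    meets = wb.iloc[np.sort(pick)].reset_index(drop=True)
    meets["meet_id"] = [f"M{i:05d}" for i in range(len(meets))]

    # going from a rainfall proxy: wetter when the temperature anomaly is low
    seasonal = _seasonal_tmax(meets["doy"].to_numpy())
    anom = meets["tmax"].to_numpy() - seasonal
    rain = -0.45 * anom / 3.0 + rng.normal(0, 0.9, size=len(meets))
    is_aw = meets["surface"].to_numpy() == "aw"
    turf_cut = np.quantile(rain[~is_aw], np.cumsum(_TURF_P)[:-1]) if (~is_aw).any() else []
    going = np.empty(len(meets), dtype=object)
    going[~is_aw] = np.array(_TURF_GOING)[np.searchsorted(turf_cut, rain[~is_aw])]
    going[is_aw] = rng.choice(_AW_GOING, size=int(is_aw.sum()), p=_AW_P)
    meets["going_raw"] = going

    # race cards: 6-7 races at ~32 min spacing; evening meets exist mostly
    # in summer (floodlit all-weather aside)
    n_races = rng.integers(6, 8, size=len(meets))
    start_minutes = rng.choice(
        [13 * 60 + 10, 13 * 60 + 50, 14 * 60 + 20, 15 * 60, 16 * 60 + 40, 17 * 60 + 30],
        p=[0.22, 0.22, 0.22, 0.14, 0.10, 0.10],
        size=len(meets),
    )
    race_rows = []
    for m in range(len(meets)):
        for r in range(n_races[m]):
            race_rows.append((m, start_minutes[m] + 32 * r))
    races = pd.DataFrame(race_rows, columns=["meet_idx", "off_minutes"])
    surface_m = meets["surface"].to_numpy()[races["meet_idx"]]
    dist = np.where(
        surface_m == "jump",
        rng.uniform(3200, 7040, size=len(races)),
        np.exp(rng.uniform(np.log(880), np.log(3520), size=len(races)))
    )
    races["distance"] = np.round(dist / 10) * 10
    races["race_id"] = [f"R{i:06d}" for i in range(len(races))]
    return meets, races


def _sample_careers(config, rng, meets):
    """Assign each horse a surface affinity and a set of meets to run at."""
    # overdispersed careers: many one-run horses, a long tail of campaigners
    runs = 1 + rng.negative_binomial(1.3, 1.3 / (1.3 + config.mean_runs - 1), size=config.n_horses)
    surface_groups = {
        s: np.flatnonzero(meets["surface"].to_numpy() == s) for s in ("flat", "aw", "jump")
    }
    horse_kind = rng.choice(["flat", "jump"], size=config.n_horses, p=[0.60, 0.40])
    debut_age = np.where(
        horse_kind == "jump",
        rng.integers(4, 7, config.n_horses),
        rng.choice([2, 3], size=config.n_horses, p=[0.7, 0.3]),
    )
    meet_dates = pd.to_datetime(meets["date"]).to_numpy()
    # pools sorted by date so career windows are contiguous index ranges
    pools = {
        "jump": surface_groups["jump"],
        "flat": np.concatenate([surface_groups["flat"], surface_groups["aw"]]),
    }
    pools = {k: v[np.argsort(meet_dates[v], kind="stable")] for k, v in pools.items()}

    n_h = config.n_horses
    # careers span multiple seasons (~10 runs a year with breaks), so a
    # horse's age advances across its racing record
    span_days = runs * 30 + 700
    t0 = rng.integers(0, max(1, (config.date_end - config.date_start).days - 60), size=n_h)
    d0 = np.datetime64(config.date_start) + t0
    d1 = d0 + span_days

    lo = np.empty(n_h, dtype=int)
    hi = np.empty(n_h, dtype=int)
    for kind, pool in pools.items():
        m = horse_kind == ("jump" if kind == "jump" else "flat")
        pool_dates = meet_dates[pool]
        lo[m] = np.searchsorted(pool_dates, d0[m], side="left")
        hi[m] = np.searchsorted(pool_dates, d1[m], side="right")
    width = np.maximum(hi - lo, 0)

    # batched sampling with replacement inside each career window; duplicate
    # meets and same-day runs are removed below, which thins long careers
    # slightly but keeps the draw fully vectorised
    horse_rep = np.repeat(np.arange(n_h), runs)
    keepable = width[horse_rep] > 0
    horse_rep = horse_rep[keepable]
    u = rng.random(len(horse_rep))
    pos = lo[horse_rep] + np.minimum((u * width[horse_rep]).astype(int),
                                     width[horse_rep] - 1)
    is_jump = horse_kind[horse_rep] == "jump"
    chosen = np.where(is_jump, pools["jump"][np.minimum(pos, len(pools["jump"]) - 1)],
                      pools["flat"][np.minimum(pos, len(pools["flat"]) - 1)])
    dts = meet_dates[chosen]
    order = np.lexsort((dts, horse_rep))
    horse_rep, chosen, dts = horse_rep[order], chosen[order], dts[order]
    first = np.ones(len(chosen), dtype=bool)
    first[1:] = (horse_rep[1:] != horse_rep[:-1]) | (dts[1:] != dts[:-1])
    horse_rep, chosen = horse_rep[first], chosen[first]

    yrs = pd.DatetimeIndex(meet_dates[chosen]).year.to_numpy()
    debut_year = np.zeros(n_h, dtype=int)
    starts = np.flatnonzero(np.r_[True, horse_rep[1:] != horse_rep[:-1]])
    debut_year[horse_rep[starts]] = yrs[starts]
    age = np.clip(debut_age[horse_rep] + (yrs - debut_year[horse_rep]), 1, 14)
    return horse_rep, chosen, age, horse_kind


def simulate_population(config: GeneratorConfig):
    """Simulate (runners, weather, truth).

    Returns a runners DataFrame in the interchange schema (plus nothing
    else), the weather DataFrame, and a :class:`GeneratorTruth` holding the
    resolved intercept, effect tables, realised random intercepts and the
    per-runner linear predictor.

    Outcomes are drawn sequentially per horse in date order, so the
    previous-incident state updates after each simulated incident.
    """
    rng = np.random.default_rng(config.seed)
    weather = simulate_weather(config, rng)
    meets, races = _build_meets(config, rng, weather)
    horse_idx, meet_idx, age, horse_kind = _sample_careers(config, rng, meets)

    n = len(horse_idx)
    if n > config.n_runners:
        keep = np.sort(rng.choice(n, size=config.n_runners, replace=False))
        horse_idx, meet_idx, age = horse_idx[keep], meet_idx[keep], age[keep]
        n = config.n_runners

    # vectorised uniform race choice within each meet's card
    u = rng.random(n)
    counts = races.groupby("meet_idx").size()
    race_start = np.zeros(len(meets), dtype=int)
    race_start[counts.index.to_numpy()] = np.concatenate([[0], np.cumsum(counts.to_numpy())[:-1]])
    n_races_per_meet = np.zeros(len(meets), dtype=int)
    n_races_per_meet[counts.index.to_numpy()] = counts.to_numpy()
    race_idx = race_start[meet_idx] + (u * n_races_per_meet[meet_idx]).astype(int)

    sex_pool = np.array(["filly", "colt", "gelding", "stallion", "rig"])
    flat_sex_p = [0.34, 0.22, 0.38, 0.0597, 0.0003]
    jump_sex_p = [0.25, 0.05, 0.65, 0.0497, 0.0003]
    horse_sex = np.where(
        horse_kind == "jump",
        rng.choice(sex_pool, size=config.n_horses, p=jump_sex_p),
        rng.choice(sex_pool, size=config.n_horses, p=flat_sex_p),
    )
    b_horse = rng.normal(0, config.sigma_horse, size=config.n_horses)
    b_meet = rng.normal(0, config.sigma_meet, size=len(meets))

    mrows = meets.iloc[meet_idx]
    rrows = races.iloc[race_idx]
    dates = pd.to_datetime(mrows["date"]).to_numpy()
    off_minutes = rrows["off_minutes"].to_numpy()
    wbgt = wbgt_from_weather(mrows["tmax"].to_numpy(), mrows["rh"].to_numpy())

    # preceding 5-day average straight from the complete simulated series
    wpivot = weather.pivot_table(index="date", columns="course_id", values="tmax")
    prev5_all = wpivot.rolling(5, min_periods=5).mean().shift(1)
    prev5 = prev5_all.to_numpy()[
        pd.Index(wpivot.index).get_indexer(mrows["date"]),
        pd.Index(wpivot.columns).get_indexer(mrows["course_id"]),
    ]

    going5_map = {
        "hard": "firm", "firm": "firm", "good to firm": "good", "good": "good",
        "good to soft": "soft", "soft": "soft", "heavy": "heavy",
        "standard": "standard", "standard to slow": "standard", "slow": "standard",
        "fast": "standard",  # excluded later anyway; effect value irrelevant
    }
    going_raw = mrows["going_raw"].to_numpy()
    going_eff = np.array([config.beta_going[going5_map[g]] for g in going_raw])
    year = pd.DatetimeIndex(dates).year.astype(str)
    year_eff = np.array([config.beta_year.get(y, 0.0) for y in year])
    pre5 = off_minutes < 17 * 60

    truth_tables = {k: (np.asarray(x, float), np.asarray(y, float))
                    for k, (x, y) in config.smooth_truths.items()}
    distance = rrows["distance"].to_numpy()
    eta0 = (
        np.interp(distance, *truth_tables["distance"])
        + np.interp(wbgt, *truth_tables["wbgt"])
        + np.interp(np.nan_to_num(prev5, nan=10.0), *truth_tables["prev5"])
        + np.interp(age, *truth_tables["age"])
        + going_eff
        + year_eff
        + config.beta_off * pre5
        + b_horse[horse_idx]
        + b_meet[meet_idx]
    )

    # group boundaries of the per-horse date-ordered runs
    order = np.lexsort((off_minutes, dates.astype("datetime64[D]").astype(int), horse_idx))
    h_sorted = horse_idx[order]
    starts = np.flatnonzero(np.r_[True, h_sorted[1:] != h_sorted[:-1]])
    lengths = np.diff(np.r_[starts, len(h_sorted)])
    max_runs = int(lengths.max()) if len(lengths) else 0

    def _expected_prevalence(alpha: float) -> float:
        # exact expectation of the sequential process: the previous-incident
        # state switches on after a horse's first incident
        q = np.zeros(config.n_horses)
        total = 0.0
        for j in range(max_runs):
            sel = starts[lengths > j] + j
            rows = order[sel]
            hs = h_sorted[sel]
            p0 = expit(alpha + eta0[rows])
            p1 = expit(alpha + eta0[rows] + config.beta_prev)
            qj = q[hs]
            total += float(np.sum((1 - qj) * p0 + qj * p1))
            q[hs] = qj + (1 - qj) * p0
        return total / n

    # intercept by bisection on the expected prevalence
    lo, hi = -30.0, 5.0
    target = config.prevalence_target
    if not (_expected_prevalence(lo) < target < _expected_prevalence(hi)):
        raise ValueError("cannot bracket intercept for requested prevalence")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _expected_prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)

    # sequential outcome draws in date order per horse so the
    # previous-incident flag updates after each simulated incident
    uni = rng.random(n)
    prev_state = np.zeros(config.n_horses, dtype=bool)
    y = np.zeros(n, dtype=np.int8)
    prev_flag = np.zeros(n, dtype=np.int8)
    eta_seq = alpha + eta0
    for j in range(max_runs):
        sel = starts[lengths > j] + j
        rows = order[sel]
        hs = h_sorted[sel]
        flag = prev_state[hs]
        prev_flag[rows] = flag
        p = expit(eta_seq[rows] + config.beta_prev * flag)
        hit = uni[rows] < p
        y[rows] = hit
        prev_state[hs[hit]] = True

    eta_final = eta_seq + config.beta_prev * prev_flag

    hh, mm = np.divmod(off_minutes.astype(int), 60)
    off_str = np.char.add(np.char.add(np.char.zfill(hh.astype(str), 2), ":"),
                          np.char.zfill(mm.astype(str), 2))
    runners = pd.DataFrame(
        {
            "horse_id": np.char.add("H", np.char.zfill(horse_idx.astype(str), 5)),
            "meet_id": mrows["meet_id"].to_numpy(),
            "course_id": mrows["course_id"].to_numpy(),
            "race_id": rrows["race_id"].to_numpy(),
            "date": pd.DatetimeIndex(dates).date,
            "off_time": off_str,
            "distance": distance,
            "race_type": np.where(np.isin(mrows["surface"].to_numpy(), ["jump"]), "jump", "flat"),
            "going_raw": going_raw,
            "age": age,
            "sex": horse_sex[horse_idx],
            "ehi": y.astype(int),
        }
    )
    truth = GeneratorTruth(
        alpha=alpha,
        smooth_truths={k: (x.tolist(), v.tolist()) for k, (x, v) in truth_tables.items()},
        beta_prev=config.beta_prev,
        beta_off=config.beta_off,
        beta_going=dict(config.beta_going),
        beta_year=dict(config.beta_year),
        b_horse={f"H{i:05d}": float(b) for i, b in enumerate(b_horse)},
        b_meet={m: float(b) for m, b in zip(meets["meet_id"], b_meet)},
        eta=eta_final,
    )
    return runners, weather, truth


def true_linear_predictor(truth: GeneratorTruth, covariates: pd.DataFrame) -> np.ndarray:
    """Recompute the generator's linear predictor for covariate rows.

    Expects columns distance, wbgt, prev5, age, prev_incident, going5, year,
    off_band, horse_id, meet_id.  Out-of-support smooth covariates raise.
    Unknown horse/meet identifiers contribute a zero random intercept.
    """
    eta = np.full(len(covariates), truth.alpha)
    for term in ("distance", "wbgt", "prev5", "age"):
        eta += truth.smooth_effect(term, covariates[term].to_numpy(float))
    eta += covariates["going5"].map(truth.beta_going).to_numpy(float)
    eta += covariates["year"].map(lambda y: truth.beta_year.get(str(y), 0.0)).to_numpy(float)
    eta += np.where(covariates["off_band"].to_numpy() == "pre5pm", truth.beta_off, 0.0)
    eta += truth.beta_prev * covariates["prev_incident"].to_numpy(float)
    eta += covariates["horse_id"].map(lambda h: truth.b_horse.get(h, 0.0)).to_numpy(float)
    eta += covariates["meet_id"].map(lambda m: truth.b_meet.get(m, 0.0)).to_numpy(float)
    return eta
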