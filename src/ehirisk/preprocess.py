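"""Exclusion filters and derived model covariates.

Produces the analysis-ready model frame: one row per retained runner with
the binary outcome, the environmental covariates (race-day WBGT and the
preceding 5-day temperature average), horse covariates (age, previous
incident), race covariates (distance, collapsed going, year, off-time band)
and the horse/meet grouping identifiers.

Exclusion rules, applied in order with per-rule counts logged:

1. rigs (a handful of cryptorchid males, too few to model as a sex level);
2. all runners at all-weather meets run on raw going "fast";
3. rows with any missing model covariate (typically an incomplete
   preceding-temperature window or a meet with no weather record).

The work is vectorised over pandas frames; the record-based entry points
convert and delegate.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time as _time

import numpy as np
import pandas as pd

from . import wbgt as _wbgt
from .records import SchemaError

__all__ = [
    "collapse_going",
    "derive_off_band",
    "derive_previous_incident",
    "exclusion_filter",
    "build_model_frame",
    "runners_to_frame",
    "MODEL_COLUMNS",
    "GOING_MAP",
]

# Turf raw categories map to four modelled levels, all-weather to one.
# All-weather "fast" does not map: those meets are excluded outright.
GOING_MAP = {
    "hard": "firm",
    "firm": "firm",
    "good to firm": "good",
    "good": "good",
    "good to soft": "soft",
    "soft": "soft",
    "heavy": "heavy",
    "standard": "standard",
    "standard to slow": "standard",
    "slow": "standard",
}

FIVE_PM = _time(17, 0)

MODEL_COLUMNS = [
    "ehi", "distance", "wbgt", "prev5", "age", "prev_incident",
    "going5", "year", "off_band", "race_type", "sex",
    "horse_id", "meet_id", "race_id",
]


def collapse_going(going_raw: str) -> str:
    """Collapse the 10 raw going categories to the 5 modelled levels.

    The unmodelled all-weather "fast" surface and unknown categories raise
    :class:`SchemaError`.
    """
    try:
        return GOING_MAP[going_raw]
    except KeyError:
        raise SchemaError(f"going category {going_raw!r} has no modelled level") from None


def derive_off_band(off_time: _time) -> str:
    """Pre/post 5 p.m. band; 17:00 exactly counts as post5pm."""
    return "pre5pm" if off_time < FIVE_PM else "post5pm"


def runners_to_frame(records) -> pd.DataFrame:
    """Convert RunnerRecord objects to the raw runners DataFrame."""
    return pd.DataFrame(
        {
            "horse_id": [r.horse_id for r in records],
            "meet_id": [r.meet_id for r in records],
            "course_id": [r.course_id for r in records],
            "race_id": [r.race_id for r in records],
            "date": [r.date for r in records],
            "off_time": [r.off_time for r in records],
            "distance": [r.distance for r in records],
            "race_type": [r.race_type for r in records],
            "going_raw": [r.going_raw for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "ehi": [r.ehi for r in records],
        }
    )


def weather_to_frame(weather) -> pd.DataFrame:
    if isinstance(weather, pd.DataFrame):
        return weather
    return pd.DataFrame(
        {
            "course_id": [w.course_id for w in weather],
            "date": [w.date for w in weather],
            "tmax": [w.tmax for w in weather],
            "rh": [w.rh for w in weather],
        }
    )


def _previous_incident_frame(df: pd.DataFrame) -> np.ndarray:
    """Vectorised strictly-prior previous-incident flag.

    The flag for a run is determined only by runs before it in
    (date, off_time) order within horse, so a run's own outcome never feeds
    its flag.  Identical (date, off_time) for one horse leaves the ordering
    undefined and raises.
    """
    work = df[["horse_id", "date", "off_time", "ehi"]].copy()
    work["_row"] = np.arange(len(work))
    work = work.sort_values(["horse_id", "date", "off_time"], kind="mergesort")
    dup = work.duplicated(subset=["horse_id", "date", "off_time"], keep=False)
    if dup.any():
        bad = work.loc[dup].iloc[0]
        raise ValueError(
            f"horse {bad['horse_id']!r} has two runs at identical date/off time "
            f"({bad['date']}, {bad['off_time']}); ordering undefined"
        )
    grp = work.groupby("horse_id", sort=False)["ehi"]
    earlier_cases = grp.cumsum() - work["ehi"]
    flags = (earlier_cases > 0).astype(int)
    out = np.empty(len(work), dtype=int)
    out[work["_row"].to_numpy()] = flags.to_numpy()
    return out


def derive_previous_incident(records) -> list[int]:
    """Record-based wrapper for the strictly-prior previous-incident flag."""
    return _previous_incident_frame(runners_to_frame(records)).tolist()


@dataclass
class ExclusionLog:
    rig: int = 0
    aw_fast: int = 0
    missing: int = 0

    def total(self) -> int:
        return self.rig + self.aw_fast + self.missing

    def to_dict(self) -> dict:
        return {"rig": self.rig, "aw_fast": self.aw_fast, "missing": self.missing}


def exclusion_filter(frame: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the three exclusion rules in order on an assembled frame.

    Expects raw columns ``sex``, ``going_raw`` and the model covariates
    (missingness is judged on distance/wbgt/prev5/age).  Idempotent.
    """
    log = ExclusionLog()
    keep = frame["sex"] != "rig"
    log.rig = int((~keep).sum())
    frame = frame[keep]

    keep = frame["going_raw"] != "fast"
    log.aw_fast = int((~keep).sum())
    frame = frame[keep]

    covariate_cols = [c for c in ("distance", "wbgt", "prev5", "age") if c in frame.columns]
    keep = frame[covariate_cols].notna().all(axis=1)
    log.missing = int((~keep).sum())
    frame = frame[keep]
    return frame.reset_index(drop=True), log


def _prev5_table(weather: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Per (course_id, date): mean tmax over the ``window`` preceding days.

    Days absent from the weather table count as missing, and any missing day
    in the window makes the average missing (never a shortened mean).
    """
    pieces = []
    for course, grp in weather.groupby("course_id", sort=False):
        s = pd.Series(grp["tmax"].to_numpy(), index=pd.DatetimeIndex(pd.to_datetime(grp["date"])))
        s = s.sort_index()
        full = s.reindex(pd.date_range(s.index.min(), s.index.max(), freq="D"))
        prev = full.rolling(window, min_periods=window).mean().shift(1)
        pieces.append(
            pd.DataFrame({"course_id": course, "date": prev.index.date, "prev5": prev.to_numpy()})
        )
    return pd.concat(pieces, ignore_index=True)


def build_model_frame(runners, weather) -> tuple[pd.DataFrame, ExclusionLog]:
    """Join runners to race-day weather, derive covariates, apply exclusions.

    Accepts RunnerRecord/WeatherDay collections or equivalent DataFrames.
    Returns the model frame (columns :data:`MODEL_COLUMNS`) and the
    exclusion log.  Rows whose meet has no weather record, or whose
    preceding 5-day temperature window is incomplete, become missing and are
    excluded with a logged count.
    """
    df = runners if isinstance(runners, pd.DataFrame) else runners_to_frame(runners)
    df = df.copy()
    wdf = weather_to_frame(weather)

    df["prev_incident"] = _previous_incident_frame(df)

    day = wdf[["course_id", "date", "tmax", "rh"]].copy()
    ok = day["rh"].notna() & day["tmax"].notna()
    day.loc[ok, "wbgt"] = _wbgt.wbgt_from_weather(
        day.loc[ok, "tmax"].to_numpy(), day.loc[ok, "rh"].to_numpy()
    )
    df = df.merge(day[["course_id", "date", "wbgt"]], on=["course_id", "date"], how="left")
    df = df.merge(_prev5_table(wdf), on=["course_id", "date"], how="left")

    df, log = exclusion_filter(df)
    df["going5"] = df["going_raw"].map(GOING_MAP)
    df["year"] = pd.to_datetime(df["date"]).dt.year.astype(str)
    off = df["off_time"]
    if len(off) and isinstance(off.iloc[0], str):
        # "HH:MM" strings order lexicographically as times
        df["off_band"] = np.where(off.to_numpy() < "17:00", "pre5pm", "post5pm")
    else:
        df["off_band"] = np.where([t < FIVE_PM for t in off], "pre5pm", "post5pm")
    return df[MODEL_COLUMNS].copy(), log
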