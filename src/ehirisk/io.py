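"""CSV readers and writers for the runner and weather record schemas.

runners.csv columns:
    horse_id,meet_id,course_id,race_id,date,off_time,distance_yards,
    race_type,going_raw,age,sex,ehi
weather.csv columns:
    course_id,date,tmax_c,rh_pct
"""

from __future__ import annotations

import csv
from datetime import date as _date, datetime, time as _time
from pathlib import Path

from .records import RunnerRecord, SchemaError, WeatherDay

RUNNER_COLUMNS = [
    "horse_id", "meet_id", "course_id", "race_id", "date", "off_time",
    "distance_yards", "race_type", "going_raw", "age", "sex", "ehi",
]
WEATHER_COLUMNS = ["course_id", "date", "tmax_c", "rh_pct"]


def _check_header(header, required, path):
    missing = [c for c in required if c not in (header or [])]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_date(s: str) -> _date:
    return datetime.strptime(s, "%Y-%m-%d").date()


def _parse_time(s: str) -> _time:
    return datetime.strptime(s, "%H:%M").time()


def read_runners(path) -> list[RunnerRecord]:
    """Read runner records from CSV, preserving row order.

    Raises :class:`SchemaError` naming the column on a bad header, and a
    row-level error naming the line number and field on an unparseable value.
    """
    path = Path(path)
    out: list[RunnerRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, RUNNER_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    RunnerRecord(
                        horse_id=row["horse_id"],
                        meet_id=row["meet_id"],
                        course_id=row["course_id"],
                        race_id=row["race_id"],
                        date=_parse_date(row["date"]),
                        off_time=_parse_time(row["off_time"]),
                        distance=float(row["distance_yards"]),
                        race_type=row["race_type"],
                        going_raw=row["going_raw"],
                        age=int(row["age"]),
                        sex=row["sex"],
                        ehi=int(row["ehi"]),
                    )
                )
            except (SchemaError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_runners(path, records) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(RUNNER_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.horse_id, r.meet_id, r.course_id, r.race_id,
                    r.date.isoformat(), r.off_time.strftime("%H:%M"),
                    f"{r.distance:g}", r.race_type, r.going_raw,
                    r.age, r.sex, r.ehi,
                ]
            )


def read_weather(path) -> list[WeatherDay]:
    """Read weather days from CSV; duplicate (course_id, date) keys are
    rejected, as is humidity outside [0, 100]."""
    path = Path(path)
    out: list[WeatherDay] = []
    seen: set[tuple] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, WEATHER_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = WeatherDay(
                    course_id=row["course_id"],
                    date=_parse_date(row["date"]),
                    tmax=float(row["tmax_c"]),
                    rh=float(row["rh_pct"]),
                )
            except (SchemaError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            key = (rec.course_id, rec.date)
            if key in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate weather key {key}")
            seen.add(key)
            out.append(rec)
    return out


def write_weather(path, records) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(WEATHER_COLUMNS)
        for r in records:
            w.writerow([r.course_id, r.date.isoformat(), f"{r.tmax:g}", f"{r.rh:g}"])


def weather_lookup(records) -> dict:
    """Index weather records as {(course_id, date): WeatherDay}."""
    return {(r.course_id, r.date): r for r in records}
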