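"""Shared fixtures: small synthetic populations and record fixtures."""

from datetime import date, time

import numpy as np
import pandas as pd
import pytest

from ehirisk.records import RunnerRecord, WeatherDay
from ehirisk.simulate import GeneratorConfig, simulate_population
from ehirisk.preprocess import build_model_frame


@pytest.fixture(scope="session")
def small_population():
    """A ~15k-runner population at 1% prevalence: large enough for a stable
    GAMM fit, small enough for fast tests."""
    cfg = GeneratorConfig(n_runners=15_000, prevalence_target=0.01, seed=5)
    runners, weather, truth = simulate_population(cfg)
    return runners, weather, truth


@pytest.fixture(scope="session")
def small_frame(small_population):
    runners, weather, truth = small_population
    frame, log = build_model_frame(runners, weather)
    return frame, log, truth


def make_runner(**kw):
    base = dict(
        horse_id="H1", meet_id="M1", course_id="C1", race_id="R1",
        date=date(2015, 7, 1), off_time=time(14, 30), distance=1760.0,
        race_type="flat", going_raw="good", age=4, sex="gelding", ehi=0,
    )
    base.update(kw)
    return RunnerRecord(**base)


def make_weather(**kw):
    base = dict(course_id="C1", date=date(2015, 7, 1), tmax=20.0, rh=60.0)
    base.update(kw)
    return WeatherDay(**base)


@pytest.fixture
def runner_factory():
    return make_runner


@pytest.fixture
def weather_factory():
    return make_weather
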