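"""Shared fixtures: one seeded weather season and the six preset runs.

The expensive artifacts (a full synthetic season and the six preset
simulations at seed 1) are built once per session and shared by the
calibration, property and acceptance tests.
"""

from __future__ import annotations

import pytest

from tomtwin.runner import RunConfig, run_season
from tomtwin.strategy import make_preset, preset_ids
from tomtwin.synthetic_weather import generate_weather

SEED = 1


@pytest.fixture(scope="session")
def season_weather():
    schedule, _ = make_preset(306)
    return generate_weather(schedule.start, schedule.end, seed=SEED)


@pytest.fixture(scope="session")
def six_runs(season_weather):
    """SeasonResult per preset id, all on the same seed-1 weather."""
    runs = {}
    for pid in preset_ids():
        config = RunConfig(preset=pid, weather_seed=SEED, quality_seed=SEED)
        runs[pid] = run_season(config, weather=season_weather)
    return runs


@pytest.fixture(scope="session")
def reference_run(six_runs):
    """The reference-grower archetype (compartment 303)."""
    return six_runs[303]
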