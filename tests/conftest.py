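from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

import regburden as rb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STUDY_START = dt.date(2000, 1, 1)
STUDY_END = dt.date(2015, 12, 31)
LOOKBACK = dt.date(1995, 1, 1)


@pytest.fixture(scope="session")
def demo_defs():
    from regburden.pipeline import demo_definitions

    return demo_definitions()


@pytest.fixture(scope="session")
def worked_defs():
    from regburden.pipeline import worked_example_definitions

    return worked_example_definitions()


def analyze(population, events, definitions, params=None):
    """Full point analysis; returns the intermediate objects tests inspect."""
    if params is None:
        params = rb.point_params(definitions)
    eff = {c: p.effective_dw for c, p in params.items()}
    windows = rb.build_windows(population, STUDY_START, STUDY_END)
    episodes = rb.build_episodes(
        events,
        windows,
        definitions,
        params=params,
        lookback_start=LOOKBACK,
        population=population,
    )
    segments = rb.build_segments(windows, episodes, eff)
    first = rb.first_diagnosis_days(events, LOOKBACK)
    return {
        "windows": windows,
        "episodes": episodes,
        "segments": segments,
        "first": first,
        "eff": eff,
        "person_years": rb.total_person_years(windows),
    }
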