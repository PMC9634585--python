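"""Synthetic register generator: reproducibility, zero-rate guarantees,
and statistical agreement with closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

import regburden as rb
from regburden.simulate import ConfigurationError
from regburden._dates import dates_to_days, to_day


def config(**kw):
    base = dict(n_persons=100, seed=1)
    base.update(kw)
    return rb.SimulationConfig(**base)


class TestGeneratePopulation:
    def test_zero_persons_rejected(self):
        with pytest.raises(Exception):
            rb.SimulationConfig(n_persons=0, seed=1)

    def test_zero_rates_mean_no_exits(self):
        pop = rb.generate_population(config(n_persons=1000))
        assert len(pop) == 1000
        assert pop["death_date"].isna().all()
        assert pop["emigration_date"].isna().all()
        assert pop["person_id"].is_unique

    def test_reproducible_given_seed(self):
        cfg = config(
            n_persons=500,
            mortality=[{"age_lo": 0, "age_hi": 110, "value": 0.01}],
            emigration_rate=0.01,
            immigration_fraction=0.2,
        )
        a = rb.generate_population(cfg)
        b = rb.generate_population(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = rb.generate_population(config(n_persons=500, seed=2, mortality=cfg.mortality))
        assert not a["birth_date"].equals(c["birth_date"])

    def test_ages_span_study_window(self):
        pop = rb.generate_population(config(n_persons=5000))
        births = dates_to_days(pop["birth_date"])
        start = to_day("2000-01-01")
        age_at_start = (start - births) / 365.25
        assert age_at_start.min() < 0  # born during the study
        assert age_at_start.max() > 90

    def test_death_count_matches_bernoulli_per_year_oracle(self):
        # flat 1%/year hazard over a 16-year horizon, everyone born at start
        cfg = config(
            n_persons=10_000,
            seed=11,
            mortality=[{"age_lo": 0, "age_hi": 110, "value": 0.01}],
        )
        pop = rb.generate_population(cfg)
        births = dates_to_days(pop["birth_date"])
        deaths = dates_to_days(pop["death_date"])
        horizon = 16 * 365.25
        died = ((deaths >= 0) & (deaths - births < horizon)).sum()
        # oracle: independent Bernoulli(q=0.01) per person-year for 16 years
        q = 0.01
        p16 = 1 - (1 - q) ** 16
        n = len(pop)
        sd = np.sqrt(n * p16 * (1 - p16))
        assert abs(died - n * p16) < 3 * sd


class TestGenerateDiagnoses:
    def test_zero_incidence_no_events(self, demo_defs):
        cfg = config(incidence={"mdd": {"base_rate": 0.0}})
        pop = rb.generate_population(cfg)
        events = rb.generate_diagnoses(pop, cfg, demo_defs)
        assert len(events) == 0

    def test_unknown_condition_rejected(self, demo_defs):
        cfg = config(incidence={"nope": {"base_rate": 0.1}})
        pop = rb.generate_population(cfg)
        with pytest.raises(ConfigurationError):
            rb.generate_diagnoses(pop, cfg, demo_defs)

    def test_comorbidity_without_definitions_rejected(self):
        cfg = config(
            incidence={"mdd": {"base_rate": 0.1}},
            comorbidity_rr={"mdd": {"ihd": 2.0}},
        )
        pop = rb.generate_population(cfg)
        with pytest.raises(ConfigurationError):
            rb.generate_diagnoses(pop, cfg)

    def test_reproducible_given_seed(self, demo_defs):
        cfg = config(
            n_persons=300,
            incidence={"mdd": {"base_rate": 0.05}, "ihd": {"base_rate": 0.03}},
            comorbidity_rr={"mdd": {"ihd": 2.0}},
            repeat_diagnosis_rate=0.5,
        )
        pop = rb.generate_population(cfg)
        a = rb.generate_diagnoses(pop, cfg, demo_defs)
        b = rb.generate_diagnoses(pop, cfg, demo_defs)
        pd.testing.assert_frame_equal(a, b)

    def test_first_event_fraction_matches_exponential_closed_form(self, demo_defs):
        # r = 0.1/year over 10 fully observed years: P(>=1 event) = 1 - e^{-1}
        cfg = rb.SimulationConfig(
            n_persons=10_000,
            seed=5,
            study_start="2000-01-01",
            study_end="2009-12-30",
            lookback_start="2000-01-01",
            incidence={"ihd": {"base_rate": 0.1}},
        )
        pop = rb.generate_population(cfg)
        # force full observation: everyone born at study start
        pop["birth_date"] = "2000-01-01"
        events = rb.generate_diagnoses(pop, cfg, demo_defs)
        n_with = events["person_id"].nunique()
        horizon_years = (to_day("2009-12-30") - to_day("2000-01-01")) / 365.25
        p = 1 - np.exp(-0.1 * horizon_years)
        sd = np.sqrt(10_000 * p * (1 - p))
        assert abs(n_with - 10_000 * p) < 3 * sd

    def test_events_respect_observability(self, demo_defs):
        cfg = config(
            n_persons=2000,
            seed=3,
            incidence={"mdd": {"base_rate": 0.1}, "ihd": {"base_rate": 0.05}},
            mortality=[{"age_lo": 0, "age_hi": 110, "value": 0.02}],
            emigration_rate=0.01,
            immigration_fraction=0.15,
            repeat_diagnosis_rate=0.3,
        )
        pop = rb.generate_population(cfg)
        events = rb.generate_diagnoses(pop, cfg, demo_defs)
        ev = events.merge(pop, on="person_id")
        days = dates_to_days(ev["event_date"])
        births = dates_to_days(ev["birth_date"])
        deaths = dates_to_days(ev["death_date"])
        emis = dates_to_days(ev["emigration_date"])
        imms = dates_to_days(ev["immigration_date"])
        lookback = to_day("1995-01-01")
        assert (days >= births).all()
        assert (days >= lookback).all()
        assert (days >= np.where(imms >= 0, imms, days)).all()
        assert (days <= np.where(deaths >= 0, deaths, days)).all()
        assert (days <= np.where(emis >= 0, emis, days)).all()
        assert (days <= to_day("2015-12-31")).all()


def _post_msd_hazard_ratio(pop, events, gmc="ihd", msd="mdd", end="2015-12-31"):
    """Person-time incidence-ratio oracle on the generator's own output."""
    end_day = to_day(end)
    births = dict(zip(pop["person_id"], dates_to_days(pop["birth_date"])))
    first = {}
    for row in events.itertuples():
        key = (row.person_id, row.condition_code)
        d = to_day(row.event_date)
        if key not in first or d < first[key]:
            first[key] = d
    pt = {True: 0.0, False: 0.0}
    ev = {True: 0, False: 0}
    for pid in pop["person_id"]:
        start = max(births[pid], to_day("1995-01-01"))
        stop = min(first.get((pid, gmc), end_day), end_day)
        a_day = first.get((pid, msd), end_day + 1)
        pre_end = min(stop, a_day)
        if pre_end > start:
            pt[False] += pre_end - start
        if stop > a_day:
            pt[True] += stop - a_day
        if (pid, gmc) in first and first[(pid, gmc)] <= end_day:
            ev[first[(pid, gmc)] > a_day] += 1
    return (ev[True] / pt[True]) / (ev[False] / pt[False])


class TestComorbidityStructure:
    def test_rate_ratio_recovered_from_person_time(self, demo_defs):
        cfg = rb.SimulationConfig(
            n_persons=50_000,
            seed=13,
            incidence={"mdd": {"base_rate": 0.03}, "ihd": {"base_rate": 0.01}},
            comorbidity_rr={"mdd": {"ihd": 3.0}},
        )
        pop = rb.generate_population(cfg)
        events = rb.generate_diagnoses(pop, cfg, demo_defs)
        hr = _post_msd_hazard_ratio(pop, events)
        assert hr == pytest.approx(3.0, rel=0.2)

    def test_null_rate_ratio_gives_equal_incidence(self, demo_defs):
        cfg = rb.SimulationConfig(
            n_persons=50_000,
            seed=17,
            incidence={"mdd": {"base_rate": 0.03}, "ihd": {"base_rate": 0.01}},
            comorbidity_rr={"mdd": {"ihd": 1.0}},
        )
        pop = rb.generate_population(cfg)
        events = rb.generate_diagnoses(pop, cfg, demo_defs)
        hr = _post_msd_hazard_ratio(pop, events)
        assert hr == pytest.approx(1.0, rel=0.15)
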