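"""Burden engine: timeline segmentation, population YLDs, HeLP and its
decomposition, age-band splitting, and agreement with the day-by-day oracle."""


import pandas as pd
import pytest

import regburden as rb
from regburden.cohort import FollowUpWindow
from regburden.conditions import MSD, ConditionDefinition, SeverityState, Uncertain
from regburden.engine import default_age_bands, validate_age_bands
from regburden.episodes import END_CENSORED, END_REMISSION, Episode

from tests.conftest import analyze
from tests.oracle import daily_help, daily_ylds

D = rb.cohort.to_day


def chronic(code, klass, category, dw):
    return ConditionDefinition(
        code,
        klass,
        category,
        (SeverityState(1.0, Uncertain.exact(dw)),),
        remission_rate=Uncertain.exact(0.0),
    )


class TestSegmentTimeline:
    WINDOW = FollowUpWindow("p", D("2000-01-01"), D("2010-01-01"), "admin_censor")

    def test_single_episode_gives_three_segments(self):
        eps = [Episode("p", "c", D("2002-01-01"), D("2005-01-01"), END_REMISSION)]
        segs = rb.segment_timeline(self.WINDOW, eps, {"c": 0.2})
        assert len(segs) == 3
        assert [s.active for s in segs] == [frozenset(), {"c"}, frozenset()]
        assert segs[1].combined_dw == pytest.approx(0.2)
        # segments tile the window
        assert segs[0].start_day == self.WINDOW.entry_day
        assert segs[-1].end_day == self.WINDOW.exit_day
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_day == b.start_day

    def test_no_episodes_single_zero_segment(self):
        segs = rb.segment_timeline(self.WINDOW, [], {})
        assert len(segs) == 1 and segs[0].combined_dw == 0.0

    def test_unclipped_episode_rejected(self):
        eps = [Episode("p", "c", D("1999-01-01"), D("2001-01-01"), END_REMISSION)]
        with pytest.raises(ValueError):
            rb.segment_timeline(self.WINDOW, eps, {"c": 0.2})

    def test_attribution_sums_to_combined_on_every_segment(self):
        eps = [
            Episode("p", "a", D("2001-01-01"), D("2006-01-01"), END_REMISSION),
            Episode("p", "b", D("2003-01-01"), D("2008-01-01"), END_REMISSION),
        ]
        segs = rb.segment_timeline(self.WINDOW, eps, {"a": 0.2, "b": 0.3})
        for s in segs:
            assert sum(s.attribution.values()) == pytest.approx(s.combined_dw, abs=1e-15)


class TestPopulationYlds:
    def test_single_chronic_condition_closed_form(self):
        # 8 years = exactly 2922 days: duration x dw with no rounding slack
        w = FollowUpWindow("p", D("2000-01-01"), D("2000-01-01") + 2922, "admin_censor")
        eps = [Episode("p", "c", w.entry_day, w.exit_day, END_CENSORED)]
        segs = {"p": rb.segment_timeline(w, eps, {"c": 0.2})}
        out = rb.population_ylds(segs, w.person_years)
        assert out.absolute_ylds == pytest.approx(1.6, abs=1e-9)
        assert out.person_years == pytest.approx(8.0, abs=1e-9)
        assert out.rate_per_100k == pytest.approx(20_000, abs=1e-6)

    def test_no_conditions_no_ylds(self):
        w = FollowUpWindow("p", D("2000-01-01"), D("2010-01-01"), "admin_censor")
        segs = {"p": rb.segment_timeline(w, [], {})}
        assert rb.population_ylds(segs, w.person_years).absolute_ylds == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            rb.population_ylds({}, 0.0)


def simulate_cohort(seed, n, demo_defs):
    """A small random cohort via the synthetic register generator."""
    config = rb.SimulationConfig(
        n_persons=n,
        seed=seed,
        incidence={
            "mdd": {"base_rate": 0.03},
            "anxiety": {"base_rate": 0.02},
            "ihd": {"base_rate": 0.02, "age_multipliers": [{"age_lo": 50, "age_hi": 95, "value": 3.0}]},
            "migraine": {"base_rate": 0.015},
            "asthma": {"base_rate": 0.02},
            "low_back_pain": {"base_rate": 0.03},
        },
        comorbidity_rr={"mdd": {"circulatory": 2.0, "asthma": 1.5}},
        mortality=[{"age_lo": 0, "age_hi": 60, "value": 0.002}, {"age_lo": 60, "age_hi": 110, "value": 0.03}],
        emigration_rate=0.005,
        immigration_fraction=0.1,
        repeat_diagnosis_rate=0.4,
    )
    pop = rb.generate_population(config)
    events = rb.generate_diagnoses(pop, config, demo_defs)
    return pop, events


class TestOracleEquivalence:
    def test_engine_matches_daily_oracle_on_random_cohorts(self, demo_defs):
        msd_codes = {c for c, d in demo_defs.items() if d.condition_class == MSD}
        for seed in range(10):
            pop, events = simulate_cohort(1000 + seed, 40, demo_defs)
            a = analyze(pop, events, demo_defs)
            # population YLDs
            got = rb.population_ylds(a["segments"], a["person_years"])
            total = 0.0
            for pid, w in a["windows"].items():
                t, _ = daily_ylds(w, a["episodes"].get(pid, []), a["eff"])
                total += t
            assert got.absolute_ylds == pytest.approx(total, abs=1e-6)
            # HeLP decomposition for an index disorder
            res = rb.help_for_index("mdd", a["segments"], a["windows"], a["first"], demo_defs)
            oracle_decomp, oracle_py = daily_help(
                "mdd", a["windows"], a["episodes"], a["eff"], a["first"], msd_codes
            )
            if res.n_exposed == 0:
                continue
            assert res.exposed_person_years == pytest.approx(oracle_py, abs=1e-9)
            for bucket, v in res.decomposition.items():
                assert v == pytest.approx(oracle_decomp.get(bucket, 0.0), abs=1e-9)


class TestHelpForIndex:
    def test_degenerate_index_only_recovers_weight(self):
        defs = {"idx": chronic("idx", MSD, "mental", 0.2)}
        pop = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "sex": ["female", "male"],
                "birth_date": ["1970-01-01", "1980-01-01"],
                "death_date": [None, None],
                "immigration_date": [None, None],
                "emigration_date": [None, None],
            }
        )
        events = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "condition_code": ["idx", "idx"],
                "event_date": ["2003-05-01", "2000-01-01"],
                "source": ["inpatient", "inpatient"],
            }
        )
        a = analyze(pop, events, defs)
        res = rb.help_for_index("idx", a["segments"], a["windows"], a["first"], defs)
        assert res.help_total == pytest.approx(0.2, abs=1e-12)
        assert res.decomposition == {"idx": pytest.approx(0.2)}

    def test_index_plus_comorbid_gmc_decomposition(self, worked_defs):
        pop, events, _ = rb.make_fixture("worked_example")
        a = analyze(pop, events, worked_defs)
        res = rb.help_for_index("index_msd", a["segments"], a["windows"], a["first"], worked_defs)
        assert res.help_total == pytest.approx(0.44, abs=1e-9)
        assert res.decomposition["index_msd"] == pytest.approx(0.176, abs=1e-9)
        assert res.decomposition["comorbid_gmc"] == pytest.approx(0.264, abs=1e-9)

    def test_conservation_and_monotonicity_on_random_cohorts(self, demo_defs):
        pop, events = simulate_cohort(7, 60, demo_defs)
        a = analyze(pop, events, demo_defs)
        for idx in ("mdd", "anxiety", rb.ANY_MSD):
            res = rb.help_for_index(idx, a["segments"], a["windows"], a["first"], demo_defs)
            assert sum(res.decomposition.values()) == pytest.approx(res.help_total, abs=1e-9)
            assert all(v >= 0 for v in res.decomposition.values())
            assert 0 <= res.help_total < 1
            assert res.exposed_person_years <= a["person_years"] + 1e-9

    def test_adding_comorbid_condition_never_decreases_help(self, worked_defs):
        # same cohort with and without the comorbid GMC active in everyone
        pop, events, _ = rb.make_fixture("worked_example")
        a = analyze(pop, events, worked_defs)
        res_with = rb.help_for_index("index_msd", a["segments"], a["windows"], a["first"], worked_defs)
        only_index = events[events["condition_code"] == "index_msd"]
        b = analyze(pop, only_index, worked_defs)
        res_without = rb.help_for_index("index_msd", b["segments"], b["windows"], b["first"], worked_defs)
        assert res_with.help_total >= res_without.help_total - 1e-12

    def test_zero_gmc_weights_reduce_to_msd_only_help(self, demo_defs):
        pop, events = simulate_cohort(21, 50, demo_defs)
        a = analyze(pop, events, demo_defs)
        res = rb.help_for_index("mdd", a["segments"], a["windows"], a["first"], demo_defs)
        msd_part = sum(
            v
            for k, v in res.decomposition.items()
            if k in demo_defs and demo_defs[k].condition_class == MSD
        )
        # zeroing GMC weights: only MSDs contribute
        eff0 = {
            c: (p if demo_defs[c].condition_class == MSD else 0.0)
            for c, p in a["eff"].items()
        }
        segs0 = rb.build_segments(a["windows"], a["episodes"], eff0)
        res0 = rb.help_for_index("mdd", segs0, a["windows"], a["first"], demo_defs)
        # the MSD-only HeLP is at least the MSD share of the combined analysis
        # (multiplicative crowding only reduces shares) and both stay in [0, 1)
        assert res0.help_total >= msd_part - 1e-12
        assert res0.n_exposed == res.n_exposed
        assert all(
            demo_defs[k].condition_class == MSD for k in res0.decomposition if res0.decomposition[k] > 0
        )

    def test_no_exposed_persons_gives_empty_result(self, demo_defs):
        pop, events, _ = rb.make_fixture("tiny")
        a = analyze(pop, events, demo_defs)
        res = rb.help_for_index("mdd", a["segments"], a["windows"], {}, demo_defs)
        assert res.n_exposed == 0 and res.help_total == 0.0


class TestAgeBands:
    def test_default_bands_partition(self):
        bands = default_age_bands()
        validate_age_bands(bands)
        assert bands[0] == (0, 5) and bands[-1] == (75, 95)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            validate_age_bands([(0, 50), (40, 95)])

    def test_single_band_equals_overall(self, worked_defs):
        pop, events, _ = rb.make_fixture("worked_example")
        a = analyze(pop, events, worked_defs)
        birth_days = dict(
            zip(pop["person_id"], rb.cohort.dates_to_days(pop["birth_date"]))
        )
        res = rb.help_for_index(
            "index_msd",
            a["segments"],
            a["windows"],
            a["first"],
            worked_defs,
            age_bands=[(0, 95)],
            birth_days=birth_days,
        )
        band = res.age_bands["0+"]
        assert band.help_total == pytest.approx(res.help_total, abs=1e-12)
        assert band.exposed_person_years == pytest.approx(res.exposed_person_years, abs=1e-9)

    def test_band_person_years_sum_to_total_exposure(self, demo_defs):
        pop, events = simulate_cohort(31, 60, demo_defs)
        a = analyze(pop, events, demo_defs)
        birth_days = dict(
            zip(pop["person_id"], rb.cohort.dates_to_days(pop["birth_date"]))
        )
        res = rb.help_by_age(
            "mdd", a["segments"], a["windows"], a["first"], demo_defs, birth_days
        )
        total_band_py = sum(b.exposed_person_years for b in res.age_bands.values())
        assert total_band_py == pytest.approx(res.exposed_person_years, abs=1e-6)
        # per-band conservation too
        for b in res.age_bands.values():
            assert sum(b.decomposition.values()) == pytest.approx(b.help_total, abs=1e-9)
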