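"""Synthetic population and diagnosis-event registers.

The real study population (all Danish residents 2000–2015, linked across the
civil, psychiatric and patient registers) is not publicly available, so this
module generates register-shaped tables with the statistical structure the
downstream analysis assumes: a closed cohort with entry by birth or
immigration and exit by death, 95th birthday, emigration or administrative
censoring; age- and sex-dependent diagnosis incidence; elevated GMC hazards
after a first MSD diagnosis (the comorbidity the analysis measures); repeat
diagnoses of the same disorder while an episode is active; and a pre-study
lookback period producing prevalent cases.

Event times are drawn from competing exponential clocks with
piecewise-constant hazards over age bands — the simplest process consistent
with "events per person-year" rate semantics.  All distributional choices
are stand-ins: nothing here is calibrated to Danish demography or incidence.
All dates are whole days; everything is deterministic given the seed.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from ._dates import DAYS_PER_YEAR, from_day, to_day
from .conditions import GMC, MSD, ConditionDefinition

MSD_SOURCES = ("inpatient", "outpatient", "emergency")
GMC_SOURCES = ("inpatient", "outpatient", "prescription")


class ConfigurationError(ValueError):
    """The simulation configuration is invalid."""


class AgeBandValue(BaseModel):
    """A value (rate or multiplier) constant over [age_lo, age_hi) years."""

    age_lo: float = Field(ge=0)
    age_hi: float
    value: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.age_hi <= self.age_lo:
            raise ValueError("age_hi must exceed age_lo")
        return self


class IncidenceModel(BaseModel):
    """Annual first-diagnosis rate: baseline × age multiplier × sex multiplier."""

    base_rate: float = Field(ge=0)
    age_multipliers: list[AgeBandValue] = []
    male_multiplier: float = Field(default=1.0, ge=0)

    def multiplier_at(self, age: float) -> float:
        for band in self.age_multipliers:
            if band.age_lo <= age < band.age_hi:
                return band.value
        return 1.0


class SimulationConfig(BaseModel):
    n_persons: int = Field(gt=0)
    seed: int = 0
    study_start: dt.date = dt.date(2000, 1, 1)
    study_end: dt.date = dt.date(2015, 12, 31)
    lookback_start: dt.date = dt.date(1995, 1, 1)
    max_age: int = 95
    incidence: dict[str, IncidenceModel] = {}
    #: MSD code -> (GMC code or broad category -> hazard ratio after first MSD dx)
    comorbidity_rr: dict[str, dict[str, float]] = {}
    mortality: list[AgeBandValue] = []  # annual death rate by age band
    emigration_rate: float = Field(default=0.0, ge=0)
    immigration_fraction: float = Field(default=0.0, ge=0, le=1)
    repeat_diagnosis_rate: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _date_order(self):
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        if not self.lookback_start <= self.study_start:
            raise ValueError("lookback_start must not be after study_start")
        return self

    @field_validator("comorbidity_rr")
    @classmethod
    def _rr_nonnegative(cls, v):
        for targets in v.values():
            for rr in targets.values():
                if rr < 0:
                    raise ValueError("rate ratios must be >= 0")
        return v


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "simulation" in raw:  # allow a combined pipeline+simulation file
        raw = raw["simulation"]
    return SimulationConfig.model_validate(raw)


def _validate_against_definitions(
    config: SimulationConfig, definitions: Mapping[str, ConditionDefinition]
) -> None:
    unknown = set(config.incidence) - set(definitions)
    if unknown:
        raise ConfigurationError(f"incidence configured for unknown conditions: {sorted(unknown)}")
    categories = {d.category for d in definitions.values()}
    for msd, targets in config.comorbidity_rr.items():
        if msd not in definitions or definitions[msd].condition_class != MSD:
            raise ConfigurationError(f"comorbidity_rr key {msd!r} is not a defined MSD")
        for tgt in targets:
            if tgt not in definitions and tgt not in categories:
                raise ConfigurationError(
                    f"comorbidity_rr target {tgt!r} is neither a condition nor a category"
                )


def _sample_death_ages(
    rng: np.random.Generator, n: int, mortality: list[AgeBandValue]
) -> np.ndarray:
    """Age at death from a piecewise-constant hazard; inf when never reached.

    The hazard is zero beyond the last configured band, so bands should
    cover the ages of interest (persons exit at the age cap regardless).
    """
    ages = np.full(n, np.inf)
    if not mortality:
        return ages
    target = rng.exponential(size=n)
    cum = 0.0
    for band in sorted(mortality, key=lambda b: b.age_lo):
        width = band.age_hi - band.age_lo
        if band.value > 0:
            need = target - cum
            hit = np.isinf(ages) & (need <= band.value * width)
            ages[hit] = band.age_lo + need[hit] / band.value
        cum += band.value * width
    return ages


def generate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Synthetic population table.

    Birth dates are uniform over the range putting ages 0 to `max_age` in
    the study window (so both children born during the study and the very
    old are represented); a configurable fraction immigrates after birth;
    deaths follow the age-band mortality hazard from birth and emigration a
    constant annual hazard.  Dates are ISO-8601 strings, missing as None.
    """
    if config.n_persons <= 0:  # pydantic enforces this; guard direct calls
        raise ConfigurationError("n_persons must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([_nonneg(config.seed), 0]))

    n = config.n_persons
    start, end = to_day(config.study_start), to_day(config.study_end)
    birth_lo = start - int(math.ceil(config.max_age * DAYS_PER_YEAR))
    birth = rng.integers(birth_lo, end + 1, size=n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")

    imm_flag = (rng.random(n) < config.immigration_fraction) & (birth < end)
    imm_u = rng.random(n)
    imm_day = birth + 1 + np.floor(imm_u * (end - birth)).astype(np.int64)

    death_age = _sample_death_ages(rng, n, config.mortality)
    death_day = np.where(
        np.isfinite(death_age),
        np.maximum(birth + 1, birth + np.round(death_age * DAYS_PER_YEAR)),
        -1,
    ).astype(np.int64)

    if config.emigration_rate > 0:
        entry = np.where(imm_flag, imm_day, birth)
        emi_years = rng.exponential(1.0 / config.emigration_rate, size=n)
        emi_day = np.maximum(
            entry + 1, entry + np.round(emi_years * DAYS_PER_YEAR).astype(np.int64)
        )
    else:
        emi_day = np.full(n, -1, dtype=np.int64)

    width = len(str(n))
    return pd.DataFrame(
        {
            "person_id": [f"p{i:0{width}d}" for i in range(n)],
            "sex": sex,
            "birth_date": [from_day(b).isoformat() for b in birth],
            "death_date": [
                from_day(d).isoformat() if d >= 0 else None for d in death_day
            ],
            "immigration_date": [
                from_day(d).isoformat() if f else None
                for d, f in zip(imm_day, imm_flag)
            ],
            "emigration_date": [
                from_day(d).isoformat() if d >= 0 and d > b else None
                for d, b in zip(emi_day, birth)
            ],
        }
    )


def _nonneg(seed: int) -> int:
    return seed if seed >= 0 else -seed + 2**31


def _hazard_segments(t0, t1, birth, inc: IncidenceModel, male: bool):
    """(start_day, end_day, annual_rate) pieces of an age-varying hazard."""
    rate0 = inc.base_rate * (inc.male_multiplier if male else 1.0)
    cuts = {t0, t1}
    for band in inc.age_multipliers:
        for age in (band.age_lo, band.age_hi):
            day = birth + int(round(age * DAYS_PER_YEAR))
            if t0 < day < t1:
                cuts.add(day)
    bounds = sorted(cuts)
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        age = (a - birth) / DAYS_PER_YEAR
        out.append((a, b, rate0 * inc.multiplier_at(age)))
    return out


def _split_at(segments, cut_days):
    """Further split hazard segments at the given absolute days."""
    out = list(segments)
    for day in sorted(cut_days):
        nxt = []
        for a, b, r in out:
            if a < day < b:
                nxt.extend([(a, day, r), (day, b, r)])
            else:
                nxt.append((a, b, r))
        out = nxt
    return out


def _first_event(rng, segments) -> int | None:
    """First event day from a piecewise-constant hazard, or None."""
    for a, b, rate in segments:
        if rate <= 0:
            continue
        t = a + rng.exponential(1.0 / rate) * DAYS_PER_YEAR
        if t < b:
            return int(t)
    return None


def generate_diagnoses(
    persons: pd.DataFrame,
    config: SimulationConfig,
    definitions: Mapping[str, ConditionDefinition] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic diagnosis events between the lookback start and each
    person's end of observability.

    MSD first diagnoses are drawn independently per condition; after a
    person's first MSD diagnosis, GMC hazards are multiplied by the
    configured rate ratios (keyed by GMC code or broad category,
    multiplicative across MSDs already diagnosed).  Remitting disorders
    additionally generate repeat-diagnosis events at `repeat_diagnosis_rate`
    while the expected-duration episode is active, so that downstream
    episode merging is exercised.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([_nonneg(config.seed), 1]))
    if definitions is not None:
        _validate_against_definitions(config, definitions)
    elif config.comorbidity_rr:
        raise ConfigurationError(
            "comorbidity_rr requires condition definitions to resolve classes"
        )

    def klass(code: str) -> str:
        return definitions[code].condition_class if definitions else MSD

    msd_codes = sorted(c for c in config.incidence if klass(c) == MSD)
    gmc_codes = sorted(c for c in config.incidence if klass(c) == GMC)

    lookback = to_day(config.lookback_start)
    end = to_day(config.study_end)

    birth = np.array([to_day(b) for b in persons["birth_date"]])
    death = np.array(
        [to_day(d) if d else end + 1 for d in persons["death_date"].fillna("")]
    )
    emi = np.array(
        [to_day(d) if d else end + 1 for d in persons["emigration_date"].fillna("")]
    )
    imm = np.array(
        [to_day(d) if d else -1 for d in persons["immigration_date"].fillna("")]
    )
    male = (persons["sex"] == "male").to_numpy()
    ids = persons["person_id"].astype(str).to_numpy()

    rows: list[tuple[str, str, int, str]] = []

    for i in range(len(persons)):
        t0 = max(int(birth[i]), lookback)
        if imm[i] >= 0:
            t0 = max(t0, int(imm[i]))
        t1 = min(int(death[i]), int(emi[i]), end)
        if t0 >= t1:
            continue

        msd_first: dict[str, int] = {}
        for code in msd_codes:
            segs = _hazard_segments(t0, t1, int(birth[i]), config.incidence[code], male[i])
            day = _first_event(rng, segs)
            if day is not None:
                msd_first[code] = day
                rows.append((ids[i], code, day, MSD_SOURCES[int(rng.integers(3))]))
                rows.extend(
                    _repeat_events(rng, ids[i], code, day, t1, config, definitions)
                )

        if not gmc_codes:
            continue
        msd_days = sorted(msd_first.values())
        for code in gmc_codes:
            segs = _hazard_segments(t0, t1, int(birth[i]), config.incidence[code], male[i])
            segs = _split_at(segs, [d for d in msd_days if t0 < d < t1])
            boosted = []
            for a, b, r in segs:
                mult = 1.0
                for msd, day in msd_first.items():
                    if day <= a:
                        targets = config.comorbidity_rr.get(msd, {})
                        if code in targets:
                            mult *= targets[code]
                        elif definitions and definitions[code].category in targets:
                            mult *= targets[definitions[code].category]
                boosted.append((a, b, r * mult))
            day = _first_event(rng, boosted)
            if day is not None:
                rows.append((ids[i], code, day, GMC_SOURCES[int(rng.integers(3))]))
                rows.extend(
                    _repeat_events(rng, ids[i], code, day, t1, config, definitions)
                )

    df = pd.DataFrame(rows, columns=["person_id", "condition_code", "_day", "source"])
    df = df.sort_values(["person_id", "_day", "condition_code"], kind="stable")
    df["event_date"] = [from_day(d).isoformat() for d in df["_day"]]
    return df[["person_id", "condition_code", "event_date", "source"]].reset_index(
        drop=True
    )


def _repeat_events(rng, pid, code, first_day, t_end, config, definitions):
    """Re-diagnosis events while the expected-duration episode is active."""
    if config.repeat_diagnosis_rate <= 0 or definitions is None:
        return []
    rate = definitions[code].remission_rate.value
    if rate <= 0:  # chronic: repeats would collapse into the same episode anyway
        return []
    dur = int(round(DAYS_PER_YEAR / rate))
    sources = MSD_SOURCES if definitions[code].condition_class == MSD else GMC_SOURCES
    out = []
    t = first_day
    episode_end = first_day + dur
    while True:
        gap = rng.exponential(1.0 / config.repeat_diagnosis_rate) * DAYS_PER_YEAR
        t = int(t + gap)
        if t >= min(episode_end, t_end) or gap < 1:
            break
        out.append((pid, code, t, sources[int(rng.integers(3))]))
        episode_end = max(episode_end, t + dur)
    return out
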