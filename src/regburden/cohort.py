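"""Follow-up windows and prevalent/incident classification.

Each resident is followed from the latest of birth, immigration and the study
start, until the earliest of death, the 95th birthday, emigration and the
study end.  Windows are half-open ``[entry, exit)`` in whole days;
person-years are days / 365.25.  A pre-study lookback window (default
1995-01-01 to the study start) identifies prevalent cases: conditions whose
first recorded diagnosis predates the person's entry.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import pandas as pd

from ._dates import DAYS_PER_YEAR, add_years, dates_to_days, from_day, to_day

logger = logging.getLogger(__name__)

EXIT_DEATH = "death"
EXIT_AGE95 = "age95"
EXIT_EMIGRATION = "emigration"
EXIT_ADMIN = "admin_censor"

PREVALENT = "prevalent"
INCIDENT = "incident"


@dataclass(frozen=True)
class Person:
    person_id: str
    sex: str
    birth_date: dt.date
    death_date: dt.date | None = None
    immigration_date: dt.date | None = None
    emigration_date: dt.date | None = None


@dataclass(frozen=True)
class FollowUpWindow:
    person_id: str
    entry_day: int
    exit_day: int
    exit_reason: str

    @property
    def entry_date(self) -> dt.date:
        return from_day(self.entry_day)

    @property
    def exit_date(self) -> dt.date:
        return from_day(self.exit_day)

    @property
    def days(self) -> int:
        return self.exit_day - self.entry_day

    @property
    def person_years(self) -> float:
        return self.days / DAYS_PER_YEAR


def follow_up_window(
    person: Person,
    study_start,
    study_end,
    max_age_years: int = 95,
) -> FollowUpWindow | None:
    """Entry/exit window for one person, or None if never under follow-up.

    Entry = max(birth, immigration, study start); exit = min(death, 95th
    birthday, emigration, study end).  Ties on exit are resolved in that
    order (death first).  Returns None when entry >= exit.
    """
    birth = to_day(person.birth_date)
    entry = max(birth, to_day(study_start))
    if person.immigration_date is not None:
        imm = to_day(person.immigration_date)
        if imm < birth:
            raise ValueError(f"{person.person_id}: immigration before birth")
        entry = max(entry, imm)

    age_cap = to_day(add_years(person.birth_date, max_age_years))
    candidates: list[tuple[int, str]] = [
        (to_day(study_end), EXIT_ADMIN),
        (age_cap, EXIT_AGE95),
    ]
    if person.death_date is not None:
        d = to_day(person.death_date)
        if d < birth:
            raise ValueError(f"{person.person_id}: death before birth")
        candidates.append((d, EXIT_DEATH))
    if person.emigration_date is not None:
        e = to_day(person.emigration_date)
        if e < birth:
            raise ValueError(f"{person.person_id}: emigration before birth")
        candidates.append((e, EXIT_EMIGRATION))

    priority = {EXIT_DEATH: 0, EXIT_AGE95: 1, EXIT_EMIGRATION: 2, EXIT_ADMIN: 3}
    exit_day, reason = min(candidates, key=lambda c: (c[0], priority[c[1]]))
    if entry >= exit_day:
        return None
    return FollowUpWindow(person.person_id, entry, exit_day, reason)


def build_windows(
    population: pd.DataFrame,
    study_start,
    study_end,
    max_age_years: int = 95,
) -> dict[str, FollowUpWindow]:
    """Windows for a whole population table; persons never at risk dropped."""
    start = to_day(study_start)
    end = to_day(study_end)
    birth = dates_to_days(population["birth_date"])
    death = dates_to_days(population.get("death_date", pd.Series([None] * len(population))))
    imm = dates_to_days(
        population.get("immigration_date", pd.Series([None] * len(population)))
    )
    emi = dates_to_days(
        population.get("emigration_date", pd.Series([None] * len(population)))
    )
    ids = population["person_id"].astype(str).to_numpy()

    windows: dict[str, FollowUpWindow] = {}
    dropped = 0
    for i in range(len(population)):
        b = int(birth[i])
        entry = max(b, start)
        if imm[i] >= 0:
            entry = max(entry, int(imm[i]))
        age_cap = to_day(add_years(from_day(b), max_age_years))
        # tie-break priority on equal exit days: death > age95 > emigration > admin
        exit_day, reason = end, EXIT_ADMIN
        if age_cap <= exit_day:
            exit_day, reason = age_cap, EXIT_AGE95
        if emi[i] >= 0 and (
            int(emi[i]) < exit_day or (int(emi[i]) == exit_day and reason == EXIT_ADMIN)
        ):
            exit_day, reason = int(emi[i]), EXIT_EMIGRATION
        if death[i] >= 0 and int(death[i]) <= exit_day:
            exit_day, reason = int(death[i]), EXIT_DEATH
        if entry >= exit_day:
            dropped += 1
            continue
        windows[ids[i]] = FollowUpWindow(ids[i], entry, exit_day, reason)
    if dropped:
        logger.info("dropped %d persons never under follow-up", dropped)
    return windows


def total_person_years(windows) -> float:
    vals = windows.values() if isinstance(windows, dict) else windows
    return sum(w.days for w in vals) / DAYS_PER_YEAR


def classify_prevalence(
    events: pd.DataFrame,
    window: FollowUpWindow,
    lookback_start,
) -> dict[str, str]:
    """Classify one person's conditions as prevalent or incident.

    A condition is prevalent when its first event (at or after the lookback
    start) predates window entry, incident otherwise; events before the
    lookback start are ignored entirely.
    """
    floor = to_day(lookback_start)
    out: dict[str, str] = {}
    if len(events) == 0:
        return out
    days = dates_to_days(events["event_date"])
    codes = events["condition_code"].to_numpy()
    firsts: dict[str, int] = {}
    for code, day in zip(codes, days):
        if day < floor:
            continue
        if code not in firsts or day < firsts[code]:
            firsts[code] = int(day)
    for code, day in firsts.items():
        out[code] = PREVALENT if day < window.entry_day else INCIDENT
    return out


def first_diagnosis_days(
    events: pd.DataFrame,
    lookback_start,
) -> dict[str, dict[str, int]]:
    """Per-person map of condition -> first event day (>= lookback start)."""
    floor = to_day(lookback_start)
    if len(events) == 0:
        return {}
    df = events.copy()
    df["_day"] = dates_to_days(df["event_date"])
    df = df[df["_day"] >= floor]
    firsts = df.groupby(["person_id", "condition_code"])["_day"].min()
    out: dict[str, dict[str, int]] = {}
    for (pid, code), day in firsts.items():
        out.setdefault(str(pid), {})[code] = int(day)
    return out


def windows_to_frame(windows: dict[str, FollowUpWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [w.person_id for w in windows.values()],
            "entry_date": [w.entry_date.isoformat() for w in windows.values()],
            "exit_date": [w.exit_date.isoformat() for w in windows.values()],
            "exit_reason": [w.exit_reason for w in windows.values()],
        }
    )
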