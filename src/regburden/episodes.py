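"""Turn diagnosis events into disability-accruing episodes.

GMCs are treated as chronic: no remission after onset, the episode runs until
censoring (death, emigration, 95th birthday or end of study).  MSD episodes
end at an expected remission date, onset + 1/rate years (or an exponential
draw with that mean under `mode="sampled"`).  Overlapping episodes of the
same disorder — a repeat diagnosis before the previous episode's remission —
are merged into one, taking the earliest onset and the latest end.  Episodes
are finally clipped to the person's follow-up window; prevalent episodes
(onset in the pre-study lookback) start accruing at window entry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._dates import dates_to_days, from_day, to_day, years_to_days, DAYS_PER_YEAR
from .cohort import FollowUpWindow
from .conditions import ConditionDefinition, DefinitionError
from .weights import ConditionParams

END_REMISSION = "remission"
END_CENSORED = "censored"

#: sentinel for an open (chronic, not yet clipped) episode end
OPEN_END = None


@dataclass(frozen=True)
class Episode:
    person_id: str
    condition_code: str
    onset_day: int
    end_day: int | None  # None while chronic and unclipped
    end_kind: str

    def __post_init__(self):
        if self.end_day is not None and not (self.onset_day < self.end_day):
            raise ValueError(
                f"episode must satisfy onset < end, got "
                f"[{self.onset_day}, {self.end_day})"
            )

    @property
    def onset_date(self):
        return from_day(self.onset_day)

    @property
    def end_date(self):
        return None if self.end_day is None else from_day(self.end_day)


def episode_from_event(
    event,
    definition: ConditionDefinition,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    *,
    params: ConditionParams | None = None,
    sex: str | None = None,
    age: float | None = None,
) -> Episode:
    """Episode implied by one diagnosis event.

    With remission rate r > 0 the duration is 1/r years (`mode="expected"`)
    or an exponential draw with mean 1/r (`mode="sampled"`); r = 0 means
    chronic, the episode stays open until clipping.  Durations are added in
    whole days (365.25 days/year, rounded to the nearest day, minimum 1).
    `sex`/`age` feed the optional stratified remission-rate lookup; `params`
    carries bootstrap-perturbed rates and overrides the definition's values.
    """
    pid = str(event.person_id if hasattr(event, "person_id") else event["person_id"])
    code = (
        event.condition_code
        if hasattr(event, "condition_code")
        else event["condition_code"]
    )
    day = to_day(event.event_date if hasattr(event, "event_date") else event["event_date"])

    if params is not None:
        rate = params.remission_for(sex, age)
    else:
        rate = definition.remission_for(sex, age).value
    if rate < 0:
        raise DefinitionError(f"{code}: negative remission rate {rate}")
    if rate == 0:
        return Episode(pid, code, day, OPEN_END, END_CENSORED)
    if mode == "expected":
        years = 1.0 / rate
    elif mode == "sampled":
        if rng is None:
            raise ValueError("mode='sampled' requires an rng")
        years = float(rng.exponential(1.0 / rate))
    else:
        raise ValueError(f"unknown duration mode {mode!r}")
    return Episode(pid, code, day, day + max(1, years_to_days(years)), END_REMISSION)


def merge_episodes(episodes: Sequence[Episode]) -> list[Episode]:
    """Merge overlapping episodes of one person-condition pair.

    Two episodes are combined when the remission date of the earlier one
    falls strictly after the onset of the later one; chains collapse into a
    single episode spanning earliest onset to latest end.  The union of
    covered days is preserved exactly.
    """
    if not episodes:
        return []
    pid = episodes[0].person_id
    code = episodes[0].condition_code
    for e in episodes:
        if e.person_id != pid or e.condition_code != code:
            raise ValueError("merge_episodes requires a single person-condition pair")
    ordered = sorted(episodes, key=lambda e: e.onset_day)
    merged = [ordered[0]]
    for e in ordered[1:]:
        cur = merged[-1]
        cur_end = np.inf if cur.end_day is None else cur.end_day
        if cur_end > e.onset_day:  # remission of first after onset of second
            if cur.end_day is None or e.end_day is None:
                new_end, end_kind = None, END_CENSORED
            else:
                later = cur if cur.end_day >= e.end_day else e
                new_end, end_kind = later.end_day, later.end_kind
            merged[-1] = replace(cur, end_day=new_end, end_kind=end_kind)
        else:
            merged.append(e)
    return merged


def clip_to_window(
    episodes: Iterable[Episode], window: FollowUpWindow
) -> list[Episode]:
    """Intersect episodes with the follow-up window [entry, exit).

    Episodes wholly outside the window are dropped; prevalent episodes start
    accruing at entry; open (chronic) episodes are closed at exit with
    end_kind "censored".
    """
    out = []
    for e in episodes:
        onset = max(e.onset_day, window.entry_day)
        end = window.exit_day if e.end_day is None else min(e.end_day, window.exit_day)
        if onset >= end:
            continue
        kind = e.end_kind
        if e.end_day is None or e.end_day > window.exit_day:
            kind = END_CENSORED
        out.append(replace(e, onset_day=onset, end_day=end, end_kind=kind))
    return out


def build_episodes(
    events: pd.DataFrame,
    windows: Mapping[str, FollowUpWindow],
    definitions: Mapping[str, ConditionDefinition],
    *,
    params: Mapping[str, ConditionParams] | None = None,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    lookback_start=None,
    population: pd.DataFrame | None = None,
) -> dict[str, list[Episode]]:
    """Clipped, merged episodes for every person under follow-up.

    Events before `lookback_start` (when given) are ignored; events for
    persons without a follow-up window are ignored.  When `population` is
    supplied, sex and age at diagnosis feed the stratified remission lookup.
    """
    if len(events) == 0:
        return {pid: [] for pid in windows}

    ev = events.copy()
    ev["_day"] = dates_to_days(ev["event_date"])
    if lookback_start is not None:
        ev = ev[ev["_day"] >= to_day(lookback_start)]
    ev["person_id"] = ev["person_id"].astype(str)
    ev = ev[ev["person_id"].isin(windows.keys())]

    unknown = set(ev["condition_code"]) - set(definitions)
    if unknown:
        raise DefinitionError(f"events reference undefined conditions: {sorted(unknown)}")

    sex_by_pid: dict[str, str] = {}
    birth_by_pid: dict[str, int] = {}
    if population is not None:
        bdays = dates_to_days(population["birth_date"])
        for i, pid in enumerate(population["person_id"].astype(str)):
            sex_by_pid[pid] = population["sex"].iloc[i]
            birth_by_pid[pid] = int(bdays[i])

    out: dict[str, list[Episode]] = {pid: [] for pid in windows}
    for (pid, code), grp in ev.groupby(["person_id", "condition_code"], sort=True):
        window = windows[pid]
        definition = definitions[code]
        sex = sex_by_pid.get(pid)
        birth = birth_by_pid.get(pid)
        raw = []
        for day in sorted(int(d) for d in grp["_day"]):
            age = None if birth is None else (day - birth) / DAYS_PER_YEAR
            if params is not None:
                rate = params[code].remission_for(sex, age)
            else:
                rate = definition.remission_for(sex, age).value
            if rate == 0:
                raw.append(Episode(pid, code, day, OPEN_END, END_CENSORED))
            elif mode == "expected":
                raw.append(
                    Episode(
                        pid,
                        code,
                        day,
                        day + max(1, years_to_days(1.0 / rate)),
                        END_REMISSION,
                    )
                )
            else:
                if rng is None:
                    raise ValueError("mode='sampled' requires an rng")
                years = float(rng.exponential(1.0 / rate))
                raw.append(
                    Episode(pid, code, day, day + max(1, years_to_days(years)), END_REMISSION)
                )
        out[pid].extend(clip_to_window(merge_episodes(raw), window))
    return out


def episodes_to_frame(episodes_by_person: Mapping[str, list[Episode]]) -> pd.DataFrame:
    rows = []
    for pid in episodes_by_person:
        for e in episodes_by_person[pid]:
            rows.append(
                {
                    "person_id": pid,
                    "condition_code": e.condition_code,
                    "onset_date": e.onset_date.isoformat(),
                    "end_date": "" if e.end_day is None else e.end_date.isoformat(),
                    "end_kind": e.end_kind,
                }
            )
    return pd.DataFrame(
        rows, columns=["person_id", "condition_code", "onset_date", "end_date", "end_kind"]
    )
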