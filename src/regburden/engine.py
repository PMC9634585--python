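"""Years lived with disability (YLDs) and the health loss proportion (HeLP).

Each person's follow-up window is segmented at every episode boundary, so
that the set of active conditions is constant within a segment.  The
segment's combined disability weight is the multiplicative combination
1 − Π(1 − wᵢ) of the active effective weights, attributed back to the active
conditions proportionally to their individual weights.

YLDs are attributed weight × segment duration in years; the population YLD
rate divides by person-years in the whole cohort.  The HeLP for an index
MSD divides the YLDs accrued by exposed persons — from their first index
diagnosis (window entry for prevalent cases) to window exit — by their
exposure person-years, and decomposes it additively into the index disorder,
each other comorbid MSD, and comorbid GMCs (by condition or broad category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._dates import DAYS_PER_YEAR, add_years, from_day, to_day
from .cohort import FollowUpWindow
from .conditions import MSD, ConditionDefinition
from .episodes import Episode
from .weights import attribute_combined, combine_multiplicative

logger = logging.getLogger(__name__)

#: pseudo-index meaning "first diagnosis of any mental/substance use disorder"
ANY_MSD = "any_msd"


@dataclass(frozen=True)
class Segment:
    person_id: str
    start_day: int
    end_day: int
    active: frozenset[str]
    combined_dw: float
    attribution: Mapping[str, float]

    @property
    def years(self) -> float:
        return (self.end_day - self.start_day) / DAYS_PER_YEAR


@dataclass(frozen=True)
class YldSummary:
    absolute_ylds: float
    person_years: float

    @property
    def rate_per_100k(self) -> float:
        return self.absolute_ylds / self.person_years * 100_000

    @property
    def help(self) -> float:
        """YLDs per person-year: the health loss proportion for this base."""
        return self.absolute_ylds / self.person_years


@dataclass
class HelpResult:
    index_condition: str
    decomposition: dict[str, float]  # bucket -> HeLP contribution
    exposed_person_years: float
    n_exposed: int
    bucket_counts: dict[str, int] = field(default_factory=dict)  # distinct persons
    age_bands: dict[str, "HelpResult"] | None = None

    @property
    def help_total(self) -> float:
        # total defined as the sum of its buckets, so conservation is exact
        return sum(self.decomposition.values())


def segment_timeline(
    window: FollowUpWindow,
    episodes: Sequence[Episode],
    effective_weights: Mapping[str, float],
) -> list[Segment]:
    """Split one person's window into segments of constant active conditions."""
    for e in episodes:
        if e.end_day is None or e.onset_day < window.entry_day or e.end_day > window.exit_day:
            raise ValueError(
                f"unclipped episode [{e.onset_day}, {e.end_day}) outside window "
                f"[{window.entry_day}, {window.exit_day})"
            )
    cuts = {window.entry_day, window.exit_day}
    for e in episodes:
        cuts.add(e.onset_day)
        cuts.add(e.end_day)
    bounds = sorted(cuts)
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        active = frozenset(
            e.condition_code for e in episodes if e.onset_day <= a and e.end_day >= b
        )
        if active:
            weights = {c: effective_weights[c] for c in sorted(active)}
            attribution = attribute_combined(weights)
            combined = combine_multiplicative(weights.values())
        else:
            attribution, combined = {}, 0.0
        segments.append(Segment(window.person_id, a, b, active, combined, attribution))
    return segments


def build_segments(
    windows: Mapping[str, FollowUpWindow],
    episodes_by_person: Mapping[str, Sequence[Episode]],
    effective_weights: Mapping[str, float],
) -> dict[str, list[Segment]]:
    return {
        pid: segment_timeline(w, list(episodes_by_person.get(pid, [])), effective_weights)
        for pid, w in windows.items()
    }


def population_ylds(
    segments_by_person: Mapping[str, Sequence[Segment]],
    person_years: float,
    include: Iterable[str] | None = None,
) -> YldSummary:
    """Absolute YLDs and rate per 100 000 person-years over the whole cohort.

    `include` restricts the attributed YLDs to a set of condition codes
    (e.g. only MSDs); person-years always cover the entire cohort.
    """
    if person_years <= 0:
        raise ValueError("population person-years must be positive")
    codes = None if include is None else set(include)
    total = 0.0
    for segments in segments_by_person.values():
        for s in segments:
            if not s.attribution:
                continue
            share = sum(
                v for c, v in s.attribution.items() if codes is None or c in codes
            )
            total += s.years * share
    return YldSummary(total, person_years)


def _bucket_of(
    code: str,
    index_condition: str,
    definitions: Mapping[str, ConditionDefinition],
    decomposition_level: str,
) -> str:
    if code == index_condition:
        return code
    d = definitions[code]
    if d.condition_class == MSD or decomposition_level == "condition":
        return code
    return d.category


def _exposure_start(
    index_condition: str,
    first_dx: Mapping[str, int],
    definitions: Mapping[str, ConditionDefinition],
) -> int | None:
    """First index-diagnosis day for one person, or None if unexposed."""
    if index_condition == ANY_MSD:
        days = [
            day
            for code, day in first_dx.items()
            if code in definitions and definitions[code].condition_class == MSD
        ]
        return min(days) if days else None
    return first_dx.get(index_condition)


def _band_label(lo: int, hi: int, max_age: int) -> str:
    return f"{lo}+" if hi >= max_age else f"{lo}-{hi - 1}"


def default_age_bands(width: int = 5, max_age: int = 95, open_from: int | None = 75):
    """5-year age bands on [0, max_age), with an open terminal band."""
    bands = []
    lo = 0
    while lo < max_age:
        if open_from is not None and lo >= open_from:
            bands.append((lo, max_age))
            break
        bands.append((lo, min(lo + width, max_age)))
        lo += width
    return bands


def validate_age_bands(age_bands: Sequence[tuple[int, int]], max_age: int = 95) -> None:
    prev_hi = 0
    for lo, hi in age_bands:
        if lo != prev_hi or hi <= lo:
            raise ValueError(f"age bands must partition [0, {max_age}) without overlap")
        prev_hi = hi
    if prev_hi != max_age:
        raise ValueError(f"age bands must cover [0, {max_age}), end at {prev_hi}")


def help_for_index(
    index_condition: str,
    segments_by_person: Mapping[str, Sequence[Segment]],
    windows: Mapping[str, FollowUpWindow],
    first_diagnosis: Mapping[str, Mapping[str, int]],
    definitions: Mapping[str, ConditionDefinition],
    *,
    decomposition_level: str = "condition",
    age_bands: Sequence[tuple[int, int]] | None = None,
    birth_days: Mapping[str, int] | None = None,
    max_age: int = 95,
    exposure_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> HelpResult:
    """HeLP for one index MSD, with additive decomposition.

    Exposure runs from the first index diagnosis (clipped to window entry for
    prevalent cases) to window exit; YLDs from all conditions accrued during
    exposure form the numerator, exposure person-years the denominator.
    `exposure_intervals` overrides the exposure definition (e.g. restrict to
    symptomatic index episodes).  With `age_bands`, exposure segments are
    split exactly at band-boundary birthdays and a per-band breakdown of the
    same structure is attached (requires `birth_days`).
    """
    if age_bands is not None:
        validate_age_bands(age_bands, max_age)
        if birth_days is None:
            raise ValueError("age-band breakdown requires birth days")

    decomposition: dict[str, float] = {}
    bucket_persons: dict[str, set[str]] = {}
    exposure_days = 0
    n_exposed = 0
    band_acc: dict[str, dict] = {}
    if age_bands is not None:
        for lo, hi in age_bands:
            band_acc[_band_label(lo, hi, max_age)] = {
                "decomp": {},
                "days": 0,
                "persons": set(),
                "bucket_persons": {},
            }

    for pid, window in windows.items():
        if exposure_intervals is not None:
            intervals = [
                (max(a, window.entry_day), min(b, window.exit_day))
                for a, b in exposure_intervals.get(pid, [])
            ]
            intervals = [(a, b) for a, b in intervals if a < b]
        else:
            start = _exposure_start(
                index_condition, first_diagnosis.get(pid, {}), definitions
            )
            if start is None:
                continue
            start = max(start, window.entry_day)
            if start >= window.exit_day:
                continue
            intervals = [(start, window.exit_day)]
        if not intervals:
            continue
        n_exposed += 1
        boundaries = None
        if age_bands is not None:
            birthday = from_day(birth_days[pid])
            boundaries = [
                (to_day(add_years(birthday, lo)), _band_label(lo, hi, max_age))
                for lo, hi in age_bands
            ]
        for a, b in intervals:
            exposure_days += b - a
            for s in segments_by_person.get(pid, []):
                lo_d, hi_d = max(s.start_day, a), min(s.end_day, b)
                if lo_d >= hi_d:
                    continue
                years = (hi_d - lo_d) / DAYS_PER_YEAR
                for code, v in s.attribution.items():
                    bucket = _bucket_of(code, index_condition, definitions, decomposition_level)
                    decomposition[bucket] = decomposition.get(bucket, 0.0) + years * v
                for code in s.active:
                    bucket = _bucket_of(code, index_condition, definitions, decomposition_level)
                    bucket_persons.setdefault(bucket, set()).add(pid)
            if boundaries is not None:
                _accrue_bands(
                    band_acc, boundaries, a, b, pid,
                    segments_by_person.get(pid, []),
                    index_condition, definitions, decomposition_level,
                )

    if n_exposed == 0:
        logger.warning("no persons exposed to index %s", index_condition)
        return HelpResult(index_condition, {}, 0.0, 0)

    exposure_py = exposure_days / DAYS_PER_YEAR
    result = HelpResult(
        index_condition,
        {k: v / exposure_py for k, v in _ordered(decomposition, index_condition, definitions).items()},
        exposure_py,
        n_exposed,
        {k: len(v) for k, v in bucket_persons.items()},
    )
    if age_bands is not None:
        result.age_bands = {}
        for label, acc in band_acc.items():
            py = acc["days"] / DAYS_PER_YEAR
            if py == 0:
                result.age_bands[label] = HelpResult(index_condition, {}, 0.0, 0)
                continue
            result.age_bands[label] = HelpResult(
                index_condition,
                {k: v / py for k, v in _ordered(acc["decomp"], index_condition, definitions).items()},
                py,
                len(acc["persons"]),
                {k: len(v) for k, v in acc["bucket_persons"].items()},
            )
    return result


def _accrue_bands(
    band_acc, boundaries, a, b, pid, segments, index_condition, definitions, level
):
    """Accrue one exposure interval into age bands, splitting at birthdays."""
    for i, (band_start, label) in enumerate(boundaries):
        band_end = boundaries[i + 1][0] if i + 1 < len(boundaries) else None
        lo = max(a, band_start)
        hi = b if band_end is None else min(b, band_end)
        if lo >= hi:
            continue
        acc = band_acc[label]
        acc["days"] += hi - lo
        acc["persons"].add(pid)
        for s in segments:
            s_lo, s_hi = max(s.start_day, lo), min(s.end_day, hi)
            if s_lo >= s_hi:
                continue
            years = (s_hi - s_lo) / DAYS_PER_YEAR
            for code, v in s.attribution.items():
                bucket = _bucket_of(code, index_condition, definitions, level)
                acc["decomp"][bucket] = acc["decomp"].get(bucket, 0.0) + years * v
            for code in s.active:
                bucket = _bucket_of(code, index_condition, definitions, level)
                acc["bucket_persons"].setdefault(bucket, set()).add(pid)


def _ordered(
    decomposition: Mapping[str, float],
    index_condition: str,
    definitions: Mapping[str, ConditionDefinition],
) -> dict[str, float]:
    """Index bucket first, then other MSDs, then GMC buckets, alphabetical."""
    def key(bucket: str):
        if bucket == index_condition:
            return (0, bucket)
        d = definitions.get(bucket)
        if d is not None and d.condition_class == MSD:
            return (1, bucket)
        return (2, bucket)

    return {k: decomposition[k] for k in sorted(decomposition, key=key)}


def help_by_age(
    index_condition: str,
    segments_by_person: Mapping[str, Sequence[Segment]],
    windows: Mapping[str, FollowUpWindow],
    first_diagnosis: Mapping[str, Mapping[str, int]],
    definitions: Mapping[str, ConditionDefinition],
    birth_days: Mapping[str, int],
    age_bands: Sequence[tuple[int, int]] | None = None,
    **kwargs,
) -> HelpResult:
    """HeLP with an age-band breakdown (default 5-year bands, open at 75+)."""
    if age_bands is None:
        age_bands = default_age_bands()
    return help_for_index(
        index_condition,
        segments_by_person,
        windows,
        first_diagnosis,
        definitions,
        age_bands=age_bands,
        birth_days=birth_days,
        **kwargs,
    )


def round_help(x: float) -> float:
    """Report HeLP to two decimals, matching the study's result style."""
    return round(x, 2)


def round_rate(x: float) -> int:
    """Report YLD rates per 100 000 person-years as whole numbers."""
    return int(round(x))
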