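"""Brute-force day-by-day oracles, independent of the interval-algebra engine.

These recompute YLDs and HeLP by materialising one value per calendar day of
follow-up: a boolean activity mask per condition, the multiplicative combined
weight per day, and proportional attribution per day.  They share no code
with regburden.engine beyond the weight definitions.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365.25


def daily_masks(window, episodes):
    """code -> boolean activity array over the window's days."""
    masks: dict[str, np.ndarray] = {}
    n = window.exit_day - window.entry_day
    for e in episodes:
        m = masks.setdefault(e.condition_code, np.zeros(n, dtype=bool))
        m[e.onset_day - window.entry_day : e.end_day - window.entry_day] = True
    return masks


def daily_ylds(window, episodes, eff_weights):
    """(total YLDs, per-condition attributed YLDs) by daily accumulation."""
    masks = daily_masks(window, episodes)
    codes = sorted(masks)
    if not codes:
        return 0.0, {}
    w = np.array([eff_weights[c] for c in codes])
    active = np.stack([masks[c] for c in codes])  # (codes, days)
    day_w = active * w[:, None]
    combined = 1.0 - np.prod(1.0 - day_w, axis=0)
    wsum = day_w.sum(axis=0)
    safe = np.where(wsum > 0, wsum, 1.0)
    shares = day_w * (combined / safe)[None, :]
    per_condition = {c: float(shares[i].sum()) / DAYS_PER_YEAR for i, c in enumerate(codes)}
    return float(combined.sum()) / DAYS_PER_YEAR, per_condition


def daily_help(index_code, windows, episodes_by_person, eff_weights, first_dx, msd_codes):
    """HeLP decomposition for an index disorder by daily accumulation."""
    num: dict[str, float] = {}
    denom_days = 0
    for pid, window in windows.items():
        fd = first_dx.get(pid, {})
        if index_code == "any_msd":
            days = [d for c, d in fd.items() if c in msd_codes]
            start = min(days) if days else None
        else:
            start = fd.get(index_code)
        if start is None:
            continue
        start = max(start, window.entry_day)
        if start >= window.exit_day:
            continue
        offset = start - window.entry_day
        masks = daily_masks(window, episodes_by_person.get(pid, []))
        denom_days += window.exit_day - start
        codes = sorted(masks)
        if not codes:
            continue
        w = np.array([eff_weights[c] for c in codes])
        active = np.stack([masks[c] for c in codes])[:, offset:]
        day_w = active * w[:, None]
        combined = 1.0 - np.prod(1.0 - day_w, axis=0)
        wsum = day_w.sum(axis=0)
        safe = np.where(wsum > 0, wsum, 1.0)
        shares = day_w * (combined / safe)[None, :]
        for i, c in enumerate(codes):
            num[c] = num.get(c, 0.0) + float(shares[i].sum()) / DAYS_PER_YEAR
    denom = denom_days / DAYS_PER_YEAR
    return {c: v / denom for c, v in num.items()}, denom


def union_days(intervals):
    """Total distinct covered days, by materialising the day set."""
    days = set()
    for a, b in intervals:
        days.update(range(a, b))
    return len(days)
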