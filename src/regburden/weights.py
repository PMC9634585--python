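"""Disability-weight algebra.

A condition's disability weight (DW) is the severity-weighted average of its
health-state weights, w = Σ pᵢwᵢ / Σ pᵢ.  Intermittent conditions are scaled
by their symptomatic fraction.  Concurrent conditions combine multiplicatively,
1 − Π(1 − wᵢ), so that no combination reaches 1, and the combined weight is
attributed back to the contributing conditions proportionally to their
individual weights.  Uncertain quantities are perturbed with triangular draws
for the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .conditions import (
    ConditionDefinition,
    DefinitionError,
    SeverityState,
    Uncertain,
)


def weighted_dw(states: Iterable[SeverityState]) -> Uncertain:
    """Severity-weighted disability weight: Σ(pᵢ·wᵢ) / Σpᵢ.

    Lower and upper bounds are combined the same way from the state bounds.
    Proportions may sum to less than 1 (register cases are never
    asymptomatic), hence the normalisation by Σpᵢ.
    """
    states = list(states)
    total = sum(s.proportion for s in states)
    if total <= 0:
        raise DefinitionError("severity proportions sum to 0")
    value = sum(s.proportion * s.dw.value for s in states) / total
    lower = sum(s.proportion * s.dw.lower for s in states) / total
    upper = sum(s.proportion * s.dw.upper for s in states) / total
    return Uncertain(value, lower, upper)


def apply_symptomatic_fraction(dw: Uncertain, fraction: float) -> Uncertain:
    """Scale a disability weight by the fraction of time symptomatic.

    Equivalent to scaling symptomatic time: a condition symptomatic 8.5% of
    the year accrues 8.5% of the YLDs an always-symptomatic condition with
    the same weight would.
    """
    if not (0 < fraction <= 1):
        raise DefinitionError(f"symptomatic fraction must be in (0, 1], got {fraction}")
    return Uncertain(dw.value * fraction, dw.lower * fraction, dw.upper * fraction)


def combine_multiplicative(weights: Iterable[float]) -> float:
    """Combined disability weight of concurrent conditions: 1 − Π(1 − wᵢ)."""
    combined_complement = 1.0
    for w in weights:
        if not (0 <= w < 1):
            raise DefinitionError(f"disability weight must be in [0, 1), got {w}")
        combined_complement *= 1.0 - w
    return 1.0 - combined_complement


def attribute_combined(weights: Mapping[str, float]) -> dict[str, float]:
    """Split the combined weight across conditions proportionally to wᵢ.

    The last share is computed by subtraction so the shares sum to the
    combined weight exactly.  All-zero weights yield all-zero shares.
    """
    if not weights:
        raise DefinitionError("attribute_combined requires at least one condition")
    combined = combine_multiplicative(weights.values())
    total = sum(weights.values())
    codes = list(weights)
    if total == 0:
        return {c: 0.0 for c in codes}
    out = {c: combined * weights[c] / total for c in codes}
    # close the float gap on the largest-weight condition so the shares sum
    # to the combined weight exactly (and zero-weight conditions stay at 0)
    largest = max(codes, key=lambda c: weights[c])
    out[largest] += combined - sum(out.values())
    return out


def perturb_triangular(q: Uncertain, rng: np.random.Generator) -> float:
    """One triangular draw on [lower, upper] with mode at the point value."""
    if q.lower == q.upper:
        return q.value
    return float(rng.triangular(q.lower, q.value, q.upper))


@dataclass(frozen=True)
class ConditionParams:
    """Resolved numeric parameters of a condition for one analysis run.

    Either point values (main estimate) or one triangular draw per quantity
    (a bootstrap iteration).  `effective_dw` is the severity-weighted weight
    scaled by the symptomatic fraction; it is what enters the multiplicative
    combination.
    """

    dw: float
    symptomatic_fraction: float
    remission_rate: float
    remission_strata: tuple[tuple[str | None, float, float, float], ...] = ()

    @property
    def effective_dw(self) -> float:
        return self.dw * self.symptomatic_fraction

    def remission_for(self, sex: str | None = None, age: float | None = None) -> float:
        if sex is not None or age is not None:
            for s_sex, lo, hi, rate in self.remission_strata:
                if s_sex is not None and (sex is None or s_sex != sex):
                    continue
                if age is not None and not (lo <= age < hi):
                    continue
                return rate
        return self.remission_rate


def point_params(
    definitions: Mapping[str, ConditionDefinition],
) -> dict[str, ConditionParams]:
    """Point (unperturbed) parameters for every condition."""
    out = {}
    for code, d in definitions.items():
        out[code] = ConditionParams(
            dw=weighted_dw(d.severity_states).value,
            symptomatic_fraction=d.symptomatic_fraction.value,
            remission_rate=d.remission_rate.value,
            remission_strata=tuple(
                (s.sex, s.age_lo, s.age_hi, s.rate.value) for s in d.remission_strata
            ),
        )
    return out


def perturbed_params(
    definitions: Mapping[str, ConditionDefinition],
    rng: np.random.Generator,
    *,
    perturb_dw: bool = True,
    perturb_remission: bool = True,
    perturb_symptomatic: bool = True,
) -> dict[str, ConditionParams]:
    """One triangular draw per uncertain quantity per condition.

    Draws are shared across all persons within an iteration: this models
    parameter uncertainty, not individual-level noise.  Conditions are
    visited in sorted order so the draw sequence is reproducible.
    """
    out = {}
    for code in sorted(definitions):
        d = definitions[code]
        dw_u = weighted_dw(d.severity_states)
        dw = perturb_triangular(dw_u, rng) if perturb_dw else dw_u.value
        rem = (
            perturb_triangular(d.remission_rate, rng)
            if perturb_remission
            else d.remission_rate.value
        )
        sf = (
            perturb_triangular(d.symptomatic_fraction, rng)
            if perturb_symptomatic
            else d.symptomatic_fraction.value
        )
        strata = tuple(
            (
                s.sex,
                s.age_lo,
                s.age_hi,
                perturb_triangular(s.rate, rng) if perturb_remission else s.rate.value,
            )
            for s in d.remission_strata
        )
        out[code] = ConditionParams(
            dw=dw, symptomatic_fraction=sf, remission_rate=rem, remission_strata=strata
        )
    return out
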