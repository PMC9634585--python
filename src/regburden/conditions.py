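"""Condition definitions: class (MSD/GMC), broad category, severity states,
remission behaviour and the intermittency (symptomatic-fraction) correction.

Each condition carries a severity distribution (proportion of cases in each
health state together with that state's disability weight and its uncertainty
interval), an annual remission rate (0 means chronic: no remission after
onset), and a symptomatic fraction in (0, 1] — 1 for every condition except
intermittent ones such as migraine, which the GBD studies treat as
symptomatic 8.5% of the year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MSD = "MSD"
GMC = "GMC"

#: the nine broad GMC categories used for grouping in reports
GMC_CATEGORIES = (
    "circulatory",
    "endocrine",
    "pulmonary",
    "gastrointestinal",
    "urogenital",
    "musculoskeletal",
    "haematological",
    "cancers",
    "neurological",
)


class DefinitionError(ValueError):
    """A condition definition violates its invariants."""


@dataclass(frozen=True)
class Uncertain:
    """A point value with a lower/upper uncertainty interval.

    Used for disability weights, remission rates and symptomatic fractions;
    the bootstrap perturbs these with triangular draws on [lower, upper]
    with mode at `value`.
    """

    value: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.value <= self.upper):
            raise DefinitionError(
                f"bounds must satisfy lower <= value <= upper, got "
                f"({self.lower}, {self.value}, {self.upper})"
            )

    @classmethod
    def exact(cls, value: float) -> "Uncertain":
        return cls(value, value, value)


@dataclass(frozen=True)
class SeverityState:
    """One health state of a condition: proportion of cases and its weight."""

    proportion: float
    dw: Uncertain

    def __post_init__(self):
        if self.proportion < 0:
            raise DefinitionError(f"negative severity proportion {self.proportion}")
        if not (0 <= self.dw.lower and self.dw.upper < 1):
            raise DefinitionError(
                f"state disability weight bounds must lie in [0, 1), got "
                f"[{self.dw.lower}, {self.dw.upper}]"
            )


@dataclass(frozen=True)
class RemissionStratum:
    """Optional sex/age-specific remission rate overriding the overall rate."""

    sex: str | None  # None matches both sexes
    age_lo: float
    age_hi: float
    rate: Uncertain


@dataclass(frozen=True)
class ConditionDefinition:
    code: str
    condition_class: str  # MSD or GMC
    category: str  # "mental" for MSDs, one of the nine broad GMC categories
    severity_states: tuple[SeverityState, ...]
    remission_rate: Uncertain  # events per year; 0 => chronic
    symptomatic_fraction: Uncertain = field(default_factory=lambda: Uncertain.exact(1.0))
    remission_strata: tuple[RemissionStratum, ...] = ()

    def __post_init__(self):
        if self.condition_class not in (MSD, GMC):
            raise DefinitionError(f"{self.code}: class must be MSD or GMC")
        if not self.severity_states:
            raise DefinitionError(f"{self.code}: at least one severity state required")
        total = sum(s.proportion for s in self.severity_states)
        # registers sample symptomatic cases only, so proportions may sum to <1
        if not (0 < total <= 1 + 1e-9):
            raise DefinitionError(
                f"{self.code}: severity proportions must sum to (0, 1], got {total}"
            )
        if self.remission_rate.lower < 0:
            raise DefinitionError(f"{self.code}: negative remission rate")
        sf = self.symptomatic_fraction
        if not (0 < sf.lower and sf.upper <= 1):
            raise DefinitionError(
                f"{self.code}: symptomatic fraction must lie in (0, 1]"
            )

    @property
    def chronic(self) -> bool:
        return self.remission_rate.value == 0

    def remission_for(self, sex: str | None = None, age: float | None = None) -> Uncertain:
        """Stratified remission-rate lookup; falls back to the overall rate."""
        if sex is not None or age is not None:
            for s in self.remission_strata:
                if s.sex is not None and sex is not None and s.sex != sex:
                    continue
                if age is not None and not (s.age_lo <= age < s.age_hi):
                    continue
                if s.sex is not None and sex is None:
                    continue
                return s.rate
        return self.remission_rate
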