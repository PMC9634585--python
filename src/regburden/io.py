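"""Readers and writers for the delimited-text table formats.

Column contracts (all dates ISO-8601, missing values empty):

* population.csv — person_id, sex, birth_date, death_date,
  immigration_date, emigration_date
* events.csv — person_id, condition_code, event_date, source
* conditions.csv — one row per severity state with condition-level columns
  repeated: condition_code, condition_class, category, state_proportion,
  state_dw, state_dw_lower, state_dw_upper, remission_rate,
  remission_rate_lower, remission_rate_upper, symptomatic_fraction,
  symptomatic_fraction_lower, symptomatic_fraction_upper
* remission_strata.csv (optional) — condition_code, sex, age_lo, age_hi,
  rate, rate_lower, rate_upper
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .conditions import (
    ConditionDefinition,
    DefinitionError,
    RemissionStratum,
    SeverityState,
    Uncertain,
)

POPULATION_COLUMNS = [
    "person_id",
    "sex",
    "birth_date",
    "death_date",
    "immigration_date",
    "emigration_date",
]
EVENT_COLUMNS = ["person_id", "condition_code", "event_date", "source"]
CONDITION_COLUMNS = [
    "condition_code",
    "condition_class",
    "category",
    "state_proportion",
    "state_dw",
    "state_dw_lower",
    "state_dw_upper",
    "remission_rate",
    "remission_rate_lower",
    "remission_rate_upper",
    "symptomatic_fraction",
    "symptomatic_fraction_lower",
    "symptomatic_fraction_upper",
]


class SchemaError(ValueError):
    """An input table does not match its column contract."""


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    _require(df, ["person_id", "sex", "birth_date"], path)
    for col in POPULATION_COLUMNS:
        if col not in df.columns:
            df[col] = None
    bad = ~df["sex"].isin(["female", "male"])
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise SchemaError(f"{path}: invalid sex values at rows {rows}")
    return df[POPULATION_COLUMNS]


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "condition_code": str})
    _require(df, EVENT_COLUMNS, path)
    return df[EVENT_COLUMNS]


def read_conditions(path) -> dict[str, ConditionDefinition]:
    df = pd.read_csv(path, dtype={"condition_code": str})
    _require(df, CONDITION_COLUMNS, path)
    return conditions_from_frame(df)


def conditions_from_frame(df: pd.DataFrame) -> dict[str, ConditionDefinition]:
    out: dict[str, ConditionDefinition] = {}
    for code, grp in df.groupby("condition_code", sort=True):
        states = tuple(
            SeverityState(
                float(r.state_proportion),
                Uncertain(float(r.state_dw), float(r.state_dw_lower), float(r.state_dw_upper)),
            )
            for r in grp.itertuples()
        )
        head = grp.iloc[0]
        for col in ("condition_class", "category", "remission_rate", "symptomatic_fraction"):
            if grp[col].nunique() != 1:
                raise SchemaError(
                    f"condition {code}: column {col} differs across severity-state rows"
                )
        try:
            out[str(code)] = ConditionDefinition(
                code=str(code),
                condition_class=str(head.condition_class),
                category=str(head.category),
                severity_states=states,
                remission_rate=Uncertain(
                    float(head.remission_rate),
                    float(head.remission_rate_lower),
                    float(head.remission_rate_upper),
                ),
                symptomatic_fraction=Uncertain(
                    float(head.symptomatic_fraction),
                    float(head.symptomatic_fraction_lower),
                    float(head.symptomatic_fraction_upper),
                ),
            )
        except DefinitionError as exc:
            raise SchemaError(f"condition {code}: {exc}") from exc
    return out


def read_remission_strata(
    path, definitions: dict[str, ConditionDefinition]
) -> dict[str, ConditionDefinition]:
    """Attach optional sex/age-stratified remission rates to definitions."""
    from dataclasses import replace

    df = pd.read_csv(path, dtype={"condition_code": str})
    _require(df, ["condition_code", "age_lo", "age_hi", "rate"], path)
    out = dict(definitions)
    for code, grp in df.groupby("condition_code", sort=True):
        if code not in out:
            raise SchemaError(f"{path}: stratified rates for undefined condition {code}")
        strata = tuple(
            RemissionStratum(
                sex=None if pd.isna(r.sex) else str(r.sex),
                age_lo=float(r.age_lo),
                age_hi=float(r.age_hi),
                rate=Uncertain(
                    float(r.rate),
                    float(getattr(r, "rate_lower", r.rate)),
                    float(getattr(r, "rate_upper", r.rate)),
                ),
            )
            for r in grp.itertuples()
        )
        out[code] = replace(out[code], remission_strata=strata)
    return out


def conditions_to_frame(definitions: Mapping[str, ConditionDefinition]) -> pd.DataFrame:
    rows = []
    for code in sorted(definitions):
        d = definitions[code]
        for s in d.severity_states:
            rows.append(
                {
                    "condition_code": code,
                    "condition_class": d.condition_class,
                    "category": d.category,
                    "state_proportion": s.proportion,
                    "state_dw": s.dw.value,
                    "state_dw_lower": s.dw.lower,
                    "state_dw_upper": s.dw.upper,
                    "remission_rate": d.remission_rate.value,
                    "remission_rate_lower": d.remission_rate.lower,
                    "remission_rate_upper": d.remission_rate.upper,
                    "symptomatic_fraction": d.symptomatic_fraction.value,
                    "symptomatic_fraction_lower": d.symptomatic_fraction.lower,
                    "symptomatic_fraction_upper": d.symptomatic_fraction.upper,
                }
            )
    return pd.DataFrame(rows, columns=CONDITION_COLUMNS)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table deterministically (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path
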