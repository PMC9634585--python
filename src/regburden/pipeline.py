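"""End-to-end pipeline: cohort → episodes → burden → privacy → bootstrap.

A validated YAML configuration names the three input tables and the analysis
settings; `run_pipeline` writes windows.csv, episodes.csv, ylds.csv,
help_results.csv (small-cell grouped), optional bootstrap CIs, and a
manifest recording the configuration hash and seed.  `make_fixture` builds
the small deterministic datasets used in the documentation and tests.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from ._dates import dates_to_days, from_day, to_day
from .bootstrap import BootstrapSpec, bootstrap_estimates
from .cohort import (
    build_windows,
    first_diagnosis_days,
    total_person_years,
    windows_to_frame,
)
from .conditions import GMC, MSD, ConditionDefinition, Uncertain, SeverityState
from .engine import (
    ANY_MSD,
    HelpResult,
    default_age_bands,
    help_for_index,
    population_ylds,
    build_segments,
)
from .episodes import build_episodes, episodes_to_frame
from .io import (
    conditions_to_frame,
    read_conditions,
    read_events,
    read_population,
    read_remission_strata,
    write_table,
)
from .privacy import ComorbidityCell, group_small_cells
from .weights import point_params

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    population: Path
    events: Path
    conditions: Path
    remission_strata: Path | None = None
    out_dir: Path = Path("out")
    study_start: dt.date = dt.date(2000, 1, 1)
    study_end: dt.date = dt.date(2015, 12, 31)
    lookback_start: dt.date = dt.date(1995, 1, 1)
    max_age: int = 95
    index_conditions: list[str] | None = None  # None: every MSD plus "any_msd"
    include_any_msd: bool = True
    age_band_width: int = 5
    age_band_open_from: int | None = 75
    decomposition_level: str = "condition"
    privacy_threshold: int = Field(default=5, ge=1)
    bootstrap: BootstrapSpec | None = None
    seed: int = 0
    log_level: str = "INFO"


def load_pipeline_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "pipeline" in raw:
        raw = raw["pipeline"]
    cfg = PipelineConfig.model_validate(raw)
    # resolve relative input paths against the config file's directory
    base = path.parent
    for f in ("population", "events", "conditions", "remission_strata", "out_dir"):
        v = getattr(cfg, f)
        if v is not None and not Path(v).is_absolute():
            setattr(cfg, f, base / v)
    return cfg


def _check_inputs(cfg: PipelineConfig) -> None:
    for f in ("population", "events", "conditions"):
        p = Path(getattr(cfg, f))
        if not p.exists():
            raise FileNotFoundError(f"{f} table not found: {p}")
    if cfg.remission_strata is not None and not Path(cfg.remission_strata).exists():
        raise FileNotFoundError(f"remission_strata table not found: {cfg.remission_strata}")


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def help_results_rows(
    result: HelpResult,
    definitions: Mapping[str, ConditionDefinition],
    threshold: int,
    age_band: str = "overall",
) -> list[dict]:
    """Flatten one HelpResult into grouped report rows.

    The index bucket is always reported as-is; comorbid cells go through the
    small-cell rule within their broad category.
    """
    rows = []
    comorbid = []
    for bucket, contribution in result.decomposition.items():
        n = result.bucket_counts.get(bucket, 0)
        if bucket == result.index_condition:
            rows.append(
                {
                    "bucket": bucket,
                    "category": "index",
                    "contribution": contribution,
                    "n_individuals": n,
                }
            )
            continue
        d = definitions.get(bucket)
        category = d.category if d is not None else bucket
        comorbid.append(
            ComorbidityCell(result.index_condition, bucket, category, n, contribution)
        )
    for cell in group_small_cells(comorbid, threshold):
        rows.append(
            {
                "bucket": cell.label,
                "category": cell.category,
                "contribution": cell.contribution,
                "n_individuals": cell.n_individuals,
            }
        )
    for r in rows:
        r.update(
            {
                "index_condition": result.index_condition,
                "age_band": age_band,
                "help_total": result.help_total,
                "exposed_person_years": result.exposed_person_years,
                "n_exposed": result.n_exposed,
            }
        )
    return rows


def make_estimator(
    definitions: Mapping[str, ConditionDefinition],
    study_start,
    study_end,
    lookback_start,
    index_conditions: Sequence[str],
    max_age: int = 95,
):
    """Wrap the burden engine as a (population, events, params) estimator."""

    msd_codes = {c for c, d in definitions.items() if d.condition_class == MSD}

    def estimator(population, events, params):
        windows = build_windows(population, study_start, study_end, max_age)
        if not windows:
            raise ValueError("no persons under follow-up")
        eff = {c: p.effective_dw for c, p in params.items()}
        episodes = build_episodes(
            events,
            windows,
            definitions,
            params=params,
            lookback_start=lookback_start,
            population=population,
        )
        segments = build_segments(windows, episodes, eff)
        py = total_person_years(windows)
        first = first_diagnosis_days(events, lookback_start)
        out = {
            "yld_rate_msd_per_100k": population_ylds(segments, py, include=msd_codes).rate_per_100k,
            "yld_rate_all_per_100k": population_ylds(segments, py).rate_per_100k,
        }
        for idx in index_conditions:
            res = help_for_index(idx, segments, windows, first, definitions)
            out[f"help_{idx}"] = res.help_total
        return out

    return estimator


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the in-memory results it wrote."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    _check_inputs(cfg)

    population = read_population(cfg.population)
    events = read_events(cfg.events)
    definitions = read_conditions(cfg.conditions)
    if cfg.remission_strata is not None:
        definitions = read_remission_strata(cfg.remission_strata, definitions)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        results = _compute(cfg, population, events, definitions, out_dir, written)
    except Exception:
        for p in written:  # do not leave partial output behind
            p.unlink(missing_ok=True)
        raise
    return results


def _compute(cfg, population, events, definitions, out_dir, written) -> dict:
    params = point_params(definitions)
    eff = {c: p.effective_dw for c, p in params.items()}

    windows = build_windows(population, cfg.study_start, cfg.study_end, cfg.max_age)
    written.append(write_table(windows_to_frame(windows), out_dir / "windows.csv"))

    episodes = build_episodes(
        events,
        windows,
        definitions,
        params=params,
        lookback_start=cfg.lookback_start,
        population=population,
    )
    written.append(write_table(episodes_to_frame(episodes), out_dir / "episodes.csv"))

    segments = build_segments(windows, episodes, eff)
    py = total_person_years(windows)
    msd_codes = sorted(c for c, d in definitions.items() if d.condition_class == MSD)
    gmc_codes = sorted(c for c, d in definitions.items() if d.condition_class == GMC)
    yld_rows = []
    for scope, include in (
        ("all", None),
        ("MSD", msd_codes),
        ("GMC", gmc_codes),
    ):
        s = population_ylds(segments, py, include=include)
        yld_rows.append(
            {
                "scope": scope,
                "absolute_ylds": s.absolute_ylds,
                "person_years": s.person_years,
                "rate_per_100k": s.rate_per_100k,
            }
        )
    ylds = pd.DataFrame(yld_rows)
    written.append(write_table(ylds, out_dir / "ylds.csv"))

    index_conditions = cfg.index_conditions
    if index_conditions is None:
        index_conditions = list(msd_codes) + ([ANY_MSD] if cfg.include_any_msd else [])

    first = first_diagnosis_days(events, cfg.lookback_start)
    birth_days = dict(
        zip(population["person_id"].astype(str), dates_to_days(population["birth_date"]))
    )
    bands = default_age_bands(cfg.age_band_width, cfg.max_age, cfg.age_band_open_from)

    help_rows = []
    help_results: dict[str, HelpResult] = {}
    for idx in index_conditions:
        res = help_for_index(
            idx,
            segments,
            windows,
            first,
            definitions,
            decomposition_level=cfg.decomposition_level,
            age_bands=bands,
            birth_days=birth_days,
            max_age=cfg.max_age,
        )
        help_results[idx] = res
        help_rows.extend(help_results_rows(res, definitions, cfg.privacy_threshold))
        for label, band_res in (res.age_bands or {}).items():
            if band_res.n_exposed == 0:
                continue
            help_rows.extend(
                help_results_rows(band_res, definitions, cfg.privacy_threshold, label)
            )
    help_df = pd.DataFrame(
        help_rows,
        columns=[
            "index_condition",
            "age_band",
            "bucket",
            "category",
            "contribution",
            "n_individuals",
            "help_total",
            "exposed_person_years",
            "n_exposed",
        ],
    )
    written.append(write_table(help_df, out_dir / "help_results.csv"))

    ci_df = None
    if cfg.bootstrap is not None:
        estimator = make_estimator(
            definitions,
            cfg.study_start,
            cfg.study_end,
            cfg.lookback_start,
            index_conditions,
            cfg.max_age,
        )
        cis = bootstrap_estimates(population, events, definitions, estimator, cfg.bootstrap)
        ci_df = pd.DataFrame(
            [
                {"quantity": k, "value": v.value, "lower": v.lower, "upper": v.upper}
                for k, v in cis.items()
            ]
        )
        written.append(write_table(ci_df, out_dir / "estimates_ci.csv"))

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_persons": int(len(population)),
        "n_windows": len(windows),
        "person_years": py,
        "outputs": sorted(p.name for p in written),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)

    return {
        "windows": windows,
        "episodes": episodes,
        "segments": segments,
        "ylds": ylds,
        "help_results": help_results,
        "help_table": help_df,
        "estimates_ci": ci_df,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# fixtures


def demo_definitions() -> dict[str, ConditionDefinition]:
    """A small condition set spanning the behaviours the engine must handle.

    Severity states and weights are GBD-style values; they are illustrative,
    not a reproduction of any study's supplementary tables.
    """
    u = Uncertain
    return {
        "mdd": ConditionDefinition(
            "mdd",
            MSD,
            "mental",
            (
                SeverityState(0.3, u(0.145, 0.099, 0.209)),
                SeverityState(0.5, u(0.396, 0.267, 0.531)),
                SeverityState(0.2, u(0.658, 0.477, 0.807)),
            ),
            remission_rate=u(0.5, 0.4, 0.6),
        ),
        "anxiety": ConditionDefinition(
            "anxiety",
            MSD,
            "mental",
            (SeverityState(0.8, u(0.133, 0.09, 0.186)),),
            remission_rate=u(0.2, 0.15, 0.25),
        ),
        "ihd": ConditionDefinition(
            "ihd",
            GMC,
            "circulatory",
            (SeverityState(1.0, u(0.08, 0.05, 0.11)),),
            remission_rate=u(0.0, 0.0, 0.0),
        ),
        "low_back_pain": ConditionDefinition(
            "low_back_pain",
            GMC,
            "musculoskeletal",
            (SeverityState(0.9, u(0.1, 0.07, 0.14)),),
            remission_rate=u(0.0, 0.0, 0.0),
        ),
        "asthma": ConditionDefinition(
            "asthma",
            GMC,
            "pulmonary",
            (SeverityState(1.0, u(0.036, 0.022, 0.055)),),
            remission_rate=u(0.0, 0.0, 0.0),
        ),
        "migraine": ConditionDefinition(
            "migraine",
            GMC,
            "neurological",
            (SeverityState(1.0, u(0.441, 0.294, 0.588)),),
            remission_rate=u(0.0, 0.0, 0.0),
            symptomatic_fraction=u(0.085, 0.058, 0.112),
        ),
    }


def worked_example_definitions() -> dict[str, ConditionDefinition]:
    """Two chronic conditions with weights 0.2 and 0.3: HeLP is 0.44 by hand."""
    u = Uncertain
    return {
        "index_msd": ConditionDefinition(
            "index_msd",
            MSD,
            "mental",
            (SeverityState(1.0, u(0.2, 0.1, 0.3)),),
            remission_rate=u(0.0, 0.0, 0.0),
        ),
        "comorbid_gmc": ConditionDefinition(
            "comorbid_gmc",
            GMC,
            "circulatory",
            (SeverityState(1.0, u(0.3, 0.2, 0.4)),),
            remission_rate=u(0.0, 0.0, 0.0),
        ),
    }


def _full_overlap_cohort(n: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Everyone carries both chronic conditions from window entry."""
    rng = np.random.default_rng(seed)
    start = to_day(dt.date(2000, 1, 1))
    births = rng.integers(to_day(dt.date(1940, 1, 1)), to_day(dt.date(2010, 1, 1)), n)
    death_offset = rng.integers(2 * 366, 80 * 366, size=n)
    width = len(str(n))
    pop_rows, ev_rows = [], []
    for i in range(n):
        pid = f"w{i:0{width}d}"
        b = int(births[i])
        death = b + int(death_offset[i])
        entry = max(b, start)
        pop_rows.append(
            {
                "person_id": pid,
                "sex": "female" if i % 2 == 0 else "male",
                "birth_date": from_day(b).isoformat(),
                "death_date": from_day(death).isoformat(),
                "immigration_date": None,
                "emigration_date": None,
            }
        )
        for code, source in (("index_msd", "inpatient"), ("comorbid_gmc", "outpatient")):
            ev_rows.append(
                {
                    "person_id": pid,
                    "condition_code": code,
                    "event_date": from_day(entry).isoformat(),
                    "source": source,
                }
            )
    return pd.DataFrame(pop_rows), pd.DataFrame(ev_rows)


def make_fixture(name: str, seed: int = 0):
    """Deterministic datasets: (population, events, definitions).

    * ``tiny`` — 5 persons covering the entry/exit edge cases (admin censor,
      age-95 exit, death, emigration, late entry by immigration) with
      prevalent and repeat diagnoses.
    * ``worked_example`` — 50 persons, all with chronic index MSD (dw 0.2)
      and chronic comorbid GMC (dw 0.3) from entry; HeLP 0.44 by hand.
    * ``recovery`` — the 20 000-person version of the same full-overlap
      design, used for parameter-recovery checks.
    """
    if name == "tiny":
        definitions = demo_definitions()
        pop = pd.DataFrame(
            [
                # full window, incident mdd with a repeat diagnosis
                ("t1", "female", "1985-06-01", None, None, None),
                # exits at 95th birthday in 2005
                ("t2", "male", "1910-03-15", None, None, None),
                # dies mid-study with a chronic GMC
                ("t3", "female", "1950-01-01", "2008-06-30", None, None),
                # emigrates mid-study
                ("t4", "male", "1970-05-20", None, None, "2010-01-01"),
                # immigrates mid-study with a prevalent (lookback) diagnosis
                ("t5", "female", "1960-09-09", None, "2003-03-01", None),
            ],
            columns=[
                "person_id",
                "sex",
                "birth_date",
                "death_date",
                "immigration_date",
                "emigration_date",
            ],
        )
        events = pd.DataFrame(
            [
                ("t1", "mdd", "2003-02-01", "inpatient"),
                ("t1", "mdd", "2004-06-01", "outpatient"),  # overlaps: merges
                ("t1", "asthma", "2005-01-01", "prescription"),
                ("t2", "ihd", "2001-07-01", "inpatient"),
                ("t3", "migraine", "2002-04-15", "prescription"),
                ("t3", "mdd", "2006-01-10", "emergency"),
                ("t4", "anxiety", "1997-05-01", "outpatient"),  # prevalent MSD
                ("t5", "mdd", "1998-11-20", "inpatient"),  # before immigration
                ("t5", "low_back_pain", "2004-08-01", "outpatient"),
            ],
            columns=["person_id", "condition_code", "event_date", "source"],
        )
        return pop, events, definitions
    if name == "worked_example":
        pop, events = _full_overlap_cohort(50, seed=seed + 11)
        return pop, events, worked_example_definitions()
    if name == "recovery":
        pop, events = _full_overlap_cohort(20_000, seed=seed + 17)
        return pop, events, worked_example_definitions()
    raise ValueError(f"unknown fixture {name!r}")


def write_fixture(name: str, out_dir, seed: int = 0) -> dict[str, Path]:
    pop, events, definitions = make_fixture(name, seed=seed)
    out_dir = Path(out_dir)
    return {
        "population": write_table(pop, out_dir / "population.csv"),
        "events": write_table(events, out_dir / "events.csv"),
        "conditions": write_table(conditions_to_frame(definitions), out_dir / "conditions.csv"),
    }
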