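"""Bootstrap confidence intervals for YLD rates and HeLP.

Each iteration resamples persons with replacement and redraws every
uncertain quantity (disability weights, remission rates, symptomatic
fractions) once per condition from a triangular distribution on its
uncertainty interval with mode at the point value.  Perturbed remission
rates change expected episode durations, so episodes are rebuilt inside
every iteration.  Confidence intervals are percentile intervals over the
iteration estimates; the point estimate comes from the unperturbed full
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .conditions import ConditionDefinition
from .weights import ConditionParams, perturbed_params, point_params

logger = logging.getLogger(__name__)

#: an estimator maps (population, events, per-condition params) -> named floats
Estimator = Callable[
    [pd.DataFrame, pd.DataFrame, Mapping[str, ConditionParams]], Mapping[str, float]
]


@dataclass(frozen=True)
class BootstrapSpec:
    n_iterations: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    perturb_dw: bool = True
    perturb_remission: bool = True
    perturb_symptomatic_fraction: bool = True
    resample_persons: bool = True
    max_failure_fraction: float = 0.01

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class EstimateCI:
    value: float
    lower: float
    upper: float


def resample_population(
    population: pd.DataFrame,
    events: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw persons with replacement; replicates get distinct person ids."""
    n = len(population)
    idx = rng.integers(0, n, size=n)
    pop = population.iloc[idx].reset_index(drop=True).copy()
    orig_ids = pop["person_id"].astype(str).to_numpy()
    new_ids = np.array([f"{pid}#{k}" for k, pid in enumerate(orig_ids)])
    pop["person_id"] = new_ids

    if len(events) == 0:
        return pop, events.copy()
    mapping = pd.DataFrame({"person_id": orig_ids, "_new_id": new_ids})
    ev = events.copy()
    ev["person_id"] = ev["person_id"].astype(str)
    ev = mapping.merge(ev, on="person_id", how="inner")
    ev["person_id"] = ev["_new_id"]
    return pop, ev.drop(columns="_new_id")


def bootstrap_estimates(
    population: pd.DataFrame,
    events: pd.DataFrame,
    definitions: Mapping[str, ConditionDefinition],
    estimator: Estimator,
    spec: BootstrapSpec,
) -> dict[str, EstimateCI]:
    """Point estimates with percentile bootstrap confidence intervals.

    The estimator is any reporting function of the burden engine wrapped to
    the (population, events, params) signature; it may return several named
    quantities, each of which receives its own interval.
    """
    rng = np.random.default_rng(spec.seed)
    point = dict(estimator(population, events, point_params(definitions)))
    draws: dict[str, list[float]] = {k: [] for k in point}
    any_perturb = (
        spec.perturb_dw or spec.perturb_remission or spec.perturb_symptomatic_fraction
    )

    failures = 0
    for _ in range(spec.n_iterations):
        if spec.resample_persons:
            pop_i, ev_i = resample_population(population, events, rng)
        else:
            pop_i, ev_i = population, events
        if any_perturb:
            params = perturbed_params(
                definitions,
                rng,
                perturb_dw=spec.perturb_dw,
                perturb_remission=spec.perturb_remission,
                perturb_symptomatic=spec.perturb_symptomatic_fraction,
            )
        else:
            params = point_params(definitions)
        try:
            est = estimator(pop_i, ev_i, params)
        except Exception:  # noqa: BLE001 - isolated iteration failure
            failures += 1
            logger.exception("bootstrap iteration failed")
            continue
        for k in draws:
            draws[k].append(float(est[k]))

    if failures > spec.max_failure_fraction * spec.n_iterations:
        raise RuntimeError(
            f"{failures}/{spec.n_iterations} bootstrap iterations failed"
        )

    alpha = (1 - spec.ci_level) / 2
    out = {}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        lo, hi = np.quantile(arr, [alpha, 1 - alpha])
        if not (lo <= point[k] <= hi):
            logger.warning(
                "percentile CI for %s does not contain the point estimate", k
            )
        out[k] = EstimateCI(point[k], float(lo), float(hi))
    return out
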