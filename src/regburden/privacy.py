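"""Small-cell grouping for reported comorbidity tables.

Comorbid conditions observed in fewer than five distinct individuals within
an index-disorder stratum are merged — smallest cell first — with other
conditions in the same broad category into an "other <category>" cell until
that cell reaches the threshold.  Categories that remain below the threshold
even after exhausting their own conditions are merged across categories into
a single "Other" cell.  Grouping conserves counts and contributions exactly
and applies to reporting only; internal computation always uses ungrouped
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

OTHER = "Other"


@dataclass(frozen=True)
class ComorbidityCell:
    index_condition: str
    label: str  # condition code, "other <category>", or "Other"
    category: str
    n_individuals: int
    contribution: float

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ValueError(f"negative cell count for {self.label}")


def _merge(cells: list[ComorbidityCell], label: str, category: str) -> ComorbidityCell:
    return ComorbidityCell(
        cells[0].index_condition,
        label,
        category,
        sum(c.n_individuals for c in cells),
        sum(c.contribution for c in cells),
    )


def group_small_cells(
    cells: list[ComorbidityCell], threshold: int = 5
) -> list[ComorbidityCell]:
    """Apply the small-cell rule to one index-disorder stratum.

    Merge order is deterministic: smallest count first, ties broken
    alphabetically by label.  If the entire stratum is below the threshold a
    single "Other" cell is returned with a logged warning.
    """
    if not cells:
        return []
    by_category: dict[str, list[ComorbidityCell]] = {}
    for c in cells:
        by_category.setdefault(c.category, []).append(c)

    kept: list[ComorbidityCell] = []
    leftover: list[ComorbidityCell] = []  # whole categories still sub-threshold
    for category in sorted(by_category):
        group = sorted(by_category[category], key=lambda c: (c.n_individuals, c.label))
        small = [c for c in group if c.n_individuals < threshold]
        ok = [c for c in group if c.n_individuals >= threshold]
        if not small:
            kept.extend(ok)
            continue
        pool = list(small)
        # absorb further (smallest-first) cells until the aggregate reaches
        # the threshold or the category is exhausted
        while sum(c.n_individuals for c in pool) < threshold and ok:
            pool.append(ok.pop(0))
        aggregate = _merge(pool, f"other {category}", category)
        if aggregate.n_individuals >= threshold:
            kept.extend(ok)
            kept.append(aggregate)
        else:  # whole category below threshold: merge across categories
            leftover.append(aggregate)

    if leftover:
        leftover.sort(key=lambda c: (c.n_individuals, c.label))
        pool = list(leftover)
        remaining = sorted(kept, key=lambda c: (c.n_individuals, c.label))
        while sum(c.n_individuals for c in pool) < threshold and remaining:
            nxt = remaining.pop(0)
            kept.remove(nxt)
            pool.append(nxt)
        other = _merge(pool, OTHER, OTHER)
        if other.n_individuals < threshold:
            logger.warning(
                "entire stratum %s below threshold %d; reporting single 'Other'",
                cells[0].index_condition,
                threshold,
            )
        kept.append(other)

    return merge_other_cells(kept)


def merge_other_cells(cells: list[ComorbidityCell]) -> list[ComorbidityCell]:
    """Collapse any duplicate labels produced by repeated grouping."""
    by_label: dict[tuple[str, str], list[ComorbidityCell]] = {}
    for c in cells:
        by_label.setdefault((c.category, c.label), []).append(c)
    out = []
    for (category, label), group in by_label.items():
        out.append(group[0] if len(group) == 1 else _merge(group, label, category))
    return sorted(out, key=lambda c: (c.category, c.label))
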