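"""Four-category image-quality grading on per-cell annotations.

An image is graded from which cells are countable (center, borders and
boundaries identifiable) and which of those have fully distinct borders,
using contiguous groups of countable cells:

1. groups of countable cells are extracted from the adjacency graph;
2. groups with at least 15 cells qualify for counting frames; ``N`` is
   the total number of qualifying cells;
3. *excellent*: some single contiguous group of >= 50 cells, all with
   distinct borders;
4. *good*: N >= 50 with no indistinct cell among the qualifying ones;
5. *fair*: N >= 50 with at most 25 % indistinct;
6. otherwise *unanalyzable*.

Groups larger than 150 cells still qualify as excellent: the historical
150-cell figure is read as a counting-effort cap, not a disqualifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geometry import contiguous_groups

__all__ = [
    "CATEGORIES",
    "CATEGORY_RANK",
    "CellFlags",
    "GradeResult",
    "grade_image",
    "tabulate_grades",
    "round_half_away",
]

#: Table layout order (best first).
CATEGORIES = ("excellent", "good", "fair", "unanalyzable")

#: Ordering for monotonicity checks: higher is better.
CATEGORY_RANK = {"unanalyzable": 0, "fair": 1, "good": 2, "excellent": 3}

MIN_GROUP_CELLS = 15
MIN_COUNTABLE = 50
MAX_INDISTINCT_FRACTION = 0.25  # enforced as (N - D) * 4 <= N, exactly


@dataclass(frozen=True)
class CellFlags:
    cell_id: int
    countable: bool
    border_distinct: bool

    def __post_init__(self) -> None:
        if self.border_distinct and not self.countable:
            raise ValueError("border_distinct implies countable")


@dataclass
class GradeResult:
    category: str
    largest_group: int
    countable_total: int
    qualifying_total: int
    indistinct_fraction: float
    groups: list[int]


def grade_image(
    flags: Sequence[CellFlags],
    adjacency: Mapping[int, Iterable[int]] | Sequence[Iterable[int]],
) -> GradeResult:
    """Grade one image from per-cell flags and the cell adjacency graph."""
    known = {f.cell_id for f in flags}
    if isinstance(adjacency, Mapping):
        referenced = set(adjacency.keys()) | {
            int(j) for nbrs in adjacency.values() for j in nbrs
        }
    else:
        referenced = set(range(len(adjacency))) | {
            int(j) for nbrs in adjacency for j in nbrs
        }
    unknown = referenced - known
    if unknown:
        raise ValueError(f"adjacency references unknown cell ids {sorted(unknown)}")

    distinct_ids = {f.cell_id for f in flags if f.border_distinct}
    countable_ids = {f.cell_id for f in flags if f.countable}

    groups = contiguous_groups(countable_ids, adjacency)
    qualifying = [g for g in groups if len(g) >= MIN_GROUP_CELLS]
    n_qualifying = sum(len(g) for g in qualifying)
    n_distinct = sum(len(g & distinct_ids) for g in qualifying)
    n_indistinct = n_qualifying - n_distinct
    indistinct_fraction = (
        n_indistinct / n_qualifying if n_qualifying else 0.0
    )

    has_excellent_group = any(
        len(g) >= MIN_COUNTABLE and g <= distinct_ids for g in groups
    )
    if has_excellent_group:
        category = "excellent"
    elif n_qualifying >= MIN_COUNTABLE and n_indistinct == 0:
        category = "good"
    elif n_qualifying >= MIN_COUNTABLE and n_indistinct * 4 <= n_qualifying:
        category = "fair"
    else:
        category = "unanalyzable"

    return GradeResult(
        category=category,
        largest_group=max((len(g) for g in groups), default=0),
        countable_total=len(countable_ids),
        qualifying_total=n_qualifying,
        indistinct_fraction=indistinct_fraction,
        groups=[len(g) for g in groups],
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed whole percents)."""
    factor = 10.0**ndigits
    scaled = x * factor
    import math

    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor


def _category_of(grade) -> str:
    if isinstance(grade, GradeResult):
        cat = grade.category
    else:
        cat = str(grade)
    if cat not in CATEGORIES:
        raise ValueError(f"unknown category {cat!r}")
    return cat


def tabulate_grades(
    grades: Sequence[GradeResult | str],
    group_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts and whole-percent shares per category, optionally per label.

    Rows are the four categories plus a TOTAL row; each label (and the
    pooled total) contributes an ``n`` and a ``pct`` column.  Percentages
    are rounded half away from zero to whole percents.
    """
    if len(grades) == 0:
        raise ValueError("cannot tabulate an empty list of grades")
    cats = [_category_of(g) for g in grades]
    if group_labels is not None and len(group_labels) != len(grades):
        raise ValueError("one label per grade required")

    labels = list(dict.fromkeys(group_labels)) if group_labels is not None else []
    columns: dict[str, list] = {}

    def _add(colname: str, selection: list[str]) -> None:
        total = len(selection)
        counts = [selection.count(c) for c in CATEGORIES]
        pcts = [int(round_half_away(100.0 * c / total)) for c in counts]
        columns[f"{colname}_n"] = counts + [total]
        columns[f"{colname}_pct"] = pcts + [100]

    for label in labels:
        _add(label, [c for c, l in zip(cats, group_labels) if l == label])
    _add("total", cats)

    return pd.DataFrame(columns, index=list(CATEGORIES) + ["TOTAL"])
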