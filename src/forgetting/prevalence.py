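"""Category prevalence and typical curves.

The headline summary of a classified corpus: how much of the evidence falls
in each retention pattern.  Datasets are weighted by their total amount of
data (participants × observations per participant) by default, so that tiny
studies do not skew the distribution; an unweighted variant is available.
A category's "typical" curve is drawn at the element-wise median of its
members' fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category, CategoryAssignment
from .models import FunctionFamily, RetentionCurve, curve_grid

__all__ = [
    "CategoryDistribution",
    "weighted_category_distribution",
    "best_fit_quality_summary",
    "typical_curve",
    "default_time_grid",
]

#: 68 years in seconds — the longest retention interval observed in the
#: survey corpus; the default plotting grid ends here.
_LONGEST_SPAN_S = 68 * 31_536_000


@dataclass(frozen=True)
class CategoryDistribution:
    """Per-category weighted proportions (excluding removed datasets)."""

    proportions: dict[Category, float]
    total_weight: float
    scheme: str

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")


def weighted_category_distribution(
    assignments: Iterable[CategoryAssignment],
    characteristics: pd.DataFrame | None = None,
    weight: str = "amount_of_data",
) -> CategoryDistribution:
    """Distribution of categories, weighted per dataset.

    ``weight`` is ``"amount_of_data"`` (requires a characteristics frame with
    that column, keyed by dataset_id) or ``"unweighted"``.  Removed datasets
    are excluded before normalisation.
    """
    assignments = [a for a in assignments if a.category is not Category.REMOVED]
    if not assignments:
        raise ValueError("no retained assignments to summarise")
    if weight == "unweighted":
        weights = {a.dataset_id: 1.0 for a in assignments}
    elif weight == "amount_of_data":
        if characteristics is None:
            raise ValueError("amount_of_data weighting requires a characteristics frame")
        table = characteristics.set_index("dataset_id")["amount_of_data"]
        weights = {}
        for a in assignments:
            if a.dataset_id not in table.index or not np.isfinite(table[a.dataset_id]):
                raise ValueError(f"missing weight for dataset {a.dataset_id}")
            weights[a.dataset_id] = float(table[a.dataset_id])
    else:
        raise ValueError(f"unknown weighting scheme {weight!r}")

    total = sum(weights.values())
    props: dict[Category, float] = {}
    for a in assignments:
        props[a.category] = props.get(a.category, 0.0) + weights[a.dataset_id] / total
    return CategoryDistribution(props, total_weight=total, scheme=weight)


def best_fit_quality_summary(
    assignments: Iterable[CategoryAssignment],
) -> pd.DataFrame:
    """How well each family fits when it wins.

    Returns, per loss family with at least one winning dataset: count, mean,
    standard error, min and max of the winning r².  Families with zero wins
    are simply absent.
    """
    rows = []
    assignments = list(assignments)
    for family in FunctionFamily:
        r2s = np.array(
            [
                a.best_r2
                for a in assignments
                if a.category.value == family.value and a.best_r2 is not None
            ]
        )
        if r2s.size == 0:
            continue
        rows.append(
            {
                "family": family.value,
                "n": int(r2s.size),
                "mean": float(r2s.mean()),
                "se": float(r2s.std(ddof=1) / np.sqrt(r2s.size)) if r2s.size > 1 else 0.0,
                "min": float(r2s.min()),
                "max": float(r2s.max()),
            }
        )
    return pd.DataFrame(rows)


def default_time_grid(n: int = 200) -> np.ndarray:
    """Log-spaced grid from 1 second to 68 years."""
    return np.logspace(0.0, np.log10(_LONGEST_SPAN_S), n)


def typical_curve(
    category: Category,
    assignments: Iterable[CategoryAssignment],
    times: Sequence[float] | None = None,
    initial_memories: Mapping[str, float] | None = None,
) -> list[tuple[float, float]]:
    """The category's representative curve on a time grid.

    Loss categories evaluate their family at the element-wise median (a, b)
    of the members' winning fits.  Increasing uses the median (a, b) of the
    attached linear fits.  No-net-change is a horizontal line at the members'
    median initial performance level, supplied via ``initial_memories``
    (dataset_id → proportion at the shortest delay).
    """
    category = Category(category)
    if times is None:
        times = default_time_grid()
    members = [a for a in list(assignments) if a.category is category]
    if not members:
        raise ValueError(f"no datasets in category {category.value}")

    if category is Category.NO_NET_CHANGE:
        if initial_memories is None:
            raise ValueError("no_net_change typical curve requires initial_memories")
        levels = [initial_memories[a.dataset_id] for a in members]
        return typical_flat_curve(levels, times)

    fits = [a.winning_fit for a in members if a.winning_fit is not None]
    if not fits:
        raise ValueError(f"category {category.value} has no attached fits")
    family = (
        FunctionFamily.LINEAR
        if category is Category.INCREASING
        else FunctionFamily(category.value)
    )
    a_med = float(np.median([f.a for f in fits]))
    b_med = float(np.median([f.b for f in fits]))
    return curve_grid(RetentionCurve(family, a_med, b_med), times)


def typical_flat_curve(
    initial_memories: Sequence[float], times: Sequence[float] | None = None
) -> list[tuple[float, float]]:
    """No-net-change typical curve: flat at the median initial level."""
    if times is None:
        times = default_time_grid()
    level = float(np.median(np.asarray(initial_memories, dtype=float)))
    return [(float(t), level) for t in times]
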