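"""Classification of retention datasets into seven patterns (or removed).

Each dataset is assigned one label:

* ``no_net_change`` — net proportion change from the shortest to the longest
  delay within the closed stability band [−.01, +.01]; no fit is consulted.
* ``increasing`` — net change above +.01 (memory improves); kept regardless of
  fit quality, with a linear fit attached for typical-curve rendering.
* one of the five loss families — the best-fitting family when its r² clears
  the trim threshold;
* ``removed`` — a loss dataset whose best fit falls below r² = .5 (a value
  about two standard deviations below the corpus mean best fit): none of the
  candidate functions captures it.

No-net-change and increasing datasets are never removed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .fitting import BestFit, FitResult, FitSet, RetentionDataset, best_fit
from .models import FunctionFamily

__all__ = [
    "Category",
    "CategoryAssignment",
    "STABILITY_BAND",
    "TRIM_THRESHOLD",
    "net_change",
    "mean_successive_change",
    "categorize",
    "apply_trimming",
    "assignments_to_frame",
]

#: Half-width of the closed no-net-change band on the net proportion change.
STABILITY_BAND = 0.01

#: Loss datasets whose best-fitting r² falls below this are removed.
TRIM_THRESHOLD = 0.5


class Category(str, enum.Enum):
    """Seven retention patterns plus the removed (untrimmed) bucket."""

    LOGARITHMIC = "logarithmic"
    POWER = "power"
    EXPONENTIAL_POWER = "exponential_power"
    HYPERBOLIC_POWER = "hyperbolic_power"
    LINEAR = "linear"
    NO_NET_CHANGE = "no_net_change"
    INCREASING = "increasing"
    REMOVED = "removed"

    def __str__(self) -> str:
        return self.value


#: Loss categories map one-to-one onto function families.
LOSS_CATEGORIES: dict[FunctionFamily, Category] = {
    f: Category(f.value) for f in FunctionFamily
}


@dataclass(frozen=True)
class CategoryAssignment:
    """A dataset's pattern label and the evidence used to assign it."""

    dataset_id: str
    category: Category
    net_change: float
    best_r2: Optional[float] = None
    winning_fit: Optional[FitResult] = None
    tie: bool = False


def net_change(ds: RetentionDataset) -> float:
    """Net proportion change: proportion at the longest delay minus at the
    shortest.  (The sum of successive changes telescopes to the same value.)"""
    return float(ds.proportions[-1] - ds.proportions[0])


def mean_successive_change(ds: RetentionDataset) -> float:
    """Mean change from one retention interval to the next."""
    return float(np.mean(np.diff(ds.proportions)))


def categorize(
    ds: RetentionDataset,
    fs: Optional[FitSet] = None,
    *,
    band: float = STABILITY_BAND,
    trim_threshold: float = TRIM_THRESHOLD,
) -> CategoryAssignment:
    """Assign a dataset to one of the seven patterns or mark it removed.

    ``fs`` (the five-family fit set) is required only for loss datasets
    (net change below −``band``); increasing datasets get a linear fit
    attached (taken from ``fs`` if supplied, else fitted here).
    """
    nc = net_change(ds)
    if abs(nc) <= band:
        return CategoryAssignment(ds.dataset_id, Category.NO_NET_CHANGE, nc)
    if nc > band:
        if fs is not None:
            lin = fs[FunctionFamily.LINEAR]
        else:
            from .fitting import fit_family

            lin = fit_family(ds, FunctionFamily.LINEAR)
        return CategoryAssignment(
            ds.dataset_id, Category.INCREASING, nc, winning_fit=lin
        )
    if fs is None:
        raise ValueError(f"{ds.dataset_id}: loss dataset requires a FitSet to categorize")
    bf: BestFit = best_fit(fs)
    if bf.fit.r2 < trim_threshold:
        return CategoryAssignment(
            ds.dataset_id, Category.REMOVED, nc, best_r2=bf.fit.r2,
            winning_fit=bf.fit, tie=bf.tie,
        )
    return CategoryAssignment(
        ds.dataset_id, LOSS_CATEGORIES[bf.family], nc, best_r2=bf.fit.r2,
        winning_fit=bf.fit, tie=bf.tie,
    )


def _group_report(
    ids: list[str],
    assignments: Mapping[str, CategoryAssignment],
    datasets: Mapping[str, RetentionDataset],
    characteristics: Optional[pd.DataFrame],
) -> dict[str, float]:
    def _mean(values):
        values = [v for v in values if v is not None and np.isfinite(v)]
        return float(np.mean(values)) if values else float("nan")

    report: dict[str, float] = {"count": len(ids)}
    report["mean_best_r2"] = _mean(assignments[i].best_r2 for i in ids)
    report["mean_n_retention_intervals"] = _mean(len(datasets[i]) for i in ids)
    report["mean_longest_ri"] = _mean(datasets[i].times[-1] for i in ids)
    report["mean_initial_memory"] = _mean(datasets[i].proportions[0] for i in ids)
    report["mean_successive_change"] = _mean(
        mean_successive_change(datasets[i]) for i in ids
    )
    if characteristics is not None and len(ids):
        sub = characteristics.set_index("dataset_id").loc[
            [i for i in ids if i in set(characteristics["dataset_id"])]
        ]
        for col, key in [
            ("sample_size", "mean_sample_size"),
            ("obs_per_participant", "mean_obs_per_participant"),
            ("multiple_study", "proportion_multiple_study"),
        ]:
            report[key] = float(sub[col].mean()) if col in sub else float("nan")
    return report


def apply_trimming(
    assignments: Iterable[CategoryAssignment],
    datasets: Mapping[str, RetentionDataset],
    characteristics: Optional[pd.DataFrame] = None,
) -> tuple[list[CategoryAssignment], list[CategoryAssignment], dict]:
    """Partition assignments into retained and removed, with a trim report.

    The report summarises both groups (count, mean best r², data-amount and
    retention-interval statistics) so the removed datasets can be compared
    with the retained ones.
    """
    assignments = list(assignments)
    retained = [a for a in assignments if a.category is not Category.REMOVED]
    removed = [a for a in assignments if a.category is Category.REMOVED]
    amap = {a.dataset_id: a for a in assignments}
    report = {
        "retained": _group_report([a.dataset_id for a in retained], amap, datasets, characteristics),
        "removed": _group_report([a.dataset_id for a in removed], amap, datasets, characteristics),
    }
    return retained, removed, report


def assignments_to_frame(assignments: Iterable[CategoryAssignment]) -> pd.DataFrame:
    """Tidy table: dataset_id, category, net_change, best_r2, a, b."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "dataset_id": a.dataset_id,
                "category": a.category.value,
                "net_change": a.net_change,
                "best_r2": a.best_r2,
                "a": a.winning_fit.a if a.winning_fit else None,
                "b": a.winning_fit.b if a.winning_fit else None,
            }
        )
    return pd.DataFrame(rows)
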