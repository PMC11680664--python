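"""Corpus data model and I/O.

A retention corpus is stored as two CSV tables:

* **measurements** — long format, one row per observation:
  ``dataset_id, time_s, proportion``;
* **characteristics** — one row per dataset with the coded study covariates
  (publication year, sample size, observations per participant, material
  complexity 1–7, multiple-study flag, distractor flag, assessment type,
  design, …).

Derived covariates (amount of data, degree of learning, retention-interval
order statistics, initial memory) are computed here, as is the zero-delay
adjustment: a reported delay of 0 s is replaced either by a nominal .01 s
(immediate tests) or by an educated estimate of instruction time
(default 30 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import RetentionDataset

__all__ = [
    "ASSESSMENT_TYPES",
    "StudyCharacteristics",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "adjust_zero_delays",
    "derive_degree_of_learning",
    "derive_retention_stats",
    "characteristics_frame",
    "collapse_assessment_types",
    "filter_rare_assessments",
]

#: Recognised assessment-type labels.  Unknown labels are preserved but
#: flagged during validation.
ASSESSMENT_TYPES = (
    "free_recall",
    "cued_recall",
    "yes_no_recognition",
    "forced_choice",
    "savings",
    "stem_completion",
    "fragment_completion",
    "anagram",
    "matching",
    "problem_solution",
    "source_monitoring",
)

#: Default canonical-column → source-column mapping (identity).
_MEASUREMENT_COLUMNS = ("dataset_id", "time_s", "proportion")
_CHARACTERISTIC_COLUMNS = (
    "dataset_id",
    "paper_id",
    "year",
    "sample_size",
    "obs_per_participant",
    "material_type",
    "complexity",
    "multiple_study",
    "distractor",
    "assessment_type",
    "design",
)


class CorpusValidationError(ValueError):
    """Raised when a corpus table violates an invariant; lists offenders."""


@dataclass(frozen=True)
class StudyCharacteristics:
    """Coded and derived covariates for one dataset.

    ``complexity`` is the 7-level material-complexity code (1 = meaningless
    isolated items … 7 = rich situational material); ``degree_of_learning``
    (1–4) combines the complexity band (1–4 vs 5–7) with single vs multiple
    study exposure.  Design is coded 0 = within-subjects, 1 = between.
    Retention-interval statistics are in seconds.
    """

    dataset_id: str
    paper_id: str
    year: int
    sample_size: float
    obs_per_participant: float
    material_type: str
    complexity: int
    multiple_study: int
    distractor: int
    assessment_type: str
    design: int
    # derived
    amount_of_data: float = field(default=float("nan"))
    degree_of_learning: int = field(default=0)
    n_retention_intervals: int = field(default=0)
    shortest_ri: float = field(default=float("nan"))
    longest_ri: float = field(default=float("nan"))
    average_ri: float = field(default=float("nan"))
    ri_range: float = field(default=float("nan"))
    initial_memory: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 1 <= int(self.complexity) <= 7:
            raise CorpusValidationError(
                f"{self.dataset_id}: complexity {self.complexity} outside 1..7"
            )
        if int(self.multiple_study) not in (0, 1):
            raise CorpusValidationError(f"{self.dataset_id}: multiple_study must be 0/1")
        if int(self.distractor) not in (0, 1):
            raise CorpusValidationError(f"{self.dataset_id}: distractor must be 0/1")
        if int(self.design) not in (0, 1):
            raise CorpusValidationError(f"{self.dataset_id}: design must be 0/1")


def derive_degree_of_learning(complexity: int, multiple_study: int) -> int:
    """Four-level degree-of-learning code.

    Level 1: complexity 1–4, single exposure (rote, once);
    level 2: complexity 1–4, multiple exposures;
    level 3: complexity 5–7, single exposure (elaborative, once);
    level 4: complexity 5–7, multiple exposures.
    """
    if not 1 <= complexity <= 7:
        raise ValueError(f"complexity {complexity} outside 1..7")
    if multiple_study not in (0, 1):
        raise ValueError("multiple_study must be 0 or 1")
    base = 1 if complexity <= 4 else 3
    return base + multiple_study


def derive_retention_stats(ds: RetentionDataset) -> dict[str, float]:
    """Order statistics of the delays plus initial memory for one dataset."""
    t = ds.t
    return {
        "n_retention_intervals": len(ds),
        "shortest_ri": float(t[0]),
        "longest_ri": float(t[-1]),
        "average_ri": float(t.mean()),
        "ri_range": float(t[-1] - t[0]),
        "initial_memory": float(ds.proportions[0]),
    }


def _with_derived(sc: StudyCharacteristics, ds: RetentionDataset) -> StudyCharacteristics:
    stats = derive_retention_stats(ds)
    return replace(
        sc,
        amount_of_data=float(sc.sample_size) * float(sc.obs_per_participant),
        degree_of_learning=derive_degree_of_learning(
            int(sc.complexity), int(sc.multiple_study)
        ),
        **stats,
    )


def adjust_zero_delays(
    ds: RetentionDataset,
    policy: str = "fixed_epsilon",
    estimate_s: float = 30.0,
) -> RetentionDataset:
    """Replace a leading 0-second delay with a positive value.

    ``fixed_epsilon`` substitutes a nominal .01 s (for genuinely immediate
    tests); ``estimate`` substitutes an educated estimate of how long test
    instructions take (default 30 s).  A zero anywhere but the first position
    is an error.  Accepts raw (times, proportions) via a permissive path:
    ``ds`` may carry a zero first delay, which :class:`RetentionDataset`
    itself forbids — pass times/proportions through
    :func:`adjust_zero_delay_times` first when constructing.
    """
    times = list(ds.times)
    return RetentionDataset(
        ds.dataset_id,
        tuple(adjust_zero_delay_times(times, policy, estimate_s)),
        ds.proportions,
    )


def adjust_zero_delay_times(
    times: Sequence[float], policy: str = "fixed_epsilon", estimate_s: float = 30.0
) -> list[float]:
    """Zero-delay adjustment on a raw delay sequence (see
    :func:`adjust_zero_delays`)."""
    times = [float(t) for t in times]
    if any(t == 0 for t in times[1:]):
        raise ValueError("zero delay at a non-first position")
    if times and times[0] == 0.0:
        if policy == "fixed_epsilon":
            times[0] = 0.01
        elif policy == "estimate":
            times[0] = float(estimate_s)
        else:
            raise ValueError(f"unknown zero-delay policy {policy!r}")
    if times and times[0] >= (times[1] if len(times) > 1 else float("inf")):
        raise ValueError("zero-delay adjustment would break strict ordering")
    return times


def _apply_mapping(frame: pd.DataFrame, mapping: Optional[Mapping[str, str]],
                   required: Sequence[str], table: str) -> pd.DataFrame:
    if mapping:
        frame = frame.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CorpusValidationError(f"{table} table missing columns: {missing}")
    return frame


def read_corpus(
    measurements: str | Path | pd.DataFrame,
    characteristics: str | Path | pd.DataFrame,
    mapping: Optional[Mapping[str, Mapping[str, str]]] = None,
    zero_delay_policy: str = "fixed_epsilon",
    zero_delay_estimate_s: float = 30.0,
) -> tuple[list[tuple[RetentionDataset, StudyCharacteristics]], list[str]]:
    """Read, join and validate a corpus.

    ``mapping`` optionally maps canonical column names to the source files'
    headers, per table: ``{"measurements": {...}, "characteristics": {...}}``.
    Returns the validated (dataset, characteristics) pairs plus a list of
    validation notices (e.g. unknown assessment labels).
    """
    meas = measurements if isinstance(measurements, pd.DataFrame) else pd.read_csv(measurements)
    chars = characteristics if isinstance(characteristics, pd.DataFrame) else pd.read_csv(characteristics)
    mapping = mapping or {}
    meas = _apply_mapping(meas, mapping.get("measurements"), _MEASUREMENT_COLUMNS, "measurements")
    chars = _apply_mapping(chars, mapping.get("characteristics"), _CHARACTERISTIC_COLUMNS, "characteristics")

    bad = meas[(meas["proportion"] < 0) | (meas["proportion"] > 1)]
    if len(bad):
        raise CorpusValidationError(
            f"proportions outside [0,1] at measurement rows {bad.index.tolist()}"
        )

    meas_ids = set(meas["dataset_id"].astype(str))
    char_ids = set(chars["dataset_id"].astype(str))
    if meas_ids != char_ids:
        raise CorpusValidationError(
            "join error — only in measurements: "
            f"{sorted(meas_ids - char_ids)}; only in characteristics: "
            f"{sorted(char_ids - meas_ids)}"
        )

    notices: list[str] = []
    records: list[tuple[RetentionDataset, StudyCharacteristics]] = []
    chars = chars.set_index(chars["dataset_id"].astype(str))
    for dataset_id, group in meas.groupby(meas["dataset_id"].astype(str), sort=True):
        group = group.sort_values("time_s")
        times = adjust_zero_delay_times(
            group["time_s"].tolist(), zero_delay_policy, zero_delay_estimate_s
        )
        ds = RetentionDataset(str(dataset_id), tuple(times), tuple(group["proportion"]))
        row = chars.loc[str(dataset_id)]
        if str(row["assessment_type"]) not in ASSESSMENT_TYPES:
            notices.append(
                f"{dataset_id}: unknown assessment type {row['assessment_type']!r}"
            )
        sc = StudyCharacteristics(
            dataset_id=str(dataset_id),
            paper_id=str(row["paper_id"]),
            year=int(row["year"]),
            sample_size=float(row["sample_size"]),
            obs_per_participant=float(row["obs_per_participant"]),
            material_type=str(row["material_type"]),
            complexity=int(row["complexity"]),
            multiple_study=int(row["multiple_study"]),
            distractor=int(row["distractor"]),
            assessment_type=str(row["assessment_type"]),
            design=int(row["design"]),
        )
        records.append((ds, _with_derived(sc, ds)))
    return records, notices


def write_corpus(
    records: Iterable[tuple[RetentionDataset, StudyCharacteristics]],
    measurements_path: str | Path,
    characteristics_path: str | Path,
) -> None:
    """Write a corpus back to the two-table CSV layout read by
    :func:`read_corpus`."""
    records = list(records)
    meas_rows = [
        {"dataset_id": ds.dataset_id, "time_s": t, "proportion": m}
        for ds, _ in records
        for t, m in zip(ds.times, ds.proportions)
    ]
    char_rows = [
        {c: getattr(sc, c) for c in _CHARACTERISTIC_COLUMNS} for _, sc in records
    ]
    pd.DataFrame(meas_rows).to_csv(measurements_path, index=False)
    pd.DataFrame(char_rows).to_csv(characteristics_path, index=False)


def characteristics_frame(
    records: Iterable[tuple[RetentionDataset, StudyCharacteristics]]
) -> pd.DataFrame:
    """All characteristics (coded + derived) as one DataFrame."""
    rows = []
    for _, sc in records:
        rows.append({f: getattr(sc, f) for f in sc.__dataclass_fields__})
    return pd.DataFrame(rows)


def collapse_assessment_types(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse stem and fragment completion into one ``completion`` level
    (they are methodologically near-identical)."""
    out = frame.copy()
    out["assessment_type"] = out["assessment_type"].replace(
        {"stem_completion": "completion", "fragment_completion": "completion"}
    )
    return out


def filter_rare_assessments(frame: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Drop datasets whose assessment type occurs fewer than ``min_count``
    times (rare measures such as anagram solution, matching, problem solving
    and source monitoring are too sparse to analyse)."""
    counts = frame["assessment_type"].value_counts()
    keep = counts[counts >= min_count].index
    return frame[frame["assessment_type"].isin(keep)].reset_index(drop=True)
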