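"""End-to-end pipeline orchestration.

Sequences the full analysis — read → zero-delay adjust → fit → categorize →
trim → prevalence → characteristics — over a two-table corpus, writing tidy
CSV outputs and a run manifest (config hash, seed, package version, stage
completions) to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .characteristics import (
    PREDICTORS_13,
    log_transform_delays,
    one_vs_rest_logistic,
    one_way_anova,
    predictor_correlation_matrix,
    reduce_predictors,
    tukey_pairwise,
)
from .classify import (
    Category,
    apply_trimming,
    assignments_to_frame,
    categorize,
)
from .corpus import (
    characteristics_frame,
    collapse_assessment_types,
    filter_rare_assessments,
    read_corpus,
)
from .fitting import fit_all, fit_quality_correlations, fitsets_to_frame
from .prevalence import (
    best_fit_quality_summary,
    typical_curve,
    weighted_category_distribution,
)
from .tree import train_guide_tree

log = logging.getLogger("forgetting")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; mirrors the CLI flags."""

    measurements: str
    characteristics: str
    output_dir: str
    column_mapping: Optional[Mapping[str, Mapping[str, str]]] = None
    zero_delay_policy: str = "fixed_epsilon"
    zero_delay_estimate_s: float = 30.0
    trim_threshold: float = 0.5
    stability_band: float = 0.01
    weighting: str = "amount_of_data"
    predictors: Sequence[str] = field(default_factory=lambda: list(PREDICTORS_13))
    reduction_mode: str = "documented"
    min_assessment_count: int = 10
    run_characteristics: bool = True
    run_tree: bool = True
    tree_max_depth: int = 5
    tree_min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.trim_threshold < 1.0:
            raise ValueError("trim threshold must be in (0, 1)")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land does not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def _stage(name: str):
        stages.append(name)
        log.info("stage complete: %s", name)

    # --- read -------------------------------------------------------------
    try:
        records, notices = read_corpus(
            config.measurements,
            config.characteristics,
            mapping=config.column_mapping,
            zero_delay_policy=config.zero_delay_policy,
            zero_delay_estimate_s=config.zero_delay_estimate_s,
        )
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("read", str(exc)) from exc
    for notice in notices:
        log.warning("validation: %s", notice)
    datasets = {ds.dataset_id: ds for ds, _ in records}
    chars = characteristics_frame(records)
    _stage("read")
    _stage("adjust")  # zero-delay adjustment happens inside the reader

    # --- fit --------------------------------------------------------------
    try:
        fitsets = {
            ds.dataset_id: fit_all(ds)
            for ds, _ in records
            if float(np.ptp(ds.m)) > 0.0
        }
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc
    fitsets_to_frame(fitsets.values()).to_csv(out / "fits.csv", index=False)
    if len(fitsets) >= 3:
        fit_quality_correlations(fitsets.values()).to_csv(out / "fit_correlations.csv")
    _stage("fit")

    # --- categorize -------------------------------------------------------
    try:
        assignments = [
            categorize(
                ds,
                fitsets.get(ds.dataset_id),
                band=config.stability_band,
                trim_threshold=config.trim_threshold,
            )
            for ds, _ in records
        ]
    except Exception as exc:
        raise PipelineError("categorize", str(exc)) from exc
    assignments_to_frame(assignments).to_csv(out / "assignments.csv", index=False)
    _stage("categorize")

    # --- trim -------------------------------------------------------------
    retained, removed, trim_report = apply_trimming(assignments, datasets, chars)
    (out / "trim_report.json").write_text(json.dumps(trim_report, indent=2))
    _stage("trim")

    # --- prevalence -------------------------------------------------------
    try:
        dist = weighted_category_distribution(retained, chars, weight=config.weighting)
        pd.DataFrame(
            [
                {"category": c.value, "proportion": p}
                for c, p in sorted(dist.proportions.items(), key=lambda kv: kv[0].value)
            ]
        ).to_csv(out / "category_distribution.csv", index=False)
        best_fit_quality_summary(retained).to_csv(out / "fit_quality_summary.csv", index=False)
        initial = {ds.dataset_id: ds.proportions[0] for ds, _ in records}
        curve_rows = []
        for cat in Category:
            if cat is Category.REMOVED:
                continue
            try:
                for t, m in typical_curve(cat, retained, initial_memories=initial):
                    curve_rows.append({"category": cat.value, "t": t, "M": m})
            except ValueError:
                continue  # empty category
        pd.DataFrame(curve_rows).to_csv(out / "typical_curves.csv", index=False)
    except Exception as exc:
        raise PipelineError("prevalence", str(exc)) from exc
    _stage("prevalence")

    # --- characteristics --------------------------------------------------
    if config.run_characteristics:
        try:
            label_map = {a.dataset_id: a.category.value for a in retained}
            frame = chars[chars["dataset_id"].isin(label_map)].reset_index(drop=True)
            frame = collapse_assessment_types(frame)
            frame = filter_rare_assessments(frame, config.min_assessment_count)
            frame = log_transform_delays(frame)
            labels = [label_map[i] for i in frame["dataset_id"]]

            corr = predictor_correlation_matrix(frame, config.predictors)
            corr.to_csv(out / "predictor_correlations.csv")
            retained_predictors, drop_log = reduce_predictors(
                corr, mode=config.reduction_mode
            )
            (out / "predictor_reduction.json").write_text(
                json.dumps(
                    {"retained": retained_predictors, "dropped": drop_log}, indent=2
                )
            )

            anova_rows, tukey_rows = [], []
            for factor in retained_predictors:
                res = one_way_anova(frame[factor], labels, factor=factor)
                anova_rows.append(
                    {
                        "factor": factor, "F": res.f, "p": res.p,
                        "eta_p2": res.eta_p2,
                        "df": f"{res.df_between}, {res.df_within}",
                    }
                )
                if res.p < 0.10:
                    for tk in tukey_pairwise(frame[factor], labels):
                        tukey_rows.append(
                            {
                                "factor": factor, "group_a": tk.group_a,
                                "group_b": tk.group_b, "t": tk.t,
                                "p_adj": tk.p_adj, "d": tk.d,
                            }
                        )
            pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
            pd.DataFrame(tukey_rows).to_csv(out / "tukey.csv", index=False)

            logit_rows = []
            for cat in sorted(set(labels)):
                if sum(l == cat for l in labels) < 10:
                    continue
                for res in one_vs_rest_logistic(
                    frame, labels, cat, retained_predictors
                ):
                    logit_rows.append(
                        {
                            "category": res.category, "predictor": res.predictor,
                            "coef": res.coef, "z": res.z, "p": res.p,
                            "penalized": res.penalized,
                        }
                    )
            pd.DataFrame(logit_rows).to_csv(out / "logistic.csv", index=False)

            if config.run_tree and len(frame) >= 50:
                tree = train_guide_tree(
                    frame, labels, retained_predictors,
                    max_depth=config.tree_max_depth, min_leaf=config.tree_min_leaf,
                )
                (out / "guide_tree.json").write_text(tree.to_json())
                (out / "guide_tree.txt").write_text(tree.to_text())
        except Exception as exc:
            raise PipelineError("characteristics", str(exc)) from exc
        _stage("characteristics")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_datasets": len(records),
        "n_removed": len(removed),
        "stages": stages,
        "validation_notices": notices,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
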