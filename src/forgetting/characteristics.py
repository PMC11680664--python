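"""Relating study characteristics to retention patterns.

Three analyses run over a classified corpus:

1. a Pearson correlation matrix over the numeric covariates, with a
   collinearity screen (|r| ≥ .70) that reduces the 13 candidate predictors
   to 9 (dropping retention range, shortest and average retention interval,
   and degree of learning, keeping longest interval and complexity);
2. per-factor one-way ANOVA across the seven patterns with Tukey HSD
   pairwise comparisons (t, adjusted p, Cohen's d);
3. one-vs-rest logistic regressions predicting, for each pattern, whether a
   dataset falls in it, from the z-scored retained predictors.

Delays span ten orders of magnitude, so retention-interval predictors are
log10-transformed by default before ANOVA/regression.  p < .05 is reported
as significant and p < .10 as marginal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PREDICTORS_13",
    "DOCUMENTED_DROPS",
    "AnovaResult",
    "TukeyResult",
    "LogisticResult",
    "predictor_correlation_matrix",
    "reduce_predictors",
    "one_way_anova",
    "tukey_pairwise",
    "one_vs_rest_logistic",
    "log_transform_delays",
]

#: The 13 numeric candidate predictors screened for collinearity.
PREDICTORS_13 = (
    "year",
    "complexity",
    "multiple_study",
    "degree_of_learning",
    "distractor",
    "design",
    "amount_of_data",
    "n_retention_intervals",
    "shortest_ri",
    "longest_ri",
    "average_ri",
    "ri_range",
    "initial_memory",
)

#: Documented collinearity resolutions: retention range tracks the longest
#: interval (r ≈ .99); shortest/longest/average intervals are mutually
#: collinear (keep longest — how long people remember is the question);
#: degree of learning tracks complexity (r ≈ .77) and multiple study.
DOCUMENTED_DROPS = {
    "ri_range": "collinear with longest_ri",
    "shortest_ri": "collinear with longest_ri/average_ri",
    "average_ri": "collinear with longest_ri",
    "degree_of_learning": "collinear with complexity and multiple_study",
}

#: Delay-scale predictors log10-transformed before ANOVA/regression.
DELAY_PREDICTORS = ("shortest_ri", "longest_ri", "average_ri", "ri_range")


@dataclass(frozen=True)
class AnovaResult:
    """One factor's one-way ANOVA across patterns."""

    factor: str
    f: float
    p: float
    eta_p2: float
    df_between: int
    df_within: int
    group_means: dict[str, float] = field(default_factory=dict)
    group_ses: dict[str, float] = field(default_factory=dict)
    excluded_groups: tuple[str, ...] = ()

    @property
    def marginal(self) -> bool:
        return 0.05 <= self.p < 0.10

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class TukeyResult:
    """One Tukey HSD pairwise comparison."""

    group_a: str
    group_b: str
    t: float
    p_adj: float
    d: float

    @property
    def marginal(self) -> bool:
        return 0.05 <= self.p_adj < 0.10


@dataclass(frozen=True)
class LogisticResult:
    """One predictor's coefficient in a one-vs-rest logistic regression."""

    category: str
    predictor: str
    coef: float
    z: float
    p: float
    penalized: bool = False


def predictor_correlation_matrix(
    frame: pd.DataFrame, predictors: Sequence[str] = PREDICTORS_13
) -> pd.DataFrame:
    """Pairwise Pearson correlations among numeric predictors.

    Constant predictors yield NaN entries (undefined) with a warning.
    """
    if len(frame) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    sub = frame.loc[:, list(predictors)].astype(float)
    constant = [c for c in sub.columns if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant predictors (correlations undefined): {constant}")
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def reduce_predictors(
    matrix: pd.DataFrame,
    threshold: float = 0.70,
    mode: str = "documented",
    drops: Optional[dict[str, str]] = None,
) -> tuple[list[str], list[dict[str, object]]]:
    """Collinearity reduction: retained predictor list plus a drop log.

    ``documented`` mode applies the survey's resolutions
    (:data:`DOCUMENTED_DROPS`, overridable via ``drops``).  ``greedy`` mode
    repeatedly finds the highest |r| ≥ threshold pair and drops whichever
    member is more correlated with everything else, until no pair remains
    above threshold.
    """
    cols = list(matrix.columns)
    log: list[dict[str, object]] = []
    if mode == "documented":
        drops = DOCUMENTED_DROPS if drops is None else drops
        retained = []
        for c in cols:
            if c in drops:
                partners = matrix.loc[c].drop(c).abs()
                log.append(
                    {
                        "dropped": c,
                        "reason": drops[c],
                        "max_abs_r": float(partners.max()),
                        "with": str(partners.idxmax()),
                    }
                )
            else:
                retained.append(c)
        return retained, log
    if mode != "greedy":
        raise ValueError(f"unknown reduction mode {mode!r}")

    retained = cols[:]
    work = matrix.abs().copy()
    np.fill_diagonal(work.values, 0.0)
    while True:
        sub = work.loc[retained, retained]
        peak = float(np.nanmax(sub.values)) if len(retained) > 1 else 0.0
        if peak < threshold:
            break
        i, j = np.unravel_index(np.nanargmax(sub.values), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        # drop whichever of the pair is, on average, more redundant
        drop = a if sub.loc[a].mean() >= sub.loc[b].mean() else b
        keep = b if drop == a else a
        log.append(
            {"dropped": drop, "reason": f"|r|={peak:.3f} with {keep}",
             "max_abs_r": peak, "with": keep}
        )
        retained.remove(drop)
    return retained, log


def _group_arrays(
    values: Sequence[float], groups: Sequence[str], min_size: int = 2
) -> tuple[dict[str, np.ndarray], tuple[str, ...]]:
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    frame = frame.dropna()
    arrays, excluded = {}, []
    for name, sub in frame.groupby("group", sort=True):
        arr = sub["value"].to_numpy()
        if arr.size < min_size:
            excluded.append(str(name))
        else:
            arrays[str(name)] = arr
    return arrays, tuple(excluded)


def one_way_anova(
    values: Sequence[float], groups: Sequence[str], factor: str = ""
) -> AnovaResult:
    """Standard one-way ANOVA decomposition across pattern groups.

    Groups with fewer than 2 members are excluded (and recorded).  Partial
    eta squared is SS_between / (SS_between + SS_within).
    """
    arrays, excluded = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups with ≥ 2 members")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    dfb = len(arrays) - 1
    dfw = all_values.size - len(arrays)
    msb = ssb / dfb
    msw = ssw / dfw
    f = msb / msw if msw > 0 else (0.0 if msb == 0 else np.inf)
    p = float(stats.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0
    eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return AnovaResult(
        factor=factor,
        f=float(f),
        p=p,
        eta_p2=float(eta),
        df_between=dfb,
        df_within=dfw,
        group_means={g: float(a.mean()) for g, a in arrays.items()},
        group_ses={
            g: float(a.std(ddof=1) / np.sqrt(a.size)) for g, a in arrays.items()
        },
        excluded_groups=excluded,
    )


def tukey_pairwise(
    values: Sequence[float], groups: Sequence[str]
) -> list[TukeyResult]:
    """Tukey HSD comparisons for every pair of groups.

    The t statistic uses the pooled within-group mean square from the full
    ANOVA; the adjusted p comes from the studentized-range distribution with
    k groups; Cohen's d uses the pooled SD of the two groups compared.
    """
    arrays, _ = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("Tukey needs at least 2 groups with ≥ 2 members")
    names = sorted(arrays)
    dfw = sum(a.size for a in arrays.values()) - len(arrays)
    msw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values()) / dfw
    k = len(arrays)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            diff = b.mean() - a.mean()
            se = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size))
            t = diff / se if se > 0 else 0.0
            p_adj = (
                float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfw))
                if se > 0
                else 1.0
            )
            pooled_var = (
                (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
            ) / (a.size + b.size - 2)
            d = abs(diff) / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
            out.append(
                TukeyResult(names[i], names[j], float(t), min(p_adj, 1.0), float(d))
            )
    return out


def log_transform_delays(
    frame: pd.DataFrame, predictors: Iterable[str] = DELAY_PREDICTORS
) -> pd.DataFrame:
    """log10-transform delay-scale predictors (delays span ~10 orders of
    magnitude; raw seconds would let a handful of decade-scale studies
    dominate every linear analysis)."""
    out = frame.copy()
    for col in predictors:
        if col in out.columns:
            out[col] = np.log10(np.maximum(out[col].astype(float), 1e-12))
    return out


def one_vs_rest_logistic(
    frame: pd.DataFrame,
    labels: Sequence[str],
    category: str,
    predictors: Sequence[str],
    min_positives: int = 10,
) -> list[LogisticResult]:
    """Logistic regression of (pattern == category) on z-scored predictors.

    Returns one :class:`LogisticResult` per predictor.  On perfect separation
    or non-convergence the coefficients come from an L2-penalized fallback
    and are flagged (``penalized=True``, z and p undefined).
    """
    y = (pd.Series(list(labels), index=frame.index) == category).astype(int)
    if int(y.sum()) < min_positives:
        raise ValueError(
            f"category {category!r} has {int(y.sum())} positives; need ≥ {min_positives}"
        )
    X = frame.loc[:, list(predictors)].astype(float)
    near_dup = []
    corr = X.corr().abs()
    for i, a in enumerate(predictors):
        for b in list(predictors)[i + 1 :]:
            if corr.loc[a, b] > 0.999:
                near_dup.append((a, b))
    if near_dup:
        warnings.warn(f"near-duplicate predictors in logistic design: {near_dup}")
    Xz = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    design = sm.add_constant(Xz, has_constant="add")

    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True) or not np.all(
            np.isfinite(fit.bse)
        ):
            raise RuntimeError("unstable fit")
        params, zvals, pvals = fit.params, fit.tvalues, fit.pvalues
    except Exception:
        penalized = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
        params = fit.params
        zvals = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)

    return [
        LogisticResult(
            category=category,
            predictor=p,
            coef=float(params[p]),
            z=float(zvals[p]),
            p=float(pvals[p]),
            penalized=penalized,
        )
        for p in predictors
    ]
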