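"""Least-squares fitting of retention functions and model comparison.

Each dataset (three or more delays, proportion correct at each) is fitted by
all five families.  Logarithmic and linear fits are ordinary least squares in
closed form (``M`` on ``ln t`` and on ``t``).  The power, exponential-power
and hyperbolic-power families are fitted by nonlinear least squares in
proportion space, started from their linearizing transforms plus a small
multi-start grid.  Goodness of fit is always the coefficient of determination
r² on the untransformed proportion scale, so fits are directly comparable
across families; the family with the highest r² is the best fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .models import FAMILY_ORDER, FunctionFamily, RetentionCurve, _raw_evaluate

__all__ = [
    "RetentionDataset",
    "FitResult",
    "FitSet",
    "BestFit",
    "DegenerateDatasetError",
    "r_squared",
    "fit_family",
    "fit_all",
    "best_fit",
    "fit_quality_correlations",
    "fitsets_to_frame",
]

#: Floor applied to proportions inside linearizing transforms only (log and
#: reciprocal transforms are undefined at 0).
_TRANSFORM_FLOOR = 1e-6

#: Multiplicative perturbations (±50 %) around the linearization-based start.
_MULTISTART_FACTORS = (0.5, 1.0, 1.5)


class DegenerateDatasetError(ValueError):
    """Raised when r² is undefined (observed proportions have zero variance)."""


@dataclass(frozen=True)
class RetentionDataset:
    """One study condition's retention series: delays (s) and proportions."""

    dataset_id: str
    times: tuple[float, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "times", tuple(t.tolist()))
        object.__setattr__(self, "proportions", tuple(m.tolist()))
        if t.size != m.size:
            raise ValueError(f"{self.dataset_id}: times and proportions differ in length")
        if t.size < 3:
            raise ValueError(f"{self.dataset_id}: need at least 3 retention intervals")
        if np.any(t <= 0):
            raise ValueError(f"{self.dataset_id}: delays must be positive (adjust zero delays first)")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.dataset_id}: delays must be strictly increasing")
        if np.any((m < 0) | (m > 1)):
            raise ValueError(f"{self.dataset_id}: proportions must lie in [0, 1]")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def m(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitResult:
    """One family's fitted parameters and goodness of fit on one dataset."""

    family: FunctionFamily
    a: float
    b: float
    r2: float
    converged: bool = True

    @property
    def curve(self) -> RetentionCurve:
        return RetentionCurve(self.family, self.a, self.b)


@dataclass(frozen=True)
class FitSet:
    """All five family fits for one dataset."""

    dataset_id: str
    fits: dict[FunctionFamily, FitResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.fits) != set(FunctionFamily):
            missing = [f.value for f in FunctionFamily if f not in self.fits]
            raise ValueError(f"{self.dataset_id}: missing fits for {missing}")

    def __getitem__(self, family: FunctionFamily) -> FitResult:
        return self.fits[FunctionFamily(family)]

    def r2_vector(self) -> np.ndarray:
        return np.array([self.fits[f].r2 for f in FAMILY_ORDER])


class BestFit(NamedTuple):
    family: FunctionFamily
    fit: FitResult
    tie: bool


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SSE/SST on the proportion scale.

    SST is about the observed mean.  r² may be negative when the model does
    worse than the mean; it is undefined for constant observations.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateDatasetError(
            "r² undefined: observed proportions have zero variance "
            "(route through net-change classification instead)"
        )
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def _sse(family: FunctionFamily, a: float, b: float, t: np.ndarray, m: np.ndarray) -> float:
    with np.errstate(all="ignore"):
        pred = _raw_evaluate(family, a, b, t)
        if not np.all(np.isfinite(pred)):
            return math.inf
        out = float(np.sum((m - pred) ** 2))
    return out if math.isfinite(out) else math.inf


def _closed_form_fit(ds: RetentionDataset, family: FunctionFamily) -> FitResult:
    t, m = ds.t, ds.m
    if family is FunctionFamily.LOGARITHMIC:
        # M = a - b ln t  =>  slope of OLS(M ~ ln t) is -b
        slope, intercept = np.polyfit(np.log(t), m, 1)
        a, b = float(intercept), float(-slope)
    else:  # linear: M = b t + a
        slope, intercept = np.polyfit(t, m, 1)
        a, b = float(intercept), float(slope)
    pred = _raw_evaluate(family, a, b, t)
    return FitResult(family, a, b, r_squared(m, pred), converged=True)


def _linearized_start(ds: RetentionDataset, family: FunctionFamily) -> tuple[float, float]:
    """Starting (a, b) from the family's linearizing transform."""
    t = ds.t
    m = np.maximum(ds.m, _TRANSFORM_FLOOR)
    if family is FunctionFamily.POWER:
        # ln M = ln a + b ln t
        slope, intercept = np.polyfit(np.log(t), np.log(m), 1)
        return float(np.exp(intercept)), float(slope)
    if family is FunctionFamily.EXPONENTIAL_POWER:
        # ln M = ln a - b sqrt(t)
        slope, intercept = np.polyfit(np.sqrt(t), np.log(m), 1)
        return float(np.exp(intercept)), float(-slope)
    if family is FunctionFamily.HYPERBOLIC_POWER:
        # 1/M = a + b sqrt(t)
        slope, intercept = np.polyfit(np.sqrt(t), 1.0 / m, 1)
        return float(intercept), float(slope)
    raise ValueError(f"{family} has a closed-form fit; no start needed")


def _anchor_start(
    ds: RetentionDataset, family: FunctionFamily, floor: float
) -> tuple[float, float]:
    """Start solved exactly through the (floored) first and last points.

    Robust when interior/terminal proportions hit 0, where the global
    linearizing transform is dominated by the floor.
    """
    t0, t1 = ds.times[0], ds.times[-1]
    m0 = max(ds.proportions[0], floor)
    m1 = max(ds.proportions[-1], floor)
    if family is FunctionFamily.POWER:
        b = math.log(m1 / m0) / math.log(t1 / t0)
        return m0 / t0**b, b
    if family is FunctionFamily.EXPONENTIAL_POWER:
        b = -math.log(m1 / m0) / (math.sqrt(t1) - math.sqrt(t0))
        return m0 * math.exp(b * math.sqrt(t0)), b
    # hyperbolic
    b = (1.0 / m1 - 1.0 / m0) / (math.sqrt(t1) - math.sqrt(t0))
    return 1.0 / m0 - b * math.sqrt(t0), b


def _scan_start(ds: RetentionDataset, family: FunctionFamily) -> tuple[float, float]:
    """Best (a, b) from a 1-D profile scan over the rate parameter.

    For each candidate b on a log grid spanning the data's natural rate
    scale, the scale parameter is solved in closed form (exactly for the
    families linear in a; via the reciprocal transform for the hyperbolic
    family) and the proportion-space SSE evaluated.  Catches steep-decay
    optima far from the global linearizing transform.
    """
    t, m = ds.t, ds.m
    if family is FunctionFamily.POWER:
        span = math.log(t[-1] / t[0])
        g = lambda b: np.power(t, b)
    else:
        span = math.sqrt(t[-1]) - math.sqrt(t[0])
        if family is FunctionFamily.EXPONENTIAL_POWER:
            g = lambda b: np.exp(-b * np.sqrt(t))
        else:
            g = None
    b_char = 1.0 / max(span, 1e-12)
    b_grid = b_char * np.logspace(-2.5, 4.5, 57)
    b_grid = np.concatenate([-b_grid, [0.0], b_grid])
    best: tuple[float, tuple[float, float]] = (math.inf, (1.0, 0.0))
    m_floor = np.maximum(m, 0.02)
    sqrt_t = np.sqrt(t)
    for b in b_grid:
        if family is FunctionFamily.HYPERBOLIC_POWER:
            # two scale candidates: reciprocal-space mean, and anchored
            # exactly through the (floored) first point
            a_candidates = (
                float(np.mean(1.0 / m_floor - b * sqrt_t)),
                1.0 / m_floor[0] - b * sqrt_t[0],
            )
        else:
            with np.errstate(all="ignore"):
                basis = g(b)
                if not np.all(np.isfinite(basis)):
                    continue
                denom = float(basis @ basis)
                if denom <= 0 or not math.isfinite(denom):
                    continue
                a_candidates = (float(m @ basis) / denom,)
        for a in a_candidates:
            sse = _sse(family, a, float(b), t, m)
            if sse < best[0]:
                best = (sse, (a, float(b)))
    return best[1]


def _nls_fit(ds: RetentionDataset, family: FunctionFamily) -> FitResult:
    t, m = ds.t, ds.m
    a0, b0 = _linearized_start(ds, family)

    def model(tt, a, b):
        with np.errstate(all="ignore"):
            pred = _raw_evaluate(family, a, b, tt)
        # keep the optimizer on finite ground if it wanders through a pole
        return np.nan_to_num(pred, nan=1e6, posinf=1e6, neginf=-1e6)

    starts = []
    for fa in _MULTISTART_FACTORS:
        for fb in _MULTISTART_FACTORS:
            sa = a0 * fa if a0 != 0 else (fa - 1.0) * 0.1
            sb = b0 * fb if b0 != 0 else (fb - 1.0) * 0.01
            starts.append((sa, sb))
    # endpoint-anchored, profile-scan and flat fallback starts (robust to
    # zero proportions and steep-decay optima)
    for floor in (0.02, 0.08):
        starts.append(_anchor_start(ds, family, floor))
    starts.append(_scan_start(ds, family))
    mean_m = max(float(np.mean(m)), _TRANSFORM_FLOOR)
    if family is FunctionFamily.HYPERBOLIC_POWER:
        starts.append((1.0 / mean_m, 0.0))
    else:
        starts.append((mean_m, 0.0))

    best_params = (a0, b0)
    best_sse = _sse(family, a0, b0, t, m)
    converged = False
    for start in starts:
        start_sse = _sse(family, start[0], start[1], t, m)
        if start_sse < best_sse:
            best_sse = start_sse
            best_params = (float(start[0]), float(start[1]))
        if not math.isfinite(start_sse):
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(model, t, m, p0=start, maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        sse = _sse(family, float(popt[0]), float(popt[1]), t, m)
        if sse < best_sse:
            best_sse = sse
            best_params = (float(popt[0]), float(popt[1]))
        converged = True

    a, b = best_params
    if math.isinf(best_sse):
        # even the start was invalid (e.g. hyperbolic pole inside the data):
        # report a flat fallback at the mean so r² is well defined
        if family is FunctionFamily.HYPERBOLIC_POWER:
            a, b = 1.0 / max(float(np.mean(m)), _TRANSFORM_FLOOR), 0.0
        else:
            a, b = float(np.mean(m)), 0.0
        converged = False
    pred = _raw_evaluate(family, a, b, t)
    return FitResult(family, a, b, r_squared(m, pred), converged=converged)


def fit_family(ds: RetentionDataset, family: FunctionFamily) -> FitResult:
    """Fit one family to one dataset by (non)linear least squares.

    Residuals are in proportion space and unclamped; r² is computed on the
    untransformed scale.  Raises :class:`DegenerateDatasetError` for
    zero-variance data.
    """
    family = FunctionFamily(family)
    if float(np.ptp(ds.m)) == 0.0:
        raise DegenerateDatasetError(
            f"{ds.dataset_id}: constant proportions; classify as no-net-change instead"
        )
    if family in (FunctionFamily.LOGARITHMIC, FunctionFamily.LINEAR):
        return _closed_form_fit(ds, family)
    return _nls_fit(ds, family)


def fit_all(ds: RetentionDataset) -> FitSet:
    """Fit all five families to one dataset."""
    return FitSet(ds.dataset_id, {f: fit_family(ds, f) for f in FunctionFamily})


def best_fit(fs: FitSet, tol: float = 1e-10) -> BestFit:
    """Select the family with maximal r².

    Ties within ``tol`` are broken by the fixed reporting order (logarithmic,
    power, exponential-power, hyperbolic-power, linear) and flagged.
    """
    r2s = {f: fs[f].r2 for f in FAMILY_ORDER}
    top = max(r2s.values())
    contenders = [f for f in FAMILY_ORDER if top - r2s[f] <= tol]
    winner = contenders[0]
    return BestFit(winner, fs[winner], tie=len(contenders) > 1)


def fit_quality_correlations(fitsets: Iterable[FitSet]) -> pd.DataFrame:
    """Pearson correlations between per-family r² vectors across datasets.

    Entries involving a constant r² vector are NaN (undefined).  The diagonal
    is fixed at 1.
    """
    fitsets = list(fitsets)
    if len(fitsets) < 3:
        raise ValueError("need at least 3 fitsets to correlate fit qualities")
    frame = pd.DataFrame(
        {f.value: [fs[f].r2 for fs in fitsets] for f in FAMILY_ORDER}
    )
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def fitsets_to_frame(fitsets: Iterable[FitSet]) -> pd.DataFrame:
    """Tidy table of fits: dataset_id, family, a, b, r2, converged."""
    rows = [
        {
            "dataset_id": fs.dataset_id,
            "family": f.value,
            "a": fs[f].a,
            "b": fs[f].b,
            "r2": fs[f].r2,
            "converged": fs[f].converged,
        }
        for fs in fitsets
        for f in FAMILY_ORDER
    ]
    return pd.DataFrame(rows)
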