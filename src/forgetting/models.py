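"""Two-parameter retention functions.

Five classical families describe proportion remembered ``M`` as a function of
retention delay ``t`` (seconds), each with a scale parameter ``a`` and a rate
parameter ``b``:

====================  =========================
logarithmic           ``M = a - b ln(t)``
power                 ``M = a t^b``
exponential_power     ``M = a e^(-b sqrt(t))``
hyperbolic_power      ``M = 1 / (a + b sqrt(t))``
linear                ``M = b t + a``
====================  =========================

The logarithmic and linear families can predict proportions outside [0, 1];
a boundary constraint (``clamp``) truncates predictions into the unit
interval.  Clamping is applied uniformly to all families for prediction and
plotting, but is kept out of the least-squares residuals so that fits are not
distorted at the boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FunctionFamily",
    "RetentionCurve",
    "evaluate_curve",
    "curve_grid",
]


class FunctionFamily(str, enum.Enum):
    """The five candidate retention-function families."""

    LOGARITHMIC = "logarithmic"
    POWER = "power"
    EXPONENTIAL_POWER = "exponential_power"
    HYPERBOLIC_POWER = "hyperbolic_power"
    LINEAR = "linear"

    def __str__(self) -> str:  # stable serialization label
        return self.value


#: Fixed reporting / tie-break order: the four classical curvilinear families
#: first, then linear.
FAMILY_ORDER: tuple[FunctionFamily, ...] = (
    FunctionFamily.LOGARITHMIC,
    FunctionFamily.POWER,
    FunctionFamily.EXPONENTIAL_POWER,
    FunctionFamily.HYPERBOLIC_POWER,
    FunctionFamily.LINEAR,
)


@dataclass(frozen=True)
class RetentionCurve:
    """A retention function: a family plus its (a, b) parameters.

    ``a`` is the scale parameter (on the proportion scale, except for the
    hyperbolic family where it is a reciprocal-scale intercept) and ``b`` the
    rate of change per unit of transformed time.
    """

    family: FunctionFamily
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("curve parameters must be finite")
        if not isinstance(self.family, FunctionFamily):
            object.__setattr__(self, "family", FunctionFamily(self.family))

    def to_record(self) -> dict[str, object]:
        return {"family": self.family.value, "a": self.a, "b": self.b}

    @classmethod
    def from_record(cls, record: Mapping[str, object]) -> "RetentionCurve":
        return cls(
            family=FunctionFamily(record["family"]),
            a=float(record["a"]),
            b=float(record["b"]),
        )


def _raw_evaluate(family: FunctionFamily, a: float, b: float, t: np.ndarray) -> np.ndarray:
    if family is FunctionFamily.LOGARITHMIC:
        return a - b * np.log(t)
    if family is FunctionFamily.POWER:
        return a * np.power(t, b)
    if family is FunctionFamily.EXPONENTIAL_POWER:
        return a * np.exp(-b * np.sqrt(t))
    if family is FunctionFamily.HYPERBOLIC_POWER:
        return 1.0 / (a + b * np.sqrt(t))
    if family is FunctionFamily.LINEAR:
        return b * t + a
    raise ValueError(f"unknown family {family!r}")


def evaluate_curve(curve: RetentionCurve, t, clamp: bool = True):
    """Evaluate a retention curve at delay(s) ``t`` (seconds, > 0).

    Parameters
    ----------
    curve
        The curve to evaluate.
    t
        Scalar or array of positive delays in seconds.
    clamp
        If true, truncate predictions into [0, 1] (the boundary constraint).
        With ``clamp=False`` a non-positive hyperbolic denominator raises.

    Returns
    -------
    Proportion remembered, same shape as ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("retention delays must be strictly positive")
    if curve.family is FunctionFamily.HYPERBOLIC_POWER:
        denom = curve.a + curve.b * np.sqrt(t_arr)
        if not clamp and np.any(denom <= 0):
            raise ValueError("hyperbolic denominator must be positive")
        if clamp:
            # a non-positive denominator means the curve has left the valid
            # region; the clamped prediction saturates at the boundary
            with np.errstate(divide="ignore"):
                m = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), np.inf)
        else:
            m = 1.0 / denom
    else:
        m = _raw_evaluate(curve.family, curve.a, curve.b, t_arr)
    if clamp:
        m = np.clip(m, 0.0, 1.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(m)
    return m


def curve_grid(curve: RetentionCurve, times: Iterable[float]) -> list[tuple[float, float]]:
    """Evaluate a curve (clamped) on an ordered positive time grid.

    Returns a list of ``(t, M)`` pairs, one per grid point.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("time grid is empty")
    if np.any(t <= 0):
        raise ValueError("time grid must be strictly positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    m = evaluate_curve(curve, t, clamp=True)
    return list(zip(t.tolist(), np.asarray(m, dtype=float).tolist()))
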