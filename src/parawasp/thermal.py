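"""Linear development-rate model, lower thresholds, and thermal constants.

Mean development rate (the reciprocal 1/d of mean stage duration d, in 1/day)
is regressed on rearing temperature, 1/d = a + bT.  The lower developmental
threshold t = −a/b is the temperature where the fitted rate extrapolates to
zero, and the thermal constant K = 1/b is the number of degree-days required
to complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohorts import IMMATURE_STAGES, IndividualRecord

__all__ = [
    "RatePoint",
    "LinearFit",
    "ThermalParams",
    "development_rates",
    "fit_linear",
    "thermal_params",
    "predict_duration",
    "EGG_TO_ADULT",
]

EGG_TO_ADULT = "egg_to_adult"


@dataclass(frozen=True)
class RatePoint:
    temperature: float
    rate: float           # 1/day, reciprocal of mean development time
    n: int                # individuals contributing
    stage: str


@dataclass(frozen=True)
class LinearFit:
    a: float              # intercept, 1/day
    b: float              # slope, 1/(day·°C)
    r_squared: float
    stage: str
    temperature_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class ThermalParams:
    t: float              # lower developmental threshold, °C
    K: float              # thermal constant, degree-days


def _completed_duration(record: IndividualRecord, stage: str) -> float | None:
    """Days spent in ``stage`` if the individual completed it, else None."""
    if stage == EGG_TO_ADULT:
        if record.reached_adult:
            return float(sum(record.stage_durations.values()))
        return None
    if stage not in IMMATURE_STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if stage not in record.stage_durations or record.died_in_stage == stage:
        return None
    return float(record.stage_durations[stage])


def development_rates(
    records: Sequence[IndividualRecord], stage: str
) -> list[RatePoint]:
    """One rate point per temperature where ≥1 individual completed ``stage``.

    The rate is the reciprocal of the mean duration among completers (one
    regression point per temperature); temperatures where the stage was never
    completed — e.g. the extremes where development fails — are excluded.
    """
    durations: dict[float, list[float]] = {}
    for r in records:
        d = _completed_duration(r, stage)
        if d is not None:
            durations.setdefault(r.temperature, []).append(d)
    if not durations:
        raise ValueError(f"stage {stage!r} was never completed at any temperature")
    return [
        RatePoint(
            temperature=t,
            rate=1.0 / float(np.mean(ds)),
            n=len(ds),
            stage=stage,
        )
        for t, ds in sorted(durations.items())
    ]


def fit_linear(points: Sequence[RatePoint]) -> LinearFit:
    """Ordinary least squares of rate on temperature; R² = 1 − SS_res/SS_tot."""
    if len(points) < 2:
        raise ValueError("need at least 2 rate points")
    T = np.array([p.temperature for p in points])
    y = np.array([p.rate for p in points])
    if np.unique(T).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    res = stats.linregress(T, y)
    return LinearFit(
        a=float(res.intercept),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        stage=points[0].stage,
        temperature_range=(float(T.min()), float(T.max())),
        n_points=len(points),
    )


def thermal_params(fit: LinearFit) -> ThermalParams:
    """Lower threshold t = −a/b (°C) and thermal constant K = 1/b (degree-days).

    A non-positive slope means development does not speed up with warming over
    the fitted range — biologically invalid for this model — and is rejected.
    """
    if fit.b <= 0:
        raise ValueError(f"slope b = {fit.b} is not positive; "
                         "no meaningful threshold/thermal constant")
    return ThermalParams(t=-fit.a / fit.b, K=1.0 / fit.b)


def predict_duration(fit: LinearFit, T: float) -> float:
    """Predicted stage duration 1/(a + bT) at temperature ``T``.

    Undefined at or below the lower threshold, where the fitted rate is
    non-positive (development would never complete).
    """
    rate = fit.a + fit.b * T
    if rate <= 0:
        raise ValueError(
            f"T = {T} °C is at or below the developmental threshold "
            f"(predicted rate {rate:.4g} ≤ 0)"
        )
    return 1.0 / rate
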