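"""Degree-day estimation of monthly and annual generation numbers.

The number of generations an insect can complete in a period of ``d`` days at
mean temperature ``Tm`` is the degree-day accumulation above the lower
developmental threshold ``t`` divided by the thermal constant ``K``:

    NG = (Tm − t) · d / K     (clamped at 0 when Tm ≤ t)

Coffee-growing regions are stratified into mean-temperature isotherm bands
(≤17, >17–≤20, >20–≤23, >23 °C); each band is evaluated at a representative
temperature (the band boundary), producing a monthly grid and annual totals
per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .thermal import ThermalParams

__all__ = [
    "IsothermSpec",
    "CalendarSpec",
    "GenerationEstimate",
    "generations",
    "monthly_table",
    "classify_isotherm",
    "default_isotherms",
    "default_calendar",
]

MONTHS = ("January", "February", "March", "April", "May", "June", "July",
          "August", "September", "October", "November", "December")


@dataclass(frozen=True)
class IsothermSpec:
    """One mean-temperature band; open bounds are ``None``.

    Bands are left-open/right-closed: a temperature Tm belongs to the band
    with t_low < Tm ≤ t_high.  ``representative_Tm`` is the temperature at
    which generation numbers are evaluated (the band boundary by default).
    """

    label: str
    t_low: Optional[float]
    t_high: Optional[float]
    representative_Tm: float

    def __post_init__(self) -> None:
        if self.t_low is not None and self.t_high is not None:
            if not self.t_low < self.t_high:
                raise ValueError(f"isotherm {self.label}: t_low must be < t_high")

    def contains(self, Tm: float) -> bool:
        lo_ok = self.t_low is None or Tm > self.t_low
        hi_ok = self.t_high is None or Tm <= self.t_high
        return lo_ok and hi_ok


@dataclass(frozen=True)
class CalendarSpec:
    month_days: dict[str, int]
    annual_days: int

    def __post_init__(self) -> None:
        for m, d in self.month_days.items():
            if not 28 <= d <= 31:
                raise ValueError(f"{m}: days-in-month must lie in 28..31")
        if self.annual_days not in (365, 366):
            raise ValueError("annual_days must be 365 or 366")


@dataclass(frozen=True)
class GenerationEstimate:
    species: str
    isotherm: str
    month: str            # a month name or "annual"
    NG: float


def default_isotherms() -> list[IsothermSpec]:
    """The four isotherm bands of the Colombian coffee region, evaluated at
    their boundary temperatures (the open >23 band at its lower boundary)."""
    return [
        IsothermSpec("<=17", None, 17.0, 17.0),
        IsothermSpec(">17-<=20", 17.0, 20.0, 20.0),
        IsothermSpec(">20-<=23", 20.0, 23.0, 23.0),
        IsothermSpec(">23", 23.0, None, 23.0),
    ]


def default_calendar() -> CalendarSpec:
    """Common-year calendar: February = 28 days, 365 days total."""
    days = dict(zip(MONTHS, (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)))
    return CalendarSpec(month_days=days, annual_days=365)


def generations(Tm: float, t: float, K: float, days: int) -> float:
    """NG = max(0, (Tm − t)·days/K); degree-day accumulation below the
    threshold is clamped to zero."""
    if K <= 0:
        raise ValueError("thermal constant K must be positive")
    if days < 1:
        raise ValueError("days must be >= 1")
    return max(0.0, (Tm - t) * days / K)


def monthly_table(
    thermal: dict[str, ThermalParams],
    isotherms: Optional[Sequence[IsothermSpec]] = None,
    calendar: Optional[CalendarSpec] = None,
) -> list[GenerationEstimate]:
    """Monthly and annual generation numbers per species and isotherm.

    ``thermal`` maps species label to its egg-to-adult :class:`ThermalParams`.
    The annual row is computed directly from ``annual_days`` (not by summing
    rounded monthly cells); values are unrounded — round to 2 decimals for
    display.
    """
    isotherms = list(isotherms) if isotherms is not None else default_isotherms()
    calendar = calendar if calendar is not None else default_calendar()
    _validate_partition(isotherms)
    out: list[GenerationEstimate] = []
    for species, params in thermal.items():
        for iso in isotherms:
            for month, ndays in calendar.month_days.items():
                out.append(
                    GenerationEstimate(
                        species=species,
                        isotherm=iso.label,
                        month=month,
                        NG=generations(iso.representative_Tm, params.t, params.K, ndays),
                    )
                )
            out.append(
                GenerationEstimate(
                    species=species,
                    isotherm=iso.label,
                    month="annual",
                    NG=generations(iso.representative_Tm, params.t, params.K,
                                   calendar.annual_days),
                )
            )
    return out


def _validate_partition(isotherms: Sequence[IsothermSpec]) -> None:
    bounded = sorted(isotherms, key=lambda s: (-1e30 if s.t_low is None else s.t_low))
    if not bounded:
        raise ValueError("no isotherms supplied")
    if bounded[0].t_low is not None:
        raise ValueError("isotherms do not cover the lower tail (first t_low must be open)")
    if bounded[-1].t_high is not None:
        raise ValueError("isotherms do not cover the upper tail (last t_high must be open)")
    for a, b in zip(bounded, bounded[1:]):
        if a.t_high is None or b.t_low is None or a.t_high != b.t_low:
            raise ValueError(
                f"isotherms {a.label!r} and {b.label!r} overlap or leave a gap"
            )


def classify_isotherm(Tm: float, isotherms: Sequence[IsothermSpec]) -> str:
    """Label of the unique band with t_low < Tm ≤ t_high."""
    _validate_partition(isotherms)
    for iso in isotherms:
        if iso.contains(Tm):
            return iso.label
    raise ValueError(f"no isotherm contains Tm = {Tm}")  # pragma: no cover
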