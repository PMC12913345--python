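"""Synthetic individual-level cohorts for parasitoid thermal-biology assays.

The laboratory design being emulated follows individual wasps (the larval-pupal
ectoparasitoid *Prorops nasuta* and the adult endoparasitoid *Phymastichus
coffea*, both natural enemies of the coffee berry borer) reared at constant
temperatures from oviposition to death.  Each individual yields the duration of
every life stage it completed (egg, larva, pupa), the stage in which it died if
it died prematurely, its sex if it emerged as an adult, its adult longevity,
and — for reproducing females — egg counts recorded once per observation
interval.

The generator draws whole-day stage durations from a discretized gamma
distribution (positivity guaranteed, mean/SD configurable), applies a Bernoulli
survival filter at each stage, assigns sex to emerging adults, and draws female
lifetime fecundity from a negative binomial spread over adult life with a
symmetric triangular age profile.  Identical ``(config, seed)`` pairs produce
identical cohorts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "STAGES",
    "IMMATURE_STAGES",
    "P_NASUTA",
    "P_COFFEA",
    "StageSpec",
    "CohortConfig",
    "IndividualRecord",
    "CohortFormatError",
    "paper_default_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

STAGES = ("egg", "larva", "pupa", "adult")
IMMATURE_STAGES = ("egg", "larva", "pupa")

P_NASUTA = "P_nasuta"
P_COFFEA = "P_coffea"

#: Coefficient of variation used for adult-longevity draws (the assays report
#: only means; dispersion is a modelling choice, see docs/methods.md).
LONGEVITY_CV = 0.30


class CohortFormatError(ValueError):
    """Raised when a cohort file contains a malformed or invalid row."""


@dataclass(frozen=True)
class StageSpec:
    """Duration and survival parameters for one life stage at one temperature."""

    stage_name: str
    duration_mean: float
    duration_sd: float
    survival_prob: float

    def __post_init__(self) -> None:
        if self.stage_name not in STAGES:
            raise ValueError(f"unknown stage name {self.stage_name!r}")
        if not self.duration_mean > 0:
            raise ValueError("duration_mean must be > 0")
        if self.duration_sd < 0:
            raise ValueError("duration_sd must be >= 0")
        if not 0.0 <= self.survival_prob <= 1.0:
            raise ValueError("survival_prob must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Full design of a constant-temperature cohort experiment.

    ``stage_specs`` maps temperature (°C) to the ordered list of
    :class:`StageSpec` for egg → larva → pupa → adult; the adult entry's
    ``duration_mean`` is unused (longevity is configured separately) but its
    ``survival_prob`` models post-emergence establishment.  ``observation
    interval`` is the egg-count recording cadence in days (daily censusing for
    P. coffea; 15-day host-bean dissections for P. nasuta).
    """

    species_label: str
    temperatures: list[float]
    n_per_temperature: int
    stage_specs: dict[float, list[StageSpec]]
    female_proportion: dict[float, float]
    adult_longevity_mean: dict[float, float]
    fecundity_mean: dict[float, float]
    fecundity_dispersion: float
    observation_interval: int

    def validate(self) -> None:
        if self.n_per_temperature < 0:
            raise ValueError("n_per_temperature must be >= 0")
        if self.observation_interval < 1:
            raise ValueError("observation_interval must be >= 1 day")
        if not self.fecundity_dispersion > 0:
            raise ValueError("fecundity_dispersion must be > 0")
        for mapping, name in (
            (self.stage_specs, "stage_specs"),
            (self.female_proportion, "female_proportion"),
            (self.adult_longevity_mean, "adult_longevity_mean"),
            (self.fecundity_mean, "fecundity_mean"),
        ):
            missing = [t for t in self.temperatures if t not in mapping]
            if missing:
                raise ValueError(f"{name} lacks temperatures {missing}")
        for t, specs in self.stage_specs.items():
            names = tuple(s.stage_name for s in specs)
            if names != STAGES:
                raise ValueError(
                    f"stage_specs[{t}] must be ordered {STAGES}, got {names}"
                )
        for t, p in self.female_proportion.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"female_proportion[{t}] outside [0, 1]")


@dataclass(frozen=True)
class IndividualRecord:
    """One insect's observed life history under one constant temperature.

    ``stage_durations`` holds whole-day durations for the immature stages the
    individual entered (the duration in the death stage is the number of days
    survived there).  Fields beyond the stage of death are absent: ``sex`` is
    ``None`` for pre-adult deaths, ``egg_counts`` is empty for males and for
    any death before reproduction.
    """

    individual_id: int
    temperature: float
    stage_durations: dict[str, int]
    died_in_stage: Optional[str]
    sex: Optional[str]
    adult_longevity: Optional[int]
    egg_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for stage, d in self.stage_durations.items():
            if stage not in IMMATURE_STAGES:
                raise ValueError(f"unexpected stage {stage!r} in durations")
            if d <= 0:
                raise ValueError(f"{stage} duration must be strictly positive")
        if self.died_in_stage is not None and self.died_in_stage not in STAGES:
            raise ValueError(f"unknown death stage {self.died_in_stage!r}")

    @property
    def reached_adult(self) -> bool:
        return self.died_in_stage is None or self.died_in_stage == "adult"

    @property
    def total_eggs(self) -> int:
        return int(sum(self.egg_counts))


# ---------------------------------------------------------------------------
# Study-design defaults
# ---------------------------------------------------------------------------

# Fractions of total immature development spent in each stage, proportional to
# the per-stage thermal constants (egg/larva/pupa degree-day shares).
_NASUTA_STAGE_FRACTIONS = {"egg": 0.12, "larva": 0.51, "pupa": 0.37}
_COFFEA_STAGE_FRACTIONS = {"egg": 0.085, "larva": 0.458, "pupa": 0.457}

_DURATION_CV = 0.15  # per-stage duration SD as a fraction of the mean


def _specs_from_totals(
    fractions: dict[str, float],
    total_mean: float,
    survival: dict[str, float],
) -> list[StageSpec]:
    specs = []
    for stage in IMMATURE_STAGES:
        mean = max(1.0, fractions[stage] * total_mean)
        specs.append(
            StageSpec(stage, mean, _DURATION_CV * mean, survival.get(stage, 0.0))
        )
    specs.append(StageSpec("adult", 1.0, 0.0, survival.get("adult", 0.0)))
    return specs


def paper_default_config(species: str) -> CohortConfig:
    """Default cohort design anchored to the published assay results.

    Anchors: female proportions per temperature (P. nasuta strongly
    female-biased when cool, ~1:1 for P. coffea), total egg-to-adult
    development means (64.8 d at 16 °C down to 19 d at 30 °C for P. nasuta;
    87.35 d at 19 °C down to 32.78 d at 28 °C for P. coffea), stage survival
    giving ≥0.80 egg-to-adult survival at 22–25 °C for P. nasuta and the
    printed per-stage values for P. coffea (egg 0.75 at 16 °C, larva 0.41 at
    32 °C, adult 0.87 at 25 °C), fecundity peaks at 25 °C (27 and 38
    eggs/female), and zero viability at 32/35 °C (and 16 °C past the egg for
    P. coffea).
    """
    temps = [16.0, 19.0, 22.0, 25.0, 28.0, 30.0, 32.0, 35.0]
    if species == P_NASUTA:
        totals = {16.0: 64.8, 19.0: 50.0, 22.0: 36.0, 25.0: 29.0, 28.0: 22.0, 30.0: 19.0}
        # Egg-to-adult survival (all four stages) decomposed as the 4th root
        # per stage where only the total is known.
        surv_total = {16.0: 0.45, 19.0: 0.65, 22.0: 0.82, 25.0: 0.82, 28.0: 0.45, 30.0: 0.40}
        stage_specs: dict[float, list[StageSpec]] = {}
        for t, tot in totals.items():
            s = surv_total[t] ** 0.25
            stage_specs[t] = _specs_from_totals(
                _NASUTA_STAGE_FRACTIONS, tot,
                {"egg": s, "larva": s, "pupa": s, "adult": s},
            )
        # 32 °C: eggs hatch-capable but development does not progress past the
        # egg stage; 35 °C: all die as eggs.
        stage_specs[32.0] = _specs_from_totals(
            _NASUTA_STAGE_FRACTIONS, 17.0, {"egg": 0.70, "larva": 0.0}
        )
        stage_specs[35.0] = _specs_from_totals(_NASUTA_STAGE_FRACTIONS, 17.0, {"egg": 0.0})
        return CohortConfig(
            species_label=P_NASUTA,
            temperatures=temps,
            n_per_temperature=200,
            stage_specs=stage_specs,
            female_proportion={16.0: 0.96, 19.0: 0.83, 22.0: 0.62, 25.0: 0.59,
                               28.0: 0.36, 30.0: 0.21, 32.0: 0.0, 35.0: 0.0},
            adult_longevity_mean={16.0: 40.0, 19.0: 40.0, 22.0: 41.0, 25.0: 42.0,
                                  28.0: 20.0, 30.0: 12.0, 32.0: 1.0, 35.0: 1.0},
            fecundity_mean={16.0: 8.0, 19.0: 12.0, 22.0: 18.0, 25.0: 27.0,
                            28.0: 10.0, 30.0: 3.0, 32.0: 0.0, 35.0: 0.0},
            fecundity_dispersion=5.0,
            observation_interval=15,
        )
    if species == P_COFFEA:
        totals = {19.0: 87.35, 22.0: 46.0, 25.0: 38.0, 28.0: 32.78, 30.0: 34.0}
        surv = {
            "egg": {16.0: 0.75, 19.0: 0.88, 22.0: 0.90, 25.0: 0.92, 28.0: 0.90,
                    30.0: 0.88, 32.0: 0.85, 35.0: 0.0},
            "larva": {16.0: 0.0, 19.0: 0.85, 22.0: 0.88, 25.0: 0.90, 28.0: 0.88,
                      30.0: 0.85, 32.0: 0.41, 35.0: 0.0},
            "pupa": {16.0: 0.0, 19.0: 0.85, 22.0: 0.88, 25.0: 0.90, 28.0: 0.85,
                     30.0: 0.82, 32.0: 0.0, 35.0: 0.0},
            "adult": {16.0: 0.0, 19.0: 0.61, 22.0: 0.80, 25.0: 0.87, 28.0: 0.80,
                      30.0: 0.63, 32.0: 0.0, 35.0: 0.0},
        }
        stage_specs = {}
        for t in temps:
            tot = totals.get(t)
            if tot is None:
                # Eggs develop slowly at 16 °C (no larval survival); immature
                # stages are fast but non-viable above 30 °C.
                tot = 82.0 if t == 16.0 else 31.0
            stage_specs[t] = _specs_from_totals(
                _COFFEA_STAGE_FRACTIONS, tot,
                {st: surv[st][t] for st in STAGES},
            )
        return CohortConfig(
            species_label=P_COFFEA,
            temperatures=temps,
            n_per_temperature=250,
            stage_specs=stage_specs,
            female_proportion={16.0: 0.50, 19.0: 0.51, 22.0: 0.52, 25.0: 0.52,
                               28.0: 0.52, 30.0: 0.52, 32.0: 0.50, 35.0: 0.50},
            adult_longevity_mean={16.0: 1.12, 19.0: 4.0, 22.0: 3.0, 25.0: 3.5,
                                  28.0: 2.5, 30.0: 2.0, 32.0: 0.25, 35.0: 0.25},
            fecundity_mean={16.0: 4.0, 19.0: 4.0, 22.0: 20.0, 25.0: 38.0,
                            28.0: 25.0, 30.0: 15.0, 32.0: 0.0, 35.0: 0.0},
            fecundity_dispersion=5.0,
            observation_interval=1,
        )
    raise ValueError(f"unknown species label {species!r}; "
                     f"expected {P_NASUTA!r} or {P_COFFEA!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_duration(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Whole-day duration from a discretized gamma, floored at 1 day."""
    if sd <= 0:
        return max(1, int(round(mean)))
    shape = (mean / sd) ** 2
    scale = mean / shape
    return max(1, int(round(rng.gamma(shape, scale))))


def _draw_fecundity(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Lifetime egg total from a negative binomial with size ``dispersion``."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _allocate_eggs(
    rng: np.random.Generator, total: int, longevity: int, interval: int
) -> tuple[int, ...]:
    """Spread a lifetime egg total over adult life in observation intervals.

    Daily allocation follows a symmetric triangular profile over adult days
    1..longevity (reproduction rises to mid-life then declines), then days are
    binned into recording intervals.
    """
    days = np.arange(1, longevity + 1)
    weights = np.minimum(days, longevity + 1 - days).astype(float)
    weights /= weights.sum()
    per_day = rng.multinomial(total, weights)
    n_intervals = math.ceil(longevity / interval)
    return tuple(
        int(per_day[i * interval:(i + 1) * interval].sum())
        for i in range(n_intervals)
    )


def generate_cohort(config: CohortConfig, seed: int) -> list[IndividualRecord]:
    """Simulate ``n_per_temperature`` individuals at every configured temperature.

    Deterministic: identical ``(config, seed)`` pairs produce identical
    cohorts.  Individuals are simulated stage by stage; once an individual dies
    in stage *s* no later-stage fields are generated.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    records: list[IndividualRecord] = []
    next_id = 0
    for temp in config.temperatures:
        specs = {s.stage_name: s for s in config.stage_specs[temp]}
        for _ in range(config.n_per_temperature):
            durations: dict[str, int] = {}
            died: Optional[str] = None
            for stage in IMMATURE_STAGES:
                spec = specs[stage]
                durations[stage] = _draw_duration(
                    rng, spec.duration_mean, spec.duration_sd
                )
                if rng.random() >= spec.survival_prob:
                    died = stage
                    break
            sex: Optional[str] = None
            longevity: Optional[int] = None
            eggs: tuple[int, ...] = ()
            if died is None:
                sex = "female" if rng.random() < config.female_proportion[temp] else "male"
                mean_lon = config.adult_longevity_mean[temp]
                longevity = _draw_duration(rng, mean_lon, LONGEVITY_CV * mean_lon)
                if rng.random() >= specs["adult"].survival_prob:
                    # failed post-emergence establishment: dies on adult day 1
                    died = "adult"
                    longevity = 1
                elif sex == "female":
                    total = _draw_fecundity(
                        rng, config.fecundity_mean[temp], config.fecundity_dispersion
                    )
                    eggs = _allocate_eggs(
                        rng, total, longevity, config.observation_interval
                    )
            records.append(
                IndividualRecord(
                    individual_id=next_id,
                    temperature=temp,
                    stage_durations=durations,
                    died_in_stage=died,
                    sex=sex,
                    adult_longevity=longevity,
                    egg_counts=eggs,
                )
            )
            next_id += 1
    return records


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_HEADER = [
    "id", "temperature_C", "egg_d", "larva_d", "pupa_d",
    "died_in_stage", "sex", "adult_longevity_d", "egg_counts",
]


def _fmt_temp(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))


def write_cohort(records: Sequence[IndividualRecord], path) -> None:
    """Write records as comma-separated UTF-8 text (missing values empty)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in records:
            writer.writerow([
                r.individual_id,
                _fmt_temp(r.temperature),
                r.stage_durations.get("egg", ""),
                r.stage_durations.get("larva", ""),
                r.stage_durations.get("pupa", ""),
                r.died_in_stage or "",
                r.sex or "",
                r.adult_longevity if r.adult_longevity is not None else "",
                ";".join(str(c) for c in r.egg_counts),
            ])


def read_cohort(path) -> list[IndividualRecord]:
    """Read a cohort file, reporting malformed rows with their line numbers."""
    records: list[IndividualRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError("empty file: missing header") from None
        if header != _HEADER:
            raise CohortFormatError(f"unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_HEADER):
                raise CohortFormatError(
                    f"line {lineno}: expected {len(_HEADER)} fields, got {len(row)}"
                )
            try:
                durations = {}
                for stage, cell in zip(IMMATURE_STAGES, row[2:5]):
                    if cell != "":
                        d = int(cell)
                        if d < 0:
                            raise ValueError(f"negative {stage} duration")
                        durations[stage] = d
                eggs = tuple(int(c) for c in row[8].split(";")) if row[8] else ()
                if any(c < 0 for c in eggs):
                    raise ValueError("negative egg count")
                records.append(
                    IndividualRecord(
                        individual_id=int(row[0]),
                        temperature=float(row[1]),
                        stage_durations=durations,
                        died_in_stage=row[5] or None,
                        sex=row[6] or None,
                        adult_longevity=int(row[7]) if row[7] != "" else None,
                        egg_counts=eggs,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise CohortFormatError(f"line {lineno}: {exc}") from exc
    return records
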