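"""Age-stage two-sex life tables, demographic parameters, and bootstrap inference.

A cohort of individuals reared from oviposition (age 0, in days) at one
constant temperature is summarised as an age-stage schedule: ``s_xj`` is the
probability that a newborn is alive and in stage ``j`` at age ``x`` (both
sexes tracked, so male development and pre-adult mortality dilute fecundity
exactly as in the age-stage two-sex framework), and ``f_xj`` is the mean
number of eggs laid at age ``x`` per individual alive in stage ``j``
(non-zero only in the adult stage).  The marginal age schedules are

    l_x = Σ_j s_xj          (age-specific survival)
    m_x = Σ_j s_xj f_xj / l_x   (age-specific fecundity, 0 where l_x = 0)

from which the demographic parameters follow:

    R0 = Σ_x l_x m_x                         net reproductive rate
    Σ_x exp(−r(x+1)) l_x m_x = 1             Euler–Lotka, intrinsic rate r
    λ = e^r,  T = ln(R0)/r,  Dt = ln 2 / r

The Euler–Lotka exponent uses x+1 with ages indexed from 0 — the age-stage
two-sex convention — rather than the classical x.  Uncertainty is quantified
by resampling individuals with replacement (percentile intervals); two
cohorts are compared through the bootstrap distribution of the parameter
difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohorts import IMMATURE_STAGES, STAGES, IndividualRecord

__all__ = [
    "AgeStageSchedule",
    "AgeSchedule",
    "DemographicParams",
    "BootstrapResult",
    "ComparisonResult",
    "build_schedules",
    "net_reproductive_rate",
    "intrinsic_rate",
    "derived_params",
    "bootstrap_params",
    "compare_temperatures",
]

PARAMETERS = ("R0", "r", "lambda", "T", "Dt")

_EULER_TOL = 1e-12
_CHUNK = 256  # bootstrap replicates per resampling block (memory bound)


@dataclass
class AgeStageSchedule:
    ages: np.ndarray                 # integer days, 0 .. last observed death
    stages: tuple[str, ...]
    s_xj: np.ndarray                 # (n_ages, n_stages)
    f_xj: np.ndarray                 # (n_ages, n_stages)


@dataclass
class AgeSchedule:
    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray


@dataclass
class DemographicParams:
    """R0, r (1/day), λ = e^r (per day), T = ln(R0)/r (days), Dt = ln2/r (days).

    T and Dt are NaN ("not applicable") when r = 0 or r ≤ 0 respectively.
    """

    R0: float
    r: float
    lam: float
    T_gen: float
    Dt: float


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n_excluded: int = 0   # replicates where the parameter was undefined


@dataclass
class ComparisonResult:
    parameter: str
    diff: float
    ci_low: float
    ci_high: float
    p: float
    B: int
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Per-individual timelines
# ---------------------------------------------------------------------------

def _death_age(r: IndividualRecord) -> int:
    dev = sum(r.stage_durations.values())
    if r.reached_adult:
        return dev + int(r.adult_longevity or 0)
    return dev


def _egg_days(r: IndividualRecord, interval: int) -> dict[int, float]:
    """Eggs attributed to absolute ages, spreading each observation interval
    uniformly over the adult days it covers (exact conservation of totals)."""
    if not r.egg_counts:
        return {}
    dev = sum(r.stage_durations.values())
    L = int(r.adult_longevity or 0)
    out: dict[int, float] = {}
    for i, count in enumerate(r.egg_counts):
        if count == 0:
            continue
        lo = i * interval
        hi = min((i + 1) * interval, L)
        ndays = hi - lo
        if ndays <= 0:
            ndays, hi = 1, lo + 1  # counts beyond recorded longevity: pile up
        per_day = count / ndays
        for a in range(lo, hi):
            x = dev + a
            out[x] = out.get(x, 0.0) + per_day
    return out


def _cohort_arrays(
    records: Sequence[IndividualRecord], observation_interval: int
) -> tuple[np.ndarray, np.ndarray]:
    """(alive, eggs) matrices of shape (n, n_ages); ages 0..max death age."""
    n = len(records)
    max_age = max(_death_age(r) for r in records)
    n_ages = max_age + 1
    alive = np.zeros((n, n_ages))
    eggs = np.zeros((n, n_ages))
    for i, r in enumerate(records):
        alive[i, : _death_age(r)] = 1.0
        for x, e in _egg_days(r, observation_interval).items():
            eggs[i, x] = e
    return alive, eggs


def build_schedules(
    records: Sequence[IndividualRecord], observation_interval: int = 1
) -> tuple[AgeStageSchedule, AgeSchedule]:
    """Estimate the age-stage schedule and its marginal age schedules.

    ``s_xj`` is the fraction of the initial cohort alive in stage j at age x
    (age 0 = oviposition day); interval egg counts are spread uniformly within
    each observation interval.  Requires a non-empty cohort sharing one
    temperature.
    """
    if not records:
        raise ValueError("empty cohort")
    temps = {r.temperature for r in records}
    if len(temps) > 1:
        raise ValueError(f"records span several temperatures: {sorted(temps)}")
    n = len(records)
    max_age = max(_death_age(r) for r in records)
    ages = np.arange(max_age + 1)
    s_xj = np.zeros((ages.size, len(STAGES)))
    eggs_x = np.zeros(ages.size)
    stage_index = {s: k for k, s in enumerate(STAGES)}
    for r in records:
        bound = 0
        for stage in IMMATURE_STAGES:
            if stage not in r.stage_durations:
                break
            d = r.stage_durations[stage]
            s_xj[bound:bound + d, stage_index[stage]] += 1.0
            bound += d
        if r.reached_adult and r.adult_longevity:
            s_xj[bound:bound + r.adult_longevity, stage_index["adult"]] += 1.0
        for x, e in _egg_days(r, observation_interval).items():
            eggs_x[x] += e
    s_xj /= n
    adult_col = stage_index["adult"]
    adult_alive = s_xj[:, adult_col] * n
    f_xj = np.zeros_like(s_xj)
    nonzero = adult_alive > 0
    f_xj[nonzero, adult_col] = eggs_x[nonzero] / adult_alive[nonzero]
    lx = s_xj.sum(axis=1)
    mx = np.zeros_like(lx)
    alive = lx > 0
    mx[alive] = (s_xj[alive] * f_xj[alive]).sum(axis=1) / lx[alive]
    return (
        AgeStageSchedule(ages=ages, stages=STAGES, s_xj=s_xj, f_xj=f_xj),
        AgeSchedule(ages=ages, lx=lx, mx=mx),
    )


# ---------------------------------------------------------------------------
# Demographic parameters
# ---------------------------------------------------------------------------

def net_reproductive_rate(schedule: AgeSchedule) -> float:
    """R0 = Σ_x l_x m_x — expected offspring per newborn; equals the cohort's
    total egg output divided by its initial size."""
    return float(np.sum(schedule.lx * schedule.mx))


def _euler_lotka_root(phi: np.ndarray, tol: float = _EULER_TOL) -> float:
    """Unique real root of Σ_x exp(−r(x+1)) φ_x = 1 for φ = l·m ≥ 0.

    Bracketed bisection (the left-hand side is strictly decreasing in r)
    refined by Newton steps until |Σ − 1| < tol.
    """
    phi = np.asarray(phi, float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite schedule")
    R0 = phi.sum()
    if R0 <= 0:
        raise ValueError("R0 = 0: the Euler-Lotka equation has no root")
    w = np.arange(1, phi.size + 1, dtype=float)

    def f(r: float) -> float:
        return float(np.exp(-r * w) @ phi) - 1.0

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) > 0:
            break
        lo *= 2.0
    for _ in range(200):
        if f(hi) < 0:
            break
        hi *= 2.0
    # bisection to a narrow bracket
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    r = 0.5 * (lo + hi)
    for _ in range(50):
        fr = f(r)
        if abs(fr) < tol:
            break
        fprime = float(-(w * np.exp(-r * w)) @ phi)
        step = fr / fprime
        r_new = r - step
        if not lo <= r_new <= hi:
            r_new = 0.5 * (lo + hi)
        if f(r_new) > 0:
            lo = r_new
        else:
            hi = r_new
        r = r_new
    return r


def intrinsic_rate(schedule: AgeSchedule) -> float:
    """Intrinsic rate of increase r solving the Euler–Lotka equation."""
    return _euler_lotka_root(schedule.lx * schedule.mx)


def derived_params(R0: float, r: float) -> DemographicParams:
    """λ = e^r; T = ln(R0)/r and Dt = ln2/r where defined, else NaN."""
    if not math.isfinite(r):
        raise ValueError("r must be finite")
    lam = math.exp(r)
    T_gen = math.log(R0) / r if r != 0 else math.nan
    Dt = math.log(2) / r if r > 0 else math.nan
    return DemographicParams(R0=R0, r=r, lam=lam, T_gen=T_gen, Dt=Dt)


def cohort_params(
    records: Sequence[IndividualRecord], observation_interval: int = 1
) -> DemographicParams:
    """Point estimates of all demographic parameters for one cohort."""
    _, sched = build_schedules(records, observation_interval)
    R0 = net_reproductive_rate(sched)
    if R0 <= 0:
        return DemographicParams(R0=R0, r=math.nan, lam=math.nan,
                                 T_gen=math.nan, Dt=math.nan)
    r = intrinsic_rate(sched)
    return derived_params(R0, r)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _solve_r_many(phi: np.ndarray, iters: int = 80) -> np.ndarray:
    """Vectorised bisection for the Euler–Lotka root, one row per replicate."""
    B, X = phi.shape
    w = np.arange(1, X + 1, dtype=float)

    def f(r: np.ndarray) -> np.ndarray:
        return np.einsum("bx,bx->b", np.exp(-np.outer(r, w)), phi) - 1.0

    lo = np.full(B, -1.0)
    hi = np.full(B, 1.0)
    for _ in range(60):
        bad = f(lo) <= 0
        if not bad.any():
            break
        lo[bad] *= 2.0
    for _ in range(60):
        bad = f(hi) >= 0
        if not bad.any():
            break
        hi[bad] *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        above = f(mid) > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def _replicate_params(
    eggs: np.ndarray, rng: np.random.Generator, B: int
) -> dict[str, np.ndarray]:
    """Bootstrap replicate values of every parameter (NaN where undefined).

    ``eggs`` is the (n, n_ages) per-individual egg matrix; resampling
    individuals with replacement makes the replicate per-capita egg schedule
    φ_x a weighted column mean, from which R0 = Σφ and r solves Euler–Lotka.
    """
    n = eggs.shape[0]
    out = {p: np.full(B, np.nan) for p in PARAMETERS}
    done = 0
    probs = np.full(n, 1.0 / n)
    while done < B:
        b = min(_CHUNK, B - done)
        counts = rng.multinomial(n, probs, size=b).astype(float)
        phi = counts @ eggs / n
        R0 = phi.sum(axis=1)
        out["R0"][done:done + b] = R0
        pos = R0 > 0
        if pos.any():
            r = _solve_r_many(phi[pos])
            block = np.full(b, np.nan)
            block[pos] = r
            out["r"][done:done + b] = block
            out["lambda"][done:done + b] = np.exp(block)
            with np.errstate(divide="ignore", invalid="ignore"):
                T = np.where(block != 0, np.log(np.where(R0 > 0, R0, np.nan)) / block, np.nan)
                Dt = np.where(block > 0, math.log(2) / block, np.nan)
            out["T"][done:done + b] = T
            out["Dt"][done:done + b] = Dt
        done += b
    return out


def _estimates(params: DemographicParams) -> dict[str, float]:
    return {"R0": params.R0, "r": params.r, "lambda": params.lam,
            "T": params.T_gen, "Dt": params.Dt}


def bootstrap_params(
    records: Sequence[IndividualRecord],
    B: int = 10_000,
    seed: int = 0,
    observation_interval: int = 1,
) -> dict[str, BootstrapResult]:
    """Percentile-bootstrap 95% intervals for R0, r, λ, T, and Dt.

    Individuals are resampled with replacement; replicates with R0 = 0 leave
    r/λ/T/Dt undefined and are excluded from those percentiles (their count is
    reported as ``n_excluded``).  The R0 lower bound is clamped at zero — the
    net reproductive rate cannot be negative.  Deterministic for fixed
    ``(records, B, seed)``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not records:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    _, eggs = _cohort_arrays(records, observation_interval)
    reps = _replicate_params(eggs, rng, B)
    est = _estimates(cohort_params(records, observation_interval))
    results: dict[str, BootstrapResult] = {}
    for p in PARAMETERS:
        vals = reps[p]
        defined = vals[np.isfinite(vals)]
        n_excl = B - defined.size
        if defined.size == 0:
            warnings.warn(
                f"all {B} bootstrap replicates degenerate for {p}; CI undefined"
            )
            results[p] = BootstrapResult(est[p], math.nan, math.nan, B, seed, n_excl)
            continue
        lo, hi = np.percentile(defined, [2.5, 97.5])
        if p == "R0":
            lo = max(0.0, lo)
        if math.isfinite(est[p]):
            lo, hi = min(lo, est[p]), max(hi, est[p])
        results[p] = BootstrapResult(est[p], float(lo), float(hi), B, seed, n_excl)
    return results


def compare_temperatures(
    records_a: Sequence[IndividualRecord],
    records_b: Sequence[IndividualRecord],
    B: int = 10_000,
    seed: int = 0,
    observation_interval: int = 1,
) -> dict[str, ComparisonResult]:
    """Bootstrap test for parameter differences between two cohorts.

    Each replicate resamples both cohorts and takes the parameter difference
    (a − b); the two-sided p applies the small-sample correction
    p = 2·min((c+1)/(B+1), …) to the tail counts of the difference
    distribution.  Replicates where a parameter is undefined in either cohort
    are excluded (count reported).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not records_a or not records_b:
        raise ValueError("both cohorts must be non-empty")
    rng = np.random.default_rng(seed)
    _, eggs_a = _cohort_arrays(records_a, observation_interval)
    _, eggs_b = _cohort_arrays(records_b, observation_interval)
    reps_a = _replicate_params(eggs_a, rng, B)
    reps_b = _replicate_params(eggs_b, rng, B)
    est_a = _estimates(cohort_params(records_a, observation_interval))
    est_b = _estimates(cohort_params(records_b, observation_interval))
    results: dict[str, ComparisonResult] = {}
    for p in PARAMETERS:
        diff = reps_a[p] - reps_b[p]
        defined = diff[np.isfinite(diff)]
        n_excl = B - defined.size
        point = est_a[p] - est_b[p]
        if defined.size == 0:
            warnings.warn(f"no defined bootstrap replicates for {p}")
            results[p] = ComparisonResult(p, point, math.nan, math.nan,
                                          math.nan, B, n_excl)
            continue
        Beff = defined.size
        c_le = int(np.sum(defined <= 0))
        c_ge = int(np.sum(defined >= 0))
        pval = min(1.0, 2.0 * min((c_le + 1) / (Beff + 1), (c_ge + 1) / (Beff + 1)))
        lo, hi = np.percentile(defined, [2.5, 97.5])
        results[p] = ComparisonResult(p, point, float(lo), float(hi),
                                      float(pval), B, n_excl)
    return results
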