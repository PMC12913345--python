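"""Age-stage schedules, demographic parameters, Euler–Lotka, and bootstrap."""

import math

import numpy as np
import pytest

import parawasp as pw
from parawasp.lifetable import AgeSchedule, _euler_lotka_root

from conftest import single_temp_config


def rec(i, temp=25.0, durations=None, died=None, sex=None, longevity=None, eggs=()):
    return pw.IndividualRecord(
        individual_id=i, temperature=temp,
        stage_durations=durations or {}, died_in_stage=died, sex=sex,
        adult_longevity=longevity, egg_counts=tuple(eggs),
    )


def schedule(lx, mx):
    lx = np.asarray(lx, float)
    return AgeSchedule(ages=np.arange(lx.size), lx=lx, mx=np.asarray(mx, float))


def bisect_r(phi, tol=1e-13):
    """Independent bisection-only Euler-Lotka oracle."""
    phi = np.asarray(phi, float)
    w = np.arange(1, phi.size + 1)
    f = lambda r: float(np.exp(-r * w) @ phi) - 1.0
    lo, hi = -1.0, 1.0
    while f(lo) <= 0:
        lo *= 2
    while f(hi) >= 0:
        hi *= 2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSchedules:
    def test_lx_steps_at_observed_death(self):
        """Two individuals, one dying in the egg on day 3: l_x drops from 1.0
        to 0.5 at x = 3."""
        cohort = [
            rec(0, durations={"egg": 3}, died="egg"),
            rec(1, durations={"egg": 3, "larva": 5, "pupa": 4},
                sex="male", longevity=6),
        ]
        _, sched = pw.build_schedules(cohort)
        assert sched.lx[0] == 1.0
        assert sched.lx[2] == 1.0
        assert sched.lx[3] == 0.5
        assert sched.lx[12] == 0.5 and sched.lx[-1] == 0.0

    def test_identical_individuals_give_binary_occupancy(self):
        cohort = [rec(i, durations={"egg": 2, "larva": 3, "pupa": 2},
                      sex="female", longevity=4, eggs=(8, 2, 0, 0))
                  for i in range(5)]
        agestage, _ = pw.build_schedules(cohort)
        assert set(np.unique(agestage.s_xj)) <= {0.0, 1.0}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pw.build_schedules([])

    def test_mixed_temperatures_rejected(self):
        with pytest.raises(ValueError, match="temperatures"):
            pw.build_schedules([rec(0, temp=22.0, durations={"egg": 2}, died="egg"),
                                rec(1, temp=25.0, durations={"egg": 2}, died="egg")])

    def test_survival_to_emergence_matches_binomial_oracle(self, nasuta_config):
        """l_x at the mean emergence age sits within 2 SE of the configured
        egg-to-adult emergence survival."""
        n = 2_000
        cfg = single_temp_config(nasuta_config, 25.0, n)
        records = pw.generate_cohort(cfg, seed=23)
        _, sched = pw.build_schedules(records, cfg.observation_interval)
        emergence_ages = [sum(r.stage_durations.values()) for r in records
                          if r.reached_adult]
        x = int(round(np.mean(emergence_ages)))
        p = 0.82 ** 0.75  # product of the three immature stage survivals
        se = math.sqrt(p * (1 - p) / n)
        assert abs(sched.lx[x] - p) < 2.5 * se

    def test_conservation_of_total_eggs(self, nasuta_config):
        """Σ l_x m_x · n equals the cohort's total egg count (exactly, since
        interval counts are spread over the days each female lived)."""
        for interval_temp in ((25.0, 1), (25.0, 15)):
            temp, interval = interval_temp
            cfg = single_temp_config(nasuta_config, temp, 300)
            import dataclasses
            cfg = dataclasses.replace(cfg, observation_interval=interval)
            records = pw.generate_cohort(cfg, seed=29)
            _, sched = pw.build_schedules(records, interval)
            total = sum(r.total_eggs for r in records)
            assert np.sum(sched.lx * sched.mx) * len(records) == pytest.approx(
                total, rel=1e-10
            )


class TestParameters:
    def test_r0_hand_sum(self):
        assert pw.net_reproductive_rate(schedule([1, 0.5], [0, 10])) == 5.0
        assert pw.net_reproductive_rate(schedule([1, 0.5], [0, 0])) == 0.0

    def test_euler_lotka_identity_at_r0_of_one(self):
        assert pw.intrinsic_rate(schedule([1, 1], [0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_single_age_closed_form(self):
        """Reproduction concentrated at age 4 with l·m = 2: e^{-5r}·2 = 1."""
        sched = schedule([1, 1, 1, 1, 1], [0, 0, 0, 0, 2])
        assert pw.intrinsic_rate(sched) == pytest.approx(math.log(2) / 5, abs=1e-12)

    def test_zero_r0_has_no_root(self):
        with pytest.raises(ValueError, match="R0"):
            pw.intrinsic_rate(schedule([1, 0.5], [0, 0]))

    def test_solver_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            phi = rng.uniform(0, 0.5, size=rng.integers(5, 60))
            if phi.sum() <= 0:
                continue
            assert _euler_lotka_root(phi) == pytest.approx(bisect_r(phi), abs=1e-10)

    def test_derived_params(self):
        p = pw.derived_params(R0=math.e, r=1.0)
        assert p.lam == pytest.approx(math.e)
        assert p.T_gen == pytest.approx(1.0)
        assert p.Dt == pytest.approx(math.log(2))
        p0 = pw.derived_params(R0=1.0, r=0.0)
        assert p0.lam == 1.0
        assert math.isnan(p0.T_gen) and math.isnan(p0.Dt)

    def test_growth_sign_equivalences(self, nasuta_cohort, nasuta_config):
        """r > 0 ⇔ R0 > 1 ⇔ λ > 1 on every viable cohort."""
        interval = nasuta_config.observation_interval
        for temp in (16.0, 19.0, 22.0, 25.0, 28.0, 30.0):
            cohort = [r for r in nasuta_cohort if r.temperature == temp]
            params = pw.cohort_params(cohort, interval)
            if params.R0 <= 0:
                continue
            assert (params.r > 0) == (params.R0 > 1) == (params.lam > 1)
            assert params.lam == pytest.approx(math.exp(params.r), rel=1e-14)

    def test_r0_matches_generator_expectation(self, nasuta_config):
        """R0 on a large synthetic cohort approaches the closed-form
        expectation female_proportion × egg-to-adult survival × mean fecundity."""
        cfg = single_temp_config(nasuta_config, 25.0, 5_000)
        records = pw.generate_cohort(cfg, seed=37)
        _, sched = pw.build_schedules(records, cfg.observation_interval)
        expected = 0.59 * 0.82 * 27.0
        assert pw.net_reproductive_rate(sched) == pytest.approx(expected, rel=0.05)


class TestBootstrap:
    def test_deterministic_for_fixed_seed(self, nasuta_25, nasuta_config):
        interval = nasuta_config.observation_interval
        b1 = pw.bootstrap_params(nasuta_25, B=400, seed=5, observation_interval=interval)
        b2 = pw.bootstrap_params(nasuta_25, B=400, seed=5, observation_interval=interval)
        assert b1 == b2

    def test_identical_individuals_collapse_interval(self):
        cohort = [rec(i, durations={"egg": 2, "larva": 3, "pupa": 2},
                      sex="female", longevity=4, eggs=(6, 4, 0, 0))
                  for i in range(30)]
        boot = pw.bootstrap_params(cohort, B=200, seed=1)
        for p, b in boot.items():
            assert b.ci_low == pytest.approx(b.estimate, abs=1e-12)
            assert b.ci_high == pytest.approx(b.estimate, abs=1e-12)

    def test_r0_interval_nonnegative_and_ordered(self, nasuta_cohort, nasuta_config):
        cohort = [r for r in nasuta_cohort if r.temperature == 30.0]
        boot = pw.bootstrap_params(cohort, B=500, seed=9,
                                   observation_interval=nasuta_config.observation_interval)
        b = boot["R0"]
        assert b.ci_low >= 0.0
        assert b.ci_low <= b.estimate <= b.ci_high

    def test_small_B_rejected(self, nasuta_25):
        with pytest.raises(ValueError, match="B"):
            pw.bootstrap_params(nasuta_25, B=50, seed=0)

    def test_ci_covers_generator_expectation(self, nasuta_config):
        cfg = single_temp_config(nasuta_config, 25.0, 200)
        records = pw.generate_cohort(cfg, seed=41)
        boot = pw.bootstrap_params(records, B=2_000, seed=43,
                                   observation_interval=cfg.observation_interval)
        expected = 0.59 * 0.82 * 27.0
        assert boot["R0"].ci_low <= expected <= boot["R0"].ci_high


class TestCompare:
    def test_identical_cohorts_not_significant(self, nasuta_25, nasuta_config):
        interval = nasuta_config.observation_interval
        comp = pw.compare_temperatures(nasuta_25, nasuta_25, B=500, seed=3,
                                       observation_interval=interval)
        for p in ("R0", "r", "lambda"):
            assert comp[p].diff == 0.0
            assert comp[p].ci_low <= 0.0 <= comp[p].ci_high
            assert comp[p].p > 0.5

    def test_swap_negates_difference_with_same_p(self, nasuta_cohort, nasuta_config):
        interval = nasuta_config.observation_interval
        a = [r for r in nasuta_cohort if r.temperature == 22.0]
        b = [r for r in nasuta_cohort if r.temperature == 25.0]
        ab = pw.compare_temperatures(a, b, B=500, seed=7, observation_interval=interval)
        ba = pw.compare_temperatures(b, a, B=500, seed=7, observation_interval=interval)
        assert ab["R0"].diff == pytest.approx(-ba["R0"].diff)
        # mirrored resampling shares the seed, so the p-values coincide
        assert ab["R0"].p == pytest.approx(ba["R0"].p, abs=0.05)

    def test_doubled_fecundity_detected(self, nasuta_config):
        import dataclasses
        cfg = single_temp_config(nasuta_config, 25.0, 400)
        cfg2 = dataclasses.replace(cfg, fecundity_mean={**cfg.fecundity_mean, 25.0: 54.0})
        a = pw.generate_cohort(cfg, seed=51)
        b = pw.generate_cohort(cfg2, seed=52)
        comp = pw.compare_temperatures(a, b, B=1_000, seed=53,
                                       observation_interval=cfg.observation_interval)
        assert comp["R0"].p < 0.05
        assert comp["R0"].diff < 0
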