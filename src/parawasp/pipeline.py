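"""End-to-end orchestration: cohorts → comparisons → thermal fits → life
tables → generation tables, with reproducible configuration and a run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohorts, groupstats, lifetable, phenology, thermal

__all__ = ["RunConfig", "RunReport", "load_config", "validate_config", "run_pipeline"]

log = logging.getLogger("parawasp")

_MODES = ("synthetic", "file")
_SPECIES = (cohorts.P_NASUTA, cohorts.P_COFFEA)


@dataclass
class RunConfig:
    mode: str = "synthetic"
    species: str = cohorts.P_NASUTA
    seed: Optional[int] = None
    bootstrap_B: int = 10_000
    alpha: float = 0.05
    adjust: str = "none"
    cohort_path: Optional[str] = None
    isotherm_path: Optional[str] = None
    out_dir: str = "parawasp_out"
    # optional overrides of the study-design defaults (mainly for small runs)
    n_per_temperature: Optional[int] = None
    temperatures: Optional[list[float]] = None


@dataclass
class RunReport:
    outputs: dict[str, str]
    warnings: list[str]
    version: str
    config: dict
    seed: Optional[int]


def load_config(path) -> RunConfig:
    """Read a YAML/JSON key-value config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)


def _load_isotherms(path) -> list[phenology.IsothermSpec]:
    df = pd.read_csv(path, comment="#")
    specs = []
    for _, row in df.iterrows():
        specs.append(
            phenology.IsothermSpec(
                label=str(row["label"]),
                t_low=None if pd.isna(row["t_low"]) else float(row["t_low"]),
                t_high=None if pd.isna(row["t_high"]) else float(row["t_high"]),
                representative_Tm=float(row["representative_Tm"]),
            )
        )
    return specs


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff the config is runnable."""
    issues: list[str] = []
    if config.mode not in _MODES:
        issues.append(f"mode must be one of {_MODES}, got {config.mode!r}")
    if config.species not in _SPECIES:
        issues.append(f"species must be one of {_SPECIES}, got {config.species!r}")
    if config.mode == "synthetic" and config.seed is None:
        issues.append("seed is required in synthetic mode")
    if config.mode == "file" and not config.cohort_path:
        issues.append("cohort_path is required in file mode")
    if not 0.0 < config.alpha < 1.0:
        issues.append(f"alpha must lie in (0, 1), got {config.alpha}")
    if config.adjust not in groupstats.ADJUST_METHODS:
        issues.append(f"adjust must be one of {groupstats.ADJUST_METHODS}")
    if config.bootstrap_B < 100:
        issues.append("bootstrap_B must be >= 100")
    if config.n_per_temperature is not None and config.n_per_temperature < 0:
        issues.append("n_per_temperature must be >= 0")
    if config.isotherm_path:
        try:
            specs = _load_isotherms(config.isotherm_path)
            phenology._validate_partition(specs)
        except (OSError, KeyError, ValueError) as exc:
            issues.append(f"isotherm_path: {exc}")
    return issues


def _config_hash(config: RunConfig) -> str:
    # identifies the analysis (not where its outputs land)
    payload = dataclasses.asdict(config)
    payload.pop("out_dir")
    payload = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every analysis stage; identical config+seed → identical outputs.

    Stages that cannot run on the given data (e.g. life tables at temperatures
    where nothing reproduces, or thermal fits with fewer than two viable
    temperatures) are skipped with a logged warning rather than failing the
    run.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    outputs: dict[str, str] = {}
    warnings_list: list[str] = []

    def warn(msg: str) -> None:
        log.warning(msg)
        warnings_list.append(msg)

    # one seed fans out to independent per-stage streams
    root = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    ss_cohort, ss_boot, ss_pairs = root.spawn(3)
    log.info("parawasp %s | seed=%s B=%d hash=%s",
             __version__, config.seed, config.bootstrap_B, cfg_hash)

    # ------------------------------------------------------------------ cohort
    base = cohorts.paper_default_config(config.species)
    interval = base.observation_interval
    if config.mode == "synthetic":
        if config.temperatures is not None:
            base = dataclasses.replace(base, temperatures=list(config.temperatures))
        if config.n_per_temperature is not None:
            base = dataclasses.replace(base, n_per_temperature=config.n_per_temperature)
        records = cohorts.generate_cohort(base, _child_seed(ss_cohort))
    else:
        records = cohorts.read_cohort(config.cohort_path)
    cohort_file = out_dir / "cohort.csv"
    cohorts.write_cohort(records, cohort_file)
    outputs["cohort"] = str(cohort_file)

    # ----------------------------------------------------------- comparisons
    for response in groupstats.RESPONSES:
        samples = groupstats.samples_from_records(records, response)
        if len(samples) < 2:
            warn(f"comparisons for {response!r} skipped: fewer than 2 groups with data")
            continue
        if response == "survival":
            fit = groupstats.survival_logit_fit(samples, config.alpha, adjust="holm")
            gdf = pd.DataFrame(
                [dataclasses.asdict(g) for g in fit.groups]
            )
            cdf = pd.DataFrame([{
                "response": response, "group_a": c.group_a, "group_b": c.group_b,
                "z": c.z, "p": c.p_value, "adjusted_p": c.adjusted_p,
                "significant": c.significant,
            } for c in fit.contrasts])
            path = out_dir / "survival_logit.csv"
            _write_table(gdf, path, cfg_hash)
            outputs["survival_logit"] = str(path)
            path = out_dir / "comparisons_survival.csv"
            _write_table(cdf, path, cfg_hash)
            outputs["comparisons_survival"] = str(path)
            continue
        kw = groupstats.kruskal_wallis(samples)
        comps = groupstats.dunn_pairwise(samples, config.alpha, config.adjust)
        order = sorted(
            samples, key=lambda s: float(np.median(s.values)), reverse=True
        )
        letters = groupstats.compact_letter_display(
            comps, [s.group_label for s in order]
        )
        cdf = pd.DataFrame([{
            "response": response, "group_a": c.group_a, "group_b": c.group_b,
            "z": c.z, "p": c.p_value, "adjusted_p": c.adjusted_p,
            "significant": c.significant,
        } for c in comps])
        path = out_dir / f"comparisons_{response}.csv"
        _write_table(cdf, path, cfg_hash)
        outputs[f"comparisons_{response}"] = str(path)
        ldf = pd.DataFrame([{
            "group": s.group_label,
            "median": float(np.median(s.values)),
            "n": len(s.values),
            "letters": letters.letters[s.group_label],
            "kw_H": kw.H, "kw_df": kw.df, "kw_p": kw.p_value,
        } for s in samples])
        path = out_dir / f"letters_{response}.csv"
        _write_table(ldf, path, cfg_hash)
        outputs[f"letters_{response}"] = str(path)

    # ---------------------------------------------------------------- thermal
    thermal_rows = []
    egg_to_adult_params: Optional[thermal.ThermalParams] = None
    for stage in (*cohorts.IMMATURE_STAGES, thermal.EGG_TO_ADULT):
        try:
            points = thermal.development_rates(records, stage)
            fit = thermal.fit_linear(points)
            params = thermal.thermal_params(fit)
        except ValueError as exc:
            warn(f"thermal fit for stage {stage!r} skipped: {exc}")
            continue
        if stage == thermal.EGG_TO_ADULT:
            egg_to_adult_params = params
        thermal_rows.append({
            "species": config.species, "stage": stage,
            "T_min": fit.temperature_range[0], "T_max": fit.temperature_range[1],
            "a": fit.a, "b": fit.b, "R2": fit.r_squared,
            "t": params.t, "K": params.K, "n_points": fit.n_points,
        })
    if thermal_rows:
        path = out_dir / "thermal.csv"
        _write_table(pd.DataFrame(thermal_rows), path, cfg_hash)
        outputs["thermal"] = str(path)

    # ------------------------------------------------------------ life tables
    by_temp: dict[float, list] = {}
    for r in records:
        by_temp.setdefault(r.temperature, []).append(r)
    lt_temps = []
    for temp in sorted(by_temp):
        cohort = by_temp[temp]
        params = lifetable.cohort_params(cohort, interval)
        if params.R0 <= 0:
            warn(f"life table at {temp} °C skipped: no reproduction (R0 = 0)")
            continue
        boot = lifetable.bootstrap_params(
            cohort, B=config.bootstrap_B, seed=_child_seed(ss_boot),
            observation_interval=interval,
        )
        rows = [{
            "parameter": p, "estimate": b.estimate, "ci_low": b.ci_low,
            "ci_high": b.ci_high, "B": b.B, "seed": b.seed,
            "n_excluded": b.n_excluded,
        } for p, b in boot.items()]
        path = out_dir / f"lifetable_{temp:g}C.csv"
        _write_table(pd.DataFrame(rows), path, cfg_hash)
        outputs[f"lifetable_{temp:g}C"] = str(path)
        lt_temps.append(temp)

    if len(lt_temps) >= 2:
        pair_rows = []
        pair_seeds = ss_pairs.spawn(len(lt_temps) * (len(lt_temps) - 1) // 2)
        k = 0
        for i in range(len(lt_temps)):
            for j in range(i + 1, len(lt_temps)):
                ta, tb = lt_temps[i], lt_temps[j]
                comp = lifetable.compare_temperatures(
                    by_temp[ta], by_temp[tb], B=config.bootstrap_B,
                    seed=_child_seed(pair_seeds[k]),
                    observation_interval=interval,
                )
                k += 1
                for p, c in comp.items():
                    pair_rows.append({
                        "parameter": p, "temp_a": ta, "temp_b": tb,
                        "diff": c.diff, "ci_low": c.ci_low, "ci_high": c.ci_high,
                        "p": c.p, "n_excluded": c.n_excluded,
                    })
        path = out_dir / "lifetable_pairwise.csv"
        _write_table(pd.DataFrame(pair_rows), path, cfg_hash)
        outputs["lifetable_pairwise"] = str(path)

    # ------------------------------------------------------------ generations
    if egg_to_adult_params is None:
        warn("generation table skipped: no egg-to-adult thermal fit")
    else:
        isotherms = (_load_isotherms(config.isotherm_path)
                     if config.isotherm_path else None)
        table = phenology.monthly_table(
            {config.species: egg_to_adult_params}, isotherms
        )
        gdf = pd.DataFrame([{
            "species": g.species, "isotherm": g.isotherm,
            "month": g.month, "NG": g.NG,
        } for g in table])
        path = out_dir / "generations.csv"
        _write_table(gdf, path, cfg_hash)
        outputs["generations"] = str(path)

    report = RunReport(
        outputs=outputs,
        warnings=warnings_list,
        version=__version__,
        config=dataclasses.asdict(config),
        seed=config.seed,
    )
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, default=str)
    return report
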