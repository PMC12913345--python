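"""Nonparametric temperature comparisons and a logit survival model.

Development time, adult longevity, fecundity, and sex ratio across constant
temperatures are compared with tie-corrected Kruskal–Wallis tests followed by
Dunn's pairwise z tests; results are summarised with compact letter displays
(groups sharing a letter are not significantly different).  Egg-to-adult
survival is modelled with a saturated one-factor binomial GLM on the logit
scale, with pairwise Wald contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohorts import IndividualRecord

__all__ = [
    "GroupedSample",
    "KWResult",
    "PairwiseComparison",
    "LetterDisplay",
    "GroupLogit",
    "SurvivalLogitFit",
    "kruskal_wallis",
    "dunn_pairwise",
    "compact_letter_display",
    "survival_logit_fit",
    "samples_from_records",
]

ADJUST_METHODS = ("none", "holm", "bonferroni")


@dataclass(frozen=True)
class GroupedSample:
    group_label: float
    values: tuple[float, ...]


@dataclass(frozen=True)
class KWResult:
    H: float          # tie-corrected statistic (reported as chi-square)
    df: int
    p_value: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: float
    group_b: float
    z: float
    p_value: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class LetterDisplay:
    letters: dict[float, str]


def _check_groups(samples: Sequence[GroupedSample]) -> None:
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if len(s.values) == 0:
            raise ValueError(f"group {s.group_label} is empty")


def kruskal_wallis(samples: Sequence[GroupedSample]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p on k−1 df.

    Degenerate input where every pooled value is identical carries no rank
    information and is reported as H = 0, p = 1.
    """
    _check_groups(samples)
    df = len(samples) - 1
    pooled = np.concatenate([np.asarray(s.values, float) for s in samples])
    if np.all(pooled == pooled[0]):
        return KWResult(H=0.0, df=df, p_value=1.0)
    H, p = stats.kruskal(*[list(s.values) for s in samples])
    return KWResult(H=float(H), df=df, p_value=float(p))


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals.copy()
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(pvals, method=method)[1]


def dunn_pairwise(
    samples: Sequence[GroupedSample],
    alpha: float = 0.05,
    adjust: str = "none",
) -> list[PairwiseComparison]:
    """Dunn's rank-based multiple-comparison z tests after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j) )
    with midranks over the pooled sample and a tie correction summed over tied
    groups of size t.  Two-sided p from the standard normal; adjusted per
    ``adjust`` (none | holm | bonferroni).
    """
    _check_groups(samples)
    values = [np.asarray(s.values, float) for s in samples]
    pooled = np.concatenate(values)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start:start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    comps: list[PairwiseComparison] = []
    zs, ps = [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = math.sqrt(sigma2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            zs.append(z)
            ps.append(2.0 * stats.norm.sf(abs(z)))
    adj = _adjust(np.asarray(ps), adjust)
    k = 0
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            comps.append(
                PairwiseComparison(
                    group_a=samples[i].group_label,
                    group_b=samples[j].group_label,
                    z=float(zs[k]),
                    p_value=float(ps[k]),
                    adjusted_p=float(min(1.0, adj[k])),
                    significant=bool(adj[k] < alpha),
                )
            )
            k += 1
    return comps


def compact_letter_display(
    comparisons: Sequence[PairwiseComparison],
    groups_ordered_by_median: Sequence[float],
) -> LetterDisplay:
    """Insert-and-absorb compact letter display.

    Starts from one letter column holding every group; each significant pair
    splits every column containing both members; columns that become subsets
    of another are absorbed.  Letters run from 'a' in the supplied (descending
    median) group order, so the top-ranked group always carries 'a'.
    Non-transitive significance patterns are representable (a group may carry
    several letters).
    """
    order = list(groups_ordered_by_median)
    columns: list[set[float]] = [set(order)]
    for comp in comparisons:
        if not comp.significant:
            continue
        new_columns: list[set[float]] = []
        for col in columns:
            if comp.group_a in col and comp.group_b in col:
                new_columns.append(col - {comp.group_a})
                new_columns.append(col - {comp.group_b})
            else:
                new_columns.append(col)
        # absorb subsets
        columns = []
        for col in new_columns:
            if not col:
                continue
            if any(col < other for other in new_columns if other is not col):
                continue
            if col in columns:
                continue
            columns.append(col)
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in order}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx)
        for g in order:
            if g in col:
                letters[g] += letter
    return LetterDisplay(letters=letters)


# ---------------------------------------------------------------------------
# Survival GLM (saturated one-factor binomial, logit link)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupLogit:
    group_label: float
    n: int
    successes: int
    proportion: float
    logit: float
    se: float
    continuity_corrected: bool


@dataclass(frozen=True)
class SurvivalLogitFit:
    groups: tuple[GroupLogit, ...]
    contrasts: tuple[PairwiseComparison, ...]


def survival_logit_fit(
    binary_outcomes: Sequence[GroupedSample],
    alpha: float = 0.05,
    adjust: str = "holm",
) -> SurvivalLogitFit:
    """Per-group logit MLEs and pairwise Wald contrasts for 0/1 outcomes.

    For the saturated one-factor binomial GLM the group MLE is logit(p̂) with
    SE = sqrt(1/s + 1/f) (s successes, f failures).  Groups with s = 0 or
    f = 0 are flagged and handled with a +0.5 continuity correction.  Contrast
    z = (logit_i − logit_j)/sqrt(SE_i² + SE_j²), adjusted per ``adjust``.
    """
    _check_groups(binary_outcomes)
    groups: list[GroupLogit] = []
    for s in binary_outcomes:
        vals = np.asarray(s.values, float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"group {s.group_label}: outcomes must be 0/1")
        n = vals.size
        succ = int(vals.sum())
        fail = n - succ
        corrected = succ == 0 or fail == 0
        sc, fc = (succ + 0.5, fail + 0.5) if corrected else (float(succ), float(fail))
        groups.append(
            GroupLogit(
                group_label=s.group_label,
                n=n,
                successes=succ,
                proportion=succ / n,
                logit=math.log(sc / fc),
                se=math.sqrt(1.0 / sc + 1.0 / fc),
                continuity_corrected=corrected,
            )
        )
    zs, ps, pairs = [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            se = math.sqrt(gi.se**2 + gj.se**2)
            z = (gi.logit - gj.logit) / se
            zs.append(z)
            ps.append(2.0 * stats.norm.sf(abs(z)))
            pairs.append((gi.group_label, gj.group_label))
    adj = _adjust(np.asarray(ps), adjust) if ps else np.array([])
    contrasts = tuple(
        PairwiseComparison(
            group_a=a, group_b=b, z=float(z), p_value=float(p),
            adjusted_p=float(min(1.0, q)), significant=bool(q < alpha),
        )
        for (a, b), z, p, q in zip(pairs, zs, ps, adj)
    )
    return SurvivalLogitFit(groups=tuple(groups), contrasts=contrasts)


# ---------------------------------------------------------------------------
# Response extraction from cohort records
# ---------------------------------------------------------------------------

RESPONSES = ("development", "longevity", "fecundity", "sex_ratio", "survival")


def samples_from_records(
    records: Sequence[IndividualRecord], response: str
) -> list[GroupedSample]:
    """Group a cohort into per-temperature samples for one response variable.

    development: total immature development (days) of individuals reaching
    adulthood; longevity: adult longevity (days) of females surviving
    establishment; fecundity: lifetime egg totals of those females; sex_ratio:
    0/1 female indicators among emerged adults; survival: 0/1 egg-to-adult
    outcome for every individual.  Temperatures with no qualifying individual
    are dropped.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    by_temp: dict[float, list[float]] = {}
    for r in records:
        emerged = r.reached_adult
        established = r.died_in_stage is None
        value: Optional[float] = None
        if response == "development" and emerged:
            value = float(sum(r.stage_durations.values()))
        elif response == "longevity" and established and r.sex == "female":
            value = float(r.adult_longevity)
        elif response == "fecundity" and established and r.sex == "female":
            value = float(r.total_eggs)
        elif response == "sex_ratio" and emerged:
            value = 1.0 if r.sex == "female" else 0.0
        elif response == "survival":
            value = 1.0 if established else 0.0
        if value is not None:
            by_temp.setdefault(r.temperature, []).append(value)
    return [
        GroupedSample(group_label=t, values=tuple(v))
        for t, v in sorted(by_temp.items())
    ]
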