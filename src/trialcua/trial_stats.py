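"""Clinical-effectiveness comparisons on disability scores.

Within-arm improvement is summarised as the mean change from baseline with a
t-based 95% CI (improvement positive: baseline minus follow-up). Between-arm
contrasts use the Mann-Whitney U test; the within-participant trajectory over
the three assessments uses the Friedman test. Both rank tests use midranks
for ties; the Mann-Whitney p-value is computed by exact enumeration of rank
assignments for small samples (combined n <= 12) and otherwise by the normal
approximation with tie-corrected variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChangeSummary",
    "MannWhitneyResult",
    "FriedmanResult",
    "mean_change_from_baseline",
    "mann_whitney",
    "friedman",
    "between_arm_difference",
    "effectiveness_table",
]

EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class ChangeSummary:
    arm: str
    timepoint: str
    mean_change: float
    ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    u_x: float
    u_y: float
    p_value: float
    method: str


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    df: int


def mean_change_from_baseline(
    baseline, followup, arm: str = "", timepoint: str = ""
) -> ChangeSummary:
    """Mean within-participant improvement (baseline - follow-up) with t-CI.

    Scores are paired by position; improvement is positive when the
    follow-up score is lower (less disability).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and follow-up must be paired 1-d score vectors")
    n = b.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    change = b - f
    mean = float(change.mean())
    se = float(change.std(ddof=1) / np.sqrt(n))
    half = stats.t.ppf(0.975, n - 1) * se
    return ChangeSummary(arm=arm, timepoint=timepoint, mean_change=mean, ci95=(mean - half, mean + half), n=n)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    nx, ny = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))  # midranks for ties
    rank_sum_x = ranks[:nx].sum()
    u_x = rank_sum_x - nx * (nx + 1) / 2.0
    return float(u_x), float(nx * ny - u_x)


def _exact_two_sided_p(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Two-sided p by enumerating all assignments of the pooled midranks."""
    n = ranks.size
    mu = nx * (n - nx) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12  # guard float fuzz in midranks
    hits = 0
    for idx in combinations(range(n), nx):
        rs = ranks[list(idx)].sum()
        u = rs - nx * (nx + 1) / 2.0
        if abs(u - mu) >= dev_obs:
            hits += 1
    return hits / comb(n, nx)


def mann_whitney(x, y) -> MannWhitneyResult:
    """Mann-Whitney U test with midranks and a two-sided p-value.

    ``u_x + u_y == len(x) * len(y)`` always. For combined samples of at most
    12 observations the p-value enumerates all rank assignments exactly
    (valid with ties since midranks are enumerated); larger samples use the
    normal approximation with tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    u_x, u_y = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(ranks, nx, u_x)
        method = "exact"
    else:
        mu = nx * ny / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum()
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
        if sigma2 <= 0:  # all observations identical
            return MannWhitneyResult(u_x, u_y, 1.0, "asymptotic")
        z = (abs(u_x - mu) - 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
        method = "asymptotic"
    return MannWhitneyResult(u_x, u_y, float(p), method)


def friedman(scores) -> FriedmanResult:
    """Friedman chi-squared over repeated measures (participants x timepoints).

    Ranks each participant's scores across the timepoints with midranks for
    ties and applies the tie-corrected chi-squared statistic on k-1 degrees
    of freedom. When every participant's scores are completely tied the
    statistic is 0 (no evidence of a time effect).
    """
    table = np.asarray(scores, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("scores must be a 2-d table with >= 2 timepoints")
    n, k = table.shape
    if n < 2:
        raise ValueError("need at least two participants")
    if not np.isfinite(table).all():
        raise ValueError("missing cells are not allowed")
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    # tie correction: t = sizes of tie groups within each row
    tie_sum = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1.0))
    if correction <= 0:  # every row fully tied
        return FriedmanResult(0.0, 1.0, k - 1)
    stat /= correction
    stat = max(stat, 0.0)
    return FriedmanResult(float(stat), float(stats.chi2.sf(stat, k - 1)), k - 1)


def between_arm_difference(changes_new, changes_ref) -> tuple[float, tuple[float, float], float]:
    """Difference of mean changes (new - reference) with Welch 95% CI and p.

    The contrast is the arithmetic difference of the two arms' mean change
    scores; the interval and p-value come from Welch's unequal-variance
    t-test.
    """
    a = np.asarray(changes_new, dtype=float)
    b = np.asarray(changes_ref, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per arm")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return float(a.mean() - b.mean()), (float(ci.low), float(ci.high)), float(res.pvalue)


def effectiveness_table(
    cohort: pd.DataFrame,
    new_arm: str = "TBMT",
    ref_arm: str = "CBMT",
) -> pd.DataFrame:
    """Arm-by-week effectiveness report on ODI change scores.

    One row per follow-up week: per-arm mean change from baseline with its
    t-CI, the between-arm difference (new minus reference) with Welch CI,
    and the Mann-Whitney p-value comparing the arms' change scores.
    """
    for col in ("arm", "odi_baseline", "odi_week4", "odi_week8"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    rows = []
    for week, col in (("week4", "odi_week4"), ("week8", "odi_week8")):
        per_arm = {}
        changes = {}
        for arm in (ref_arm, new_arm):
            sub = cohort[cohort["arm"] == arm]
            summ = mean_change_from_baseline(sub["odi_baseline"], sub[col], arm=arm, timepoint=week)
            per_arm[arm] = summ
            changes[arm] = (sub["odi_baseline"] - sub[col]).to_numpy()
        diff, diff_ci, _ = between_arm_difference(changes[new_arm], changes[ref_arm])
        mw = mann_whitney(changes[new_arm], changes[ref_arm])
        rows.append(
            {
                "timepoint": week,
                f"{ref_arm}_mean_change": per_arm[ref_arm].mean_change,
                f"{ref_arm}_ci_low": per_arm[ref_arm].ci95[0],
                f"{ref_arm}_ci_high": per_arm[ref_arm].ci95[1],
                f"{new_arm}_mean_change": per_arm[new_arm].mean_change,
                f"{new_arm}_ci_low": per_arm[new_arm].ci95[0],
                f"{new_arm}_ci_high": per_arm[new_arm].ci95[1],
                "difference": diff,
                "difference_ci_low": diff_ci[0],
                "difference_ci_high": diff_ci[1],
                "mann_whitney_p": mw.p_value,
            }
        )
    return pd.DataFrame(rows)
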