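"""Disability scoring, utility mapping and QALY construction.

The Oswestry Disability Index (ODI) is a 10-item back-pain disability
questionnaire; each item is scored 0 (no limitation) to 5 (worst), and the
total is rescaled to 0-100 with higher scores meaning worse disability.
Health-state utility is obtained from the ODI through a published linear
mapping onto the SF-6D scale,

    SF-6D = 0.78275 - 0.00518 * ODI,

which stays strictly inside (0, 1) for any ODI in [0, 100]. Quality-adjusted
life years (QALYs) over a short follow-up are utility multiplied by time in
years; with assessments at weeks 4 and 8 the default convention averages the
two utilities and applies the full 8-week horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MappingCoefficients",
    "ODI_TO_SF6D",
    "QalyResult",
    "odi_score",
    "map_odi_to_sf6d",
    "qaly",
    "arm_mean_qaly",
    "qalys_from_cohort",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class MappingCoefficients:
    """Linear ODI -> SF-6D mapping: ``utility = intercept - slope * ODI``.

    The defaults come from a published regression of SF-6D utilities on ODI
    totals in back-pain patients. Validity requires the mapped utility to
    stay inside (0, 1) over the whole ODI range and to decrease with ODI.
    """

    intercept: float = 0.78275
    slope: float = 0.00518

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive (utility decreases with disability)")
        if not 0.0 < self.intercept < 1.0:
            raise ValueError("intercept must lie in (0, 1)")
        if self.intercept - self.slope * 100.0 <= 0.0:
            raise ValueError("mapping must stay positive over ODI in [0, 100]")


ODI_TO_SF6D = MappingCoefficients()


@dataclass(frozen=True)
class QalyResult:
    participant_id: str
    sf6d_week4: float
    sf6d_week8: float
    qaly: float


def odi_score(item_responses: Sequence, answered: int | None = None) -> float:
    """Total ODI on the 0-100 scale from the ten item responses.

    Missing items (``None`` or NaN) are allowed; the total is rescaled to the
    items actually answered: ``100 * sum(answered items) / (5 * n_answered)``.

    Parameters
    ----------
    item_responses : sequence of length 10
        Integer responses in [0, 5]; missing entries may be ``None``/NaN.
    answered : int, optional
        Expected number of answered items, checked against the responses if
        given.
    """
    items = list(item_responses)
    if len(items) != 10:
        raise ValueError(f"expected 10 item responses, got {len(items)}")
    present = [v for v in items if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not present:
        raise ValueError("at least one item must be answered")
    for v in present:
        if not float(v).is_integer() or not 0 <= int(v) <= 5:
            raise ValueError(f"item response {v!r} outside the 0-5 range")
    if answered is not None and answered != len(present):
        raise ValueError(f"answered={answered} but {len(present)} non-missing responses supplied")
    return 100.0 * sum(int(v) for v in present) / (5.0 * len(present))


def map_odi_to_sf6d(odi: float, coeffs: MappingCoefficients = ODI_TO_SF6D) -> float:
    """SF-6D utility for an ODI total via the linear mapping.

    ODI outside [0, 100] is rejected rather than clamped: the mapping is only
    calibrated on the valid score range.
    """
    odi = float(odi)
    if not 0.0 <= odi <= 100.0:
        raise ValueError(f"ODI must lie in [0, 100], got {odi}")
    return coeffs.intercept - coeffs.slope * odi


def qaly(
    sf6d_week4: float,
    sf6d_week8: float,
    horizon_weeks: float = 8.0,
    convention: str = "mean_utility",
) -> float:
    """QALYs accrued over the follow-up horizon from the two utility assessments.

    conventions
    -----------
    ``"mean_utility"`` (default)
        mean(u4, u8) * horizon_weeks / 52 — the average utility is held over
        the whole horizon.
    ``"period_average"``
        mean(u4 * 4/52, u8 * horizon/52) — each assessment is credited with
        its own elapsed duration and the two period QALYs are averaged.
    """
    for name, u in (("sf6d_week4", sf6d_week4), ("sf6d_week8", sf6d_week8)):
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {u}")
    if horizon_weeks <= 0:
        raise ValueError("horizon_weeks must be positive")
    if convention == "mean_utility":
        return 0.5 * (sf6d_week4 + sf6d_week8) * horizon_weeks / WEEKS_PER_YEAR
    if convention == "period_average":
        return 0.5 * (sf6d_week4 * 4.0 / WEEKS_PER_YEAR + sf6d_week8 * horizon_weeks / WEEKS_PER_YEAR)
    raise ValueError(f"unknown QALY convention {convention!r}")


def arm_mean_qaly(
    qalys: Iterable[float],
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Arm mean QALY with a 95% percentile-bootstrap confidence interval.

    Resamples within the arm with replacement; an arm whose members are all
    identical yields a degenerate (point) interval.
    """
    values = np.asarray(list(qalys), dtype=float)
    if values.size == 0:
        raise ValueError("empty QALY collection")
    mean = float(values.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    boot = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return mean, (float(lo), float(hi))


def qalys_from_cohort(
    cohort: pd.DataFrame,
    coeffs: MappingCoefficients = ODI_TO_SF6D,
    horizon_weeks: float = 8.0,
    convention: str = "mean_utility",
) -> pd.DataFrame:
    """Per-participant utilities and QALYs from a wide cohort table.

    Expects columns ``odi_week4`` and ``odi_week8``; returns a copy with
    ``sf6d_week4``, ``sf6d_week8`` and ``qaly`` appended.
    """
    for col in ("odi_week4", "odi_week8"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    out = cohort.copy()
    out["sf6d_week4"] = [map_odi_to_sf6d(v, coeffs) for v in out["odi_week4"]]
    out["sf6d_week8"] = [map_odi_to_sf6d(v, coeffs) for v in out["odi_week8"]]
    out["qaly"] = [
        qaly(u4, u8, horizon_weeks=horizon_weeks, convention=convention)
        for u4, u8 in zip(out["sf6d_week4"], out["sf6d_week8"])
    ]
    return out
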