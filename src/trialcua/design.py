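"""Trial-design arithmetic for a two-arm parallel trial.

Covers the three pre-trial computations a small rehabilitation RCT needs:
the two-proportion sample-size formula ``m = c[p1(1-p1) + p2(1-p2)]/(p1-p2)^2``
(with ``c = 7.9`` giving 80% power at a two-sided 5% level), inflation of the
total for anticipated attrition, and permuted-block allocation sequences that
keep arm sizes balanced after every complete block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DesignParams",
    "SampleSizePlan",
    "sample_size_per_group",
    "adjust_for_attrition",
    "plan_sample_size",
    "permuted_block_sequence",
    "write_allocation",
]

#: power constant for 80% power at two-sided alpha = 0.05
POWER_CONSTANT_80 = 7.9


@dataclass(frozen=True)
class DesignParams:
    """Design inputs for a two-arm trial powered on a difference of proportions.

    Parameters
    ----------
    p1, p2 : float
        Anticipated success proportions in the two arms, each in [0, 1] and
        distinct (equal proportions make the sample size undefined).
    c : float
        Power constant; 7.9 corresponds to 80% power.
    attrition_rate : float
        Anticipated drop-out fraction in [0, 1).
    block_size : int
        Permuted-block size; must be divisible by ``n_arms``.
    n_arms : int
        Number of arms (>= 2).
    """

    p1: float
    p2: float
    c: float = POWER_CONSTANT_80
    attrition_rate: float = 0.10
    block_size: int = 4
    n_arms: int = 2

    def __post_init__(self) -> None:
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p1 == self.p2:
            raise ValueError("p1 and p2 must differ; equal proportions give an undefined sample size")
        if self.c <= 0:
            raise ValueError("power constant c must be positive")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise ValueError("attrition_rate must lie in [0, 1)")
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")
        if self.block_size <= 0 or self.block_size % self.n_arms != 0:
            raise ValueError("block_size must be a positive multiple of n_arms")


def sample_size_per_group(p1: float, p2: float, c: float = POWER_CONSTANT_80) -> float:
    """Per-group sample size for comparing two proportions.

    Returns ``c * [p1(1-p1) + p2(1-p2)] / (p1-p2)**2`` — the classic
    normal-approximation formula with the power/significance level folded
    into the constant ``c``.

    Raises
    ------
    ValueError
        If a proportion is outside [0, 1], ``c <= 0``, or ``p1 == p2``
        (the difference in the denominator vanishes and the size is
        undefined, rather than infinite).
    """
    for name, v in (("p1", p1), ("p2", p2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if c <= 0:
        raise ValueError("power constant c must be positive")
    if p1 == p2:
        raise ValueError("sample size undefined for equal proportions (zero denominator)")
    return c * (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / (p1 - p2) ** 2


def adjust_for_attrition(n_total: int, rate: float, mode: str = "nearest") -> int:
    """Inflate a total sample size for anticipated attrition.

    ``n_total * (1 + rate)`` rounded to an integer. ``mode="nearest"``
    (default) rounds half away from zero, so a 10% allowance on 42 gives
    46 (from 46.2); ``mode="ceil"`` always rounds up (47 in that example).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if rate < 0:
        raise ValueError("attrition rate must be non-negative")
    if rate >= 1:
        raise ValueError("attrition rate must be < 1")
    raw = n_total * (1.0 + rate)
    if mode == "nearest":
        adjusted = math.floor(raw + 0.5)
    elif mode == "ceil":
        adjusted = math.ceil(raw)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return max(adjusted, n_total)


@dataclass(frozen=True)
class SampleSizePlan:
    """Result of the full design chain: raw size -> per group -> total -> attrition-adjusted."""

    per_group_raw: float
    per_group: int
    total: int
    adjusted_total: int


def plan_sample_size(
    p1: float,
    p2: float,
    c: float = POWER_CONSTANT_80,
    n_arms: int = 2,
    attrition_rate: float = 0.0,
    attrition_rounding: str = "nearest",
) -> SampleSizePlan:
    """Run the whole design chain and return every intermediate quantity.

    The fractional per-group size is rounded up to whole participants,
    multiplied by the number of arms, then inflated for attrition.
    """
    raw = sample_size_per_group(p1, p2, c)
    per_group = math.ceil(raw)
    total = per_group * n_arms
    adjusted = adjust_for_attrition(total, attrition_rate, mode=attrition_rounding)
    return SampleSizePlan(raw, per_group, total, adjusted)


def permuted_block_sequence(
    n: int,
    block_size: int = 4,
    seed: int | None = None,
    arms: Sequence[str] = ("A", "B"),
) -> list[str]:
    """Permuted-block allocation sequence of length ``n``.

    Each complete block of ``block_size`` contains ``block_size / len(arms)``
    assignments to every arm, in an order drawn uniformly at random from the
    balanced permutations of the block (6 distinct orderings for two arms in
    blocks of four). A trailing partial block, if ``n`` is not a multiple of
    the block size, is the leading portion of one more permuted block, so the
    final imbalance is bounded by the block composition.

    The sequence is deterministic for a fixed ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    n_arms = len(arms)
    if n_arms < 2:
        raise ValueError("need at least two arms")
    if block_size <= 0 or block_size % n_arms != 0:
        raise ValueError(f"block_size {block_size} is not divisible by the number of arms ({n_arms})")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.asarray(arms, dtype=object), block_size // n_arms)
    seq: list[str] = []
    while len(seq) < n:
        seq.extend(rng.permutation(base).tolist())
    return seq[:n]


def write_allocation(sequence: Sequence[str], path) -> None:
    """Write an allocation sequence as two-column delimited text (index, arm)."""
    if len(sequence) == 0:
        raise ValueError("empty allocation sequence")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("participant_index,arm_label\n")
        for i, arm in enumerate(sequence, start=1):
            fh.write(f"{i},{arm}\n")
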