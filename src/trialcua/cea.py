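"""Incremental cost-utility analysis with a participant-level bootstrap.

The incremental cost-effectiveness ratio (ICER) compares a new intervention
against a reference arm:

    ICER = (C_new - C_ref) / (E_new - E_ref) = dC / dE

with effects measured in QALYs. A numeric ratio is only meaningful in the
trade-off quadrants of the cost-effectiveness plane; when the new arm is
cheaper *and* more effective (dC < 0, dE > 0) it *dominates* the reference
and no ratio is reported, and symmetrically for "dominated". Uncertainty is
propagated by a nonparametric bootstrap that resamples participants with
replacement within each arm, preserving arm sizes, and recomputes the
incremental pair for each replicate; the replicate cloud on the plane and
its quadrant proportions summarise joint cost-effect uncertainty.

The module is organised statsmodels-style: :class:`CostUtilityModel` is
built from participant-level data and ``fit()`` returns a
:class:`CEAResults` carrying estimates, intervals, replicates and
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CostModel, default_cost_model, naira_to_usd
from .outcomes import ODI_TO_SF6D, MappingCoefficients, qalys_from_cohort

__all__ = [
    "ArmSummary",
    "Icer",
    "CostUtilityModel",
    "CEAResults",
    "incremental",
    "icer",
    "bootstrap_cea",
    "ce_plane_summary",
    "quadrant_of",
    "plot_ce_plane",
    "ceac",
]

QUADRANTS = ("NE", "SE", "SW", "NW")


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm point estimates with percentile-bootstrap intervals."""

    arm: str
    n: int
    mean_cost_naira: float
    mean_qaly: float
    cost_ci: tuple[float, float] | None = None
    qaly_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class Icer:
    """ICER outcome: a numeric ratio in trade-off quadrants, else a label.

    ``label`` is one of ``dominant`` (cheaper and more effective),
    ``dominated`` (costlier and less effective), ``tradeoff_NE`` /
    ``tradeoff_SW`` (numeric ratio applies), or ``indeterminate`` (zero
    incremental effect; no division is attempted). ``value`` is ``None``
    unless the label is a trade-off.
    """

    value: float | None
    label: str


def incremental(summary_new: ArmSummary, summary_ref: ArmSummary) -> tuple[float, float]:
    """(dCost, dEffect): new arm minus reference arm, component-wise."""
    return (
        summary_new.mean_cost_naira - summary_ref.mean_cost_naira,
        summary_new.mean_qaly - summary_ref.mean_qaly,
    )


def icer(delta_cost: float, delta_effect: float) -> Icer:
    """Classify (dC, dE) and compute the ratio where it is meaningful.

    Dominance labels require strict inequalities in both coordinates; a zero
    incremental effect is "indeterminate" (the ratio is undefined); zero
    incremental cost with a nonzero effect yields a ratio of exactly 0 under
    the adjacent trade-off label.
    """
    if delta_effect == 0:
        return Icer(None, "indeterminate")
    if delta_cost < 0 and delta_effect > 0:
        return Icer(None, "dominant")
    if delta_cost > 0 and delta_effect < 0:
        return Icer(None, "dominated")
    label = "tradeoff_NE" if delta_effect > 0 else "tradeoff_SW"
    return Icer(delta_cost / delta_effect, label)


def quadrant_of(delta_effect: float, delta_cost: float) -> str:
    """Cost-effectiveness-plane quadrant (dE horizontal, dC vertical).

    SE (dE>0, dC<0) is the dominant quadrant. Points exactly on an axis are
    assigned to the quadrant reached next when sweeping clockwise: the +dC
    half-axis to NE, +dE to SE, -dC to SW, -dE to NW; the origin to NE. With
    continuous data ties have probability ~0; the rule only pins down edge
    cases deterministically.
    """
    if delta_effect > 0:
        if delta_cost > 0:
            return "NE"
        return "SE"  # includes dC == 0
    if delta_effect < 0:
        if delta_cost < 0:
            return "SW"
        return "NW"  # includes dC == 0
    # dE == 0: on the cost axis
    return "NE" if delta_cost >= 0 else "SW"


def _quadrant_proportions(delta_effects: np.ndarray, delta_costs: np.ndarray) -> dict[str, float]:
    de = np.asarray(delta_effects, dtype=float)
    dc = np.asarray(delta_costs, dtype=float)
    n = de.size
    counts = dict.fromkeys(QUADRANTS, 0)
    ne = (de > 0) & (dc > 0)
    se = (de > 0) & (dc <= 0)
    sw = (de < 0) & (dc < 0)
    nw = (de < 0) & (dc >= 0)
    on_cost_axis = de == 0
    counts["NE"] = int(ne.sum() + (on_cost_axis & (dc >= 0)).sum())
    counts["SE"] = int(se.sum())
    counts["SW"] = int(sw.sum() + (on_cost_axis & (dc < 0)).sum())
    counts["NW"] = int(nw.sum())
    return {q: counts[q] / n for q in QUADRANTS}


class CEAResults:
    """Results of a fitted cost-utility comparison.

    Attributes
    ----------
    arm_new, arm_ref : ArmSummary
        Per-arm means with bootstrap intervals.
    delta_cost, delta_effect : float
        Incremental cost (naira) and effect (QALYs), new minus reference.
    icer : Icer
        Ratio/dominance classification of the point estimate.
    replicates : pandas.DataFrame
        One row per bootstrap replicate, columns ``delta_cost`` and
        ``delta_effect``.
    delta_cost_ci, delta_effect_ci : (float, float)
        95% bootstrap intervals for the incremental quantities.
    quadrant_proportions : dict
        Fraction of replicates in each plane quadrant (sums to 1).
    """

    def __init__(
        self,
        arm_new: ArmSummary,
        arm_ref: ArmSummary,
        replicates: pd.DataFrame,
        delta_cost_ci: tuple[float, float],
        delta_effect_ci: tuple[float, float],
        seed: int | None,
        ci_method: str,
        exchange_rate: float | None = None,
    ) -> None:
        self.arm_new = arm_new
        self.arm_ref = arm_ref
        self.delta_cost, self.delta_effect = incremental(arm_new, arm_ref)
        self.icer = icer(self.delta_cost, self.delta_effect)
        self.replicates = replicates
        self.delta_cost_ci = delta_cost_ci
        self.delta_effect_ci = delta_effect_ci
        self.quadrant_proportions = _quadrant_proportions(
            replicates["delta_effect"].to_numpy(), replicates["delta_cost"].to_numpy()
        )
        self.seed = seed
        self.ci_method = ci_method
        self.exchange_rate = exchange_rate

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    def summary(self) -> str:
        """Plain-text report: arm means, incrementals, ICER and plane quadrants."""
        rate = self.exchange_rate
        lines = []
        lines.append("Cost-utility analysis (participant-level bootstrap)")
        lines.append("=" * 66)
        hdr = f"{'arm':<16}{'n':>4}{'mean cost (naira)':>20}{'mean QALY':>12}"
        lines.append(hdr)
        lines.append("-" * 66)
        for s in (self.arm_new, self.arm_ref):
            lines.append(f"{s.arm:<16}{s.n:>4}{s.mean_cost_naira:>20,.0f}{s.mean_qaly:>12.4f}")
        lines.append("-" * 66)
        usd = f" (US ${naira_to_usd(self.delta_cost, rate):,.2f})" if rate else ""
        lines.append(f"Incremental cost:   {self.delta_cost:,.0f} naira{usd}")
        lines.append(
            f"                    95% CI ({self.delta_cost_ci[0]:,.0f}, {self.delta_cost_ci[1]:,.0f})"
        )
        lines.append(f"Incremental effect: {self.delta_effect:.4f} QALY")
        lines.append(
            f"                    95% CI ({self.delta_effect_ci[0]:.4f}, {self.delta_effect_ci[1]:.4f})"
        )
        if self.icer.value is None:
            lines.append(f"ICER:               {self.icer.label}")
        else:
            lines.append(f"ICER:               {self.icer.value:,.0f} naira/QALY ({self.icer.label})")
        props = ", ".join(f"{q}={self.quadrant_proportions[q]:.3f}" for q in QUADRANTS)
        lines.append(f"Plane quadrants ({self.n_reps} replicates): {props}")
        lines.append(f"CI method: {self.ci_method}; seed: {self.seed}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit (replicates excluded)."""
        return {
            "arms": {
                s.arm: {
                    "n": s.n,
                    "mean_cost_naira": s.mean_cost_naira,
                    "mean_qaly": s.mean_qaly,
                    "cost_ci": list(s.cost_ci) if s.cost_ci else None,
                    "qaly_ci": list(s.qaly_ci) if s.qaly_ci else None,
                }
                for s in (self.arm_new, self.arm_ref)
            },
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "delta_cost_ci": list(self.delta_cost_ci),
            "delta_effect_ci": list(self.delta_effect_ci),
            "icer": self.icer.value,
            "icer_label": self.icer.label,
            "quadrant_proportions": self.quadrant_proportions,
            "n_reps": self.n_reps,
            "ci_method": self.ci_method,
            "seed": self.seed,
        }

    def plot_plane(self, ax=None, path=None):
        """Scatter the bootstrap replicates on the cost-effectiveness plane."""
        return plot_ce_plane(
            self.replicates, point=(self.delta_effect, self.delta_cost), ax=ax, path=path
        )

    def ceac(self, wtp: Sequence[float]) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

        An extension beyond the core analysis: for each threshold lambda, the
        fraction of replicates with positive net monetary benefit
        ``lambda * dE - dC``.
        """
        return ceac(self.replicates, wtp)


class CostUtilityModel:
    """Two-arm cost-utility comparison on participant-level cost/effect data.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per participant with arm label, cost and effect columns.
    new_arm, ref_arm : str
        Arm labels; the ICER is new minus reference.
    cost_col, effect_col : str
        Column names for per-participant cost (naira) and effect (QALYs).
    exchange_rate : float, optional
        Naira per USD, used only for display in ``summary()``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        new_arm: str = "TBMT",
        ref_arm: str = "CBMT",
        cost_col: str = "cost_naira",
        effect_col: str = "qaly",
        exchange_rate: float | None = None,
    ) -> None:
        for col in ("arm", cost_col, effect_col):
            if col not in data.columns:
                raise ValueError(f"data is missing column {col!r}")
        for arm in (new_arm, ref_arm):
            if (data["arm"] == arm).sum() == 0:
                raise ValueError(f"arm {arm!r} has no participants")
        self.data = data.reset_index(drop=True)
        self.new_arm = new_arm
        self.ref_arm = ref_arm
        self.cost_col = cost_col
        self.effect_col = effect_col
        self.exchange_rate = exchange_rate

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        cost_model: CostModel | None = None,
        coeffs: MappingCoefficients = ODI_TO_SF6D,
        qaly_convention: str = "mean_utility",
        new_arm: str = "TBMT",
        ref_arm: str = "CBMT",
    ) -> "CostUtilityModel":
        """Build the model from a raw cohort of ODI trajectories.

        Maps week-4/week-8 ODI to SF-6D utilities and QALYs; fills the cost
        column from the protocol cost model if it is absent.
        """
        cost_model = cost_model or default_cost_model()
        df = qalys_from_cohort(
            cohort,
            coeffs=coeffs,
            horizon_weeks=cost_model.horizon_weeks,
            convention=qaly_convention,
        )
        if "cost_naira" not in df.columns:
            df["cost_naira"] = [float(cost_model.arm_total_naira(a)) for a in df["arm"]]
        return cls(
            df,
            new_arm=new_arm,
            ref_arm=ref_arm,
            exchange_rate=cost_model.exchange_rate,
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CostUtilityModel":
        return cls(data, **kwargs)

    def fit(self, reps: int = 1000, seed: int | None = None, ci_method: str = "percentile") -> CEAResults:
        """Point estimates plus a within-arm participant bootstrap.

        ``ci_method`` is ``"percentile"`` (default) or ``"bca"``
        (bias-corrected and accelerated, jackknife acceleration).
        """
        return bootstrap_cea(
            self.data,
            reps=reps,
            seed=seed,
            new_arm=self.new_arm,
            ref_arm=self.ref_arm,
            cost_col=self.cost_col,
            effect_col=self.effect_col,
            ci_method=ci_method,
            exchange_rate=self.exchange_rate,
        )


def _percentile_ci(boot: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(lo), float(hi)


def _bca_ci(boot: np.ndarray, point: float, jackknife: np.ndarray) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from bootstrap + jackknife values."""
    b = boot.size
    # bias correction; clip so z0 stays finite when all replicates fall on one side
    prop = np.clip((boot < point).mean(), 1.0 / (b + 1), b / (b + 1.0))
    z0 = stats.norm.ppf(prop)
    jmean = jackknife.mean()
    dev = jmean - jackknife
    denom = (dev**2).sum() ** 1.5
    a = (dev**3).sum() / (6.0 * denom) if denom > 0 else 0.0
    out = []
    for alpha in (0.025, 0.975):
        z = stats.norm.ppf(alpha)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.percentile(boot, 100.0 * adj)))
    return out[0], out[1]


def _jackknife_deltas(
    new_vals: np.ndarray, ref_vals: np.ndarray
) -> np.ndarray:
    """Leave-one-participant-out incremental means over the pooled cohort."""
    deltas = []
    n_new, n_ref = new_vals.size, ref_vals.size
    sum_new, sum_ref = new_vals.sum(), ref_vals.sum()
    mean_ref = sum_ref / n_ref
    mean_new = sum_new / n_new
    for v in new_vals:
        deltas.append((sum_new - v) / (n_new - 1) - mean_ref)
    for v in ref_vals:
        deltas.append(mean_new - (sum_ref - v) / (n_ref - 1))
    return np.asarray(deltas)


def bootstrap_cea(
    data: pd.DataFrame,
    reps: int = 1000,
    seed: int | None = None,
    new_arm: str = "TBMT",
    ref_arm: str = "CBMT",
    cost_col: str = "cost_naira",
    effect_col: str = "qaly",
    ci_method: str = "percentile",
    exchange_rate: float | None = None,
) -> CEAResults:
    """Within-arm participant bootstrap of the incremental cost-effect pair.

    Each replicate resamples participants with replacement separately within
    each arm (arm sizes preserved; a participant's cost and effect travel
    together), recomputes arm means and the incremental pair. Deterministic
    for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if ci_method not in ("percentile", "bca"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    groups = {}
    for arm in (new_arm, ref_arm):
        sub = data[data["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"arm {arm!r} is empty")
        groups[arm] = (
            sub[cost_col].to_numpy(dtype=float),
            sub[effect_col].to_numpy(dtype=float),
        )

    rng = np.random.default_rng(seed)
    boot_means: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for arm in (new_arm, ref_arm):  # fixed draw order => reproducibility
        costs, effects = groups[arm]
        n = costs.size
        idx = rng.integers(0, n, size=(reps, n))
        boot_means[arm] = (costs[idx].mean(axis=1), effects[idx].mean(axis=1))

    dc = boot_means[new_arm][0] - boot_means[ref_arm][0]
    de = boot_means[new_arm][1] - boot_means[ref_arm][1]
    replicates = pd.DataFrame({"delta_cost": dc, "delta_effect": de})

    point_dc = groups[new_arm][0].mean() - groups[ref_arm][0].mean()
    point_de = groups[new_arm][1].mean() - groups[ref_arm][1].mean()

    if ci_method == "percentile":
        dc_ci = _percentile_ci(dc)
        de_ci = _percentile_ci(de)
    else:
        dc_ci = _bca_ci(dc, point_dc, _jackknife_deltas(groups[new_arm][0], groups[ref_arm][0]))
        de_ci = _bca_ci(de, point_de, _jackknife_deltas(groups[new_arm][1], groups[ref_arm][1]))

    summaries = {}
    for arm in (new_arm, ref_arm):
        costs, effects = groups[arm]
        cost_boot, qaly_boot = boot_means[arm]
        summaries[arm] = ArmSummary(
            arm=arm,
            n=costs.size,
            mean_cost_naira=float(costs.mean()),
            mean_qaly=float(effects.mean()),
            cost_ci=_percentile_ci(cost_boot),
            qaly_ci=_percentile_ci(qaly_boot),
        )

    return CEAResults(
        arm_new=summaries[new_arm],
        arm_ref=summaries[ref_arm],
        replicates=replicates,
        delta_cost_ci=dc_ci,
        delta_effect_ci=de_ci,
        seed=seed,
        ci_method=ci_method,
        exchange_rate=exchange_rate,
    )


def ce_plane_summary(replicates: pd.DataFrame, path=None) -> dict[str, float]:
    """Quadrant proportions of a replicate cloud; optionally write the plane plot.

    ``replicates`` must have ``delta_cost`` and ``delta_effect`` columns.
    """
    if len(replicates) == 0:
        raise ValueError("empty replicate set")
    props = _quadrant_proportions(
        replicates["delta_effect"].to_numpy(), replicates["delta_cost"].to_numpy()
    )
    if path is not None:
        plot_ce_plane(replicates, path=path)
    return props


def plot_ce_plane(replicates: pd.DataFrame, point=None, ax=None, path=None):
    """Cost-effectiveness plane: dE on the horizontal axis, dC on the vertical.

    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    ax.scatter(
        replicates["delta_effect"], replicates["delta_cost"], s=10, alpha=0.5, edgecolors="none"
    )
    if point is not None:
        ax.scatter([point[0]], [point[1]], marker="x", color="crimson", zorder=3, label="point estimate")
        ax.legend(loc="best", frameon=False)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("Incremental effect (QALY)")
    ax.set_ylabel("Incremental cost (naira)")
    ax.set_title("Cost-effectiveness plane (bootstrap replicates)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def ceac(replicates: pd.DataFrame, wtp: Sequence[float]) -> pd.DataFrame:
    """Probability the new arm is cost-effective at each willingness-to-pay.

    For each threshold, the fraction of replicates with net monetary benefit
    ``wtp * dE - dC > 0``.
    """
    dc = replicates["delta_cost"].to_numpy(dtype=float)
    de = replicates["delta_effect"].to_numpy(dtype=float)
    rows = [
        {"wtp": float(l), "p_cost_effective": float(((l * de - dc) > 0).mean())} for l in wtp
    ]
    return pd.DataFrame(rows)
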