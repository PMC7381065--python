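"""Protocol-driven resource costing for a two-arm rehabilitation trial.

Per-participant costs are determined by the treatment protocol: each resource
item is either a one-off purchase (a phone, a consultation fee) or recurs at a
fixed weekly frequency over the treatment horizon (SMS reminders, clinic
visits, transport). Arm totals are exact integer naira whenever the unit
costs are integers; conversion to US dollars is a display step, kept separate
so that currency rounding never contaminates the incremental analysis.

Two USD views are provided: :func:`naira_to_usd` (plain division by the
exchange rate) and :func:`usd_breakdown`, which reproduces the rounding chain
used in published per-item cost tables — per-unit USD rounded to cents, item
totals to one decimal, then summed — because the two do not agree at the
tenth-of-a-dollar level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "ResourceItem",
    "CostModel",
    "item_cost",
    "arm_total_cost_naira",
    "naira_to_usd",
    "usd_breakdown",
    "default_cost_model",
]

#: naira per US dollar; back-derived from the paired naira/USD unit prices
#: of the cost table (e.g. 1,000 -> 2.78, 20,000 -> 55.56)
DEFAULT_EXCHANGE_RATE = 360.0


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResourceItem:
    """One costed resource: a one-off purchase or a weekly-recurring service.

    ``weeks`` overrides the model horizon for this item when set; one-off
    items ignore frequency entirely.
    """

    name: str
    unit_cost_naira: float
    arms: tuple[str, ...]
    frequency_per_week: float = 0.0
    one_off: bool = False
    weeks: float | None = None

    def __post_init__(self) -> None:
        if self.unit_cost_naira < 0:
            raise ValueError(f"{self.name}: unit cost must be non-negative")
        if self.frequency_per_week < 0:
            raise ValueError(f"{self.name}: frequency must be non-negative")
        if self.weeks is not None and self.weeks <= 0:
            raise ValueError(f"{self.name}: weeks must be positive")
        if not self.arms:
            raise ValueError(f"{self.name}: item must apply to at least one arm")

    def units(self, horizon_weeks: float) -> float:
        """Number of billed units over the horizon (1 for a one-off item)."""
        if self.one_off:
            return 1.0
        weeks = self.weeks if self.weeks is not None else horizon_weeks
        return self.frequency_per_week * weeks


def item_cost(item: ResourceItem, horizon_weeks: float):
    """Total naira cost of one item per participant over the horizon.

    Returns a Python int when the arithmetic is exact in integers.
    """
    if horizon_weeks <= 0:
        raise ValueError("horizon_weeks must be positive")
    total = item.unit_cost_naira * item.units(horizon_weeks)
    if float(total).is_integer():
        return int(total)
    return total


@dataclass(frozen=True)
class CostModel:
    """Unit costs, frequencies and horizon defining per-participant arm costs."""

    items: tuple[ResourceItem, ...]
    exchange_rate: float = DEFAULT_EXCHANGE_RATE
    horizon_weeks: float = 8.0

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ValueError("exchange_rate must be positive")
        if self.horizon_weeks <= 0:
            raise ValueError("horizon_weeks must be positive")

    @property
    def arms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            for a in it.arms:
                seen.setdefault(a, None)
        return tuple(seen)

    def arm_items(self, arm: str) -> tuple[ResourceItem, ...]:
        if arm not in self.arms:
            raise ValueError(f"unknown arm {arm!r}; model covers {self.arms}")
        return tuple(it for it in self.items if arm in it.arms)

    def arm_total_naira(self, arm: str):
        return arm_total_cost_naira(self, arm)

    def arm_total_usd(self, arm: str) -> float:
        return naira_to_usd(self.arm_total_naira(arm), self.exchange_rate)

    @classmethod
    def from_yaml(cls, path) -> "CostModel":
        """Load a cost model from a YAML config.

        Layout::

            exchange_rate: 360
            horizon_weeks: 8
            items:
              - name: sms_reminders
                unit_cost_naira: 50
                frequency_per_week: 3
                arms: [TBMT, CBMT]
              - name: phone
                unit_cost_naira: 20000
                one_off: true
                arms: [TBMT]
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        items = tuple(
            ResourceItem(
                name=spec["name"],
                unit_cost_naira=spec["unit_cost_naira"],
                arms=tuple(spec["arms"]),
                frequency_per_week=spec.get("frequency_per_week", 0.0),
                one_off=spec.get("one_off", False),
                weeks=spec.get("weeks"),
            )
            for spec in raw["items"]
        )
        return cls(
            items=items,
            exchange_rate=raw.get("exchange_rate", DEFAULT_EXCHANGE_RATE),
            horizon_weeks=raw.get("horizon_weeks", 8.0),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "exchange_rate": self.exchange_rate,
            "horizon_weeks": self.horizon_weeks,
            "items": [
                {
                    "name": it.name,
                    "unit_cost_naira": it.unit_cost_naira,
                    "arms": list(it.arms),
                    "frequency_per_week": it.frequency_per_week,
                    "one_off": it.one_off,
                    **({"weeks": it.weeks} if it.weeks is not None else {}),
                }
                for it in self.items
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def arm_total_cost_naira(model: CostModel, arm: str):
    """Per-participant naira total for one arm: sum of item costs.

    Integer-exact when all unit costs, frequencies and the horizon are
    integers.
    """
    items = model.arm_items(arm)
    return sum(item_cost(it, model.horizon_weeks) for it in items)


def naira_to_usd(amount: float, rate: float = DEFAULT_EXCHANGE_RATE, ndigits: int | None = None) -> float:
    """Convert naira to USD at ``rate`` naira per dollar.

    ``ndigits`` applies display rounding (half-up); by default the exact
    quotient is returned.
    """
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    usd = amount / rate
    if ndigits is None:
        return usd
    return _round_half_up(usd, ndigits)


def usd_breakdown(model: CostModel, arm: str) -> pd.DataFrame:
    """Per-item cost table for one arm, in naira and display USD.

    The USD column follows the rounding chain of published per-item tables:
    the per-unit dollar price is rounded to 2 decimals, multiplied by the
    unit count and rounded to 1 decimal per item; the arm total is the sum
    of the rounded item figures. This reproduces published column totals
    (e.g. 61.8 / 106.3) that direct conversion of the naira totals does not.
    """
    items = model.arm_items(arm)
    rows = []
    for it in items:
        units = it.units(model.horizon_weeks)
        naira = item_cost(it, model.horizon_weeks)
        per_unit_usd = _round_half_up(it.unit_cost_naira / model.exchange_rate, 2)
        usd = _round_half_up(per_unit_usd * units, 1)
        rows.append(
            {
                "item": it.name,
                "unit_cost_naira": it.unit_cost_naira,
                "units": units,
                "cost_naira": naira,
                "unit_cost_usd": per_unit_usd,
                "cost_usd": usd,
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "item": "total",
        "unit_cost_naira": float("nan"),
        "units": float("nan"),
        "cost_naira": df["cost_naira"].sum(),
        "unit_cost_usd": float("nan"),
        "cost_usd": _round_half_up(float(df["cost_usd"].sum()), 1),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def default_cost_model() -> CostModel:
    """Cost model for the telerehabilitation (TBMT) vs clinic (CBMT) protocols.

    Both arms receive thrice-weekly SMS/reminder calls (50 naira each) and a
    one-off physiotherapy consultation (1,000 naira). The telerehabilitation
    arm additionally needs an app-compatible phone (20,000 naira, one-off);
    the clinic arm incurs thrice-weekly clinic visits (1,000 naira each) and
    transport/refreshment (500 naira per visit) over the 8-week horizon.
    """
    items = (
        ResourceItem("sms_reminders", 50, ("TBMT", "CBMT"), frequency_per_week=3),
        ResourceItem("phone", 20_000, ("TBMT",), one_off=True),
        ResourceItem("clinic_visit", 1_000, ("CBMT",), frequency_per_week=3),
        ResourceItem("consultation", 1_000, ("TBMT", "CBMT"), one_off=True),
        ResourceItem("transport_refreshment", 500, ("CBMT",), frequency_per_week=3),
    )
    return CostModel(items=items, exchange_rate=DEFAULT_EXCHANGE_RATE, horizon_weeks=8.0)
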