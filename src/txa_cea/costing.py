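"""Costing: one-off trial-period costs and the post-discharge cost schedule.

Trial-period (entry) costs per person are built exactly as the source tables
combine them: length of stay times per-day unit costs, procedure probabilities
times procedure tariffs, transfusion probability times mean units times
per-unit price, plus the itemised TXA administration cost in the TXA arm.
Post-discharge ("monitoring") costs accrue among survivors: a year-1 amount
spread pro rata over days 29-365 (the inpatient episode itself is already
costed, so monitoring starts after the trial window), fixed annual amounts in
years 2 and 3, and a configurable fraction (default one-third) of the year-3
amount from year 4 onwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    ArmResourceUse,
    ParameterSet,
    PROCEDURE_TYPES,
    TRANSFUSION_TYPES,
    UnitCosts,
)
from .survival import DAYS_PER_YEAR, TRIAL_DAYS, MortalitySchedule


def txa_admin_cost(components: dict[str, float]) -> float:
    """Total one-off TXA drug + administration cost (component sum)."""
    if any(v < 0 for v in components.values()):
        raise ValueError("cost components must be non-negative")
    return float(sum(components.values()))


def inpatient_cost(arm_use: ArmResourceUse, unit_costs: UnitCosts) -> float:
    """Mean inpatient-stay cost: ward days plus ICU days at their per-day costs."""
    los = arm_use.total_los_days.mean
    icu = arm_use.icu_days.mean
    if icu > los:
        raise ValueError(f"ICU days ({icu}) cannot exceed total length of stay ({los})")
    return (los - icu) * unit_costs.bed_day + icu * unit_costs.icu_day


def procedure_cost(arm_use: ArmResourceUse, unit_costs: UnitCosts) -> float:
    """Mean per-person procedure cost: occurrence probability x tariff."""
    return float(
        sum(
            arm_use.procedures[k].p * unit_costs.procedures[k]
            for k in PROCEDURE_TYPES
        )
    )


def transfusion_cost(arm_use: ArmResourceUse, unit_costs: UnitCosts) -> float:
    """Mean per-person transfusion cost: probability x mean units x unit price."""
    return float(
        sum(
            arm_use.transfusions[k].given.p
            * arm_use.transfusions[k].units.mean
            * unit_costs.transfusions[k]
            for k in TRANSFUSION_TYPES
        )
    )


def entry_cost_components(params: ParameterSet, arm: str) -> dict[str, float]:
    """Itemised one-off cost at model entry for one arm."""
    use = params.resource_use[arm]
    out = {
        "txa_admin": txa_admin_cost(params.txa_admin_components) if arm == "txa" else 0.0,
        "inpatient_stay": inpatient_cost(use, params.unit_costs),
        "procedures": procedure_cost(use, params.unit_costs),
        "transfusions": transfusion_cost(use, params.unit_costs),
    }
    return out


@dataclass(frozen=True)
class CostSchedule:
    """One-off entry cost plus annual alive-state (monitoring) amounts."""

    arm: str
    entry_cost: float
    year1: float  # accrues over days 29-365 only
    year2: float
    year3: float
    year4_plus: float

    def annual_amount(self, year: np.ndarray) -> np.ndarray:
        """Alive-state annual amount for 1-indexed model year(s)."""
        year = np.asarray(year)
        return np.select(
            [year == 1, year == 2, year == 3],
            [self.year1, self.year2, self.year3],
            default=self.year4_plus,
        )

    def per_cycle_amounts(self, schedule: MortalitySchedule) -> np.ndarray:
        """Alive-state cost per cycle (full occupancy), aligned with ``schedule``.

        Daily cycles in year 1 carry the year-1 amount pro rata over days
        29-365 (zero during the costed inpatient window); annual cycles carry
        the full annual amount of their model year.
        """
        year = (schedule.start_day // DAYS_PER_YEAR).astype(int) + 1
        amounts = self.annual_amount(year) * schedule.length_days / DAYS_PER_YEAR
        daily = schedule.length_days == 1
        year1_daily = daily & (year == 1)
        amounts[year1_daily & (schedule.start_day < TRIAL_DAYS)] = 0.0
        monitored = year1_daily & (schedule.start_day >= TRIAL_DAYS)
        amounts[monitored] = self.year1 / (DAYS_PER_YEAR - TRIAL_DAYS)
        return amounts


def build_cost_schedule(params: ParameterSet, arm: str) -> CostSchedule:
    """Cost schedule for one arm from the validated parameter set."""
    if arm not in params.resource_use:
        raise ValueError(f"unknown arm {arm!r}")
    pd_ = params.postdischarge
    return CostSchedule(
        arm=arm,
        entry_cost=float(sum(entry_cost_components(params, arm).values())),
        year1=pd_.year1,
        year2=pd_.year2,
        year3=pd_.year3,
        year4_plus=pd_.year4_plus,
    )
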