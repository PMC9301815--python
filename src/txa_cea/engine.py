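"""Markov cohort trace: life years, QALYs and costs over a mortality schedule.

The engine walks the two-state (alive/dead) cohort through the cycles of a
:class:`~txa_cea.survival.MortalitySchedule`, accruing discounted and
undiscounted life years, quality-adjusted life years and alive-state costs,
plus the one-off entry cost at time zero.

Two conventions are configurable. ``half_cycle_correction`` credits people who
die within a cycle with half a cycle of accrual (off by default: deaths occur
at cycle end, the usual spreadsheet convention). ``discount_timing`` applies
the discount factor at each cycle's start or end (default end). Year-one
cycles are daily, so either choice is numerically negligible there; for the
annual cycles the defaults reproduce the classic discrete-time cohort model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costing import CostSchedule
from .params import ParameterSet
from .survival import DAYS_PER_YEAR, MortalitySchedule


def discount_factor(t_days, rate: float):
    """Discount factor at ``t_days`` since model entry, continuous-time exponent."""
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (1.0 + rate) ** (-t / DAYS_PER_YEAR)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class UtilitySchedule:
    """Survivor utility with additive age-band decrements."""

    base_utility: float
    decrements: tuple[tuple[float, float], ...]  # (min_age, decrement), ascending

    @classmethod
    def from_params(cls, params: ParameterSet) -> "UtilitySchedule":
        decs = sorted((d.min_age, d.decrement) for d in params.utility_decrements)
        return cls(params.utility_survivor.value, tuple(decs))

    def at_age(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        dec = np.zeros_like(age)
        for min_age, d in self.decrements:
            dec = np.where(age >= min_age, d, dec)
        return self.base_utility - dec


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and accruals, with discounted/undiscounted totals."""

    arm: str
    start_day: np.ndarray
    length_days: np.ndarray
    alive_start: np.ndarray
    deaths: np.ndarray
    ly: np.ndarray  # undiscounted per-cycle accruals
    qaly: np.ndarray
    cost: np.ndarray  # alive-state cost only; entry cost kept separately
    ly_disc: np.ndarray
    qaly_disc: np.ndarray
    cost_disc: np.ndarray
    entry_cost: float

    @property
    def total_ly(self) -> float:
        return float(self.ly_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost(self) -> float:
        return float(self.entry_cost + self.cost_disc.sum())

    @property
    def total_ly_undiscounted(self) -> float:
        return float(self.ly.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.entry_cost + self.cost.sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle, for audit and plotting."""
        return pd.DataFrame(
            {
                "start_day": self.start_day,
                "length_days": self.length_days,
                "alive_start": self.alive_start,
                "deaths": self.deaths,
                "ly": self.ly,
                "qaly": self.qaly,
                "cost": self.cost,
                "ly_discounted": self.ly_disc,
                "qaly_discounted": self.qaly_disc,
                "cost_discounted": self.cost_disc,
            }
        )


def run_trace(
    schedule: MortalitySchedule,
    utilities: UtilitySchedule,
    cost_schedule: CostSchedule,
    discount_rate_costs: float = 0.035,
    discount_rate_qalys: float = 0.035,
    half_cycle_correction: bool = False,
    discount_timing: str = "end",
) -> CohortTrace:
    """Run the cohort through the schedule and accrue outcomes.

    The entry cost is incurred at time zero (undiscounted by construction).
    Residual cohort alive at the horizon accrues nothing further.
    """
    if discount_timing not in ("end", "start"):
        raise ValueError(f"discount_timing must be 'end' or 'start', got {discount_timing!r}")

    p = schedule.p_death
    frac_year = schedule.length_days / DAYS_PER_YEAR
    alive_start = np.concatenate([[1.0], np.cumprod(1.0 - p)[:-1]])
    deaths = alive_start * p

    # occupancy credited for accrual within the cycle
    death_credit = 0.5 if half_cycle_correction else 0.0
    occupancy = alive_start * (1.0 - p) + death_credit * deaths

    ly = occupancy * frac_year
    qaly = ly * utilities.at_age(schedule.attained_age)
    cost = occupancy * cost_schedule.per_cycle_amounts(schedule)

    t_disc = schedule.start_day + (schedule.length_days if discount_timing == "end" else 0.0)
    disc_q = discount_factor(t_disc, discount_rate_qalys)
    disc_c = discount_factor(t_disc, discount_rate_costs)

    return CohortTrace(
        arm=schedule.arm,
        start_day=schedule.start_day,
        length_days=schedule.length_days,
        alive_start=alive_start,
        deaths=deaths,
        ly=ly,
        qaly=qaly,
        cost=cost,
        ly_disc=ly * disc_q,
        qaly_disc=qaly * disc_q,
        cost_disc=cost * disc_c,
        entry_cost=cost_schedule.entry_cost,
    )


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted and undiscounted lifetime totals for one strategy."""

    arm: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float


def lifetime_outputs(trace: CohortTrace) -> ArmOutcome:
    """Collapse a trace to the per-arm totals used downstream."""
    return ArmOutcome(
        arm=trace.arm,
        cost=trace.total_cost,
        ly=trace.total_ly,
        qaly=trace.total_qaly,
        cost_undiscounted=trace.total_cost_undiscounted,
        ly_undiscounted=trace.total_ly_undiscounted,
        qaly_undiscounted=trace.total_qaly_undiscounted,
    )
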