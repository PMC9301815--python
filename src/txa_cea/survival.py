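"""Mortality schedules over the lifetime horizon.

The cohort faces three mortality regimes. During the first 28 days the daily
probability of death comes from the trial itself: the cumulative 28-day risk
in the control arm (548/5981) is spread over the days according to a
front-loaded daily shape, and the treatment arm's cumulative risk is the
control risk multiplied by the all-cause mortality risk ratio. For the
remaining 337 days of the first year, general-population annual death
probabilities are inflated by the first-year standardised mortality ratio
(SMR 5.21) and converted to daily probabilities. From the second year onward
the model switches to annual cycles with the long-term SMR (1.74).

SMRs are applied on the hazard scale, ``1 - (1 - q) ** smr``, which keeps
probabilities below one at old ages where multiplying ``q`` by 5.21 would not.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import LifeTableSpec, ParameterSet

TRIAL_DAYS = 28
DAYS_PER_YEAR = 365


# ---------------------------------------------------------------------------
# probability/rate identities


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Constant hazard rate over duration ``t`` equivalent to probability ``p``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {p}")
    return -np.log1p(-p) / t


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Inverse of :func:`prob_to_rate`."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return -np.expm1(-rate * t)


def apply_smr(q_annual, smr: float):
    """Inflate an annual death probability by an SMR on the hazard scale."""
    q_annual = np.asarray(q_annual, dtype=float)
    if np.any((q_annual < 0) | (q_annual >= 1)):
        raise ValueError("annual probability must lie in [0, 1)")
    if smr <= 0:
        raise ValueError(f"SMR must be positive, got {smr}")
    out = -np.expm1(smr * np.log1p(-q_annual))
    return float(out) if out.ndim == 0 else out


def annual_to_daily(q_annual):
    """Daily probability whose 365-fold compounding recovers ``q_annual``."""
    q_annual = np.asarray(q_annual, dtype=float)
    if np.any((q_annual < 0) | (q_annual >= 1)):
        raise ValueError("annual probability must lie in [0, 1)")
    out = -np.expm1(np.log1p(-q_annual) / DAYS_PER_YEAR)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# life table


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual probabilities of death for the general population."""

    ages: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if ages.ndim != 1 or ages.shape != q.shape or len(ages) == 0:
            raise ValueError("life table needs matching 1-D age and q columns")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous integers")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age) -> np.ndarray:
        """Annual death probability at integer age(s); clipped at the last row."""
        idx = np.clip(np.asarray(age, dtype=int) - self.min_age, 0, len(self.ages) - 1)
        return self.q_annual[idx]

    def survival_to(self, from_age: int, to_age: int) -> float:
        """Probability of surviving from one exact integer age to another."""
        sel = (self.ages >= from_age) & (self.ages < to_age)
        return float(np.prod(1.0 - self.q_annual[sel]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        if not {"age", "q_annual"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'age,q_annual'")
        return cls(df["age"].to_numpy(), df["q_annual"].to_numpy())

    @classmethod
    def packaged(cls) -> "LifeTable":
        """The vendored synthetic UK-style all-persons table."""
        with resources.as_file(
            resources.files("txa_cea.data").joinpath("uk_life_table_synthetic.csv")
        ) as p:
            return cls.from_csv(p)

    @classmethod
    def gompertz_makeham(
        cls,
        makeham: float = 2.0e-4,
        a: float = 1.25e-5,
        b: float = 0.104,
        max_age: int = 100,
    ) -> "LifeTable":
        """Fully parametric synthetic table, hazard ``makeham + a * exp(b * age)``.

        Defaults approximate UK all-persons period mortality (life expectancy
        ~81 years at birth).
        """
        ages = np.arange(0, max_age + 1)
        mu = makeham + a * np.exp(b * ages)
        return cls(ages, -np.expm1(-mu))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "q_annual": self.q_annual}).to_csv(
            path, index=False
        )


def load_life_table(spec: LifeTableSpec) -> LifeTable:
    """Resolve a life-table specification from the configuration."""
    if spec.source == "packaged":
        return LifeTable.packaged()
    if spec.source == "file":
        if not spec.path:
            raise ValueError("life_table.source is 'file' but no path is given")
        return LifeTable.from_csv(spec.path)
    if spec.source == "gompertz_makeham":
        return LifeTable.gompertz_makeham(spec.makeham, spec.gompertz_a, spec.gompertz_b)
    raise ValueError(f"unknown life-table source {spec.source!r}")


# ---------------------------------------------------------------------------
# trial-period daily curve


@dataclass(frozen=True)
class TrialDailyCurve:
    """Daily death probabilities over the 28-day trial window.

    ``unconditional`` holds per-day death fractions of the entering cohort
    (summing to ``cumulative_risk``); ``conditional`` the per-day probability
    of dying given alive at the start of the day, so that
    ``1 - prod(1 - conditional)`` equals the cumulative risk.
    """

    unconditional: np.ndarray
    cumulative_risk: float

    @property
    def conditional(self) -> np.ndarray:
        alive = 1.0 - np.concatenate([[0.0], np.cumsum(self.unconditional)[:-1]])
        with np.errstate(invalid="ignore"):
            out = np.where(alive > 0, self.unconditional / alive, 0.0)
        return out

    def rescaled(self, cumulative_risk: float) -> "TrialDailyCurve":
        """Same daily shape, different cumulative risk."""
        return make_trial_curve(cumulative_risk, self.unconditional)


def default_shape(kind: str = "geometric", ratio: float = 0.9, n_days: int = TRIAL_DAYS) -> np.ndarray:
    """Default front-loaded (or uniform) daily death-share weights.

    The trial reported most deaths early in the 28-day window; a geometric
    decay with per-day ratio 0.9 emulates that front-loading. Lifetime results
    are driven by the cumulative risk, not the shape (see tests).
    """
    if kind == "geometric":
        return ratio ** np.arange(n_days, dtype=float)
    if kind == "uniform":
        return np.ones(n_days)
    raise ValueError(f"unknown trial-curve shape {kind!r}")


def make_trial_curve(cumulative_risk: float, shape: np.ndarray) -> TrialDailyCurve:
    """Spread a cumulative 28-day risk over days proportionally to ``shape``."""
    shape = np.asarray(shape, dtype=float)
    if np.any(shape < 0):
        raise ValueError("shape weights must be non-negative")
    total = shape.sum()
    if total <= 0:
        raise ValueError("shape weights must sum to a positive value")
    if not 0.0 <= cumulative_risk < 1.0:
        raise ValueError(f"cumulative risk must lie in [0, 1), got {cumulative_risk}")
    return TrialDailyCurve(shape / total * cumulative_risk, cumulative_risk)


# ---------------------------------------------------------------------------
# full schedule


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-cycle death probabilities partitioning the whole horizon.

    Cycles are 28 daily trial cycles, 337 daily SMR-adjusted cycles, then
    annual cycles until the attained-age cap.
    """

    arm: str
    start_day: np.ndarray  # days since model entry at cycle start
    length_days: np.ndarray
    p_death: np.ndarray  # probability of dying within the cycle, given alive
    attained_age: np.ndarray  # exact age at cycle start

    def __len__(self) -> int:
        return len(self.p_death)

    @property
    def cumulative_risk_28day(self) -> float:
        return float(-np.expm1(np.sum(np.log1p(-self.p_death[:TRIAL_DAYS]))))

    def survival_at_cycle_starts(self) -> np.ndarray:
        return np.concatenate([[1.0], np.cumprod(1.0 - self.p_death)])


def build_schedule(
    params: ParameterSet,
    life_table: LifeTable,
    arm: str,
    curve: TrialDailyCurve | None = None,
) -> MortalitySchedule:
    """Assemble the per-cycle mortality schedule for one arm.

    The treatment-effect risk ratio acts on the 28-day cumulative-risk scale
    in the TXA arm, preserving the daily shape; there is no treatment effect
    after day 28.
    """
    if arm not in ("txa", "no_txa"):
        raise ValueError(f"unknown arm {arm!r}")
    start_age = params.start_age
    if life_table.min_age > int(start_age) or life_table.max_age < int(params.horizon_age) - 1:
        raise ValueError(
            "life table must cover [floor(start_age), horizon_age - 1], got "
            f"[{life_table.min_age}, {life_table.max_age}]"
        )

    risk = params.risk28_value
    if curve is None:
        shape = default_shape(params.trial_curve.shape, params.trial_curve.ratio)
        curve = make_trial_curve(risk, shape)
    if arm == "txa":
        risk_arm = params.rr_mortality.value * risk
        if risk_arm >= 1.0:
            raise ValueError(
                f"RR x 28-day risk = {risk_arm:.3f} is not a valid probability"
            )
        curve = curve.rescaled(risk_arm)

    # 28 daily trial cycles
    start = [np.arange(TRIAL_DAYS, dtype=float)]
    length = [np.ones(TRIAL_DAYS)]
    p = [curve.conditional]

    # 337 daily cycles, first-year SMR
    days = np.arange(TRIAL_DAYS, DAYS_PER_YEAR, dtype=float)
    ages = start_age + days / DAYS_PER_YEAR
    q1 = apply_smr(life_table.q_at(np.floor(ages)), params.smr_y1.value)
    start.append(days)
    length.append(np.ones(len(days)))
    p.append(annual_to_daily(q1))

    # annual cycles with the long-term SMR until the age cap
    n_years = int(np.ceil(params.horizon_age - (start_age + 1.0)))
    yr_start = DAYS_PER_YEAR * np.arange(1, n_years + 1, dtype=float)
    yr_ages = start_age + yr_start / DAYS_PER_YEAR
    keep = yr_ages < params.horizon_age
    yr_start, yr_ages = yr_start[keep], yr_ages[keep]
    q2 = apply_smr(life_table.q_at(np.floor(yr_ages)), params.smr_y2plus.value)
    start.append(yr_start)
    length.append(np.full(len(yr_start), float(DAYS_PER_YEAR)))
    p.append(q2)

    start_day = np.concatenate(start)
    return MortalitySchedule(
        arm=arm,
        start_day=start_day,
        length_days=np.concatenate(length),
        p_death=np.concatenate(p),
        attained_age=start_age + start_day / DAYS_PER_YEAR,
    )
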