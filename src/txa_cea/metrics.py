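"""Incremental cost-effectiveness statistics.

Incrementals are always TXA minus no-TXA. On the cost-effectiveness plane the
x-axis is the incremental effect and the y-axis the incremental cost, so the
quadrants are NE (more effective, more costly), SE (more effective, cheaper:
dominant), NW (less effective, more costly: dominated) and SW (less effective,
cheaper). In the SW quadrant the ICER is read as "saved per unit of effect
lost" — equivalently the ICER of the comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ArmOutcome

QUADRANTS = ("NE", "NW", "SE", "SW")


def quadrant_of(delta_effect: float, delta_cost: float) -> str:
    """Quadrant by signs of (effect, cost); axis draws go to the E>=0 / C>=0 side."""
    east = delta_effect >= 0
    north = delta_cost >= 0
    return ("N" if north else "S") + ("E" if east else "W")


@dataclass(frozen=True)
class ICER:
    """ICER value with its quadrant and a degenerate-case label.

    ``label`` is ``"icer"`` for NE, ``"saved_per_unit_lost"`` for SW,
    ``"dominant"`` (SE), ``"dominated"`` (NW) or ``"undefined"`` when the
    incremental effect is zero.
    """

    value: float
    quadrant: str
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.label in ("dominant", "dominated", "undefined"):
            return self.label
        return f"{self.value:.0f} ({self.quadrant})"


def icer(delta_cost: float, delta_effect: float) -> ICER:
    """Incremental cost-effectiveness ratio with dominance handling."""
    quadrant = quadrant_of(delta_effect, delta_cost)
    if delta_effect == 0:
        label = "undefined"
        value = np.nan if delta_cost == 0 else np.inf * np.sign(delta_cost)
        return ICER(float(value), quadrant, label)
    value = delta_cost / delta_effect
    label = {"NE": "icer", "SW": "saved_per_unit_lost",
             "SE": "dominant", "NW": "dominated"}[quadrant]
    return ICER(value, quadrant, label)


def inmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Incremental net monetary benefit, ``wtp * dE - dC``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * delta_effect - delta_cost


@dataclass(frozen=True)
class CEResult:
    """Full incremental comparison of TXA vs no-TXA."""

    no_txa: ArmOutcome
    txa: ArmOutcome
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.txa.cost - self.no_txa.cost

    @property
    def delta_ly(self) -> float:
        return self.txa.ly - self.no_txa.ly

    @property
    def delta_qaly(self) -> float:
        return self.txa.qaly - self.no_txa.qaly

    @property
    def icer_ly(self) -> ICER:
        return icer(self.delta_cost, self.delta_ly)

    @property
    def icer_qaly(self) -> ICER:
        return icer(self.delta_cost, self.delta_qaly)

    @property
    def inmb(self) -> float:
        return inmb(self.delta_cost, self.delta_qaly, self.wtp)

    @property
    def quadrant(self) -> str:
        return quadrant_of(self.delta_qaly, self.delta_cost)

    def to_dict(self) -> dict[str, float | str]:
        return {
            "cost_no_txa": self.no_txa.cost,
            "cost_txa": self.txa.cost,
            "ly_no_txa": self.no_txa.ly,
            "ly_txa": self.txa.ly,
            "qaly_no_txa": self.no_txa.qaly,
            "qaly_txa": self.txa.qaly,
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_ly": self.icer_ly.value,
            "icer_qaly": self.icer_qaly.value,
            "inmb": self.inmb,
            "quadrant": self.quadrant,
        }


def compare(no_txa: ArmOutcome, txa: ArmOutcome, wtp: float = 20_000.0) -> CEResult:
    return CEResult(no_txa=no_txa, txa=txa, wtp=wtp)


# ---------------------------------------------------------------------------
# probabilistic summaries


def default_threshold_grid() -> np.ndarray:
    """Willingness-to-pay grid, 0 to 50,000 GBP/QALY in 500 GBP steps."""
    return np.arange(0.0, 50_001.0, 500.0)


def ceac(
    delta_cost: np.ndarray,
    delta_effect: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from per-draw incrementals.

    For each threshold, the probability TXA is cost-effective is the share of
    draws with positive incremental net benefit; draws with exactly zero net
    benefit are split evenly between the strategies.
    """
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_effect, dtype=float)
    if dc.size == 0 or dc.shape != de.shape:
        raise ValueError("need at least one PSA draw with matching shapes")
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    nb = thresholds[:, None] * de[None, :] - dc[None, :]
    p_txa = (nb > 0).mean(axis=1) + 0.5 * (nb == 0).mean(axis=1)
    return pd.DataFrame(
        {"threshold": thresholds, "p_txa": p_txa, "p_no_txa": 1.0 - p_txa}
    )


def p_cost_effective(
    delta_cost: np.ndarray, delta_effect: np.ndarray, wtp: float
) -> float:
    """Probability TXA is cost-effective at a single threshold."""
    return float(ceac(delta_cost, delta_effect, np.array([wtp]))["p_txa"].iloc[0])


def quadrant_shares(
    delta_cost: np.ndarray, delta_effect: np.ndarray
) -> dict[str, float]:
    """Share of PSA draws in each cost-effectiveness-plane quadrant."""
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_effect, dtype=float)
    if dc.size == 0 or dc.shape != de.shape:
        raise ValueError("need at least one PSA draw with matching shapes")
    east = de >= 0
    north = dc >= 0
    n = dc.size
    return {
        "NE": float((east & north).sum()) / n,
        "NW": float((~east & north).sum()) / n,
        "SE": float((east & ~north).sum()) / n,
        "SW": float((~east & ~north).sum()) / n,
    }
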