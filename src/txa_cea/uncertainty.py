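"""Parameter uncertainty: distribution fitting, PSA driver, scenario runner.

Distributions are fitted from the printed summaries exactly as the input
tables describe them: log-normals for the SMRs and the mortality risk ratio
(location ``ln(point)``, i.e. the point estimate is the log-scale median;
scale from the 95% CI width), betas from exact event counts for probabilities,
a method-of-moments beta for the survivor utility, and gammas from mean/SE for
lengths of stay, transfusion units and post-discharge costs (whose SE is a
configurable fraction of the mean, 50% in the base case). Parameters with no
distribution in the tables — unit costs, discount rates, utility decrements,
TXA administration — are fixed during PSA.

Draws are mutually independent across parameters and arms. Reproducibility:
draw ``i`` uses the random substream seeded by ``(seed, i)``, so results do
not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import CEResult, ceac, compare, p_cost_effective, quadrant_shares
from .model import run_outcomes
from .params import (
    ARMS,
    PROCEDURE_TYPES,
    TRANSFUSION_TYPES,
    EventCount,
    MeanSE,
    ParameterSet,
    TransfusionUse,
    default_parameters,
)
from .survival import LifeTable, load_life_table

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# distribution specs


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one scalar parameter.

    ``family`` is one of ``lognormal``, ``beta``, ``gamma`` or ``fixed``;
    ``source`` records which kind of printed summary parameterised it.
    """

    family: str
    source: str  # point+CI | counts | mean+SE | fixed
    params: dict[str, float]
    point: float

    def mean(self) -> float:
        """Analytic mean (beta/gamma) or log-scale median (log-normal)."""
        p = self.params
        if self.family == "fixed":
            return self.point
        if self.family == "lognormal":
            return float(np.exp(p["mu"]))  # median: the fitted point estimate
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.family == "fixed":
            return self.point if size is None else np.full(size, self.point)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size)
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        raise ValueError(f"unknown family {self.family!r}")


def lognormal_from_ci(point: float, lo: float, hi: float) -> DistributionSpec:
    """Log-normal with median ``point`` and sigma from the 95% CI width."""
    if min(point, lo, hi) <= 0:
        raise ValueError("log-normal requires positive point and bounds")
    if not lo <= point <= hi:
        raise ValueError(f"CI must bracket the point: {lo} <= {point} <= {hi}")
    sigma = (np.log(hi) - np.log(lo)) / (2 * Z95)
    if sigma == 0.0:
        return DistributionSpec("fixed", "point+CI", {}, point)
    return DistributionSpec(
        "lognormal", "point+CI",
        {"mu": float(np.log(point)), "sigma": float(sigma)}, point,
    )


def beta_from_counts(events: float, n: int) -> DistributionSpec:
    """Beta(events, n - events); mean is the observed proportion."""
    if n <= 0:
        raise ValueError("need a positive denominator")
    if not 0 <= events <= n:
        raise ValueError(f"events must lie in [0, {n}], got {events}")
    if events in (0, n):  # degenerate: point mass at the boundary
        return DistributionSpec("fixed", "counts", {}, events / n)
    return DistributionSpec(
        "beta", "counts",
        {"alpha": float(events), "beta": float(n - events)}, events / n,
    )


def beta_from_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Method-of-moments beta from a mean and a symmetric-normal 95% CI."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if not lo <= mean <= hi:
        raise ValueError(f"CI must bracket the mean: {lo} <= {mean} <= {hi}")
    se = (hi - lo) / (2 * Z95)
    if se == 0.0:
        return DistributionSpec("fixed", "point+CI", {}, mean)
    var = se**2
    if var >= mean * (1 - mean):
        raise ValueError("CI too wide: method-of-moments beta infeasible")
    factor = mean * (1 - mean) / var - 1.0
    return DistributionSpec(
        "beta", "point+CI",
        {"alpha": mean * factor, "beta": (1 - mean) * factor}, mean,
    )


def gamma_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Gamma with the given mean and standard error (shape/scale by moments)."""
    if mean < 0 or se < 0:
        raise ValueError("mean and SE must be non-negative")
    if mean == 0 or se == 0:
        # zero-mean or certain items are held fixed, not sampled
        return DistributionSpec("fixed", "mean+SE", {}, mean)
    return DistributionSpec(
        "gamma", "mean+SE", {"shape": (mean / se) ** 2, "scale": se**2 / mean}, mean
    )


# ---------------------------------------------------------------------------
# joint sampling


def build_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Fitted distribution for every sampled parameter, keyed by dotted path.

    The iteration order of this dict fixes the order in which random numbers
    are consumed, so it is part of the reproducibility contract.
    """
    pd_ = params.postdischarge
    frac = params.psa_cost_se_fraction
    dists: dict[str, DistributionSpec] = {
        "smr_y1": lognormal_from_ci(*params.smr_y1.as_tuple()),
        "smr_y2plus": lognormal_from_ci(*params.smr_y2plus.as_tuple()),
        "rr_mortality": lognormal_from_ci(*params.rr_mortality.as_tuple()),
        "risk28": beta_from_counts(params.risk28.events, params.risk28.n),
        "utility_survivor": beta_from_ci(*params.utility_survivor.as_tuple()),
        "postdischarge.year1": gamma_from_mean_se(pd_.year1, frac * pd_.year1),
        "postdischarge.year2": gamma_from_mean_se(pd_.year2, frac * pd_.year2),
        "postdischarge.year3": gamma_from_mean_se(pd_.year3, frac * pd_.year3),
    }
    for arm in ARMS:
        use = params.resource_use[arm]
        base = f"resource_use.{arm}"
        dists[f"{base}.total_los_days"] = gamma_from_mean_se(
            use.total_los_days.mean, use.total_los_days.se
        )
        dists[f"{base}.icu_days"] = gamma_from_mean_se(
            use.icu_days.mean, use.icu_days.se
        )
        for k in PROCEDURE_TYPES:
            c = use.procedures[k]
            dists[f"{base}.procedures.{k}"] = beta_from_counts(c.events, c.n)
        for k in TRANSFUSION_TYPES:
            t = use.transfusions[k]
            dists[f"{base}.transfusions.{k}.given"] = beta_from_counts(
                t.given.events, t.given.n
            )
            dists[f"{base}.transfusions.{k}.units"] = gamma_from_mean_se(
                t.units.mean, t.units.se
            )
    return dists


def _rebuild(params: ParameterSet, v: dict[str, float]) -> ParameterSet:
    """ParameterSet with the drawn values substituted.

    Sampled probabilities re-enter count parameters as fractional effective
    numerators at the original denominator. ICU days are capped at the drawn
    length of stay so the stay decomposition stays coherent in extreme draws.
    """

    def count(c: EventCount, p: float) -> EventCount:
        return EventCount(events=p * c.n, n=c.n)

    arms = {}
    for arm in ARMS:
        use = params.resource_use[arm]
        base = f"resource_use.{arm}"
        los = v[f"{base}.total_los_days"]
        arms[arm] = replace(
            use,
            total_los_days=replace(use.total_los_days, mean=los),
            icu_days=replace(use.icu_days, mean=min(v[f"{base}.icu_days"], los)),
            procedures={
                k: count(use.procedures[k], v[f"{base}.procedures.{k}"])
                for k in PROCEDURE_TYPES
            },
            transfusions={
                k: TransfusionUse(
                    given=count(
                        use.transfusions[k].given, v[f"{base}.transfusions.{k}.given"]
                    ),
                    units=replace(
                        use.transfusions[k].units,
                        mean=v[f"{base}.transfusions.{k}.units"],
                    ),
                )
                for k in TRANSFUSION_TYPES
            },
        )

    return replace(
        params,
        smr_y1=replace(params.smr_y1, value=v["smr_y1"]),
        smr_y2plus=replace(params.smr_y2plus, value=v["smr_y2plus"]),
        rr_mortality=replace(params.rr_mortality, value=v["rr_mortality"]),
        risk28=count(params.risk28, v["risk28"]),
        utility_survivor=replace(params.utility_survivor, value=v["utility_survivor"]),
        postdischarge=replace(
            params.postdischarge,
            year1=v["postdischarge.year1"],
            year2=v["postdischarge.year2"],
            year3=v["postdischarge.year3"],
        ),
        resource_use=arms,
    )


def sample_parameter_set(
    params: ParameterSet,
    seed: int,
    draw_index: int,
    dists: dict[str, DistributionSpec] | None = None,
) -> tuple[ParameterSet, dict[str, float]]:
    """One joint PSA draw, reproducible given ``(seed, draw_index)``.

    Returns the rebuilt parameter set and the dict of sampled values. Draws
    whose treatment-arm 28-day risk would reach 1 are rejected and redrawn
    from an extension of the same substream (impossible in practice at these
    magnitudes, but the model precondition is enforced).
    """
    if dists is None:
        dists = build_distributions(params)
    rng = np.random.default_rng((seed, draw_index))
    for _attempt in range(100):
        values = {key: float(spec.sample(rng)) for key, spec in dists.items()}
        if values["rr_mortality"] * values["risk28"] < 1.0:
            return _rebuild(params, values), values
    raise RuntimeError("could not draw a valid parameter set after 100 attempts")


# ---------------------------------------------------------------------------
# PSA driver


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incrementals (TXA minus no-TXA) plus per-arm totals."""

    seed: int
    cost: dict[str, np.ndarray]
    ly: dict[str, np.ndarray]
    qaly: dict[str, np.ndarray]
    n_rejected: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost["txa"] - self.cost["no_txa"]

    @property
    def delta_ly(self) -> np.ndarray:
        return self.ly["txa"] - self.ly["no_txa"]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly["txa"] - self.qaly["no_txa"]

    def mean_result(self, wtp: float = 20_000.0) -> dict[str, float]:
        """Mean probabilistic totals and incrementals."""
        out = {}
        for arm in ARMS:
            out[f"cost_{arm}"] = float(self.cost[arm].mean())
            out[f"ly_{arm}"] = float(self.ly[arm].mean())
            out[f"qaly_{arm}"] = float(self.qaly[arm].mean())
        out["delta_cost"] = float(self.delta_cost.mean())
        out["delta_ly"] = float(self.delta_ly.mean())
        out["delta_qaly"] = float(self.delta_qaly.mean())
        out["inmb"] = wtp * out["delta_qaly"] - out["delta_cost"]
        return out

    def ceac(self, thresholds: np.ndarray | None = None) -> pd.DataFrame:
        return ceac(self.delta_cost, self.delta_qaly, thresholds)

    def p_cost_effective(self, wtp: float = 20_000.0) -> float:
        return p_cost_effective(self.delta_cost, self.delta_qaly, wtp)

    def quadrant_shares(self) -> dict[str, float]:
        return quadrant_shares(self.delta_cost, self.delta_qaly)

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: incremental cost, LYs and QALYs."""
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "delta_cost": self.delta_cost,
                "delta_ly": self.delta_ly,
                "delta_qaly": self.delta_qaly,
            }
        )


def run_psa(
    params: ParameterSet | None = None,
    life_table: LifeTable | None = None,
    n_draws: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte Carlo PSA: sample, rebuild both arms, record incrementals."""
    if params is None:
        params = default_parameters()
    if life_table is None:
        life_table = load_life_table(params.life_table)
    if n_draws is None:
        n_draws = params.psa_n
    if seed is None:
        seed = params.seed
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    dists = build_distributions(params)
    cost = {arm: np.empty(n_draws) for arm in ARMS}
    ly = {arm: np.empty(n_draws) for arm in ARMS}
    qaly = {arm: np.empty(n_draws) for arm in ARMS}
    for i in range(n_draws):
        drawn, _ = sample_parameter_set(params, seed, i, dists)
        for arm in ARMS:
            out = run_outcomes(drawn, life_table, arm)
            cost[arm][i] = out.cost
            ly[arm][i] = out.ly
            qaly[arm][i] = out.qaly
    return PSAResult(seed=seed, cost=cost, ly=ly, qaly=qaly)


# ---------------------------------------------------------------------------
# deterministic scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides (dotted configuration paths)."""

    name: str
    description: str
    overrides: dict[str, object]


def standard_scenarios(params: ParameterSet | None = None) -> list[ScenarioSpec]:
    """The shipped one-way deterministic sensitivity analyses.

    The "inpatient costs excluded in year 1" variant sets the year-1
    monitoring amount to the year-2 level, stripping the acute-year excess
    attributable to the already-costed admission; the exact amount behind the
    published variant is not stated, so this row is qualitative.
    """
    if params is None:
        params = default_parameters()
    rr = params.rr_mortality
    return [
        ScenarioSpec("base_case", "Base case", {}),
        ScenarioSpec(
            "monitoring_full_year4_plus",
            "Full monitoring costs for year 4 onwards",
            {"costs.post_discharge.year4_plus_fraction": 1.0},
        ),
        ScenarioSpec(
            "monitoring_stop_after_year3",
            "Monitoring costs not included beyond 3 years",
            {"costs.post_discharge.year4_plus_fraction": 0.0},
        ),
        ScenarioSpec(
            "discount_0pct",
            "0% discount rate (costs and QALYs)",
            {"model.discount_rate_costs": 0.0, "model.discount_rate_qalys": 0.0},
        ),
        ScenarioSpec(
            "discount_6pct",
            "6% discount rate (costs and QALYs)",
            {"model.discount_rate_costs": 0.06, "model.discount_rate_qalys": 0.06},
        ),
        ScenarioSpec(
            "utility_0_5",
            "Survivor utility 0.5",
            {"utilities.survivor": {"value": 0.5, "ci": [0.5, 0.5]}},
        ),
        ScenarioSpec(
            "monitoring_year1_excl_inpatient",
            "Year-1 monitoring without inpatient-attributable costs",
            {"costs.post_discharge.year1": params.postdischarge.year2},
        ),
        ScenarioSpec(
            "rr_lower_ci",
            f"Mortality risk ratio at lower 95% bound ({rr.lo})",
            {"mortality.rr_mortality.value": rr.lo},
        ),
        ScenarioSpec(
            "rr_upper_ci",
            f"Mortality risk ratio at upper 95% bound ({rr.hi})",
            {"mortality.rr_mortality.value": rr.hi},
        ),
        ScenarioSpec(
            "txa_admin_zero",
            "TXA administration cost set to zero",
            {"costs.txa_admin." + k: 0.0 for k in params.txa_admin_components},
        ),
    ]


META_ANALYSIS_OVERRIDES: dict[str, object] = {
    # pre-trial evidence: pooled RR 0.60 (0.42-0.87), control risk 71/850
    "mortality.rr_mortality": {"value": 0.60, "ci": [0.42, 0.87]},
    "mortality.risk28": {"events": 71, "n": 850},
}


def meta_analysis_params(params: ParameterSet | None = None) -> ParameterSet:
    """Parameter set for the pre-trial meta-analysis evidence scenario."""
    if params is None:
        params = default_parameters()
    return params.with_overrides(META_ANALYSIS_OVERRIDES)


def apply_scenario(params: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    return params.with_overrides(scenario.overrides) if scenario.overrides else params


def run_dsa(
    params: ParameterSet | None = None,
    life_table: LifeTable | None = None,
    scenarios: list[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """One deterministic model run per scenario; table shaped like a DSA report."""
    if params is None:
        params = default_parameters()
    if life_table is None:
        life_table = load_life_table(params.life_table)
    if scenarios is None:
        scenarios = standard_scenarios(params)

    rows = []
    for sc in scenarios:
        p = apply_scenario(params, sc)
        outcomes = {arm: run_outcomes(p, life_table, arm) for arm in ARMS}
        res: CEResult = compare(outcomes["no_txa"], outcomes["txa"], wtp=p.wtp_threshold)
        rows.append(
            {
                "scenario": sc.name,
                "description": sc.description,
                "delta_cost": res.delta_cost,
                "delta_ly": res.delta_ly,
                "delta_qaly": res.delta_qaly,
                "icer_ly": res.icer_ly.value,
                "icer_qaly": res.icer_qaly.value,
                "inmb": res.inmb,
                "quadrant": res.quadrant,
            }
        )
    return pd.DataFrame(rows)
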