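"""High-level model runs: one arm, both arms, deterministic base case."""

from __future__ import annotations

from .costing import build_cost_schedule
from .engine import ArmOutcome, CohortTrace, UtilitySchedule, lifetime_outputs, run_trace
from .metrics import CEResult, compare
from .params import ARMS, ParameterSet, default_parameters
from .survival import LifeTable, build_schedule, load_life_table


def run_arm(params: ParameterSet, life_table: LifeTable, arm: str) -> CohortTrace:
    """Build the schedules for one arm and run the cohort trace."""
    schedule = build_schedule(params, life_table, arm)
    return run_trace(
        schedule,
        UtilitySchedule.from_params(params),
        build_cost_schedule(params, arm),
        discount_rate_costs=params.discount_rate_costs,
        discount_rate_qalys=params.discount_rate_qalys,
        half_cycle_correction=params.half_cycle_correction,
        discount_timing=params.discount_timing,
    )


def run_outcomes(params: ParameterSet, life_table: LifeTable, arm: str) -> ArmOutcome:
    return lifetime_outputs(run_arm(params, life_table, arm))


def run_base_case(
    params: ParameterSet | None = None,
    life_table: LifeTable | None = None,
) -> CEResult:
    """Deterministic comparison of TXA vs no-TXA at the point estimates."""
    if params is None:
        params = default_parameters()
    if life_table is None:
        life_table = load_life_table(params.life_table)
    outcomes = {arm: run_outcomes(params, life_table, arm) for arm in ARMS}
    return compare(outcomes["no_txa"], outcomes["txa"], wtp=params.wtp_threshold)
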