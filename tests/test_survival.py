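"""Survival building blocks: rate identities, SMR, trial curve, schedules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from txa_cea.params import default_parameters
from txa_cea.survival import (
    LifeTable,
    annual_to_daily,
    apply_smr,
    build_schedule,
    default_shape,
    make_trial_curve,
    prob_to_rate,
    rate_to_prob,
)

probs = st.floats(min_value=0.0, max_value=0.999)


class TestRateIdentities:
    def test_known_values(self):
        assert prob_to_rate(0.0) == 0.0
        assert prob_to_rate(0.05) == pytest.approx(-np.log(0.95))
        assert prob_to_rate(0.05) == pytest.approx(0.051293, abs=1e-6)

    def test_probability_one_is_infinite_rate(self):
        with pytest.raises(ValueError):
            prob_to_rate(1.0)

    @given(p=probs, t=st.floats(min_value=0.01, max_value=100))
    def test_round_trip(self, p, t):
        assert rate_to_prob(prob_to_rate(p, t), t) == pytest.approx(p, abs=1e-12)


class TestApplySMR:
    def test_identity_at_smr_one(self):
        assert apply_smr(0.3, 1.0) == pytest.approx(0.3)

    def test_zero_stays_zero(self):
        assert apply_smr(0.0, 5.21) == 0.0

    def test_first_year_smr_value(self):
        assert apply_smr(0.01, 5.21) == pytest.approx(1 - 0.99**5.21)
        assert apply_smr(0.01, 5.21) == pytest.approx(0.051015, abs=1e-6)

    @given(q=probs, smr=st.floats(min_value=0.1, max_value=10))
    def test_stays_a_probability_and_monotone_in_smr(self, q, smr):
        out = apply_smr(q, smr)
        assert 0.0 <= out < 1.0
        assert apply_smr(q, smr * 1.5) >= out


class TestAnnualToDaily:
    def test_values(self):
        assert annual_to_daily(0.0) == 0.0
        assert annual_to_daily(0.05) == pytest.approx(1.4052e-4, rel=1e-4)

    @given(q=probs)
    def test_compounding_recovers_annual(self, q):
        daily = annual_to_daily(q)
        assert 1 - (1 - daily) ** 365 == pytest.approx(q, abs=1e-10)


class TestTrialCurve:
    @pytest.mark.parametrize("kind", ["geometric", "uniform"])
    def test_survival_product_identity(self, kind):
        curve = make_trial_curve(0.092, default_shape(kind))
        implied = 1 - np.prod(1 - curve.conditional)
        assert implied == pytest.approx(0.092, abs=1e-12)

    def test_uniform_weights_give_equal_daily_fractions(self):
        curve = make_trial_curve(0.092, np.ones(28))
        assert curve.unconditional == pytest.approx(np.full(28, 0.092 / 28))

    def test_zero_risk_gives_zero_curve(self):
        curve = make_trial_curve(0.0, default_shape())
        assert np.all(curve.unconditional == 0)
        assert np.all(curve.conditional == 0)

    def test_rescaling_preserves_day_shares(self):
        base = make_trial_curve(0.092, default_shape())
        scaled = base.rescaled(0.084)
        assert scaled.cumulative_risk == pytest.approx(0.084)
        assert scaled.unconditional / 0.084 == pytest.approx(
            base.unconditional / 0.092
        )

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            make_trial_curve(0.1, np.array([1.0, -0.5]))

    @given(risk=st.floats(min_value=0.0, max_value=0.5))
    def test_unconditional_fractions_sum_to_risk(self, risk):
        curve = make_trial_curve(risk, default_shape())
        assert curve.unconditional.sum() == pytest.approx(risk, abs=1e-12)


class TestLifeTable:
    def test_packaged_table_covers_model_ages(self, life_table):
        assert life_table.min_age == 0
        assert life_table.max_age == 100
        assert np.all((life_table.q_annual >= 0) & (life_table.q_annual <= 1))

    def test_packaged_table_is_uk_like(self, life_table):
        # life expectancy at birth ~81y for UK all-persons period tables
        e0 = sum(
            np.prod(1 - life_table.q_annual[:a]) for a in range(101)
        )
        assert 78 < e0 < 84

    def test_gompertz_makeham_generator(self):
        lt = LifeTable.gompertz_makeham()
        assert lt.max_age == 100
        assert np.all(np.diff(lt.q_annual[30:]) > 0)  # increasing adult mortality

    def test_non_contiguous_ages_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable(np.array([1, 3]), np.array([0.1, 0.2]))

    def test_csv_round_trip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        again = LifeTable.from_csv(path)
        assert np.allclose(again.q_annual, life_table.q_annual)


class TestSchedule:
    def test_cycle_structure_partitions_horizon(self, params, life_table):
        s = build_schedule(params, life_table, "no_txa")
        assert np.all(s.length_days[:365] == 1)
        assert np.all(s.length_days[365:] == 365)
        # contiguous: each cycle starts where the previous ended
        assert np.all(np.diff(s.start_day) == s.length_days[:-1])
        assert s.attained_age[-1] < params.horizon_age

    def test_control_28day_cumulative_risk(self, params, life_table):
        s = build_schedule(params, life_table, "no_txa")
        assert s.cumulative_risk_28day == pytest.approx(params.risk28_value, abs=1e-12)

    def test_rr_scales_txa_cumulative_risk(self, params, life_table):
        s = build_schedule(params, life_table, "txa")
        assert s.cumulative_risk_28day == pytest.approx(
            1.03 * params.risk28_value, abs=1e-12
        )

    def test_null_effect_gives_identical_schedules(self, params, life_table):
        neutral = params.with_overrides({"mortality.rr_mortality.value": 1.0})
        a = build_schedule(neutral, life_table, "txa")
        b = build_schedule(neutral, life_table, "no_txa")
        assert np.array_equal(a.p_death, b.p_death)

    def test_arms_differ_only_in_trial_window(self, params, life_table):
        a = build_schedule(params, life_table, "txa")
        b = build_schedule(params, life_table, "no_txa")
        assert not np.array_equal(a.p_death[:28], b.p_death[:28])
        assert np.array_equal(a.p_death[28:], b.p_death[28:])

    def test_impossible_risk_rejected(self, params, life_table):
        bad = params.with_overrides(
            {"mortality.rr_mortality": {"value": 11.0, "ci": [11.0, 11.0]}}
        )
        with pytest.raises(ValueError, match="not a valid probability"):
            build_schedule(bad, life_table, "txa")

    def test_smr_monotonically_reduces_life_expectancy(self, params, life_table):
        def life_exp(smr1, smr2):
            p = params.with_overrides(
                {
                    "mortality.smr_year1": {"value": smr1, "ci": [smr1, smr1]},
                    "mortality.smr_year2plus": {"value": smr2, "ci": [smr2, smr2]},
                }
            )
            s = build_schedule(p, life_table, "no_txa")
            surv = s.survival_at_cycle_starts()[:-1]
            return float((surv * (1 - s.p_death) * s.length_days).sum())

        base = life_exp(5.21, 1.74)
        assert life_exp(6.0, 1.74) < base
        assert life_exp(5.21, 2.5) < base
        assert life_exp(1.0, 1.0) > base

    def test_neutral_schedule_tracks_raw_life_table(self, params, life_table):
        """SMR=1 and no trial deaths: schedule survival ~ life-table survival.

        The only divergence is the 28-day trial window, which carries no
        general-population mortality (a factor (1-q)^(28/365) at the start
        age), so agreement is to a few parts in 10^3, exact thereafter in
        relative change.
        """
        start = 58  # integer start age so the oracle is a clean product
        p = params.with_overrides(
            {
                "model.start_age": float(start),
                "mortality.smr_year1": {"value": 1.0, "ci": [1.0, 1.0]},
                "mortality.smr_year2plus": {"value": 1.0, "ci": [1.0, 1.0]},
                "mortality.risk28": {"events": 0, "n": 5981},
                "mortality.rr_mortality": {"value": 1.0, "ci": [1.0, 1.0]},
            }
        )
        s = build_schedule(p, life_table, "no_txa")
        surv = s.survival_at_cycle_starts()
        year_start_idx = np.where(s.start_day % 365 == 0)[0]
        for idx in year_start_idx[1:]:
            k = int(s.start_day[idx] // 365)
            oracle = life_table.survival_to(start, start + k)
            assert surv[idx] == pytest.approx(oracle, rel=5e-3)
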