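"""Distribution fitting, PSA reproducibility, scenario machinery."""

import numpy as np
import pytest

from txa_cea.uncertainty import (
    beta_from_ci,
    beta_from_counts,
    build_distributions,
    gamma_from_mean_se,
    lognormal_from_ci,
    meta_analysis_params,
    run_psa,
    sample_parameter_set,
    standard_scenarios,
)


class TestLognormalFromCI:
    def test_risk_ratio_fit(self):
        spec = lognormal_from_ci(1.03, 0.92, 1.16)
        assert spec.params["mu"] == pytest.approx(np.log(1.03))
        assert spec.params["mu"] == pytest.approx(0.029559, abs=1e-6)
        assert spec.params["sigma"] == pytest.approx(0.059134, abs=1e-6)

    def test_smr_fit_sigma_closed_form(self):
        spec = lognormal_from_ci(5.21, 4.25, 6.38)
        assert spec.params["sigma"] == pytest.approx(
            (np.log(6.38) - np.log(4.25)) / (2 * 1.959964), abs=1e-6
        )

    def test_degenerate_ci_collapses_to_point(self):
        spec = lognormal_from_ci(2.0, 2.0, 2.0)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0)) == 2.0

    def test_median_equals_point(self):
        spec = lognormal_from_ci(5.21, 4.25, 6.38)
        assert spec.mean() == pytest.approx(5.21, abs=1e-6)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_ci(1.0, 0.0, 2.0)


class TestBetaFromCounts:
    def test_trial_mortality_counts(self):
        spec = beta_from_counts(548, 5981)
        assert spec.params == {"alpha": 548.0, "beta": 5433.0}
        assert spec.mean() == pytest.approx(0.09162, abs=5e-6)

    def test_procedure_counts(self):
        assert beta_from_counts(4781, 5953).mean() == pytest.approx(0.8031, abs=1e-4)

    def test_zero_events_point_mass(self):
        spec = beta_from_counts(0, 10)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0)) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            beta_from_counts(0, 0)


class TestBetaFromCI:
    def test_utility_fit_method_of_moments(self):
        spec = beta_from_ci(0.735, 0.70, 0.77)
        assert spec.params["alpha"] == pytest.approx(448.2, abs=0.5)
        assert spec.params["beta"] == pytest.approx(161.6, abs=0.5)

    def test_moment_identity(self):
        spec = beta_from_ci(0.735, 0.70, 0.77)
        assert spec.mean() == pytest.approx(0.735, abs=1e-9)

    def test_degenerate_se(self):
        assert beta_from_ci(0.5, 0.5, 0.5).family == "fixed"

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_ci(0.5, -1.5, 2.5)


class TestGammaFromMeanSE:
    def test_length_of_stay_fit(self):
        spec = gamma_from_mean_se(5.83, 1.46)
        assert spec.params["shape"] == pytest.approx(15.945, abs=1e-3)
        assert spec.params["scale"] == pytest.approx(0.36563, abs=1e-5)

    def test_cost_with_se_half_of_mean(self):
        spec = gamma_from_mean_se(4350, 2175)
        assert spec.params["shape"] == pytest.approx(4.0)
        assert spec.params["scale"] == pytest.approx(1087.5)

    def test_moment_identity(self):
        spec = gamma_from_mean_se(5.83, 1.46)
        assert spec.mean() == pytest.approx(5.83, abs=1e-9)

    def test_zero_se_held_fixed(self):
        spec = gamma_from_mean_se(0.2, 0.0)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0), 3) == pytest.approx([0.2] * 3)


class TestJointSampling:
    def test_every_fitted_mean_matches_source_point(self, params):
        for key, spec in build_distributions(params).items():
            assert spec.mean() == pytest.approx(spec.point, abs=1e-6), key

    def test_fixed_inputs_absent_from_distributions(self, params):
        # unit costs, discount rates, decrements and the TXA administration
        # cost have no distribution in the source tables
        keys = build_distributions(params)
        assert len(keys) == 34  # 8 shared + 13 per arm
        assert not any(
            k.startswith(("txa_admin", "discount", "unit_costs", "utilities.decrements"))
            for k in keys
        )

    def test_draw_reproducible_given_seed_and_index(self, params):
        a, va = sample_parameter_set(params, seed=42, draw_index=7)
        b, vb = sample_parameter_set(params, seed=42, draw_index=7)
        assert va == vb
        assert a == b
        _, vc = sample_parameter_set(params, seed=42, draw_index=8)
        assert vc != va

    def test_sample_mean_of_rr_near_analytic(self, params):
        draws = [
            sample_parameter_set(params, 3, i)[1]["rr_mortality"] for i in range(3000)
        ]
        sigma = 0.059133
        analytic_mean = 1.03 * np.exp(sigma**2 / 2)
        analytic_sd = analytic_mean * np.sqrt(np.exp(sigma**2) - 1)
        assert np.mean(draws) == pytest.approx(
            analytic_mean, abs=3 * analytic_sd / np.sqrt(len(draws))
        )

    def test_txa_arm_risk_is_rr_times_drawn_risk(self, params, life_table):
        from txa_cea.survival import build_schedule

        drawn, v = sample_parameter_set(params, seed=5, draw_index=0)
        sched = build_schedule(drawn, life_table, "txa")
        assert sched.cumulative_risk_28day == pytest.approx(
            v["rr_mortality"] * v["risk28"], abs=1e-12
        )


class TestPSA:
    def test_degenerate_psa_reproduces_deterministic(self, params, life_table, base_result):
        """Collapsing every distribution to its point recovers the base case."""
        import dataclasses

        from txa_cea.model import run_base_case

        dists = {
            k: dataclasses.replace(s, family="fixed", params={})
            for k, s in build_distributions(params).items()
        }
        drawn, values = sample_parameter_set(params, seed=0, draw_index=0, dists=dists)
        assert values["rr_mortality"] == 1.03
        res = run_base_case(drawn, life_table)
        assert res.delta_cost == pytest.approx(base_result.delta_cost, abs=1e-9)
        assert res.delta_qaly == pytest.approx(base_result.delta_qaly, abs=1e-12)
        assert res.icer_qaly.value == pytest.approx(base_result.icer_qaly.value, abs=1e-6)

    def test_psa_seed_reproducibility(self, params, life_table):
        a = run_psa(params, life_table, n_draws=20, seed=11)
        b = run_psa(params, life_table, n_draws=20, seed=11)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        c = run_psa(params, life_table, n_draws=20, seed=12)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_psa_mean_near_deterministic(self, params, life_table, base_result):
        """Mean probabilistic totals sit close to the deterministic totals."""
        res = run_psa(params, life_table, n_draws=400, seed=3)
        means = res.mean_result()
        assert means["cost_no_txa"] == pytest.approx(base_result.no_txa.cost, rel=0.02)
        assert means["qaly_no_txa"] == pytest.approx(base_result.no_txa.qaly, rel=0.02)


class TestScenarios:
    def test_shipped_scenario_names(self, params):
        names = [s.name for s in standard_scenarios(params)]
        assert names[0] == "base_case"
        assert len(names) == 10
        assert len(set(names)) == 10

    def test_rr_one_with_identical_resource_use_zero_incrementals(self, params, life_table):
        """A null treatment effect with identical arm profiles is exactly null."""
        from txa_cea.model import run_base_case
        from txa_cea.params import ARMS
        import dataclasses

        p = params.with_overrides(
            {
                "mortality.rr_mortality.value": 1.0,
                **{f"costs.txa_admin.{k}": 0.0 for k in params.txa_admin_components},
            }
        )
        p = dataclasses.replace(
            p, resource_use={arm: p.resource_use["no_txa"] for arm in ARMS}
        )
        res = run_base_case(p, life_table)
        assert res.delta_cost == 0.0
        assert res.delta_ly == 0.0
        assert res.delta_qaly == 0.0

    def test_meta_analysis_parameterisation(self, params):
        meta = meta_analysis_params(params)
        assert meta.rr_mortality.as_tuple() == (0.60, 0.42, 0.87)
        assert (meta.risk28.events, meta.risk28.n) == (71, 850)
        assert meta.risk28_value == pytest.approx(0.0835, abs=2e-4)
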