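"""Simulator behaviour: start points, stopping rules, designs, drifts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

import gsrchoice as g
from gsrchoice.simulate import start_projections


def p_choice_A(res) -> float:
    ok = ~res["censored"]
    return float(np.mean(res["choice"][ok] == 0))


class TestStartPoints:
    def test_zero_variability_starts_at_origin(self, rng):
        a, b = start_projections("diffusion", 0.0, 1000, rng)
        assert not a.any() and not b.any()
        assert np.array_equal(g.sample_start("accumulator", 0.0, rng), [0.0, 0.0])

    def test_diffusion_balance_uniform(self, rng):
        a, b = start_projections("diffusion", 1.0, 100_000, rng)
        balance = a - b
        assert stats.kstest(balance, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_accumulator_balance_triangular_peaked_at_zero(self, rng):
        # many more uniform pairs combine to a balance of zero than to +-s_v
        a, b = start_projections("accumulator", 1.0, 100_000, rng)
        balance = a - b
        tri = stats.triang(c=0.5, loc=-1, scale=2)
        assert stats.kstest(balance, tri.cdf).pvalue > 0.01

    def test_negative_variability_rejected(self, rng):
        with pytest.raises(ValueError):
            start_projections("diffusion", -0.1, 10, rng)

    def test_gsr_start_state_reproduces_projections(self, rng):
        frame = g.make_option_frame(2.0)
        state = g.sample_start("gsr", 1.0, rng, frame)
        pa, pb = g.project(state, frame.u_A), g.project(state, frame.u_B)
        assert 0.0 <= pa <= 1.0 and 0.0 <= pb <= 1.0


class TestStoppingRule:
    def test_zero_drift_diffusion_is_unbiased(self, rng):
        res = g.first_passage(np.zeros(10_000), np.zeros(10_000), np.pi, 1.0, rng=rng)
        assert abs(p_choice_A(res) - 0.5) < 3 * 0.005

    def test_exchangeable_race_is_unbiased(self, rng):
        n = 10_000
        d = np.full(n, 1.5)
        res = g.first_passage(d, d, np.pi / 2, 1.0, rng=rng)
        assert abs(p_choice_A(res) - 0.5) < 3 * 0.005

    @pytest.mark.parametrize("delta", [0.25, 0.75, 1.5])
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    def test_gamma_pi_matches_wiener_absorption(self, delta, theta, rng):
        """The gamma = pi simulator is a 1-D DDM with boundaries +-theta."""
        n = 4000
        res = g.first_passage(
            np.full(n, delta), np.full(n, -delta), np.pi, theta, rng=rng
        )
        p_hat = p_choice_A(res)
        p_true = g.absorption_probability(theta, delta)
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < 3 * se + 1e-9

    def test_race_matches_independent_diffusion_oracle(self, rng):
        """gamma = pi/2 equals two independent racing diffusions."""
        n, dt, theta, d_a, d_b = 4000, 1e-3, 1.0, 1.2, 0.8
        res = g.first_passage(
            np.full(n, d_a), np.full(n, d_b), np.pi / 2, theta, rng=rng
        )
        win_t = res["decision_time"][~res["censored"]]
        # brute-force oracle: step two independent 1-D diffusions directly
        orng = np.random.default_rng(777)
        x = np.zeros(n)
        y = np.zeros(n)
        t_or = np.full(n, np.nan)
        sdt = math.sqrt(dt)
        for step in range(10_000):
            x += d_a * dt + sdt * orng.standard_normal(n)
            y += d_b * dt + sdt * orng.standard_normal(n)
            done = ((x >= theta) | (y >= theta)) & np.isnan(t_or)
            t_or[done] = (step + 1) * dt
            if not np.isnan(t_or).any():
                break
        assert stats.ks_2samp(win_t, t_or[~np.isnan(t_or)]).pvalue > 0.01

    def test_rt_translates_exactly_with_non_decision_time(self):
        kw = dict(phi=0.3, mu_mag=2.0, theta=1.0, nu=0.0, gamma=np.pi)
        t1 = g.simulate_trial(g.ParameterSet(tau=0.2, **kw), rng=np.random.default_rng(9))
        t2 = g.simulate_trial(g.ParameterSet(tau=0.7, **kw), rng=np.random.default_rng(9))
        assert t1.n_steps == t2.n_steps
        assert t2.rt - t1.rt == pytest.approx(0.5)
        assert t1.rt >= 0.2

    def test_dt_refinement_converges_to_closed_form(self):
        """First-crossing on the discrete grid biases choice probabilities by
        O(sqrt(dt)); refining dt from 0.01 to 0.001 must shrink the error
        against the closed-form absorption probability."""
        n, delta, theta = 100_000, 0.8, 1.0
        p_true = g.absorption_probability(theta, delta)
        err = {}
        for dt in (0.01, 0.001):
            rng = np.random.default_rng(42)
            res = g.first_passage(
                np.full(n, delta), np.full(n, -delta), np.pi, theta, dt=dt, rng=rng
            )
            err[dt] = abs(p_choice_A(res) - p_true)
        assert err[0.001] < err[0.01]
        assert err[0.001] < 0.01

    def test_censoring_is_flagged_not_raised(self, rng):
        res = g.first_passage(np.zeros(50), np.zeros(50), np.pi, 5.0, t_max=0.05, rng=rng)
        assert res["censored"].all()

    def test_non_finite_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            g.first_passage([np.nan], [0.0], np.pi, 1.0, rng=rng)

    def test_trace_sums_to_net_balance(self, rng):
        tr = g.simulate_trial(
            g.ParameterSet(phi=0.3, mu_mag=2.0, theta=1.0, tau=0.1, nu=0.0, gamma=2.2),
            rng=rng, keep_trace=True,
        )
        assert np.sum(tr.trace) == pytest.approx(tr.balance_end - tr.balance_start)
        assert len(tr.trace) == tr.n_steps


class TestDesigns:
    def test_application_design_structure(self):
        d = g.DesignSpec.application()
        assert d.n_conditions == 12
        assert d.n_trials == 120

    def test_dataset_replicates_design(self, rng):
        d = g.DesignSpec.application()
        base = {
            "phi": {0: 0.2, 1: 0.4, 2: 0.6},
            "mu_mag": {(0, 1): 2.0, (0, 2): 3.0, (1, 1): 3.0, (1, 2): 4.0},
            "theta": {0: 2.0, 1: 2.5},
            "gamma": {0: 2.0, 1: 2.6},
            "tau": 0.3, "nu": 0.5, "s_v": 0.3,
        }
        cmap = g.build_condition_parameters(base, d)
        tables = [
            g.simulate_dataset(cmap, d, rng, participant=i) for i in range(34)
        ]
        assert all(len(t) == 120 for t in tables)
        assert sum(len(t) for t in tables) == 4080
        labels = set(tables[0]["condition"])
        assert len(labels) == 12

    def test_empty_design_gives_empty_table(self, rng):
        d = g.DesignSpec(conditions=[(0, 0, 0)], trials_per_condition=0)
        base = dict(phi=0.3, mu_mag=2.0, theta=2.0, tau=0.3, nu=0.5, gamma=2.2)
        cmap = g.build_condition_parameters(base, d)
        table = g.simulate_dataset(cmap, d, rng)
        assert len(table) == 0
        assert "rt" in table.columns


class TestConditionMapping:
    def test_application_mapping_has_14_free_parameters(self):
        d = g.DesignSpec.application()
        base = {
            "phi": {0: 0.2, 1: 0.4, 2: 0.6},
            "mu_mag": {(0, 1): 2.0, (0, 2): 3.0, (1, 1): 3.0, (1, 2): 4.0},
            "theta": {0: 2.0, 1: 2.5},
            "gamma": {0: 2.0, 1: 2.6},
            "tau": 0.3, "nu": 0.5, "s_v": 0.3,
        }
        cmap = g.build_condition_parameters(base, d)
        assert cmap.n_free_parameters == 14
        # mean drift pinned to zero in the lowest-match conditions
        assert cmap[(0, 0, 0)].mu_mag == 0.0
        assert cmap[(1, 0, 1)].mu_mag == 0.0

    def test_single_condition_mapping_has_6_free_parameters(self):
        base = dict(phi=0.3, mu_mag=2.0, theta=2.0, tau=0.3, nu=0.5, gamma=2.2)
        cmap = g.build_condition_parameters(base, g.DesignSpec.single(100))
        assert cmap.n_free_parameters == 6

    def test_degenerate_design_counts_distinct_fields(self):
        d = g.DesignSpec(conditions=[(0, 0, 0)], trials_per_condition=5)
        base = dict(phi=0.1, mu_mag=1.0, theta=1.0, tau=0.2, nu=0.1, gamma=np.pi)
        cmap = g.build_condition_parameters(base, d)
        assert cmap.n_free_parameters == len(base)

    def test_missing_level_is_a_configuration_error(self):
        d = g.DesignSpec.application()
        base = {
            "phi": {0: 0.2},  # match levels 1 and 2 missing
            "mu_mag": 2.0, "theta": 2.0, "tau": 0.3, "nu": 0.5, "gamma": 2.2,
        }
        with pytest.raises(KeyError):
            g.build_condition_parameters(base, d)


class TestMatchDrifts:
    def test_ambiguous_match_gives_equal_proportions(self, rng):
        p = g.match_favoring_probability(0.0, math.pi / 12, math.pi / 3)
        assert p == pytest.approx(0.5, abs=1e-12)
        d_c, d_i = g.accumulator_drifts_from_match(3.0, 0.0, 0.0, rng)
        assert d_c[0] == pytest.approx(d_i[0])

    def test_zero_drift_gives_pure_variability(self, rng):
        d_c, d_i = g.accumulator_drifts_from_match(0.0, 0.5, 1.0, rng, n=20_000)
        assert abs(d_c.mean()) < 0.02 and abs(d_i.mean()) < 0.02

    def test_favoring_probability_matches_integration_oracle(self):
        sd, sep = math.pi / 12, math.pi / 3
        for frac in (0.0, 1 / 3, 2 / 3):
            mean = frac * sep / 2

            def wrapped_pdf(x):
                return sum(
                    stats.norm.pdf(x + 2 * math.pi * k, mean, sd) for k in range(-5, 6)
                )

            oracle, _ = quad(wrapped_pdf, 0.0, math.pi, limit=200)
            assert g.match_favoring_probability(frac, sd, sep) == pytest.approx(
                oracle, abs=1e-9
            )

    def test_correct_proportion_increases_with_match(self):
        ps = [
            g.match_favoring_probability(f, math.pi / 12, math.pi / 3)
            for f in (0.0, 1 / 3, 2 / 3)
        ]
        assert ps[0] < ps[1] < ps[2]
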