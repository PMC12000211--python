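"""Accumulated-evidence profiles, bimodality coefficient, K-L identification.

Profile shape tests run the simulator in discrete-sample mode (one evidence
sample per step, ``dt = 1``), where the threshold is expressed in units of
the per-sample evidence SD — the regime the profile method describes.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import entropy

import gsrchoice as g
from gsrchoice.profiles import profile_from_values, trial_balance_values


def discrete_profile(gamma, delta, theta, n, seed, bin_range, model_class=None, bins=61):
    """Normalised end-of-trial profile from the discrete-sample walk."""
    rng = np.random.default_rng(seed)
    if model_class is None:
        from gsrchoice.simulate import _infer_model_class

        model_class = _infer_model_class(gamma)
    d_a, d_b = g.trial_drifts(model_class, 0.3, delta, 0.0, gamma, n, rng)
    res = g.first_passage(d_a, d_b, gamma, theta, dt=1.0, t_max=2000.0, rng=rng)
    keep = ~res["censored"]
    vals = res["balance_net"][keep] / res["n_steps"][keep]
    return vals, res["n_steps"][keep]


class TestProfileConstruction:
    def test_constant_traces_give_point_mass(self):
        trials = pd.DataFrame(
            {"censored": [False] * 4, "rt": [1.0] * 4, "correct": [1] * 4}
        )
        trials.attrs["traces"] = [np.full(10, 0.7)] * 4
        prof = g.profile_from_trials(trials, bins=11)
        c = prof.centers
        assert prof.mass[np.argmin(np.abs(c - 0.7))] == pytest.approx(1.0)

    def test_missing_trace_is_a_data_error(self):
        trials = pd.DataFrame({"censored": [False, False]})
        trials.attrs["traces"] = [np.ones(3), None]
        with pytest.raises(ValueError, match="trial 1"):
            g.profile_from_trials(trials)

    def test_mass_sums_to_one(self, rng):
        prof = profile_from_values(rng.standard_normal(1000))
        assert prof.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_relative_evidence_profile_has_central_gap(self):
        """gamma = pi under-samples moderate evidence: gap in the middle."""
        vals, _ = discrete_profile(np.pi, 1.0, 2.0, 20_000, 5, None)
        prof = profile_from_values(vals, bins=61, bin_range=(-4, 4))
        c = prof.centers
        central = prof.mass[np.abs(c) < 0.3].sum()
        flanks = prof.mass[(np.abs(c) > 0.5) & (np.abs(c) < 3.0)].sum()
        assert central < 0.02
        assert flanks > 0.5

    def test_accumulator_profile_tracks_stimulus_distribution(self):
        """The absolute-evidence profile stays close to the distribution of
        unconditioned stimulus means; the relative-evidence profile does not."""
        rng = np.random.default_rng(17)
        theta, delta = 2.0, 0.5
        lim = 6.0
        out = {}
        for gamma in (np.pi, np.pi / 2):
            vals, steps = discrete_profile(gamma, delta, theta, 20_000, 11, None)
            # oracle: balance means of random (unconditioned) samples with the
            # same per-trial sample counts and the same per-sample distribution
            mean_inc = {
                np.pi: 2 * delta * math.cos(0.3),
                np.pi / 2: delta * (math.cos(0.3) - math.sin(0.3)),
            }[gamma]
            sd_inc = {np.pi: 2.0, np.pi / 2: math.sqrt(2.0)}[gamma]
            stim = rng.normal(mean_inc, sd_inc / np.sqrt(steps))
            p = profile_from_values(vals, bin_range=(-lim, lim))
            q = profile_from_values(stim, bin_range=(-lim, lim))
            out[gamma] = g.kl_divergence(p, q)
        assert out[np.pi / 2] < out[np.pi]

    def test_relative_evidence_profile_inflates_variance(self):
        """Extreme evidence is over-sampled: the end-of-trial profile has
        greater variance than unconditioned stimulus means of the same length."""
        rng = np.random.default_rng(23)
        vals, steps = discrete_profile(np.pi, 0.5, 2.0, 20_000, 29, None)
        stim = rng.normal(2 * 0.5 * math.cos(0.3), 2.0 / np.sqrt(steps))
        assert vals.var() > stim.var()

    def test_bimodality_ordering_diffusion_vs_accumulator(self):
        v_diff, _ = discrete_profile(np.pi, 0.5, 1.0, 10_000, 31, None)
        v_acc, _ = discrete_profile(np.pi / 2, 0.5, 1.0, 10_000, 37, None)
        assert g.bimodality_coefficient(v_diff) > g.bimodality_coefficient(v_acc)


class TestContinuousProfile:
    def test_symmetric_without_drift(self):
        prof = g.ddm_continuous_profile(1.0, 0.0)
        c = prof.centers
        assert np.allclose(prof.mass, prof.mass[::-1], atol=1e-12)
        assert prof.mean() == pytest.approx(0.0, abs=1e-12)

    def test_starkly_bimodal_with_zero_central_mass(self):
        prof = g.ddm_continuous_profile(1.0, 0.5)
        c = prof.centers
        half_bin = (c[1] - c[0]) / 2
        assert prof.mass[np.abs(c) < half_bin].sum() < 1e-3
        assert prof.mass[c > 0].sum() > 0.5

    def test_branch_mass_equals_absorption_probability(self):
        prof = g.ddm_continuous_profile(1.0, 0.5)
        assert prof.mass[prof.centers > 0].sum() == pytest.approx(
            g.absorption_probability(1.0, 0.5), abs=2e-3
        )

    def test_branch_mass_matches_simulator_choice_probability(self, rng):
        theta, delta, n = 1.0, 0.5, 20_000
        res = g.first_passage(
            np.full(n, delta), np.full(n, -delta), np.pi, theta, rng=rng
        )
        ok = ~res["censored"]
        p_sim = np.mean(res["choice"][ok] == 0)
        prof = g.ddm_continuous_profile(theta, delta)
        p_prof = prof.mass[prof.centers > 0].sum()
        se = math.sqrt(p_prof * (1 - p_prof) / n)
        assert abs(p_sim - p_prof) < 3 * se + 2e-3

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            g.ddm_continuous_profile(1.0, 0.5, t_grid=np.array([1.0]))
        with pytest.raises(ValueError):
            g.ddm_continuous_profile(1.0, 0.5, t_grid=np.array([-1.0, 1.0]))


class TestBimodalityCoefficient:
    def test_balanced_two_point_sample_approaches_one(self):
        x = np.tile([-1.0, 1.0], 5000)
        assert g.bimodality_coefficient(x) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_sample(self, rng):
        # skewness 0, excess kurtosis -1.2  ->  B = 1/1.8 = 5/9
        b = g.bimodality_coefficient(rng.uniform(size=200_000))
        assert b == pytest.approx(5 / 9, abs=0.01)

    def test_normal_sample(self, rng):
        # skewness 0, excess kurtosis 0  ->  B = 1/3
        b = g.bimodality_coefficient(rng.standard_normal(200_000))
        assert b == pytest.approx(1 / 3, abs=0.01)

    @settings(deadline=None, max_examples=40)
    @given(
        a=st.floats(min_value=0.1, max_value=50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-100, max_value=100),
        seed=st.integers(min_value=0, max_value=999),
    )
    def test_location_scale_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert g.bimodality_coefficient(a * x + b) == pytest.approx(
            g.bimodality_coefficient(x), rel=1e-9
        )

    def test_small_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            g.bimodality_coefficient([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            g.bimodality_coefficient([2.0] * 10)


class TestKLDivergence:
    def test_identical_profiles_give_zero(self, rng):
        p = profile_from_values(rng.standard_normal(500), bin_range=(-4, 4))
        assert g.kl_divergence(p, p) == 0.0

    def test_point_mass_against_smoothed_reference(self):
        p = g.EvidenceProfile(np.linspace(0, 1, 5), [0, 1, 0, 0], n=10, normalized=True)
        q = g.EvidenceProfile(np.linspace(0, 1, 5), [0.5, 0, 0.5, 0], n=10, normalized=True)
        eps = 0.01
        q_sm = (np.array([0.5, 0, 0.5, 0]) + eps) / (1 + 4 * eps)
        assert g.kl_divergence(p, q, smooth=eps) == pytest.approx(np.log(1 / q_sm[1]))

    def test_matches_independent_entropy_computation(self, rng):
        for _ in range(5):
            a = rng.dirichlet(np.ones(20))
            b = rng.dirichlet(np.ones(20))
            edges = np.linspace(-1, 1, 21)
            p = g.EvidenceProfile(edges, a, n=100, normalized=True)
            q = g.EvidenceProfile(edges, b, n=100, normalized=True)
            assert g.kl_divergence(p, q) == pytest.approx(entropy(a, b), abs=1e-12)

    def test_mismatched_bins_rejected(self, rng):
        p = profile_from_values(rng.standard_normal(100), bin_range=(-4, 4))
        q = profile_from_values(rng.standard_normal(100), bin_range=(-3, 3))
        with pytest.raises(ValueError):
            g.kl_divergence(p, q)


class TestGammaIdentification:
    GRID = np.linspace(np.pi / 8, np.pi, 8)
    LIM = 4.0

    def _grid_profiles(self, n, seed):
        ps = lambda gam: g.ParameterSet(
            phi=0.3, mu_mag=1.0, theta=2.0, tau=0.0, nu=0.0, gamma=gam
        )
        rng = np.random.default_rng(seed)
        return [
            g.simulate_profile(
                ps(gam), n, rng, model_class="gsr", dt=1.0, t_max=2000.0,
                bin_range=(-self.LIM, self.LIM),
            )
            for gam in self.GRID
        ]

    def test_recovers_accumulator_angle_within_one_grid_spacing(self):
        profiles = self._grid_profiles(20_000, 101)
        vals, _ = discrete_profile(np.pi / 2, 1.0, 2.0, 20_000, 103, None, model_class="gsr")
        obs = profile_from_values(vals, bin_range=(-self.LIM, self.LIM))
        fit = g.fit_gamma_by_kl(obs, self.GRID, profiles)
        spacing = self.GRID[1] - self.GRID[0]
        assert abs(fit.gamma - np.pi / 2) <= spacing

    def test_exact_grid_profile_recovers_that_gamma(self):
        profiles = self._grid_profiles(20_000, 107)
        fit = g.fit_gamma_by_kl(profiles[3], self.GRID, profiles)
        assert fit.kl_values[3] == 0.0
        assert abs(fit.gamma - self.GRID[3]) < 0.1

    def test_relative_evidence_data_lands_near_upper_edge(self):
        profiles = self._grid_profiles(20_000, 109)
        vals, _ = discrete_profile(np.pi, 1.0, 2.0, 20_000, 113, None, model_class="gsr")
        obs = profile_from_values(vals, bin_range=(-self.LIM, self.LIM))
        fit = g.fit_gamma_by_kl(obs, self.GRID, profiles)
        spacing = self.GRID[1] - self.GRID[0]
        assert fit.gamma > np.pi - 2 * spacing

    def test_needs_at_least_four_grid_points(self):
        profiles = self._grid_profiles(100, 3)[:3]
        with pytest.raises(ValueError):
            g.fit_gamma_by_kl(profiles[0], self.GRID[:3], profiles)
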