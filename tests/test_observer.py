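"""Observer core: noise composition, densities (closed form vs numeric
convolution), posteriors, boundaries, choice probabilities, simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import noiseblind as nb
from noiseblind.observer import GridError, internal_densities

ALL_CONDITIONS = [(c, v) for c in (0.15, 0.6) for v in (0.0, 4.0, 10.0)]


def convolved_density(sigma, grid, offset=3.0, sd=8.0):
    """Numeric-convolution oracle for the component-conditioned density."""
    gen = norm.pdf(grid, offset, sd)
    if sigma == 0:
        return gen
    step = grid[1] - grid[0]
    kernel = norm.pdf(grid, 0.0, sigma)
    return np.convolve(gen, kernel, mode="same") * step


def neutral_frame(n, contrast, variability, rng, cue=0.5, optional=False):
    """Vectorized trial frame for one condition cell."""
    category = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    mu = rng.normal(category * 3.0, 8.0)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "block": 0,
            "contrast": contrast,
            "variability": variability,
            "set_size": 8,
            "cue_p_cw": cue,
            "category": category,
            "mu_deg": mu,
            "is_optional": optional,
        }
    )


class TestNoiseComposition:
    def test_total_noise_combines_in_quadrature(self, group_params):
        assert nb.total_noise(group_params, (0.6, 10.0)) == pytest.approx(
            7.5628, abs=1e-4
        )

    def test_zero_variability_collapses_to_encoding_noise(self, group_params):
        assert nb.total_noise(group_params, (0.6, 0.0)) == 3.31
        assert nb.total_noise(group_params, (0.15, 0.0)) == 10.1

    def test_all_zero_params_give_zero_noise(self):
        p = nb.ObserverNoiseParams(nC_low=0, nC_high=0, nV_med=0, nV_high=0)
        assert nb.total_noise(p, (0.6, 10.0)) == 0.0

    def test_unknown_level_error_lists_known_levels(self, group_params):
        with pytest.raises(ValueError, match="0.15"):
            nb.total_noise(group_params, (0.3, 0.0))

    def test_reversed_encoding_order_warns(self):
        with pytest.warns(UserWarning, match="nC_low < nC_high"):
            nb.ObserverNoiseParams(nC_low=1.0, nC_high=5.0, nV_high=2.0)


class TestDensities:
    def test_generative_density_value_and_mass(self, grid):
        dens = nb.generative_mu_density(grid)
        assert np.interp(3.0, grid, dens.density_cw) == pytest.approx(
            1 / (8 * np.sqrt(2 * np.pi)), rel=1e-6
        )
        assert np.trapezoid(dens.density_cw, grid) == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(dens.density_cw, dens.density_ccw[::-1])

    def test_component_density_closed_form_value(self, grid):
        dens = nb.build_density((0.6, 0.0), 3.31, grid)
        assert np.interp(0.0, grid, dens.density_cw) == pytest.approx(
            0.0434, abs=2e-4
        )

    def test_zero_sigma_returns_generative_density(self, grid):
        dens = nb.build_density(None, 0.0, grid)
        gen = nb.generative_mu_density(grid)
        assert np.allclose(dens.density_cw, gen.density_cw)

    @pytest.mark.parametrize("sigma", [0.0, 3.31, 6.8, 10.1])
    def test_component_density_matches_convolution_oracle(self, grid, sigma):
        dens = nb.build_density(None, sigma, grid)
        oracle = convolved_density(sigma, grid)
        assert np.max(np.abs(dens.density_cw - oracle)) < 1e-6

    def test_narrow_grid_raises_mass_error(self):
        with pytest.raises(GridError, match="widen"):
            nb.build_density(None, 10.0, nb.make_grid(20.0))

    def test_sign_density_zero_sigma_is_truncated_mixture(self, grid):
        dens = nb.build_sign_density(None, 0.0, grid)
        mix = 0.5 * (norm.pdf(grid, 3, 8) + norm.pdf(grid, -3, 8))
        pos = grid > 0
        assert np.allclose(dens.density_cw[pos], 2 * mix[pos])
        assert np.all(dens.density_cw[grid < 0] == 0)

    @given(sigma=st.floats(0.5, 20.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_sign_density_mass_and_mirror_symmetry(self, sigma):
        grid = nb.make_grid(max(60.0, 3 + 7 * np.hypot(8, sigma)))
        dens = nb.build_sign_density(None, sigma, grid)
        assert np.trapezoid(dens.density_cw, grid) == pytest.approx(1.0, abs=1e-3)
        assert np.max(np.abs(dens.density_cw - dens.density_ccw[::-1])) < 1e-10

    def test_sign_density_matches_quadrature_oracle(self, grid):
        from scipy.integrate import quad

        sigma = 3.31
        dens = nb.build_sign_density(None, sigma, grid)
        f = lambda m, x: (norm.pdf(m, 3, 8) + norm.pdf(m, -3, 8)) * norm.pdf(
            x - m, 0, sigma
        )
        for x in (-5.0, 0.0, 2.0, 10.0):
            oracle = quad(f, 0, 80, args=(x,), limit=200)[0]
            assert np.interp(x, grid, dens.density_cw) == pytest.approx(
                oracle, abs=1e-9
            )


class TestInternalModels:
    def test_main_variants_are_canonical_flag_settings(self):
        assert nb.OMNISCIENT.integration_aware and nb.OMNISCIENT.variability_identified
        assert nb.VARIABILITY_MIXER.integration_aware
        assert not nb.VARIABILITY_MIXER.variability_identified
        assert not nb.NOISE_BLIND.integration_aware

    def test_irrelevant_flags_are_canonicalised(self):
        spec = nb.InternalModelSpec(
            integration_aware=False, variability_identified=True
        )
        assert spec.variability_identified is False

    def test_flag_grid_generates_nine_distinct_variants(self):
        # awareness x identification per source: 3 states per side
        assert len(nb.model_grid()) == 9

    def test_omniscient_equals_noise_blind_at_zero_variability(self, group_params):
        omni = internal_densities(nb.OMNISCIENT, group_params, ALL_CONDITIONS)
        blind = internal_densities(nb.NOISE_BLIND, group_params, ALL_CONDITIONS)
        cell = (0.6, 0.0)
        assert np.allclose(
            omni[cell].density_cw, blind[cell].density_cw, atol=1e-12
        )

    def test_mixer_is_equal_weight_average_on_two_level_design(self, group_params):
        conds = [(0.15, 0.0), (0.15, 10.0), (0.6, 0.0), (0.6, 10.0)]
        omni = internal_densities(nb.OMNISCIENT, group_params, conds)
        mixer = internal_densities(nb.VARIABILITY_MIXER, group_params, conds)
        expected = 0.5 * (omni[(0.6, 0.0)].density_cw + omni[(0.6, 10.0)].density_cw)
        assert np.allclose(mixer[(0.6, 0.0)].density_cw, expected, atol=1e-12)
        assert np.allclose(mixer[(0.6, 10.0)].density_cw, expected, atol=1e-12)

    def test_noise_blind_component_density_understates_evidence_spread(
        self, group_params, grid
    ):
        blind = internal_densities(
            nb.NOISE_BLIND, group_params, ALL_CONDITIONS, grid,
            conditioning="component",
        )
        cw = blind[(0.6, 10.0)].density_cw
        mean = np.trapezoid(grid * cw, grid)
        sd = np.sqrt(np.trapezoid((grid - mean) ** 2 * cw, grid))
        assert sd == pytest.approx(np.sqrt(64 + 3.31**2), abs=0.02)
        assert sd < np.sqrt(64 + 7.5628**2)  # generative evidence SD ~10.9


class TestPosteriorAndBoundary:
    def test_neutral_posterior_at_zero_is_half(self, group_params, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        assert nb.posterior_cw(0.0, 0.5, dens) == pytest.approx(0.5)

    def test_equal_likelihoods_pass_the_prior_through(self, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        assert nb.posterior_cw(0.0, 0.75, dens) == pytest.approx(0.75)

    def test_component_posterior_matches_gaussian_ratio_oracle(self, grid):
        dens = nb.build_density(None, 3.31, grid)
        s2 = 64 + 3.31**2
        oracle = 1 / (1 + np.exp(-6 * 3.0 / s2))
        assert nb.posterior_cw(3.0, 0.5, dens) == pytest.approx(oracle, abs=1e-4)
        assert oracle == pytest.approx(0.5597, abs=1e-3)

    def test_posterior_monotone_in_evidence(self, grid):
        dens = nb.build_sign_density(None, 5.0, grid)
        xs = np.linspace(-40, 40, 401)
        p = nb.posterior_cw(xs, 0.75, dens)
        assert np.all(np.diff(p) >= -1e-12)

    def test_evidence_outside_grid_is_an_error(self, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        with pytest.raises(ValueError, match="outside the grid"):
            nb.posterior_cw(100.0, 0.5, dens)

    def test_neutral_boundary_is_exactly_zero(self, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        assert nb.decision_boundary(0.5, dens) == 0.0

    def test_component_boundary_matches_analytic_root(self, grid):
        # pi * L_cw = (1 - pi) * L_ccw with Gaussian pair N(+/-3, S):
        # x* = -ln(3) * S^2 / 6 for a 75% CW cue.
        dens = nb.build_density(None, 3.31, grid)
        s2 = 64 + 3.31**2
        assert nb.decision_boundary(0.75, dens) == pytest.approx(
            -np.log(3) * s2 / 6, abs=1e-3
        )

    def test_boundary_monotone_decreasing_in_cue(self, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        cues = [0.3, 0.5, 0.6, 0.75, 0.9]
        bounds = [nb.decision_boundary(c, dens) for c in cues]
        assert np.all(np.diff(bounds) < 0)

    def test_tie_breaking_uses_fair_coin(self, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        rng = np.random.default_rng(0)
        picks = {nb.choose_and_confidence(0.0, 0.5, dens, rng)[0] for _ in range(50)}
        assert picks == {1, -1}
        _, conf = nb.choose_and_confidence(0.0, 0.5, dens, rng)
        assert conf == 0.5

    def test_cue_can_override_mildly_opposing_evidence(self, grid):
        dens = nb.build_sign_density(None, 3.31, grid)
        choice, conf = nb.choose_and_confidence(-0.5, 0.75, dens)
        assert choice == 1 and conf > 0.5


class TestChoiceProbability:
    def test_symmetric_trial_is_fifty_fifty(self, group_params, exp1_conditions):
        obs = nb.BayesianObserver(group_params, nb.OMNISCIENT, exp1_conditions)
        assert obs.choice_probability(0.0, (0.6, 0.0), 0.5) == pytest.approx(0.5)

    def test_matches_gaussian_tail_oracle(self, group_params, exp1_conditions):
        obs = nb.BayesianObserver(group_params, nb.OMNISCIENT, exp1_conditions)
        assert obs.choice_probability(3.0, (0.6, 0.0), 0.5) == pytest.approx(
            norm.cdf(3 / 3.31), abs=1e-9
        )

    def test_all_variants_agree_on_neutral_trials(self, group_params, exp1_conditions):
        for mu in (-5.0, 0.7, 12.0):
            probs = {
                spec.name: nb.BayesianObserver(
                    group_params, spec, exp1_conditions
                ).choice_probability(mu, (0.6, 10.0), 0.5)
                for spec in nb.model_grid()
            }
            assert len(set(probs.values())) == 1


class TestOptIn:
    @pytest.mark.parametrize(
        "conf, expected", [(0.9, True), (0.6, False), (0.75, False)]
    )
    def test_threshold_rule_with_tie_toward_sure_option(self, conf, expected):
        assert nb.opt_in_decision(conf) is expected

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError):
            nb.opt_in_decision(0.3)


class TestSimulateObserver:
    def test_noiseless_observer_is_perfect_on_neutral_trials(self, exp1_trials):
        p = nb.ObserverNoiseParams(nC_low=0, nC_high=0, nV_med=0, nV_high=0)
        rec = nb.simulate_observer(exp1_trials, p, nb.OMNISCIENT, seed=0)
        neutral = rec[rec.cue_p_cw == 0.5]
        assert neutral["correct"].mean() == 1.0

    def test_baseline_accuracy_matches_integration_oracle(self, group_params):
        # E[Phi(|mu|/3.31)] over the mixture = 0.8828 (quadrature oracle)
        rng = np.random.default_rng(1)
        frame = neutral_frame(100_000, 0.6, 0.0, rng)
        rec = nb.simulate_observer(frame, group_params, nb.OMNISCIENT, seed=2)
        assert rec["correct"].mean() == pytest.approx(0.8828, abs=0.005)

    def test_same_seed_same_choices_different_confidence_across_specs(
        self, exp1_trials, group_params
    ):
        omni = nb.simulate_observer(exp1_trials, group_params, nb.OMNISCIENT, seed=3)
        blind = nb.simulate_observer(exp1_trials, group_params, nb.NOISE_BLIND, seed=3)
        neutral = omni.cue_p_cw == 0.5
        assert np.array_equal(omni.loc[neutral, "choice"], blind.loc[neutral, "choice"])
        highv = neutral & (omni.variability == 10.0)
        assert not np.allclose(
            omni.loc[highv, "confidence"], blind.loc[highv, "confidence"]
        )

    def test_omniscient_confidence_is_calibrated(self, group_params):
        rng = np.random.default_rng(4)
        frame = neutral_frame(100_000, 0.6, 10.0, rng)
        rec = nb.simulate_observer(
            frame, group_params, nb.OMNISCIENT, seed=5, round_confidence=False
        )
        bins = pd.qcut(rec["confidence"], 10, duplicates="drop")
        grouped = rec.groupby(bins, observed=True)
        gap = (grouped["confidence"].mean() - grouped["correct"].mean()).abs()
        assert gap.max() < 0.02

    def test_opt_in_only_on_optional_trials(self, group_params):
        trials = nb.sample_trial_sequence(nb.EXP3_CONFIG, seed=6)
        rec = nb.simulate_observer(trials, group_params, nb.OMNISCIENT, seed=7)
        assert rec.loc[~rec.is_optional.astype(bool), "opted_in"].isna().all()
        optional = rec[rec.is_optional.astype(bool)]
        assert set(optional["opted_in"].unique()) <= {0.0, 1.0}
        out = optional[optional.opted_in == 0]
        assert out["choice"].eq(0).all() and out["correct"].isna().all()


class TestEnsembleObserver:
    def test_zero_item_noise_reproduces_the_mean_exactly(self, exp1_trials):
        rec = nb.simulate_ensemble_observer(exp1_trials[:200], 0.0, seed=0)
        mu = np.array([t.mu_deg for t in exp1_trials[:200]])
        assert np.allclose(rec["evidence_x"], mu, atol=1e-12)

    def test_evidence_spread_is_item_noise_over_sqrt_n(self, exp1_trials):
        rec = nb.simulate_ensemble_observer(exp1_trials, 9.36, seed=1)
        mu = np.array([t.mu_deg for t in exp1_trials])
        resid = rec["evidence_x"].to_numpy() - mu
        assert resid.std() == pytest.approx(9.36 / np.sqrt(8), rel=0.08)

    def test_evidence_spread_is_independent_of_variability(self, exp1_trials):
        rec = nb.simulate_ensemble_observer(exp1_trials, 9.36, seed=2)
        mu = np.array([t.mu_deg for t in exp1_trials])
        v = np.array([t.variability for t in exp1_trials])
        resid = rec["evidence_x"].to_numpy() - mu
        sd_by_v = [resid[v == lvl].std() for lvl in (0.0, 4.0, 10.0)]
        assert max(sd_by_v) - min(sd_by_v) < 0.35
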