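"""Tissue-scale mutation accumulation: Poisson counts, trajectories, slopes."""

import numpy as np
import pytest
from scipy import stats

from cryptdrift import (
    FixationSummary,
    InvalidConfigurationError,
    RateDensity,
    TissueScenario,
    TumorigenicRateError,
    density_sequence,
    human_scenarios,
    linear_slope,
    mutation_count_distribution,
    poisson_mutation_cap,
    posterior_fixed_density,
    tissue_trajectory,
)
from cryptdrift.presets import MOUSE_SI


@pytest.fixture(scope="module")
def mouse_division_scenario():
    return TissueScenario.from_preset(MOUSE_SI, "division")


@pytest.fixture(scope="module")
def mouse_division_pipeline(mouse_division_scenario):
    scn = mouse_division_scenario
    _, summary = posterior_fixed_density(
        scn.baseline_rate, scn.crypt.niche_size, scn.dfe, scn.target,
        division_rate=scn.crypt.division_rate,
    )
    m_cap = poisson_mutation_cap(summary.mu_hat, scn.lifetime_days)
    densities, summary, _ = density_sequence(
        scn.baseline_rate, scn.crypt.niche_size, scn.dfe, scn.target,
        m_max=max(1, m_cap), division_rate=scn.crypt.division_rate,
    )
    return densities, summary


class TestMutationCounts:
    def test_no_time_no_mutations(self):
        n = mutation_count_distribution(1e-5, 0.0, 1e6)
        assert n[0] == pytest.approx(1e6)
        assert np.all(n[1:] == 0)

    def test_unit_mean_poisson(self):
        n = mutation_count_distribution(1e-3, 1000.0, 1e6)
        assert n[1] == pytest.approx(1e6 * np.exp(-1.0), rel=1e-12)
        assert n.sum() == pytest.approx(1e6, rel=1e-8)

    def test_cap_controls_tail(self):
        cap = poisson_mutation_cap(1e-3, 1000.0)
        assert stats.poisson.sf(cap, 1.0) < 1e-10
        with pytest.raises(InvalidConfigurationError):
            mutation_count_distribution(1e-3, 1000.0, 1e6, m_cap=1)

    def test_counts_match_sampled_crypts(self):
        # Sampling oracle: per-crypt Poisson draws at the same mean.
        rng = np.random.default_rng(7)
        mean = 1.3
        c = 100_000
        draws = rng.poisson(mean, c)
        n = mutation_count_distribution(mean, 1.0, c)
        for m in range(4):
            observed = np.sum(draws == m)
            se = np.sqrt(c * (n[m] / c) * (1 - n[m] / c))
            assert abs(observed - n[m]) < 3 * se


class TestTrajectory:
    def test_effectless_mutations_leave_tissue_unchanged(self, mouse_division_scenario):
        # Point-mass densities at the baseline rate: every Z_m equals Z_normal.
        scn = mouse_division_scenario
        densities = [
            RateDensity.initial(scn.baseline_rate, scn.target) for _ in range(10)
        ]
        for m, f in enumerate(densities, start=1):
            f.m = m
        summary = FixationSummary(p_hat=0.1, expected_ratio=1.0, mu_hat=1e-5)
        curve = tissue_trajectory(
            scn, densities, np.linspace(0.0, scn.lifetime_days, 10), summary=summary
        )
        assert np.allclose(curve.fraction, 1.0, atol=1e-12)

    def test_decline_matches_linear_slope_early(self, mouse_division_scenario,
                                                mouse_division_pipeline):
        scn = mouse_division_scenario
        densities, summary = mouse_division_pipeline
        t_grid = np.linspace(0.0, scn.lifetime_days / 10.0, 30)
        curve = tissue_trajectory(scn, densities, t_grid, summary=summary)
        # Numerical derivative at the origin vs the analytic slope.
        num = (curve.fraction[1] - curve.fraction[0]) / (t_grid[1] - t_grid[0])
        assert num == pytest.approx(curve.slope_linear, rel=0.01)
        # Linearity: at a tenth of the lifetime the curve deviates from the
        # slope line by <5% of its own decline.
        decline = 1.0 - curve.fraction[-1]
        linear = 1.0 + curve.slope_linear * t_grid[-1]
        assert abs(curve.fraction[-1] - linear) < 0.05 * decline

    def test_deleterious_expectation_monotone_decline(self, mouse_division_scenario,
                                                      mouse_division_pipeline):
        scn = mouse_division_scenario
        densities, summary = mouse_division_pipeline
        curve = tissue_trajectory(
            scn, densities, np.linspace(0.0, scn.lifetime_days, 20), summary=summary
        )
        assert curve.fraction[0] == pytest.approx(1.0)
        assert np.all(np.diff(curve.fraction) < 0)

    def test_fraction_independent_of_crypt_count(self, mouse_division_scenario,
                                                 mouse_division_pipeline):
        densities, summary = mouse_division_pipeline
        t_grid = np.linspace(0.0, 1000.0, 5)
        scn_a = mouse_division_scenario
        scn_b = TissueScenario(
            crypt=scn_a.crypt, dfe=scn_a.dfe, target=scn_a.target,
            lifetime_days=scn_a.lifetime_days, n_crypts=scn_a.n_crypts * 57.0,
        )
        fa = tissue_trajectory(scn_a, densities, t_grid, summary=summary).fraction
        fb = tissue_trajectory(scn_b, densities, t_grid, summary=summary).fraction
        assert np.array_equal(fa, fb)

    def test_expectation_mode_close_to_plug_in(self, mouse_division_scenario,
                                               mouse_division_pipeline):
        # The Jensen gap between E[Z*(rate)] and Z*(E[rate]) is small for the
        # yeast DFE at mouse rates.
        scn = mouse_division_scenario
        densities, summary = mouse_division_pipeline
        t_grid = np.array([0.0, scn.lifetime_days])
        plug = tissue_trajectory(scn, densities, t_grid, summary=summary)
        exp = tissue_trajectory(
            scn, densities, t_grid, summary=summary, z_expectation_mode=True
        )
        d_plug = 1.0 - plug.fraction[-1]
        d_exp = 1.0 - exp.fraction[-1]
        assert d_exp == pytest.approx(d_plug, rel=0.5)
        # Z* is convex in the division rate, so averaging Z* over the rate
        # density (Jensen) yields more tissue — hence less decline — than
        # plugging in the expected rate.
        assert d_exp < d_plug

    def test_tumorigenic_expected_rate_rejected(self):
        # An expected division rate at/above nu makes the crypt steady state
        # diverge; the trajectory must refuse and point to the tumour pipeline.
        scn = TissueScenario(
            crypt=MOUSE_SI.crypt, dfe=MOUSE_SI.dfe, target="division",
            lifetime_days=1095.0, n_crypts=1e6,
        )
        runaway = RateDensity.initial(0.5, "division")  # above nu = 1/3
        runaway.m = 1
        # p_hat chosen tiny so the Poisson cap stays at the single supplied m.
        summary = FixationSummary(p_hat=1e-9, expected_ratio=2.5, mu_hat=None)
        with pytest.raises(TumorigenicRateError):
            tissue_trajectory(scn, [runaway], [0.0, 1095.0], summary=summary)


class TestLinearSlope:
    def test_neutral_expectation_gives_zero_slope(self, mouse_division_scenario):
        summary = FixationSummary(p_hat=0.1, expected_ratio=1.0)
        assert linear_slope(mouse_division_scenario, summary) == 0.0

    def test_differentiation_slope_is_niche_size_free(self):
        # Neutral fixation: 1/X1 cancels the X1-fold mutant supply, bit for bit.
        slopes = []
        for x1 in (2, 6, 20):
            crypt = MOUSE_SI.crypt.with_niche_size(x1)
            scn = TissueScenario(
                crypt=crypt, dfe=MOUSE_SI.dfe, target="differentiation",
                lifetime_days=1095.0, n_crypts=1e6,
            )
            _, summary = posterior_fixed_density(
                crypt.differentiation_rate, x1, MOUSE_SI.dfe, "differentiation",
                division_rate=crypt.division_rate,
            )
            slopes.append(linear_slope(scn, summary))
        assert slopes[0] == slopes[1] == slopes[2]

    def test_deleterious_slopes_are_negative(self, mouse_division_scenario,
                                             mouse_division_pipeline):
        _, summary = mouse_division_pipeline
        assert linear_slope(mouse_division_scenario, summary) < 0.0

    def test_tumorigenic_mean_rejected(self, mouse_division_scenario):
        theta = (mouse_division_scenario.crypt.differentiation_rate
                 / mouse_division_scenario.crypt.division_rate)
        summary = FixationSummary(p_hat=0.5, expected_ratio=theta + 0.1)
        with pytest.raises(TumorigenicRateError):
            linear_slope(mouse_division_scenario, summary)


@pytest.fixture(scope="module")
def curves():
    return human_scenarios(n_grid=2**12)


class TestHumanScenarios:
    def test_all_four_scenarios_decline(self, curves):
        assert set(curves) == {
            "human_colon_niche6_division",
            "human_colon_niche6_differentiation",
            "human_colon_niche20_division",
            "human_colon_niche20_differentiation",
        }
        for curve in curves.values():
            assert curve.slope_linear < 0
            assert curve.fraction[0] == 1.0

    def test_small_niche_declines_faster(self, curves):
        for target in ("division", "differentiation"):
            d6 = 1.0 - curves[f"human_colon_niche6_{target}"].fraction_at_end()
            d20 = 1.0 - curves[f"human_colon_niche20_{target}"].fraction_at_end()
            assert d6 > d20

    def test_neutral_fixation_outpaces_selection(self, curves):
        # Differentiation-rate mutations escape purifying selection entirely.
        for niche in ("niche6", "niche20"):
            d_div = 1.0 - curves[f"human_colon_{niche}_division"].fraction_at_end()
            d_diff = 1.0 - curves[f"human_colon_{niche}_differentiation"].fraction_at_end()
            assert d_diff > d_div
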