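"""Mutation DFE, fixation probability, posterior, and the fixation recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptdrift import (
    DFEParameters,
    FixationKernel,
    InvalidConfigurationError,
    RateDensity,
    density_sequence,
    dfe_density,
    expected_effect_boundary,
    fixation_probability,
    iterate_density,
    make_rate_grid,
    posterior_fixed_density,
)


def _truncated_exp_mean_below_one(shape: float) -> float:
    """E[e | e < 1] for e ~ Exp(mean 1/shape), the truncation correction."""
    return (1.0 - np.exp(-shape) * (1.0 + shape)) / (shape * -np.expm1(-shape))


class TestDensity:
    def test_branch_limits_at_baseline(self, yeast_dfe):
        # Raw (un-renormalized) density approaches beta*(1-P_B)/r0 from below
        # and alpha*P_B/r0 from above the baseline rate.
        r0 = 0.2
        lo = dfe_density(r0 * (1 - 1e-12), r0, yeast_dfe, "division", renormalize=False)
        hi = dfe_density(r0 * (1 + 1e-12), r0, yeast_dfe, "division", renormalize=False)
        pb = yeast_dfe.beneficial_fraction
        assert lo == pytest.approx(yeast_dfe.beta * (1 - pb) / r0, rel=1e-9)
        assert hi == pytest.approx(yeast_dfe.alpha * pb / r0, rel=1e-9)

    @staticmethod
    def _branch(dfe, target, side):
        """Grid and density of one branch, with the one-sided limit at r0."""
        grid = make_rate_grid(1.0, dfe, target)
        i1 = int(np.searchsorted(grid, 1.0))
        if side == "below":
            g = grid[: i1 + 1]
            d = dfe_density(g, 1.0, dfe, target)
            d[-1] = dfe_density(1.0 - 1e-13, 1.0, dfe, target)
        else:
            g = grid[i1:]
            d = dfe_density(g, 1.0, dfe, target)
            d[0] = dfe_density(1.0 + 1e-13, 1.0, dfe, target)
        return g, d

    def test_beneficial_mass_is_pb_after_renormalization(self, yeast_dfe):
        g_above, d_above = self._branch(yeast_dfe, "division", "above")
        mass_above = np.trapezoid(d_above, g_above)
        assert mass_above == pytest.approx(yeast_dfe.beneficial_fraction, abs=1e-6)
        g_below, d_below = self._branch(yeast_dfe, "division", "below")
        total = mass_above + np.trapezoid(d_below, g_below)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_deleterious_mean_matches_truncated_closed_form(self, yeast_dfe):
        g, d = self._branch(yeast_dfe, "division", "below")
        mass = np.trapezoid(d, g)
        mean = np.trapezoid(g * d, g) / mass
        # Mean deleterious multiplier is 1 - E[e | e < 1], the closed-form
        # truncated-exponential mean; without truncation it would be 1 - s_minus.
        assert mean == pytest.approx(
            1.0 - _truncated_exp_mean_below_one(yeast_dfe.beta), rel=1e-6
        )
        assert mean > 1.0 - yeast_dfe.mean_deleterious_effect

    def test_differentiation_branches_mirrored(self, yeast_dfe):
        # Beneficial mutations decrease the differentiation rate.
        g, d = self._branch(yeast_dfe, "differentiation", "below")
        mass_below = np.trapezoid(d, g)
        assert mass_below == pytest.approx(yeast_dfe.beneficial_fraction, abs=1e-6)

    def test_negative_rate_rejected(self, yeast_dfe):
        with pytest.raises(InvalidConfigurationError):
            dfe_density(-0.1, 1.0, yeast_dfe)


class TestFixationProbability:
    @pytest.mark.parametrize(
        ("r", "x1", "expected"),
        [
            (1.0, 6, 1.0 / 6.0),
            (2.0, 2, 2.0 / 3.0),
            (0.5, 1, 1.0),
            (3.0, 1, 1.0),
        ],
    )
    def test_exact_values(self, r, x1, expected):
        assert fixation_probability(r, x1) == pytest.approx(expected, rel=1e-12)

    def test_continuous_through_neutral_point(self):
        for eps in (1e-6, 1e-9, 1e-12):
            for x1 in (2, 6, 20):
                assert fixation_probability(1 + eps, x1) == pytest.approx(
                    1.0 / x1, rel=1e-4
                )
                assert fixation_probability(1 - eps, x1) == pytest.approx(
                    1.0 / x1, rel=1e-4
                )

    @given(x1=st.integers(2, 40))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_relative_rate(self, x1):
        r = np.linspace(0.2, 3.0, 200)
        p = fixation_probability(r, x1)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p <= 1))

    def test_deeply_deleterious_limit(self):
        assert fixation_probability(1e-9, 30) == pytest.approx(0.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(InvalidConfigurationError):
            fixation_probability(0.0, 6)


class TestPosterior:
    def test_single_cell_niche_posterior_equals_prior(self, yeast_dfe):
        # Constant pfix cancels in the posterior; agreement is limited only
        # by the quadrature normalization.
        dens, summary = posterior_fixed_density(1.0, 1, yeast_dfe, "division")
        prior = dfe_density(dens.grid, 1.0, yeast_dfe, "division")
        assert summary.p_hat == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(dens.density, prior, rtol=1e-6, atol=1e-12)

    def test_neutral_target_independent_of_niche_size(self, yeast_dfe):
        results = {
            x1: posterior_fixed_density(1.0 / 3.0, x1, yeast_dfe, "differentiation")
            for x1 in (2, 6, 20)
        }
        ratios = [s.expected_ratio for _, s in results.values()]
        assert ratios[0] == ratios[1] == ratios[2]
        for x1, (_, s) in results.items():
            assert s.p_hat == pytest.approx(1.0 / x1, abs=1e-6)

    def test_division_fixations_expected_deleterious(self, yeast_dfe):
        # Reported niche sizes: drift outweighs selection, fixed mutations
        # lower the expected division rate.
        for x1 in (6, 10, 20):
            _, s = posterior_fixed_density(1.0, x1, yeast_dfe, "division")
            assert s.expected_ratio < 1.0

    def test_differentiation_ratio_matches_closed_form(self, yeast_dfe):
        _, s = posterior_fixed_density(1.0, 6, yeast_dfe, "differentiation")
        pb = yeast_dfe.beneficial_fraction
        ben_mean = 1.0 - _truncated_exp_mean_below_one(yeast_dfe.alpha)
        del_mean = 1.0 + yeast_dfe.mean_deleterious_effect
        closed = (1.0 - pb) * del_mean + pb * ben_mean
        assert s.expected_ratio == pytest.approx(closed, rel=1e-5)
        assert s.expected_ratio == pytest.approx(1.20, abs=0.01)

    def test_mu_hat_identity(self, yeast_dfe):
        _, s = posterior_fixed_density(
            0.2, 6, yeast_dfe, "division", division_rate=0.2
        )
        assert s.mu_hat == pytest.approx(
            s.p_hat * yeast_dfe.mutation_rate * 0.2 * 6, rel=1e-12
        )

    def test_drift_limit(self):
        # As both effect scales shrink, selection fades and p_hat approaches
        # the neutral 1/X1; the leading deviation is linear in the scale
        # because the DFE is asymmetric (mostly deleterious).
        devs = []
        for s_eff in (0.04, 0.02, 0.01):
            weak = DFEParameters(1e-4, s_eff, s_eff, 0.0575)
            _, s = posterior_fixed_density(1.0, 6, weak, "division")
            devs.append(abs(s.p_hat - 1.0 / 6.0))
            assert s.expected_ratio == pytest.approx(1.0, abs=2 * s_eff)
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] / devs[1] == pytest.approx(0.5, abs=0.1)
        assert devs[2] < 0.03 * (1.0 / 6.0)

    def test_strong_selection_limit(self, yeast_dfe):
        # Mostly large-effect beneficial mutations: p_hat approaches 1.
        strong = DFEParameters(1e-4, 0.217, 5.0, 0.99)
        _, s_strong = posterior_fixed_density(1.0, 6, strong, "division")
        _, s_yeast = posterior_fixed_density(1.0, 6, yeast_dfe, "division")
        assert s_strong.p_hat > 0.5
        assert s_strong.p_hat > s_yeast.p_hat


class TestRecursion:
    def test_iterating_point_mass_reproduces_posterior(self, yeast_dfe):
        start = RateDensity.initial(1.0, "division")
        f1 = iterate_density(start, 6, yeast_dfe)
        ref, _ = posterior_fixed_density(1.0, 6, yeast_dfe, "division", grid=f1.grid)
        assert f1.m == 1
        assert np.allclose(f1.density, ref.density, rtol=1e-9)

    def test_mass_conserved_over_ten_iterations(self, yeast_dfe):
        densities, _, kernel = density_sequence(
            1.0, 6, yeast_dfe, "division", m_max=10
        )
        for f in densities:
            assert f.mass() == pytest.approx(1.0, abs=1e-9)
        # Raw (pre-renormalization) propagation mass stays within 1e-6.
        raw = kernel.matrix @ (kernel.weights * densities[-1].density)
        assert np.trapezoid(raw, kernel.grid) == pytest.approx(1.0, abs=1e-6)

    def test_expected_division_rate_ratchets_down(self, yeast_dfe):
        densities, _, _ = density_sequence(1.0, 6, yeast_dfe, "division", m_max=10)
        means = [f.mean() for f in densities]
        assert np.all(np.diff(means) < 0)

    def test_expected_differentiation_rate_ratchets_up(self, yeast_dfe):
        densities, _, _ = density_sequence(
            1.0 / 3.0, 6, yeast_dfe, "differentiation", m_max=6
        )
        means = [f.mean() for f in densities]
        assert np.all(np.diff(means) > 0)

    def test_mismatched_grid_rejected(self, yeast_dfe):
        densities, _, kernel = density_sequence(1.0, 6, yeast_dfe, "division", m_max=1)
        other = RateDensity(
            target="division", r0=1.0,
            grid=np.linspace(0.0, 2.0, 100),
            density=np.full(100, 0.5), m=1,
        )
        from cryptdrift import GridCoverageError

        with pytest.raises(GridCoverageError):
            kernel.propagate(other)


class TestExpectedEffectBoundary:
    def test_ratio_is_one_at_boundary(self, yeast_dfe):
        from cryptdrift.dfe import _expected_ratio

        s_plus = yeast_dfe.mean_beneficial_effect
        pb = yeast_dfe.beneficial_fraction
        (boundary,) = expected_effect_boundary(6, s_plus, [pb])
        assert np.isfinite(boundary)
        assert _expected_ratio(6, boundary, s_plus, pb, 2**11) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_boundary_rises_with_niche_size(self, yeast_dfe):
        # Stronger selection in larger niches tolerates worse deleterious DFEs.
        s_plus = yeast_dfe.mean_beneficial_effect
        pb = yeast_dfe.beneficial_fraction
        (b4,) = expected_effect_boundary(4, s_plus, [pb])
        (b8,) = expected_effect_boundary(8, s_plus, [pb])
        assert b4 < b8

    def test_large_niche_ratio_nonmonotone_in_deleterious_scale(self, yeast_dfe):
        # At X1 = 20, very damaging mutations stop fixing: the expected ratio
        # dips and then rises again as s_minus grows.
        from cryptdrift.dfe import _expected_ratio

        s_vals = np.linspace(0.05, 1.5, 12)
        ratios = [
            _expected_ratio(20, s, yeast_dfe.mean_beneficial_effect,
                            yeast_dfe.beneficial_fraction, 2**11)
            for s in s_vals
        ]
        k = int(np.argmin(ratios))
        assert 0 < k < len(ratios) - 1
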