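"""Gaussian deconvolution of E-histograms and state-fraction assignment."""

import numpy as np
import pytest

import hpfret as hp
from hpfret.mixture import GaussianComponent, MixtureFit


def _hist_from_samples(samples, n_bins=50):
    samples = np.clip(samples, 0.0, 1.0)
    density, edges = np.histogram(samples, bins=n_bins, range=(0, 1), density=True)
    return hp.EHistogram(
        edges=edges, density=density, n_samples=len(samples), samples=samples
    )


@pytest.fixture(scope="module")
def balanced_samples():
    rng = np.random.default_rng(99)
    return np.concatenate(
        [rng.normal(0.3, 0.08, 5000), rng.normal(0.8, 0.08, 5000)]
    )


class TestFitMixture:
    def test_single_gaussian_self_consistency(self):
        rng = np.random.default_rng(0)
        hist = _hist_from_samples(rng.normal(0.5, 0.08, 20_000))
        fit = hp.fit_mixture(hist, 1, seed=0)
        (c,) = fit.components
        assert c.mean == pytest.approx(0.50, abs=0.01)
        assert c.sd == pytest.approx(0.08, abs=0.01)
        assert c.weight == 1.0

    def test_equal_weight_mixture_recovers_half_half(self, balanced_samples):
        fit = hp.fit_mixture(_hist_from_samples(balanced_samples), 2, seed=0)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.02)
        np.testing.assert_allclose(fit.means, [0.3, 0.8], atol=0.01)

    @pytest.mark.parametrize("n_bins", [40, 50, 60, 80])
    def test_invariant_to_bin_count(self, balanced_samples, n_bins):
        fit = hp.fit_mixture(_hist_from_samples(balanced_samples, n_bins), 2, seed=0)
        np.testing.assert_allclose(fit.means, [0.3, 0.8], atol=0.02)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.02)

    def test_least_squares_and_em_agree_on_fractions(self, balanced_samples):
        # Two independent routes to the same state fractions (within 0.03).
        hist = _hist_from_samples(balanced_samples)
        ls = hp.fit_mixture(hist, 2, seed=0)
        em = hp.fit_mixture_em(hist.samples, 2, seed=0)
        f_ls = hp.assign_and_fractions(ls)
        f_em = hp.assign_and_fractions(em)
        assert abs(f_ls.f_closed - f_em.f_closed) < 0.03

    def test_collapsed_components_refit_at_lower_k(self):
        # Exact single-Gaussian density: a 2-component fit collapses onto
        # one mean and is refitted with k=1.
        edges = np.linspace(0, 1, 51)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = np.exp(-0.5 * ((centers - 0.5) / 0.06) ** 2)
        density /= np.sum(density * np.diff(edges))
        hist = hp.EHistogram(
            edges=edges, density=density, n_samples=10_000,
            samples=np.full(10_000, 0.5),
        )
        fit = hp.fit_mixture(hist, 2, seed=0)
        assert len(fit.components) == 1
        assert fit.components[0].mean == pytest.approx(0.5, abs=0.01)

    def test_too_few_nonzero_bins_rejected(self):
        density = np.zeros(50)
        density[10] = 50.0
        hist = hp.EHistogram(
            edges=np.linspace(0, 1, 51), density=density, n_samples=10,
            samples=np.full(10, 0.21),
        )
        with pytest.raises(ValueError, match="nonzero bins"):
            hp.fit_mixture(hist, 2)


class TestAssignAndFractions:
    def test_boundary_splits_components(self):
        fit = MixtureFit(
            components=(
                GaussianComponent(0.5, 0.3, 0.08),
                GaussianComponent(0.5, 0.8, 0.08),
            ),
            rss=0.0,
        )
        fr = hp.assign_and_fractions(fit, boundary=0.5)
        assert fr.f_open == fr.f_closed == 0.5

    def test_four_component_override_mapping(self):
        # Bimodal folded (0.60/0.85) and unfolded (0.13/0.31) distributions:
        # explicit overrides assign both low components to open.
        fit = MixtureFit(
            components=(
                GaussianComponent(0.10, 0.13, 0.05),
                GaussianComponent(0.20, 0.31, 0.05),
                GaussianComponent(0.30, 0.60, 0.05),
                GaussianComponent(0.40, 0.85, 0.05),
            ),
            rss=0.0,
        )
        fr = hp.assign_and_fractions(
            fit, overrides={0: "open", 1: "open", 2: "closed", 3: "closed"}
        )
        assert fr.f_open == pytest.approx(0.30)
        assert fr.f_closed == pytest.approx(0.70)

    def test_single_low_component_is_fully_open(self):
        fit = MixtureFit(components=(GaussianComponent(1.0, 0.2, 0.05),), rss=0.0)
        with pytest.warns(UserWarning, match="one state"):
            fr = hp.assign_and_fractions(fit)
        assert fr.f_open == 1.0 and fr.f_closed == 0.0

    def test_component_order_never_changes_fractions(self):
        comps = [
            GaussianComponent(0.2, 0.25, 0.05),
            GaussianComponent(0.3, 0.35, 0.05),
            GaussianComponent(0.5, 0.8, 0.05),
        ]
        # MixtureFit sorts by mean internally via fit construction; emulate
        # permutations by assigning from differently ordered tuples.
        base = hp.assign_and_fractions(MixtureFit(tuple(comps), 0.0))
        for perm in ([1, 0, 2], [2, 1, 0], [0, 2, 1]):
            permuted = MixtureFit(tuple(sorted(
                (comps[i] for i in perm), key=lambda c: c.mean
            )), 0.0)
            fr = hp.assign_and_fractions(permuted)
            assert fr.f_open == pytest.approx(base.f_open)
            assert fr.f_closed == pytest.approx(base.f_closed)
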