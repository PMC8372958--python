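"""EM engine: unconstrained and frozen-component mixture fits, BIC,
posteriors.  Oracles: closed forms for k=1, direct density formulas via
scipy, the generative parameters of simulated mixtures, and sklearn's
GaussianMixture as an independent EM implementation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

import cytogate as cg
from cytogate.errors import InvalidInputError
from cytogate.gmm import GaussianComponent


def sample_mixture(rng, means, covs, weights, n):
    comp = rng.choice(len(weights), size=n, p=weights)
    X = np.empty((n, 2))
    for j in range(len(weights)):
        rows = comp == j
        X[rows] = rng.multivariate_normal(means[j], covs[j], size=rows.sum())
    return X, comp


THREE_WELL_SEPARATED = (
    np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]]),  # >= 5 sigma apart
    np.array([0.01 * np.eye(2)] * 3),
    np.array([0.3, 0.4, 0.3]),
)


def nearest_match(fitted_means, true_means):
    """Greedy nearest-neighbour matching distance per true mean."""
    d = np.linalg.norm(fitted_means[None] - true_means[:, None], axis=2)
    return d.min(axis=1)


class TestFitGMM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 2)) @ np.array([[1.0, 0.3], [0.0, 0.5]])
        cfg = cg.FitConfig(seed=1)
        m = cg.fit_gmm(X, 1, cfg)
        assert np.allclose(m.components[0].mean, X.mean(axis=0))
        expected_cov = np.cov(X.T, bias=True) + cfg.covariance_floor * np.eye(2)
        assert np.allclose(m.components[0].covariance, expected_cov, atol=1e-8)
        assert m.components[0].weight == 1.0
        assert m.n_iterations <= 2

    def test_three_component_recovery(self):
        rng = np.random.default_rng(1)
        means, covs, weights = THREE_WELL_SEPARATED
        X, _ = sample_mixture(rng, means, covs, weights, 6000)
        m = cg.fit_gmm(X, 3, cg.FitConfig(seed=2))
        assert np.all(nearest_match(m.means, means) < 0.05)
        assert m.converged

    def test_duplicated_dataset_invariance(self):
        """EM updates depend on responsibilities, which are unchanged when
        every event appears twice — identical start gives identical fit."""
        rng = np.random.default_rng(2)
        means, covs, weights = THREE_WELL_SEPARATED
        X, _ = sample_mixture(rng, means, covs, weights, 1500)
        start = cg.MixtureModel(
            components=[
                GaussianComponent(mu + 0.1, 0.05 * np.eye(2), 1 / 3)
                for mu in means
            ]
        )
        cfg = cg.FitConfig(n_random_inits=0, n_memory_inits=1, seed=3)
        a = cg.fit_gmm(X, 3, cfg, inits=[start])
        b = cg.fit_gmm(np.vstack([X, X]), 3, cfg, inits=[start])
        # equality up to summation round-off over the doubled dataset
        assert np.allclose(a.means, b.means, atol=1e-9)
        assert np.allclose(a.covariances, b.covariances, atol=1e-9)
        assert np.allclose(a.weights, b.weights, atol=1e-9)

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(InvalidInputError):
            cg.fit_gmm(np.zeros((3, 2)), 5)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, 2))
        a = cg.fit_gmm(X, 2, cg.FitConfig(seed=9))
        b = cg.fit_gmm(X, 2, cg.FitConfig(seed=9))
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)
        assert a.log_likelihood == b.log_likelihood

    def test_agrees_with_sklearn(self):
        """Independent EM implementation reaches the same optimum on
        well-separated data."""
        rng = np.random.default_rng(5)
        means, covs, weights = THREE_WELL_SEPARATED
        X, _ = sample_mixture(rng, means, covs, weights, 4000)
        ours = cg.fit_gmm(X, 3, cg.FitConfig(seed=6))
        ref = GaussianMixture(
            n_components=3, n_init=5, reg_covar=1e-6, random_state=0
        ).fit(X)
        assert abs(ours.log_likelihood / len(X) - ref.score(X)) < 1e-4
        assert np.all(nearest_match(ours.means, ref.means_) < 0.02)


class TestConstrained:
    def frozen_two(self):
        return [
            GaussianComponent(np.array([0.0, 0.0]), 0.02 * np.eye(2), 0.4, True),
            GaussianComponent(np.array([1.0, 0.0]), 0.02 * np.eye(2), 0.6, True),
        ]

    def test_zero_frozen_equals_fit_gmm_bitwise(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(1000, 2))
        a = cg.fit_gmm(X, 3, cg.FitConfig(seed=7))
        b = cg.fit_constrained_gmm(X, [], 3, cg.FitConfig(seed=7))
        for ca, cb in zip(a.components, b.components):
            assert np.array_equal(ca.mean, cb.mean)
            assert np.array_equal(ca.covariance, cb.covariance)
            assert ca.weight == cb.weight
        assert a.log_likelihood == b.log_likelihood

    def test_frozen_parameters_bitwise_immutable(self):
        rng = np.random.default_rng(7)
        frozen = self.frozen_two()
        X = np.vstack([
            rng.multivariate_normal([0, 0], 0.02 * np.eye(2), 400),
            rng.multivariate_normal([1, 0], 0.02 * np.eye(2), 600),
            rng.multivariate_normal([4, 4], 0.02 * np.eye(2), 1000),
        ])
        m = cg.fit_constrained_gmm(X, frozen, 1, cg.FitConfig(seed=8))
        for orig, fitted in zip(frozen, m.components[:2]):
            assert fitted.frozen
            assert np.array_equal(orig.mean, fitted.mean)
            assert np.array_equal(orig.covariance, fitted.covariance)

    def test_pure_background_shrinks_free_weight(self):
        rng = np.random.default_rng(8)
        frozen = self.frozen_two()
        X = np.vstack([
            rng.multivariate_normal([0, 0], 0.02 * np.eye(2), 800),
            rng.multivariate_normal([1, 0], 0.02 * np.eye(2), 1200),
        ])
        m = cg.fit_constrained_gmm(X, frozen, 1, cg.FitConfig(seed=9))
        pi_bg = sum(c.weight for c in m.components if c.frozen)
        assert pi_bg >= 0.95

    def test_fifty_fifty_weight_split(self):
        rng = np.random.default_rng(9)
        frozen = self.frozen_two()
        n = 4000
        X = np.vstack([
            rng.multivariate_normal([0, 0], 0.02 * np.eye(2), int(n * 0.2)),
            rng.multivariate_normal([1, 0], 0.02 * np.eye(2), int(n * 0.3)),
            rng.multivariate_normal([5, 5], 0.02 * np.eye(2), int(n * 0.5)),
        ])
        m = cg.fit_constrained_gmm(X, frozen, 1, cg.FitConfig(seed=10))
        pi_bg = sum(c.weight for c in m.components if c.frozen)
        se = np.sqrt(0.25 / n)
        assert abs(pi_bg - 0.5) < 3 * se
        free = [c for c in m.components if not c.frozen][0]
        assert np.linalg.norm(free.mean - [5, 5]) < 0.05

    def test_frozen_relative_weights_maintained(self):
        rng = np.random.default_rng(10)
        frozen = self.frozen_two()
        X = np.vstack([
            rng.multivariate_normal([0, 0], 0.02 * np.eye(2), 500),
            rng.multivariate_normal([1, 0], 0.02 * np.eye(2), 750),
            rng.multivariate_normal([5, 5], 0.02 * np.eye(2), 1250),
        ])
        m = cg.fit_constrained_gmm(X, frozen, 1, cg.FitConfig(seed=11))
        w = [c.weight for c in m.components if c.frozen]
        assert np.isclose(w[0] / w[1], 0.4 / 0.6, rtol=1e-9)

    def test_bad_relative_weights_rejected(self):
        frozen = self.frozen_two()
        frozen[0].weight = 0.9  # no longer sums to 1
        with pytest.raises(InvalidInputError, match="sum to 1"):
            cg.fit_constrained_gmm(np.zeros((100, 2)) + 0.1, frozen, 1)


class TestBIC:
    def test_formula_against_direct_evaluation(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(1000, 2))
        m = cg.fit_gmm(X, 1, cg.FitConfig(seed=12))
        comp = m.components[0]
        # independent route: scipy density, explicit parameter count
        ll = multivariate_normal(comp.mean, comp.covariance).logpdf(X).sum()
        p = 2 + 3  # mean + free covariance entries; no free weight for k=1
        expected = p * np.log(1000) - 2 * ll
        assert abs(cg.bic(m, X) - expected) < 1e-9

    def test_single_event_bic_is_minus_twice_loglik(self):
        m = cg.MixtureModel(
            components=[GaussianComponent(np.zeros(2), np.eye(2), 1.0)]
        )
        X = np.array([[0.3, -0.2]])
        ll = multivariate_normal(np.zeros(2), np.eye(2)).logpdf(X).sum()
        assert np.isclose(cg.bic(m, X), -2 * ll)

    def test_overfit_penalised_on_separated_data(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            means, covs, weights = THREE_WELL_SEPARATED
            X, _ = sample_mixture(rng, means, covs, weights, 2000)
            cfg = cg.FitConfig(seed=seed, n_random_inits=2)
            b3 = cg.bic(cg.fit_gmm(X, 3, cfg), X)
            b6 = cg.bic(cg.fit_gmm(X, 6, cfg), X)
            wins += b3 < b6
        assert wins >= 6

    def test_constrained_parameter_count(self):
        frozen = [
            GaussianComponent(np.zeros(2), np.eye(2), 1.0, frozen=True),
        ]
        free = [
            GaussianComponent(np.ones(2), np.eye(2), 0.0, frozen=False)
            for _ in range(2)
        ]
        m = cg.MixtureModel(components=frozen + free)
        # 2 free comps x 5 params + 1 free-weight dof + pi_bg scalar
        assert m.n_free_parameters() == 2 * 5 + 1 + 1


class TestSelectK:
    def test_singleton_range(self):
        assert cg.select_k_by_bic(np.zeros((10, 2)), (2, 2)) == 2

    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(13)
        X = rng.multivariate_normal([1, 1], 0.05 * np.eye(2), 3000)
        cfg = cg.FitConfig(seed=14, n_random_inits=2)
        assert cg.select_k_by_bic(X, (1, 4), cfg) == 1

    def test_recovers_three_components(self):
        rng = np.random.default_rng(14)
        means, covs, weights = THREE_WELL_SEPARATED
        X, _ = sample_mixture(rng, means, covs, weights, 4000)
        cfg = cg.FitConfig(seed=15, n_random_inits=2)
        assert cg.select_k_by_bic(X, (1, 6), cfg) == 3


class TestPosteriors:
    def test_k1_all_ones(self):
        m = cg.MixtureModel(
            components=[GaussianComponent(np.zeros(2), np.eye(2), 1.0)]
        )
        r = cg.responsibilities(m, np.random.default_rng(15).normal(size=(50, 2)))
        assert np.array_equal(r, np.ones((50, 1)))

    def test_midpoint_symmetry(self):
        m = cg.MixtureModel(components=[
            GaussianComponent(np.array([-1.0, 0.0]), np.eye(2), 0.5),
            GaussianComponent(np.array([1.0, 0.0]), np.eye(2), 0.5),
        ])
        r = cg.responsibilities(m, np.array([[0.0, 0.0]]))
        assert np.allclose(r, [[0.5, 0.5]])

    def test_against_direct_density_formula(self):
        rng = np.random.default_rng(16)
        comps = [
            GaussianComponent(rng.normal(size=2), np.eye(2) * rng.uniform(0.5, 2),
                              w)
            for w in (0.2, 0.5, 0.3)
        ]
        m = cg.MixtureModel(components=comps)
        X = rng.normal(size=(100, 2), scale=2)
        dens = np.column_stack([
            c.weight * multivariate_normal(c.mean, c.covariance).pdf(X)
            for c in comps
        ])
        expected = dens / dens.sum(axis=1, keepdims=True)
        got = cg.responsibilities(m, X)
        assert np.allclose(got, expected, atol=1e-9)
        assert np.allclose(got.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(cg.assign(m, X), np.argmax(expected, axis=1))


class TestMonotonicityAndSerialization:
    @pytest.mark.parametrize("seed,k", [(0, 1), (1, 2), (2, 3), (3, 4), (4, 6)])
    def test_loglik_history_nondecreasing(self, seed, k):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(1500, 2)) * rng.uniform(0.5, 2, size=2)
        m = cg.fit_gmm(X, k, cg.FitConfig(seed=seed, n_random_inits=1))
        h = np.array(m.log_likelihood_history)
        assert np.all(np.diff(h) >= -1e-7 * np.abs(h[:-1]))
        assert np.allclose(m.weights.sum(), 1.0, atol=1e-9)

    def test_model_round_trips_through_json(self, tmp_path):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(500, 2))
        m = cg.fit_gmm(X, 2, cg.FitConfig(seed=18))
        path = m.save(tmp_path / "model.json")
        back = cg.MixtureModel.load(path)
        assert np.array_equal(back.means, m.means)
        assert np.array_equal(back.covariances, m.covariances)
        assert back.converged == m.converged
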