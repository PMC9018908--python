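import numpy as np
import pytest

from dsbnorm.mixtures import (
    MixtureFit,
    bic,
    derive_seed,
    em_fit_1d,
    fit_cells,
    sweep_cells,
    sweep_k,
)


def _bimodal(rng, n1=50, n2=50, mu2=10.0, sd=0.1):
    return np.concatenate([rng.normal(0.0, sd, n1), rng.normal(mu2, sd, n2)])


class TestEmFit:
    def test_recovers_two_well_separated_components(self):
        rng = np.random.default_rng(0)
        x = _bimodal(rng)
        truth_lo, truth_hi = x[:50].mean(), x[50:].mean()  # oracle: group means
        fit = em_fit_1d(x, k=2, seed=0)
        assert fit.converged
        assert abs(fit.means[0] - truth_lo) < 0.05 and -0.1 < fit.means[0] < 0.1
        assert abs(fit.means[1] - truth_hi) < 0.05 and 9.9 < fit.means[1] < 10.1
        assert 0.45 < fit.weights[0] < 0.55

    def test_k1_reduces_to_closed_form_mle(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 1.5, 200)
        fit = em_fit_1d(x, k=1, seed=0)
        assert np.isclose(fit.means[0], x.mean(), atol=1e-10)
        assert np.isclose(fit.sds[0], x.std(ddof=0), atol=1e-10)

    def test_constant_vector_returns_flagged_fallback(self):
        with pytest.warns(RuntimeWarning, match="zero sample variance"):
            fit = em_fit_1d(np.full(30, 2.5), k=2, seed=0)
        assert fit.fallback_used
        assert np.allclose(fit.means, 2.5)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError, match="at least"):
            em_fit_1d(np.array([1.0]), k=2)

    def test_loglik_trace_is_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        for x in (_bimodal(rng), rng.normal(size=80), rng.exponential(size=60)):
            fit = em_fit_1d(x, k=3, restarts=2, seed=5)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-9)

    def test_permutation_of_input_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(3)
        x = _bimodal(rng, mu2=4.0, sd=1.0)
        f1 = em_fit_1d(x, k=2, restarts=3, seed=3)
        f2 = em_fit_1d(rng.permutation(x), k=2, restarts=3, seed=3)
        assert np.allclose(f1.means, f2.means, atol=1e-9)
        assert np.allclose(f1.sds, f2.sds, atol=1e-9)
        assert np.allclose(f1.weights, f2.weights, atol=1e-9)

    def test_small_n_solution_matches_random_restart_search(self):
        # independent oracle: EM restarted from 200 random 2-point inits
        rng = np.random.default_rng(7)
        for v in range(5):
            n = int(rng.integers(8, 13))
            n1 = n // 2
            x = np.concatenate([rng.normal(0, 1, n1), rng.normal(8, 1, n - n1)])
            fit = em_fit_1d(x, k=2, restarts=3, seed=v)
            best = max(
                em_fit_1d(x, k=2, restarts=1, seed=1000 + 17 * v + r).loglik
                for r in range(10)
            )
            oracle = _oracle_best(x, 200, seed=99 + v)
            assert fit.loglik >= oracle - 1e-4
            assert fit.loglik >= best - 1e-4

    def test_cross_check_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(11)
        x = _bimodal(rng, mu2=6.0, sd=0.5)
        ours = em_fit_1d(x, k=2, restarts=3, seed=0)
        gm = sklearn.GaussianMixture(2, covariance_type="full", n_init=5,
                                     random_state=0).fit(x[:, None])
        sk_means = np.sort(gm.means_.ravel())
        assert np.allclose(ours.means, sk_means, atol=0.05)
        assert abs(ours.loglik - gm.score(x[:, None]) * x.size) < 0.5


def _oracle_best(x, n_restarts, seed):
    """Plain EM restarted from random pairs of points; same variance floor."""
    rng = np.random.default_rng(seed)
    n = x.size
    sv = x.var()
    floor = max(1e-6 * sv, 1e-10)
    best = -np.inf
    for _ in range(n_restarts):
        mu = rng.choice(x, 2, replace=False) + rng.normal(0, 0.1 * np.sqrt(sv), 2)
        var = np.full(2, sv)
        w = np.full(2, 0.5)
        ll_old = -np.inf
        for _ in range(500):
            lp = (-0.5 * np.log(2 * np.pi * var) - (x[:, None] - mu) ** 2 / (2 * var)
                  + np.log(w))
            m = lp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(lp - m).sum(axis=1))
            ll = lse.sum()
            if ll - ll_old < 1e-10:
                break
            ll_old = ll
            r = np.exp(lp - lse[:, None])
            Nk = r.sum(axis=0)
            w = np.maximum(Nk / n, 1e-12)
            w /= w.sum()
            mu = np.where(Nk > 0, (r * x[:, None]).sum(axis=0) / np.maximum(Nk, 1e-300), mu)
            var = np.maximum(
                (r * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(Nk, 1e-300), floor
            )
        best = max(best, ll)
    return best


class TestBic:
    def test_direct_formula(self):
        fit = MixtureFit(k=1, weights=np.ones(1), means=np.zeros(1), sds=np.ones(1),
                         loglik=-150.0, bic=np.nan, n=100, converged=True, n_iter=5)
        assert np.isclose(bic(fit), 2 * (-150.0) - 2 * np.log(100))

    def test_penalty_monotone_in_k_at_equal_loglik(self):
        args = dict(loglik=-50.0, bic=np.nan, n=40, converged=True, n_iter=1)
        f2 = MixtureFit(k=2, weights=np.ones(2) / 2, means=np.arange(2.0),
                        sds=np.ones(2), **args)
        f3 = MixtureFit(k=3, weights=np.ones(3) / 3, means=np.arange(3.0),
                        sds=np.ones(3), **args)
        assert bic(f2) > bic(f3)

    def test_undefined_for_single_observation(self):
        fit = MixtureFit(k=1, weights=np.ones(1), means=np.zeros(1), sds=np.ones(1),
                         loglik=0.0, bic=np.nan, n=1, converged=True, n_iter=0)
        with pytest.raises(ValueError):
            bic(fit)

    def test_two_clusters_prefer_k2_over_k1(self):
        x = _bimodal(np.random.default_rng(0))
        f1 = em_fit_1d(x, k=1, seed=0)
        f2 = em_fit_1d(x, k=2, seed=0)
        assert f2.bic > f1.bic


class TestSweep:
    def test_bimodal_sample_selects_k2(self):
        x = _bimodal(np.random.default_rng(0))
        best, table = sweep_k(x, k_max=6, seed=0)
        assert best.k == 2
        assert [row["k"] for row in table] == [1, 2, 3, 4, 5, 6]

    def test_unimodal_sample_selects_k1_in_most_replicates(self):
        hits = 0
        for rep in range(50):
            x = np.random.default_rng(rep).normal(size=500)
            best, _ = sweep_k(x, k_max=3, seed=rep)
            hits += best.k == 1
        assert hits >= 45  # >= 90% of replicates

    def test_ks_beyond_n_are_absent(self):
        best, table = sweep_k(np.array([0.0, 5.0]), k_max=6, seed=0)
        assert [row["k"] for row in table] == [1, 2]


class TestBatchedFitting:
    def test_batch_matches_scalar_bit_for_bit(self):
        rng = np.random.default_rng(0)
        X = np.concatenate(
            [rng.normal(0, 1, (12, 40)), rng.normal(4, 1.5, (12, 20))], axis=1
        )
        bat = fit_cells(X, k=2, restarts=3, seed=7)
        for i in range(X.shape[0]):
            f = em_fit_1d(X[i], k=2, restarts=3, seed=derive_seed(7, i))
            assert np.array_equal(f.means, bat.means[i])
            assert np.array_equal(f.sds, bat.sds[i])
            assert np.array_equal(f.weights, bat.weights[i])
            assert f.loglik == bat.loglik[i]

    def test_chunking_does_not_change_results(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 30))
        a = fit_cells(X, k=2, seed=3, chunk_size=7)
        b = fit_cells(X, k=2, seed=3, chunk_size=1000)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.loglik, b.loglik)

    def test_sweep_cells_agrees_with_scalar_sweep(self):
        rng = np.random.default_rng(2)
        X = np.concatenate(
            [rng.normal(0, 1, (6, 50)), rng.normal(7, 1, (6, 25))], axis=1
        )
        best_k, _ = sweep_cells(X, k_max=4, seed=5)
        for i in range(X.shape[0]):
            best, _ = sweep_k(X[i], k_max=4, seed=derive_seed(5, i))
            assert best.k == best_k[i]

    def test_derive_seed_is_stable_and_index_sensitive(self):
        assert derive_seed(1, 0) == derive_seed(1, 0)
        assert derive_seed(1, 0) != derive_seed(1, 1)
        assert derive_seed(1, 0) != derive_seed(2, 0)
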