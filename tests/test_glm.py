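"""Elastic-net Poisson GLM: closed forms, independent oracles, CV mechanics."""
import numpy as np
import pytest
from scipy import optimize, stats

from rewardglm.glm import (GlmConfig, PoissonEncodingGLM, cross_validate,
                           fit_poisson_elasticnet, make_folds,
                           poisson_log_likelihood)


def _random_instance(rng, n=200, p=5, scale=0.3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    w = rng.normal(scale=scale, size=p + 1)
    w[0] = np.log(0.5)
    y = rng.poisson(np.exp(X @ w))
    return X, y


class TestLogLikelihood:
    def test_unit_counts_unit_rates_closed_form(self):
        n = 37
        assert np.isclose(poisson_log_likelihood(np.ones(n), np.ones(n)), -n)

    def test_saturated_model_is_optimal(self, rng):
        y = rng.poisson(2.0, size=100).astype(float)
        mu = np.clip(y + rng.normal(size=100) * 0.3, 0.05, None)
        assert poisson_log_likelihood(y, y) >= poisson_log_likelihood(y, mu)

    def test_matches_scipy_reference(self, rng):
        for _ in range(10):
            y = rng.poisson(3.0, size=50)
            mu = rng.gamma(2.0, 1.5, size=50)
            mine = poisson_log_likelihood(y, mu)
            ref = stats.poisson.logpmf(y, mu).sum()
            assert np.isclose(mine, ref, atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            poisson_log_likelihood(np.ones(3), np.ones(4))


class TestFitting:
    def test_intercept_only_closed_form(self, rng):
        y = rng.poisson(1.3, size=500)
        m = PoissonEncodingGLM(y, np.ones((500, 1)))
        res = m.fit()
        assert res.intercept == np.log(y.mean())

    def test_huge_lambda_shrinks_weights_to_zero(self, rng):
        X, y = _random_instance(rng)
        m = PoissonEncodingGLM(y, X, config=GlmConfig(lam=1e6, alpha=0.1))
        res = m.fit()
        assert np.all(np.abs(res.weights) < 1e-8)
        assert np.isclose(res.intercept, np.log(y.mean()), atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unpenalized_fit_matches_independent_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        X, y = _random_instance(rng)
        res = PoissonEncodingGLM(y, X, config=GlmConfig(lam=0.0, tol=1e-13,
                                                        max_iter=500)).fit()

        def negll(w):
            eta = X @ w
            return float(np.sum(np.exp(eta) - y * eta))

        def grad(w):
            return X.T @ (np.exp(X @ w) - y)

        ref = optimize.minimize(negll, np.zeros(X.shape[1]), jac=grad,
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        assert np.allclose(res.params, ref.x, atol=1e-5)

    def test_objective_path_monotone_nonincreasing(self, bench_design, fast_glm_cfg):
        res = fit_poisson_elasticnet(bench_design, 0, fast_glm_cfg)
        path = res.objective_path
        assert np.all(np.diff(path) <= 1e-12)
        assert res.converged

    def test_objective_beats_zero_vector(self, rng):
        X, y = _random_instance(rng)
        cfg = GlmConfig(lam=0.05, alpha=0.5)
        res = PoissonEncodingGLM(y, X, config=cfg).fit()

        def objective(params):
            eta = X @ params
            nll = float(np.mean(np.exp(eta) - y * eta))
            w = params[1:]
            return nll + cfg.lam * (cfg.alpha * np.abs(w).sum()
                                    + 0.5 * (1 - cfg.alpha) * w @ w)

        zero = np.zeros(X.shape[1])
        zero[0] = np.log(max(y.mean(), 1e-12))
        assert objective(res.params) <= objective(zero) + 1e-12

    def test_shrinkage_monotone_in_lambda(self, rng):
        X, y = _random_instance(rng, n=400, p=6, scale=0.4)
        norms = []
        for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            res = PoissonEncodingGLM(y, X, config=GlmConfig(lam=lam)).fit()
            norms.append(np.abs(res.weights).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms[:-1], norms[1:]))

    def test_elasticnet_matches_statsmodels_oracle(self, rng):
        # independent route: statsmodels' elastic-net coordinate descent with
        # the intercept left unpenalized, same per-observation normalization
        sm = pytest.importorskip("statsmodels.api")
        X, y = _random_instance(rng, n=300, p=4)
        lam, alpha = 0.05, 0.3
        cfg = GlmConfig(lam=lam, alpha=alpha, standardize=False, tol=1e-12,
                        max_iter=300)
        mine = PoissonEncodingGLM(y, X, config=cfg).fit()
        pen = np.full(X.shape[1], lam)
        pen[0] = 0.0
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit_regularized(
            method="elastic_net", alpha=pen, L1_wt=alpha, cnvrg_tol=1e-10,
            maxiter=2000)
        assert np.allclose(mine.params, ref.params, atol=2e-4)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative integers"):
            PoissonEncodingGLM(np.array([0.5, 1.0]), np.ones((2, 1)))


class TestPrediction:
    def test_zero_weights_predict_constant(self, rng):
        X, y = _random_instance(rng)
        res = PoissonEncodingGLM(y, X, config=GlmConfig(lam=1e6)).fit()
        pred = res.predict()
        assert np.allclose(pred, pred[0])
        assert np.all(pred > 0)

    def test_prediction_invariant_to_row_order(self, rng):
        X, y = _random_instance(rng)
        res = PoissonEncodingGLM(y, X, config=GlmConfig()).fit()
        perm = rng.permutation(len(X))
        assert np.allclose(res.predict(X[perm]), res.predict(X)[perm])

    def test_predicted_psth_tracks_generative_rate(self, bench_session,
                                                   bench_design):
        # trial-averaged prediction vs the known generative rate; the
        # empirical PSTH comparison is bounded by its own sampling noise, so
        # ground truth is the sharper yardstick the simulation affords
        from rewardglm.simulate import weight_vector_for
        res = fit_poisson_elasticnet(bench_design, 1, GlmConfig())
        gt = bench_session.ground_truth[1]
        wt = weight_vector_for(gt, bench_design.column_names)
        true_rate = np.exp(gt.baseline_log_rate + bench_design.X[:, 1:] @ wt)
        pred = res.predict().reshape(-1, 200).mean(axis=0)
        true_psth = true_rate.reshape(-1, 200).mean(axis=0)
        assert np.corrcoef(pred, true_psth)[0, 1] ** 2 > 0.9
        # and the empirical comparison stays within the noise ceiling
        emp = bench_design.counts[1].reshape(-1, 200).mean(axis=0)
        r2_pred = np.corrcoef(pred, emp)[0, 1] ** 2
        r2_ceiling = np.corrcoef(true_psth, emp)[0, 1] ** 2
        assert r2_pred > 0.7 * r2_ceiling

    def test_column_mismatch_rejected(self, rng):
        X, y = _random_instance(rng)
        res = PoissonEncodingGLM(y, X).fit()
        with pytest.raises(ValueError, match="columns"):
            res.predict(X[:, :3])

    def test_summary_renders(self, bench_design):
        res = fit_poisson_elasticnet(bench_design, 0, GlmConfig())
        text = res.summary()
        assert "lambda" in text and "reward" in text


class TestCrossValidation:
    def test_folds_partition_trials_and_stratify(self, rng):
        ids = np.arange(40)
        rew = np.repeat([True, False], [30, 10])
        folds = make_folds(ids, rew, n_folds=2, seed=0)
        joined = np.sort(np.concatenate(folds))
        assert np.array_equal(joined, ids)
        for f in folds:
            assert np.sum(~rew[f]) == 5  # unrewarded balanced across halves

    def test_split_seed_determinism(self):
        ids = np.arange(30)
        rew = ids % 3 == 0
        a = make_folds(ids, rew, seed=4)
        b = make_folds(ids, rew, seed=4)
        c = make_folds(ids, rew, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_generative_model_beats_intercept_on_heldout(self, bench_session,
                                                         bench_design):
        rew = [t.rewarded for t in bench_session.trials]
        cfg = GlmConfig(seed=2)
        full = cross_validate(bench_design, 0, cfg, rewarded_flags=rew)
        null_ll = []
        for f in full:
            mu = np.full(len(f.test_rows),
                         bench_design.counts[0][
                             bench_design.rows_for_trials(f.train_trials)].mean())
            null_ll.append(poisson_log_likelihood(
                bench_design.counts[0][f.test_rows], mu))
        assert all(f.test_ll > nl for f, nl in zip(full, null_ll))

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            make_folds(np.arange(3), np.zeros(3, dtype=bool), n_folds=2, seed=0)
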