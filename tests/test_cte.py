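import numpy as np
import pytest

import hpenet as h
from hpenet.cte import subobserved_innovation_variance, var_to_ss


def refit_residual_variance(model, target, observed, L=50_000, p_fit=20, seed=0):
    """Independent oracle: simulate the full model, OLS-fit a VAR restricted
    to the observed processes, and return the target's residual variance."""
    sim = h.simulate_var(model, L, seed=seed)
    sub = h.HFSeries(
        values=sim.values[observed],
        names=tuple(f"x{i}" for i in observed),
    )
    fit = h.fit_var_ols(sub, p_fit)
    return fit.Sigma[observed.index(target), observed.index(target)]


def companion_yule_walker(model, n_lags):
    """Autocovariance oracle straight from the VAR: vectorized Lyapunov solve
    on the companion form, then the recursion Gamma_k = sum A_m Gamma_{k-m}."""
    n, p = model.n_processes, model.order
    F = model.companion()
    Q = np.zeros_like(F)
    Q[:n, :n] = model.Sigma
    m = F.shape[0]
    vec = np.linalg.solve(np.eye(m * m) - np.kron(F, F), Q.ravel())
    big = vec.reshape(m, m)
    gammas = [big[:n, :n]]
    # Gamma_k for k >= 1 from the big covariance blocks Gamma(k) = cov(x_t, x_{t-k})
    for k in range(1, n_lags + 1):
        if k < p:
            gammas.append(big[:n, k * n : (k + 1) * n])
        else:
            g = sum(model.A[j] @ gammas[k - 1 - j] for j in range(p))
            gammas.append(g)
    return np.array(gammas)


class TestStateSpace:
    def test_var1_embedding(self):
        A = np.array([[[0.5, 0.2], [0.0, 0.3]]])
        ss = var_to_ss(h.VARModel(A=A, Sigma=np.eye(2)))
        np.testing.assert_array_equal(ss.F, A[0])
        assert ss.state_dim == 2

    def test_companion_dimension(self):
        model = h.random_sparse_var(n=5, p=3, density=0.3, coupling=0.3, seed=1)
        ss = var_to_ss(model)
        assert ss.state_dim == 15
        assert ss.C.shape == (5, 15)

    def test_autocovariance_round_trip(self):
        model = h.random_sparse_var(n=4, p=2, density=0.5, coupling=0.4, seed=2)
        ss = var_to_ss(model)
        got = ss.autocovariance(3)
        want = companion_yule_walker(model, 3)
        assert np.max(np.abs(got - want)) < 1e-6


class TestRestrictedVariance:
    def test_irrelevant_source_changes_nothing(self):
        # process 0 feeds nothing: removing it leaves every target's variance
        A = np.zeros((1, 3, 3))
        A[0] = [[0.5, 0.0, 0.0], [0.0, 0.4, 0.2], [0.0, 0.3, 0.1]]
        model = h.VARModel(A=A, Sigma=np.eye(3))
        for j in (1, 2):
            s_r = h.restricted_residual_variance(model, target=j, excluded=0)
            assert s_r == pytest.approx(model.Sigma[j, j], abs=1e-10)

    def test_bivariate_closed_form(self, bivariate_coupled):
        # X2 without X1's past is white with variance 1 + a^2 (a = 1)
        s_r = h.restricted_residual_variance(bivariate_coupled, target=1, excluded=0)
        assert s_r == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_refit_oracle(self, seed):
        model = h.random_sparse_var(n=4, p=1, density=0.5, coupling=0.4, seed=30 + seed)
        target, excluded = 1, 3
        observed = [q for q in range(4) if q != excluded]
        analytic = h.restricted_residual_variance(model, target, excluded)
        refit = refit_residual_variance(model, target, observed, seed=seed)
        assert abs(analytic - refit) / refit < 0.02


class TestCTEPair:
    def test_closed_form_half_ln2(self, bivariate_coupled):
        assert h.cte_pair(bivariate_coupled, 0, 1) == pytest.approx(
            0.5 * np.log(2.0), abs=1e-9
        )

    def test_independent_processes_carry_nothing(self):
        A = np.zeros((1, 5, 5))
        np.fill_diagonal(A[0], [0.3, 0.4, 0.5, 0.2, 0.35])
        model = h.VARModel(A=A, Sigma=np.eye(5))
        result = h.cte_matrix(model)
        assert np.max(np.abs(result.matrix)) < 1e-10

    def test_mediated_influence_removed_by_conditioning(self):
        # chain 1 -> 2 -> 3 with no direct 1 -> 3 coefficient
        A = np.zeros((1, 3, 3))
        A[0, 1, 0] = 0.9
        A[0, 2, 1] = 0.9
        model = h.VARModel(A=A, Sigma=np.eye(3))
        assert h.cte_pair(model, 0, 2) < 0.01
        assert h.bivariate_te(model, 0, 2) > 0.05

    def test_bits_option_rescales(self, bivariate_coupled):
        nats = h.cte_pair(bivariate_coupled, 0, 1, units="nats")
        bits = h.cte_pair(bivariate_coupled, 0, 1, units="bits")
        assert bits == pytest.approx(nats / np.log(2))

    def test_same_index_rejected(self, bivariate_coupled):
        with pytest.raises(ValueError, match="differ"):
            h.cte_pair(bivariate_coupled, 1, 1)


class TestCTEMatrixProperties:
    @pytest.mark.parametrize("seed", range(3))
    def test_nonnegativity_on_random_models(self, seed):
        model = h.random_sparse_var(n=5, p=2, density=0.6, coupling=0.4, seed=50 + seed)
        result = h.cte_matrix(model)
        assert np.all(result.matrix >= 0)
        assert np.all(result.sigma_r + 1e-12 >= result.sigma_u)

    def test_node_aggregate_consistency(self):
        model = h.random_sparse_var(n=5, p=1, density=0.5, coupling=0.4, seed=60)
        result = h.cte_matrix(model)
        for i in range(5):
            assert h.cte_node(result, i) == result.node_out[i]
        row = np.array([0.0, 0.2, 0.4, 0.0, 0.2])
        manual = h.CTEResult(
            matrix=np.vstack([row, np.zeros((4, 5))]),
            node_out=np.zeros(5),
            sigma_u=np.ones((5, 5)),
            sigma_r=np.ones((5, 5)),
        )
        assert h.cte_node(manual, 0) == pytest.approx(0.2)

    def test_permutation_equivariance(self):
        model = h.random_sparse_var(n=4, p=1, density=0.5, coupling=0.4, seed=61)
        perm = np.array([2, 0, 3, 1])
        permuted = h.VARModel(
            A=model.A[:, perm][:, :, perm], Sigma=model.Sigma[np.ix_(perm, perm)]
        )
        base = h.cte_matrix(model).matrix
        moved = h.cte_matrix(permuted).matrix
        np.testing.assert_allclose(moved, base[np.ix_(perm, perm)], atol=1e-10)

    def test_scale_invariance_through_ols(self, sparse_var2_truth):
        sim = h.simulate_var(sparse_var2_truth, 3000, seed=62)
        base = h.cte_matrix(h.fit_var_ols(sim, 2)).matrix
        scaled_values = sim.values.copy()
        scaled_values[2] *= 37.5
        scaled = h.HFSeries(values=scaled_values, names=sim.names)
        rescaled = h.cte_matrix(h.fit_var_ols(scaled, 2)).matrix
        np.testing.assert_allclose(rescaled, base, atol=1e-8)


class TestBinarize:
    def test_fully_shrunk_model_gives_empty_graph(self, standardized_session):
        stack = h.build_regressors(standardized_session, 2)
        lam_crit = 2 * np.max(np.abs(stack.Z.T @ stack.targets))
        model, _ = h.fit_var_lasso(standardized_session, 2, 1.01 * lam_crit)
        adj = h.binarize(h.cte_matrix(model))
        assert adj.n_edges == 0

    def test_diagonal_never_links(self):
        model = h.random_sparse_var(n=5, p=1, density=1.0, coupling=0.3, seed=70)
        for rule in ("exact-zero", "quantile:0.5"):
            adj = h.binarize(h.cte_matrix(model), rule=rule)
            assert not np.diag(adj.Mbin).any()

    def test_quantile_rule_keeps_top_fraction(self):
        model = h.random_sparse_var(n=5, p=1, density=0.5, coupling=0.4, seed=71)
        adj = h.binarize(h.cte_matrix(model), rule="quantile:0.8")
        assert adj.n_edges == 4  # top 20% of the 20 off-diagonal cells

    def test_unknown_rule_rejected(self):
        model = h.random_sparse_var(seed=72)
        with pytest.raises(ValueError, match="unknown"):
            h.binarize(h.cte_matrix(model), rule="magic")

    def test_strong_coupling_recovery_has_full_recall(self):
        # CV-selected penalties keep every true link; spurious extras are the
        # known cost of the prediction-optimal lambda
        f1s, recalls = [], []
        for seed in range(5):
            truth = h.random_sparse_var(
                n=5, p=2, density=0.6, coupling=0.5, seed=80 + seed
            )
            sim = h.standardize(h.simulate_var(truth, 1440, seed=90 + seed))
            sel = h.select_lambda(sim, 2)
            model, _ = h.fit_var_lasso(sim, 2, sel.lambda_per_row)
            score = h.score_recovery(truth.support(), h.binarize(h.cte_matrix(model)))
            f1s.append(score.f1)
            recalls.append(score.recall)
        assert np.mean(recalls) == 1.0
        assert np.mean(f1s) >= 0.75


class TestGrangerEquivalence:
    def test_matches_refit_conditional_gc(self):
        # conditional GC estimated the long way: refit the restricted VAR on a
        # large simulated sample and compare the log variance ratio
        model = h.random_sparse_var(n=4, p=1, density=0.5, coupling=0.45, seed=95)
        i, j = 0, 2
        analytic = h.cte_pair(model, i, j)
        observed = [q for q in range(4) if q != i]
        s_r = refit_residual_variance(model, j, observed, seed=5)
        sim = h.simulate_var(model, 50_000, seed=5)
        full = h.fit_var_ols(sim, 20)
        s_u = full.Sigma[j, j]
        gc = 0.5 * np.log(s_r / s_u)
        assert analytic == pytest.approx(gc, rel=0.02, abs=5e-4)
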