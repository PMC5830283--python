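"""EM estimation: E-step oracle, M-step constraints, correlation update,
and full-fit behaviour on toy problems (the large recovery study lives in
the acceptance suite)."""

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import multivariate_normal

import patternirt as pt
from patternirt.core import category_prob_table
from patternirt.fit import collapse_empty_categories, e_step, m_step_item
from patternirt.quadrature import gauss_hermite_rule, qmc_rule


def _simulate(bank, n, corr, seed):
    theta = pt.simulate_theta(n, corr, seed) if bank.n_dim == 2 else None
    if theta is None:
        rng = np.random.default_rng(seed)
        theta = rng.standard_normal((n, 1))
    return pt.simulate_responses(theta, bank, seed=seed + 1)


class TestQuadrature:
    def test_gauss_hermite_weights_are_prior_masses(self):
        rule = gauss_hermite_rule(2, 15)
        assert rule.weights.sum() == pytest.approx(1.0)
        # second moments of the rule reproduce the prior covariance
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        theta = rule.with_correlation(R).theta_nodes
        M = (theta.T * rule.weights) @ theta
        np.testing.assert_allclose(M, R, atol=1e-10)

    def test_qmc_rule_reproducible_and_covering(self):
        a = qmc_rule(2, 256, seed=5)
        b = qmc_rule(2, 256, seed=5)
        np.testing.assert_array_equal(a.z_nodes, b.z_nodes)
        M = (a.z_nodes.T * a.weights) @ a.z_nodes
        np.testing.assert_allclose(M, np.eye(2), atol=0.05)


class TestEStep:
    def test_flat_likelihood_returns_prior(self):
        flat = pt.ItemBank(
            items=(pt.ItemParameters("f", a=[0.0, 0.0], d=[0.0]),),
            loading_pattern=np.array([[True, True]]),
        )
        rm = pt.ResponseMatrix.from_array(np.array([[1.0]]), item_ids=["f"])
        rule = gauss_hermite_rule(2, 11)
        es = e_step(rm, flat, np.eye(2), rule)
        np.testing.assert_allclose(es.posterior[0], rule.weights, atol=1e-12)

    def test_posterior_rows_normalized(self, toy_2d_bank):
        rm = _simulate(toy_2d_bank, 50, 0.5, seed=11)
        es = e_step(rm, toy_2d_bank, np.eye(2), gauss_hermite_rule(2, 21))
        np.testing.assert_allclose(es.posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_all_missing_row_contributes_prior_and_zero_loglik(self, toy_2d_bank):
        values = np.full((1, toy_2d_bank.n_items), np.nan)
        rm = pt.ResponseMatrix.from_array(values, item_ids=toy_2d_bank.item_ids)
        rule = gauss_hermite_rule(2, 11)
        es = e_step(rm, toy_2d_bank, np.eye(2), rule)
        np.testing.assert_allclose(es.posterior[0], rule.weights, atol=1e-12)
        assert es.loglik == pytest.approx(0.0, abs=1e-10)

    def test_marginal_loglik_matches_dense_trapezoid(self, toy_2d_bank):
        """21^2-node Gauss-Hermite marginal log-likelihood against 201^2
        brute-force trapezoid integration over [-6, 6]^2."""
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        rm = _simulate(toy_2d_bank, 50, 0.5, seed=4)
        es = e_step(rm, toy_2d_bank, R, gauss_hermite_rule(2, 21))

        g = np.linspace(-6, 6, 201)
        X, Y = np.meshgrid(g, g, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel()])
        dens = multivariate_normal(mean=[0, 0], cov=R).pdf(nodes)
        logp = [
            np.log(np.maximum(category_prob_table(it, nodes), 1e-300))
            for it in toy_2d_bank.items
        ]
        total = 0.0
        for i in range(rm.n_respondents):
            ll = np.zeros(nodes.shape[0])
            for j in range(toy_2d_bank.n_items):
                ll += logp[j][:, int(rm.values[i, j])]
            integrand = (dens * np.exp(ll)).reshape(201, 201)
            total += np.log(np.trapezoid(np.trapezoid(integrand, g, axis=1), g))
        assert es.loglik == pytest.approx(total, rel=1e-3)


class TestMStep:
    def _counts_from_sample(self, item, theta, responses, nodes):
        """Hard-assignment expected counts for a known-theta sample."""
        counts = np.zeros((nodes.shape[0], item.n_categories))
        idx = np.argmin(np.abs(nodes[:, 0][None, :] - theta[:, 0][:, None]), axis=1)
        for i, k in enumerate(idx):
            counts[k, int(responses[i])] += 1
        return counts

    def test_recovers_single_item_from_large_sample(self):
        item = pt.ItemParameters("x", a=[1.4], d=[0.6, -0.8], link="probit")
        toy = pt.ItemBank(items=(item,))
        rng = np.random.default_rng(21)
        theta = rng.standard_normal((5000, 1))
        rm = pt.simulate_responses(theta, toy, seed=22)
        rule = gauss_hermite_rule(1, 41)
        counts = self._counts_from_sample(item, theta, rm.values[:, 0], rule.theta_nodes)
        start = pt.ItemParameters("x", a=[1.0], d=[1.0, -1.0], link="probit")
        fitted, flags = m_step_item(counts, rule.theta_nodes, start, np.array([True]))
        assert not flags
        assert fitted.a[0] == pytest.approx(1.4, abs=0.1)
        np.testing.assert_allclose(fitted.d, item.d, atol=0.15)

    def test_unobserved_top_category_hits_bound_and_flags(self):
        item = pt.ItemParameters("x", a=[1.0], d=[0.5, -0.5], link="probit")
        rule = gauss_hermite_rule(1, 21)
        counts = np.zeros((rule.n_nodes, 3))
        probs = category_prob_table(item, rule.theta_nodes)
        counts[:, 0] = 100 * rule.weights * probs[:, 0]
        counts[:, 1] = 100 * rule.weights * (probs[:, 1] + probs[:, 2])
        fitted, flags = m_step_item(counts, rule.theta_nodes, item, np.array([True]))
        assert any("bound" in f for f in flags)
        assert fitted.d[1] < -5

    def test_fixed_zero_slope_untouched(self, toy_2d_bank):
        item = toy_2d_bank.items[0]  # loads on dimension 1 only
        rule = gauss_hermite_rule(2, 11)
        probs = category_prob_table(item, rule.theta_nodes)
        counts = 200 * rule.weights[:, None] * probs
        fitted, _ = m_step_item(counts, rule.theta_nodes, item, np.array([True, False]))
        assert fitted.a[1] == 0.0

    def test_negative_counts_rejected(self, toy_2d_bank):
        rule = gauss_hermite_rule(2, 5)
        counts = -np.ones((rule.n_nodes, 3))
        with pytest.raises(ValueError):
            m_step_item(counts, rule.theta_nodes, toy_2d_bank.items[0], np.array([True, False]))


class TestLatentCorrelation:
    def test_unit_diagonal_exact(self):
        rule = gauss_hermite_rule(2, 15, latent_corr=np.array([[1.0, 0.3], [0.3, 1.0]]))
        post = np.tile(rule.weights, (10, 1))
        R = pt.update_latent_corr(rule.theta_nodes, post)
        np.testing.assert_array_equal(np.diag(R), [1.0, 1.0])

    @pytest.mark.parametrize("true_corr", [0.5, 0.0])
    def test_recovery_from_simulated_posteriors(self, bank, true_corr):
        """Fitting with the item parameters held at truth, the correlation
        estimate lands within +-0.1 of the generating value at n = 2000."""
        theta = pt.simulate_theta(2000, true_corr, seed=31)
        rm = pt.simulate_responses(theta, bank, seed=32)
        rule = gauss_hermite_rule(2, 21)
        R = np.eye(2)
        for _ in range(20):
            es = e_step(rm, bank, R, rule)
            R = pt.update_latent_corr(es.theta_nodes, es.posterior)
        assert R[0, 1] == pytest.approx(true_corr, abs=0.1)


class TestCollapse:
    def test_remaps_gap_categories(self):
        item = pt.ItemParameters("x", a=[1.0], d=[1.0, 0.0, -1.0])
        toy = pt.ItemBank(items=(item,))
        values = np.array([[0.0], [1.0], [3.0], [1.0]])  # category 2 unobserved
        rm = pt.ResponseMatrix.from_array(values, item_ids=["x"])
        rm2, bank2, maps = collapse_empty_categories(rm, toy)
        assert maps == {"x": {0: 0, 1: 1, 3: 2}}
        assert bank2.items[0].n_categories == 3
        assert set(np.unique(rm2.values)) == {0.0, 1.0, 2.0}

    def test_single_category_item_rejected(self):
        item = pt.ItemParameters("x", a=[1.0], d=[0.0])
        toy = pt.ItemBank(items=(item,))
        rm = pt.ResponseMatrix.from_array(np.zeros((5, 1)), item_ids=["x"])
        with pytest.raises(ValueError, match="fewer than 2"):
            collapse_empty_categories(rm, toy)


class TestFitMgrm:
    def test_zero_iterations_returns_start(self, toy_2d_bank):
        rm = _simulate(toy_2d_bank, 40, 0.3, seed=9)
        fit = pt.fit_mgrm(rm, bank=toy_2d_bank, max_iter=0)
        assert not fit.converged
        assert fit.n_iterations == 0
        assert fit.loglik_path == []
        # neutral start: free slopes at 1
        for item, row in zip(fit.bank.items, toy_2d_bank.loading_pattern):
            np.testing.assert_array_equal(item.a[row], 1.0)

    def test_loglik_monotone_and_constraints_respected(self, study):
        """On a study-sized sample from the packaged bank, EM converges,
        the marginal log-likelihood never decreases, and structural zeros
        survive every iterate."""
        fit = pt.fit_mgrm(study.responses, bank=study.bank, tol=1e-4, max_iter=500)
        assert fit.converged
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs > -1e-6)
        for item, row in zip(fit.bank.items, study.bank.loading_pattern):
            np.testing.assert_array_equal(item.a[~row], 0.0)

    def test_matches_direct_marginal_ml_on_1d_toy(self, toy_1d_bank):
        """EM solution log-likelihood against direct joint optimization of
        the marginal likelihood over all four item parameters."""
        rm = _simulate(toy_1d_bank, 200, 0.0, seed=17)
        rule = gauss_hermite_rule(1, 41)
        fit = pt.fit_mgrm(rm, bank=toy_1d_bank, rule=rule, tol=1e-6, max_iter=1000,
                          estimate_corr=False)

        def negll(x):
            items = (
                pt.ItemParameters("t1", a=[x[0]], d=[x[1]], link="probit"),
                pt.ItemParameters("t2", a=[x[2]], d=[x[3]], link="probit"),
            )
            b = pt.ItemBank(items=items)
            return -e_step(rm, b, np.eye(1), rule).loglik

        res = optimize.minimize(negll, [1.0, 0.0, 1.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-3)

    def test_start_at_truth_stays_near_truth(self, toy_2d_bank):
        """Initialized at the generating parameters, the first EM step moves
        each parameter only within its sampling noise."""
        rm = _simulate(toy_2d_bank, 5000, 0.5, seed=23)
        fit = pt.fit_mgrm(rm, bank=toy_2d_bank, max_iter=1, start_bank=toy_2d_bank,
                          estimate_corr=False, latent_corr=np.array([[1, .5], [.5, 1]]))
        for est, truth in zip(fit.bank.items, toy_2d_bank.items):
            assert np.max(np.abs(est.a - truth.a)) < 0.2
            assert np.max(np.abs(est.d - truth.d)) < 0.2

    def test_validation_error_before_iteration(self, toy_2d_bank):
        values = np.array([[5.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 2.0]])
        rm = pt.ResponseMatrix.from_array(values, item_ids=toy_2d_bank.item_ids)
        with pytest.raises(ValueError, match="out-of-range"):
            pt.fit_mgrm(rm, bank=toy_2d_bank)

    def test_parameter_table_mdisc_is_norm_of_slopes(self, toy_2d_bank):
        rm = _simulate(toy_2d_bank, 100, 0.3, seed=29)
        fit = pt.fit_mgrm(rm, bank=toy_2d_bank, tol=1e-3, max_iter=50)
        tab = fit.parameter_table()
        norms = np.sqrt(tab[["a1", "a2"]].pow(2).sum(axis=1))
        np.testing.assert_allclose(tab["MDISC"], norms, rtol=1e-12)
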