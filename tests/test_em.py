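"""EM estimation: E-step moments, M-step closed forms, fit behavior."""

import numpy as np
import pytest

from jointeb import (
    HyperParams,
    JointEBModel,
    NumericalError,
    SimConfig,
    ValidationError,
    build_gene_blocks,
    e_step,
    generate,
    m_step,
)

from conftest import random_block, random_theta


def simulated_blocks(n_genes, seed, theta=None, **kw):
    cfg = SimConfig(n_genes=n_genes, seed=seed, **({"theta": theta} if theta else {}), **kw)
    expr, meth, truth = generate(cfg)
    blocks, _ = build_gene_blocks(expr, meth)
    return blocks, truth, cfg.theta


class TestEStep:
    def test_noiseless_limit_recovers_gene_effects(self):
        tiny = HyperParams(
            mu=np.array([7.0, 7.0, 9.5, 9.5]),
            Sigma=np.diag([2.0, 2.0, 1.5, 1.5]),
            sigma2=1e-12, delta2=1e-12, omega2=1e-12, tau2=1e-12,
        )
        blocks, truth, _ = simulated_blocks(5, seed=1, theta=tiny)
        cache = e_step(blocks, tiny)
        for _, row in truth.genes.iterrows():
            m = cache.mean(row["gene_id"])
            assert np.allclose(
                m[:4], [row["mu1"], row["mu2"], row["eta1"], row["eta2"]], atol=1e-6
            )

    def test_second_moment_matches_monte_carlo(self):
        """Cached E[beta beta'] equals the analytic-posterior MC estimate."""
        rng = np.random.default_rng(0)
        block = random_block(rng, J=2, H=2, K=2)
        theta = random_theta(rng)
        cache = e_step([block], theta)
        m, v = cache.mean("g"), cache.cov("g")
        n = 200_000
        draws = rng.multivariate_normal(m, v, size=n)
        mc = draws.T @ draws / n
        # MC standard error of each entry: Var(x_a x_b) for Gaussian x
        dv = np.diag(v)
        var_ab = (
            np.outer(dv, dv) + v**2
            + np.outer(m**2, dv) + np.outer(dv, m**2)
            + 2 * np.outer(m, m) * v
        )
        se = np.sqrt(var_ab / n)
        assert np.all(np.abs(cache.second_moment("g") - mc) < 3 * se + 1e-8)

    def test_identical_genes_identical_moments(self):
        rng = np.random.default_rng(2)
        b1 = random_block(rng, J=2, H=1, K=3, gene_id="g1")
        b2 = b1.__class__(
            gene_id="g2", G=b1.G.copy(), M=b1.M.copy(), J=b1.J, H=b1.H, K=b1.K,
            Delta=b1.Delta, p=b1.p,
        )
        theta = random_theta(rng)
        cache = e_step([b1, b2], theta)
        assert np.array_equal(cache.mean("g1"), cache.mean("g2"))
        assert np.array_equal(cache.cov("g1"), cache.cov("g2"))


class TestMStep:
    def test_matches_hand_computed_updates(self):
        """Independent dense-loop evaluation of the closed-form maximizers."""
        blocks, _, theta0 = simulated_blocks(6, seed=3)
        cache = e_step(blocks, theta0)
        updated = m_step(cache)

        p = 4
        I = len(blocks)
        ms = {b.gene_id: cache.mean(b.gene_id) for b in blocks}
        vs = {b.gene_id: cache.cov(b.gene_id) for b in blocks}
        mu_hat = sum(ms[b.gene_id][:p] for b in blocks) / I
        sigma_hat = sum(
            np.outer(ms[b.gene_id][:p] - mu_hat, ms[b.gene_id][:p] - mu_hat)
            + vs[b.gene_id][:p, :p]
            for b in blocks
        ) / I
        num_b = den_b = num_a = den_a = num_e = den_e = num_m = den_m = 0.0
        for b in blocks:
            m, v = ms[b.gene_id], vs[b.gene_id]
            for j in range(b.J):
                num_b += m[p + j] ** 2 + v[p + j, p + j]
                den_b += 1
            for h in range(b.H):
                k = p + b.J + h
                num_a += m[k] ** 2 + v[k, k]
                den_a += 1
            resid = b.D - b.Delta @ m
            row_var = np.einsum("ij,jk,ik->i", b.Delta, v, b.Delta)
            num_e += float((resid[: b.n_expr] ** 2 + row_var[: b.n_expr]).sum())
            den_e += b.n_expr
            num_m += float((resid[b.n_expr:] ** 2 + row_var[b.n_expr:]).sum())
            den_m += b.n_meth
        assert np.allclose(updated.mu, mu_hat, atol=1e-10)
        assert np.allclose(updated.Sigma, 0.5 * (sigma_hat + sigma_hat.T), atol=1e-10)
        assert updated.sigma2 == pytest.approx(num_b / den_b, abs=1e-12)
        assert updated.omega2 == pytest.approx(num_a / den_a, abs=1e-12)
        assert updated.delta2 == pytest.approx(num_e / den_e, abs=1e-12)
        assert updated.tau2 == pytest.approx(num_m / den_m, abs=1e-12)

    def test_update_never_decreases_loglik(self):
        blocks, _, theta0 = simulated_blocks(30, seed=4)
        model = JointEBModel(blocks)
        theta = random_theta(np.random.default_rng(9))
        for _ in range(3):
            cache = e_step(model.blocks, theta)
            theta_new = m_step(cache)
            assert model.loglike(theta_new) >= cache.loglik - 1e-8
            theta = theta_new

    def test_degenerate_cache_recovers_constant(self):
        """All gene-effect means equal and posterior covariance ~0 gives
        mu_hat = that constant and Sigma at the floor."""
        blocks, _, theta0 = simulated_blocks(4, seed=5)
        cache = e_step(blocks, theta0)
        v = np.full(4, 1.23)
        for gi in range(len(cache.groups)):
            cache.means[gi][:, :4] = v
            cache.covs[gi][:] = 0.0
        with pytest.warns(UserWarning):
            updated = m_step(cache)
        assert np.allclose(updated.mu, v)
        assert np.abs(updated.Sigma).max() < 1e-9


class TestFit:
    def test_fixed_point_near_truth(self):
        blocks, _, theta0 = simulated_blocks(1500, seed=6)
        res = JointEBModel(blocks).fit(start=theta0, maxiter=2, tol=0.0)
        assert np.all(np.diff(res.llf_history) >= -1e-8)
        assert np.abs(res.params.mu - theta0.mu).max() < 0.1
        assert abs(res.params.delta2 / theta0.delta2 - 1) < 0.05

    def test_maxiter_one_is_single_cycle(self):
        blocks, _, _ = simulated_blocks(20, seed=7)
        res = JointEBModel(blocks).fit(maxiter=1, tol=0.0)
        assert res.n_iter == 1
        assert not res.converged

    def test_gene_order_invariance(self):
        blocks, _, _ = simulated_blocks(40, seed=8)
        rng = np.random.default_rng(0)
        shuffled = list(blocks)
        rng.shuffle(shuffled)
        r1 = JointEBModel(blocks).fit(maxiter=10, tol=0.0)
        r2 = JointEBModel(shuffled).fit(maxiter=10, tol=0.0)
        assert np.array_equal(r1.params.mu, r2.params.mu)
        assert np.array_equal(r1.params.Sigma, r2.params.Sigma)
        assert r1.params.sigma2 == r2.params.sigma2

    def test_requires_two_genes(self):
        blocks, _, _ = simulated_blocks(1, seed=9)
        with pytest.raises(ValidationError, match="2 genes"):
            JointEBModel(blocks)

    def test_mixed_p_rejected(self):
        blocks, _, _ = simulated_blocks(3, seed=10)
        blocks[0].p = 2
        with pytest.raises(ValidationError):
            JointEBModel(blocks)


class TestDiagnostics:
    def test_residual_count_bookkeeping(self):
        blocks, _, _ = simulated_blocks(12, seed=11)
        res = JointEBModel(blocks).fit(maxiter=5, tol=0.0)
        diag = res.diagnostics()
        assert len(diag["residuals"]) == sum(b.n_obs for b in blocks)
        assert len(diag["gene_effects"]) == len(blocks)
        assert len(diag["probe_effects"]) == sum(b.J + b.H for b in blocks)

    def test_residuals_approximately_standard_normal(self):
        blocks, _, _ = simulated_blocks(800, seed=12)
        res = JointEBModel(blocks).fit()
        r = res.diagnostics()["residuals"]["std_residual"].to_numpy()
        assert len(r) > 20_000
        from scipy.stats import skew

        assert abs(skew(r)) < 0.1
        assert 0.8 < r.std() < 1.05
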