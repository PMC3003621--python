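"""Empirical Bayes model objects and EM hyperparameter estimation.

``JointEBModel`` holds the per-gene blocks; ``fit()`` runs EM on the
hyperparameters and returns a ``JointEBResults`` carrying the estimates,
the log-likelihood trace, per-gene posteriors and model-checking
diagnostics.  ``ExpressionEBModel`` is the expression-only marginal model
(gene effect dimension 2, no methylation rows) used for separability
checks and single-platform analyses.

The E-step needs E[beta_i | D_i] and Cov[beta_i | D_i] for every gene.
Because the error variances are global and the design matrix depends only
on the probe counts (J, H) and replicate number K, genes with equal
(J, H, K) share the same posterior precision; the implementation factors
it once per shape group and processes all member genes with one matrix
product, which keeps EM at a few milliseconds per iteration for thousands
of genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .data import GeneBlock
from .exceptions import NumericalError, ValidationError
from .params import HyperParams
from .posterior import (
    DiffPosterior,
    GenePosterior,
    _prior_precision,
    diff_posterior,
)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: variance updates are floored here to keep theta in the interior
VAR_FLOOR = 1e-10


class _ShapeGroup:
    """All genes sharing (J, H, K, p): one design matrix, stacked data."""

    def __init__(self, template: GeneBlock):
        self.J, self.H, self.K, self.p = template.shape_key
        self.Delta = template.Delta
        self.gene_ids: list[str] = []
        self._rows: list[np.ndarray] = []

    def add(self, block: GeneBlock) -> None:
        self.gene_ids.append(block.gene_id)
        self._rows.append(block.D)

    def finalize(self) -> None:
        self.D = np.vstack(self._rows)  # n_genes x n_obs
        del self._rows

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_expr(self) -> int:
        return 2 * self.K * self.J

    @property
    def n_obs(self) -> int:
        return self.n_expr + 2 * self.H


def _group_blocks(blocks: list[GeneBlock]) -> list[_ShapeGroup]:
    groups: dict[tuple, _ShapeGroup] = {}
    for b in blocks:
        g = groups.get(b.shape_key)
        if g is None:
            g = groups[b.shape_key] = _ShapeGroup(b)
        g.add(b)
    out = list(groups.values())
    for g in out:
        g.finalize()
    return out


@dataclass
class MomentCache:
    """E-step output: per-gene posterior means, per-shape posterior covariances."""

    groups: list[_ShapeGroup]
    means: list[np.ndarray]            # per group: n_genes x dim
    covs: list[np.ndarray]             # per group: dim x dim (shared within group)
    logliks: list[np.ndarray]          # per group: n_genes
    gene_index: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_index:
            for gi, g in enumerate(self.groups):
                for k, gene in enumerate(g.gene_ids):
                    self.gene_index[gene] = (gi, k)

    def mean(self, gene_id: str) -> np.ndarray:
        gi, k = self.gene_index[gene_id]
        return self.means[gi][k]

    def cov(self, gene_id: str) -> np.ndarray:
        gi, _ = self.gene_index[gene_id]
        return self.covs[gi]

    def second_moment(self, gene_id: str) -> np.ndarray:
        m = self.mean(gene_id)
        return np.outer(m, m) + self.cov(gene_id)

    @property
    def loglik(self) -> float:
        return float(sum(ll.sum() for ll in self.logliks))

    def posteriors(self) -> list[GenePosterior]:
        out = []
        for gi, g in enumerate(self.groups):
            for k, gene in enumerate(g.gene_ids):
                out.append(GenePosterior(gene, self.means[gi][k].copy(), self.covs[gi]))
        return sorted(out, key=lambda p: p.gene_id)


def e_step(blocks: list[GeneBlock], theta: HyperParams) -> MomentCache:
    """Posterior first/second moments of beta_i for every gene, plus loglik."""
    return _e_step_groups(_group_blocks(blocks), theta)


def _e_step_groups(groups: list[_ShapeGroup], theta: HyperParams) -> MomentCache:
    means, covs, logliks = [], [], []
    for g in groups:
        template = GeneBlock(
            gene_id="", G=np.empty(g.n_expr), M=np.empty(2 * g.H),
            J=g.J, H=g.H, K=g.K, Delta=g.Delta, p=g.p,
        )
        w = 1.0 / theta.error_variances(template)
        sp_inv, sp_logdet = _prior_precision(theta, template)
        bt_w = g.Delta.T * w
        a = bt_w @ g.Delta + sp_inv
        try:
            chol = cho_factor(a)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"posterior precision not PD for shape J={g.J}, H={g.H}: {exc}"
            ) from exc
        cov = cho_solve(chol, np.eye(a.shape[0]))
        cov = 0.5 * (cov + cov.T)
        mu_star = theta.mu_star(template)
        prior_term = sp_inv @ mu_star
        # means: solve A m = Delta' W D + Sp^-1 mu* for all genes at once
        rhs = bt_w @ g.D.T + prior_term[:, None]
        m = cho_solve(chol, rhs).T  # n_genes x dim

        resid = g.D - (g.Delta @ mu_star)[None, :]
        u = bt_w @ resid.T  # dim x n_genes
        quad = np.einsum("ij,ij->j", resid.T, w[:, None] * resid.T) - np.einsum(
            "ij,ij->j", u, cho_solve(chol, u)
        )
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        logdet = -float(np.sum(np.log(w))) + sp_logdet + logdet_a
        ll = -0.5 * (g.n_obs * _LOG_2PI + logdet + quad)

        means.append(m)
        covs.append(cov)
        logliks.append(ll)
    return MomentCache(groups=groups, means=means, covs=covs, logliks=logliks)


def m_step(
    cache: MomentCache, zero_cross: bool = False, var_floor: float = VAR_FLOOR
) -> HyperParams:
    """Closed-form maximizers of the expected complete-data log likelihood.

    mu and Sigma are the mean and (posterior-expanded) covariance of the
    gene-effect subvectors; each probe-effect variance averages the
    posterior second moments of its effects; each error variance averages
    the expected squared residuals of its platform's rows.
    """
    p = cache.groups[0].p
    n_genes_total = sum(g.n_genes for g in cache.groups)

    # --- mu ---------------------------------------------------------------
    mu_sum = np.zeros(p)
    for g, m in zip(cache.groups, cache.means):
        mu_sum += m[:, :p].sum(axis=0)
    mu_hat = mu_sum / n_genes_total

    # --- Sigma, probe-effect variances, error variances --------------------
    sigma_acc = np.zeros((p, p))
    b_ss = 0.0
    b_count = 0
    a_ss = 0.0
    a_count = 0
    expr_ss = 0.0
    expr_count = 0
    meth_ss = 0.0
    meth_count = 0
    for g, m, v in zip(cache.groups, cache.means, cache.covs):
        dev = m[:, :p] - mu_hat
        sigma_acc += dev.T @ dev + g.n_genes * v[:p, :p]

        bsl = slice(p, p + g.J)
        b_ss += float((m[:, bsl] ** 2).sum()) + g.n_genes * float(
            np.trace(v[bsl, bsl])
        )
        b_count += g.n_genes * g.J
        if g.H:
            asl = slice(p + g.J, p + g.J + g.H)
            a_ss += float((m[:, asl] ** 2).sum()) + g.n_genes * float(
                np.trace(v[asl, asl])
            )
            a_count += g.n_genes * g.H

        fitted = m @ g.Delta.T  # n_genes x n_obs
        resid2 = (g.D - fitted) ** 2
        dvd = np.einsum("ij,jk,ik->i", g.Delta, v, g.Delta)  # per-row trace term
        ne = g.n_expr
        expr_ss += float(resid2[:, :ne].sum()) + g.n_genes * float(dvd[:ne].sum())
        expr_count += g.n_genes * ne
        if g.H:
            meth_ss += float(resid2[:, ne:].sum()) + g.n_genes * float(dvd[ne:].sum())
            meth_count += g.n_genes * 2 * g.H

    sigma_hat = sigma_acc / n_genes_total
    sigma_hat = 0.5 * (sigma_hat + sigma_hat.T)
    if zero_cross and p == 4:
        sigma_hat[:2, 2:4] = 0.0
        sigma_hat[2:4, :2] = 0.0

    def _floored(value: float, name: str) -> float:
        if value <= var_floor:
            warnings.warn(f"{name} update hit the floor {var_floor}", stacklevel=2)
            return var_floor
        return value

    sigma2 = _floored(b_ss / b_count, "sigma2")
    delta2 = _floored(expr_ss / expr_count, "delta2")
    omega2 = _floored(a_ss / a_count, "omega2") if a_count else None
    tau2 = _floored(meth_ss / meth_count, "tau2") if meth_count else None
    return HyperParams(
        mu=mu_hat, Sigma=sigma_hat, sigma2=sigma2, delta2=delta2,
        omega2=omega2, tau2=tau2,
    )


def moment_init(blocks: list[GeneBlock]) -> HyperParams:
    """Method-of-moments starting values for EM.

    Gene-effect means come from probe-averaged condition means; Sigma from
    their sample covariance; delta2 from within-probe replicate variation;
    tau2 from paired condition differences across methylation probes (the
    platform has no replicates); sigma2/omega2 from between-probe spread.
    """
    p = blocks[0].p
    gvecs = []
    delta_num = delta_den = 0.0
    tau_devs = []
    b_between = []
    a_between = []
    for b in blocks:
        K = b.K
        expr = b.G.reshape(b.J, 2, K)  # probe x condition x replicate
        probe_cond_mean = expr.mean(axis=2)  # J x 2
        mu_il = probe_cond_mean.mean(axis=0)
        delta_num += float(((expr - probe_cond_mean[:, :, None]) ** 2).sum())
        delta_den += b.J * 2 * (K - 1)
        probe_dev = probe_cond_mean.mean(axis=1) - probe_cond_mean.mean()
        if b.J > 1:
            b_between.extend(probe_dev.tolist())
        if b.H:
            meth = b.M.reshape(b.H, 2)
            eta_il = meth.mean(axis=0)
            gvecs.append(np.concatenate([mu_il, eta_il]))
            diffs = meth[:, 1] - meth[:, 0]
            if b.H > 1:
                tau_devs.extend((diffs - diffs.mean()).tolist())
                a_between.extend(
                    (meth.mean(axis=1) - meth.mean()).tolist()
                )
        else:
            gvecs.append(mu_il)
    g = np.asarray(gvecs)
    mu0 = g.mean(axis=0)
    sigma0 = np.cov(g, rowvar=False, ddof=1)
    sigma0 = np.atleast_2d(sigma0)
    delta2_0 = max(delta_num / max(delta_den, 1.0), 1e-4)
    sigma2_0 = max(float(np.var(b_between, ddof=1)) if len(b_between) > 2 else 0.1, 1e-4)
    if p == 4:
        # var of within-gene centered paired differences estimates 2*tau2
        tau2_0 = max(
            0.5 * float(np.var(tau_devs, ddof=1)) if len(tau_devs) > 2 else 0.1, 1e-4
        )
        omega2_0 = max(
            float(np.var(a_between, ddof=1)) if len(a_between) > 2 else 0.1, 1e-4
        )
    else:
        tau2_0 = omega2_0 = None
    # keep Sigma0 safely PD
    sigma0 += 1e-6 * np.eye(p)
    return HyperParams(
        mu=mu0, Sigma=sigma0, sigma2=sigma2_0, delta2=delta2_0,
        omega2=omega2_0, tau2=tau2_0,
    )


# ---------------------------------------------------------------------------
# model / results objects


class JointEBModel:
    """Hierarchical empirical Bayes model for joint expression + methylation.

    Parameters
    ----------
    blocks : list of GeneBlock
        Per-gene stacked data, e.g. from ``data.build_gene_blocks``.
    """

    results_class: type = None  # set after JointEBResults is defined
    required_p = 4

    def __init__(self, blocks: list[GeneBlock]):
        if len(blocks) < 2:
            raise ValidationError("the model requires at least 2 genes")
        for b in blocks:
            if b.p != self.required_p:
                raise ValidationError(
                    f"gene {b.gene_id}: expected p={self.required_p} blocks"
                )
        self.blocks = sorted(blocks, key=lambda b: b.gene_id)
        self.groups = _group_blocks(self.blocks)
        self.n_genes = len(self.blocks)

    @classmethod
    def from_tables(cls, expr, meth) -> "JointEBModel":
        """Build the model from filtered, log2-scale tables (platform intersection)."""
        from .data import build_gene_blocks

        blocks, skip = build_gene_blocks(expr, meth)
        model = cls(blocks)
        model.skip_report = skip
        return model

    def loglike(self, theta: HyperParams) -> float:
        """Observed-data log likelihood at theta."""
        return _e_step_groups(self.groups, theta).loglik

    def start_params(self) -> HyperParams:
        return moment_init(self.blocks)

    def fit(
        self,
        start: HyperParams | None = None,
        maxiter: int = 500,
        tol: float = 1e-8,
        zero_cross: bool = False,
    ) -> "JointEBResults":
        """Estimate theta by EM.

        Iterates E (posterior moments) and M (closed-form updates) until the
        relative log-likelihood change falls below ``tol`` or ``maxiter``
        cycles.  A log-likelihood decrease beyond 1e-6 raises
        NumericalError: the M-step must be an ascent step.
        """
        if maxiter < 1:
            raise ValidationError("maxiter must be >= 1")
        theta = start if start is not None else self.start_params()
        if zero_cross:
            theta = theta.with_zero_cross()
        cache = _e_step_groups(self.groups, theta)
        history = [cache.loglik]
        converged = False
        for _ in range(maxiter):
            theta_new = m_step(cache, zero_cross=zero_cross)
            cache_new = _e_step_groups(self.groups, theta_new)
            ll_new = cache_new.loglik
            if ll_new < history[-1] - 1e-6:
                raise NumericalError(
                    f"EM log likelihood decreased: {history[-1]:.8f} -> {ll_new:.8f}"
                )
            theta, cache = theta_new, cache_new
            delta = ll_new - history[-1]
            history.append(ll_new)
            if abs(delta) < tol * (1.0 + abs(ll_new)):
                converged = True
                break
        return self.results_class(
            model=self,
            params=theta,
            cache=cache,
            llf_history=np.asarray(history),
            converged=converged,
        )


class ExpressionEBModel(JointEBModel):
    """Expression-only marginal model: gene effects (mu_1, mu_2), no methylation."""

    required_p = 2


@dataclass
class JointEBResults:
    """Fitted state: hyperparameter estimates, loglik trace, posterior cache."""

    model: JointEBModel
    params: HyperParams
    cache: MomentCache
    llf_history: np.ndarray
    converged: bool

    @property
    def llf(self) -> float:
        return float(self.llf_history[-1])

    @property
    def n_iter(self) -> int:
        return len(self.llf_history) - 1

    # --- posteriors --------------------------------------------------------
    def posteriors(self) -> list[GenePosterior]:
        return self.cache.posteriors()

    def diff_posteriors(self) -> list[DiffPosterior]:
        """Per-gene bivariate posterior of the expression/methylation changes."""
        return [diff_posterior(p) for p in self.posteriors()]

    # --- downstream conveniences -------------------------------------------
    def classify(self, c_mult: float = 1.5, rules=("max", "0.6", "0.7"), kappa: float = 0.9):
        from .classify import classify_genes

        return classify_genes(self.diff_posteriors(), c_mult=c_mult, rules=rules, kappa=kappa)

    def correlations(self):
        from .summaries import correlations

        return correlations(self.posteriors(), self.diff_posteriors())

    # --- diagnostics --------------------------------------------------------
    def diagnostics(self) -> dict[str, pd.DataFrame]:
        """Model-checking tables: standardized residuals, gene effects, probe effects.

        Residuals are (D - Delta m) scaled by the platform error SD; under a
        well-specified model they are approximately standard normal, the
        input for histogram / Q-Q checks.
        """
        theta = self.params
        p = theta.p
        resid_rows, gene_rows, probe_rows = [], [], []
        for b in self.model.blocks:
            m = self.cache.mean(b.gene_id)
            fitted = b.Delta @ m
            raw = b.D - fitted
            ne = b.n_expr
            scale = np.empty(b.n_obs)
            scale[:ne] = np.sqrt(theta.delta2)
            if b.n_meth:
                scale[ne:] = np.sqrt(theta.tau2)
            std = raw / scale
            for r in range(b.n_obs):
                resid_rows.append(
                    (b.gene_id, "expression" if r < ne else "methylation", r, std[r])
                )
            gene_rows.append((b.gene_id, *m[:p]))
            for j in range(b.J):
                probe_rows.append((b.gene_id, "expression", j + 1, m[p + j]))
            for h in range(b.H):
                probe_rows.append((b.gene_id, "methylation", h + 1, m[p + b.J + h]))
        gene_cols = ["gene_id"] + (
            ["mu1", "mu2", "eta1", "eta2"] if p == 4 else ["mu1", "mu2"]
        )
        return {
            "residuals": pd.DataFrame(
                resid_rows, columns=["gene_id", "platform", "row", "std_residual"]
            ),
            "gene_effects": pd.DataFrame(gene_rows, columns=gene_cols),
            "probe_effects": pd.DataFrame(
                probe_rows, columns=["gene_id", "platform", "probe", "effect"]
            ),
        }

    # --- reporting ----------------------------------------------------------
    def posterior_frame(self) -> pd.DataFrame:
        """Diff posteriors as a table (mean, lower-triangle covariance, correlation)."""
        rows = []
        for d in self.diff_posteriors():
            rows.append(
                (
                    d.gene_id, d.mean[0], d.mean[1],
                    d.cov[0, 0], d.cov[1, 0], d.cov[1, 1], d.correlation,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "mean_ge", "mean_meth",
                "var_ge", "cov_ge_meth", "var_meth", "posterior_corr",
            ],
        )

    def summary(self) -> str:
        theta = self.params
        lines = [
            "Joint empirical Bayes model (EM fit)",
            "=" * 52,
            f"genes: {self.model.n_genes}    iterations: {self.n_iter}"
            f"    converged: {self.converged}",
            f"log likelihood: {self.llf:.4f}",
            "",
            "Gene-effect prior mean (mu):",
            "  " + np.array2string(theta.mu, precision=4),
            "Gene-effect prior covariance (Sigma):",
        ]
        for row in theta.Sigma:
            lines.append("  " + np.array2string(row, precision=4))
        lines += [
            "",
            f"probe-effect variance, expression  (sigma2): {theta.sigma2:.5f}",
            f"error variance, expression         (delta2): {theta.delta2:.5f}",
        ]
        if theta.p == 4:
            lines += [
                f"probe-effect variance, methylation (omega2): {theta.omega2:.5f}",
                f"error variance, methylation        (tau2):   {theta.tau2:.5f}",
            ]
        return "\n".join(lines)


JointEBModel.results_class = JointEBResults
ExpressionEBModel.results_class = JointEBResults
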