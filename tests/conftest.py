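"""Shared fixtures and independent oracles.

The oracle helpers deliberately use brute-force dense linear algebra
(explicit joint-Gaussian assembly, full marginal covariance) so they stay
independent of the factorized solves in the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from jointeb import (
    ExpressionTable,
    GeneBlock,
    HyperParams,
    MethylationTable,
)
from jointeb.data import build_delta, intensity_columns


# ---------------------------------------------------------------------------
# random objects


def random_psd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    a = rng.normal(size=(p, p))
    return scale * (a @ a.T + 0.5 * np.eye(p))


def random_theta(rng: np.random.Generator, p: int = 4) -> HyperParams:
    return HyperParams(
        mu=rng.normal(size=p),
        Sigma=random_psd(rng, p),
        sigma2=float(rng.uniform(0.1, 1.0)),
        delta2=float(rng.uniform(0.05, 0.5)),
        omega2=float(rng.uniform(0.1, 1.0)) if p == 4 else None,
        tau2=float(rng.uniform(0.05, 0.5)) if p == 4 else None,
    )


def random_block(
    rng: np.random.Generator, J: int, H: int, K: int, p: int = 4, gene_id: str = "g"
) -> GeneBlock:
    n_expr, n_meth = 2 * K * J, 2 * H
    return GeneBlock(
        gene_id=gene_id,
        G=rng.normal(size=n_expr),
        M=rng.normal(size=n_meth),
        J=J,
        H=H,
        K=K,
        Delta=build_delta(J, H, K, p=p),
        p=p,
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def joint_gaussian_condition(block: GeneBlock, theta: HyperParams):
    """Posterior moments of beta | D by conditioning the explicit joint Gaussian."""
    sp = theta.prior_cov(block)
    se = np.diag(theta.error_variances(block))
    mu_star = theta.mu_star(block)
    c12 = sp @ block.Delta.T
    c22 = block.Delta @ sp @ block.Delta.T + se
    sol = np.linalg.solve(c22, block.D - block.Delta @ mu_star)
    mean = mu_star + c12 @ sol
    cov = sp - c12 @ np.linalg.solve(c22, c12.T)
    return mean, 0.5 * (cov + cov.T)


def marginal_loglik_direct(block: GeneBlock, theta: HyperParams) -> float:
    """Observed-data log density via the fully assembled marginal covariance."""
    sp = theta.prior_cov(block)
    se = np.diag(theta.error_variances(block))
    cov = block.Delta @ sp @ block.Delta.T + se
    mean = block.Delta @ theta.mu_star(block)
    return float(multivariate_normal.logpdf(block.D, mean=mean, cov=cov))


# ---------------------------------------------------------------------------
# tiny hand-built tables


@pytest.fixture
def toy_expression() -> ExpressionTable:
    """Six probes over three genes, K=2, with mixed detection calls."""
    cols = intensity_columns(("cond1", "cond2"), 2)
    rows = [
        ("p1", "A", 8.0, 8.0, 4.0, 4.0),
        ("p2", "A", 2.0, 2.0, 1.0, 1.0),
        ("p3", "B", 16.0, 16.0, 8.0, 8.0),
        ("p4", "B", 4.0, 4.0, 2.0, 2.0),
        ("p5", "C", 32.0, 32.0, 16.0, 16.0),
        ("p6", "C", 8.0, 8.0, 4.0, 4.0),
    ]
    calls = [
        ("p1", "A", "P", "P", "P", "P"),
        ("p2", "A", "P", "A", "P", "P"),
        ("p3", "B", "P", "P", "A", "A"),
        ("p4", "B", "A", "A", "A", "A"),
        ("p5", "C", "P", "P", "P", "A"),
        ("p6", "C", "M", "P", "P", "P"),
    ]
    return ExpressionTable(
        data=pd.DataFrame(rows, columns=["probe_id", "gene_id", *cols]),
        calls=pd.DataFrame(calls, columns=["probe_id", "gene_id", *cols]),
        n_replicates=2,
    )


@pytest.fixture
def toy_methylation() -> MethylationTable:
    rows = [
        ("m1", "B", 4.0, 2.0),
        ("m2", "C", 8.0, 8.0),
        ("m3", "C", 2.0, 4.0),
        ("m4", "D", 16.0, 2.0),
    ]
    return MethylationTable(
        data=pd.DataFrame(rows, columns=["probe_id", "gene_id", "cond1", "cond2"])
    )
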