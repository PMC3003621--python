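"""Hyperparameters of the hierarchical model.

The gene-level 4-vector (mu_1, mu_2, eta_1, eta_2) — mean log2 expression
and methylation in each condition — is drawn from N(mu, Sigma) where Sigma
stacks the expression block Sigma_1, the methylation block Sigma_2 and a
free 2×2 cross block coupling the platforms.  Probe effects have variances
sigma2 (expression) and omega2 (methylation); measurement errors have
variances delta2 and tau2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag

from .data import GeneBlock
from .exceptions import NumericalError, ValidationError

#: eigenvalues above this may be clipped up; below -PSD_TOL the matrix is rejected
PSD_TOL = 1e-10


def repair_psd(mat: np.ndarray, name: str = "Sigma") -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues up to PSD_TOL.

    Eigenvalues below -PSD_TOL indicate a genuinely indefinite matrix and
    raise NumericalError carrying the offending eigenvalue.
    """
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    if w[0] < -PSD_TOL:
        raise NumericalError(f"{name} is not PSD: smallest eigenvalue {w[0]:.3e}")
    if w[0] < PSD_TOL:
        warnings.warn(
            f"{name} near-singular (min eigenvalue {w[0]:.3e}); clipping to {PSD_TOL}",
            stacklevel=2,
        )
        w = np.maximum(w, PSD_TOL)
        mat = (v * w) @ v.T
        mat = 0.5 * (mat + mat.T)
    return mat


@dataclass
class HyperParams:
    """Prior parameters theta = (mu, Sigma, sigma2, delta2, omega2, tau2).

    ``mu`` has length 4 for the joint model or 2 for the expression-only
    marginal model, in which case omega2/tau2 are unused and may be None.
    """

    mu: np.ndarray
    Sigma: np.ndarray = field(repr=False)
    sigma2: float
    delta2: float
    omega2: float | None = None
    tau2: float | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        p = self.p
        if p not in (2, 4):
            raise ValidationError(f"mu must have length 2 or 4, got {p}")
        if self.Sigma.shape != (p, p):
            raise ValidationError(f"Sigma must be {p}x{p}, got {self.Sigma.shape}")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-8):
            raise ValidationError("Sigma must be symmetric")
        for name in ("sigma2", "delta2") + (("omega2", "tau2") if p == 4 else ()):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValidationError(f"{name} must be a positive number, got {v}")
        self.Sigma = repair_psd(self.Sigma, "Sigma")

    @property
    def p(self) -> int:
        return len(self.mu)

    # --- named blocks -----------------------------------------------------
    @property
    def sigma_expr(self) -> np.ndarray:
        """Sigma_1: prior covariance of (mu_1, mu_2)."""
        return self.Sigma[:2, :2]

    @property
    def sigma_meth(self) -> np.ndarray:
        """Sigma_2: prior covariance of (eta_1, eta_2)."""
        return self.Sigma[2:4, 2:4]

    @property
    def sigma_cross(self) -> np.ndarray:
        """Sigma_*: cross-platform block cov((mu_1,mu_2), (eta_1,eta_2))."""
        return self.Sigma[:2, 2:4]

    # --- per-block prior pieces -------------------------------------------
    def mu_star(self, block: GeneBlock) -> np.ndarray:
        """Prior mean of the coefficient vector: (mu, 0, ..., 0)."""
        self._check_block(block)
        out = np.zeros(block.dim)
        out[: self.p] = self.mu
        return out

    def prior_cov(self, block: GeneBlock) -> np.ndarray:
        """Block-diagonal prior covariance (Sigma, sigma2*I_J, omega2*I_H)."""
        self._check_block(block)
        parts = [self.Sigma, self.sigma2 * np.eye(block.J)]
        if block.H:
            parts.append(self.omega2 * np.eye(block.H))
        return block_diag(*parts)

    def error_variances(self, block: GeneBlock) -> np.ndarray:
        """Diagonal of Sigma_e: delta2 on expression rows, tau2 on methylation rows."""
        self._check_block(block)
        out = np.empty(block.n_obs)
        out[: block.n_expr] = self.delta2
        if block.n_meth:
            out[block.n_expr:] = self.tau2
        return out

    def _check_block(self, block: GeneBlock) -> None:
        if block.p != self.p:
            raise ValidationError(
                f"block {block.gene_id} has p={block.p}, hyperparams have p={self.p}"
            )
        if block.H and self.p == 2:
            raise ValidationError("expression-only hyperparams cannot serve a joint block")

    def as_dict(self) -> dict:
        d = {
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "sigma2": float(self.sigma2),
            "delta2": float(self.delta2),
        }
        if self.p == 4:
            d["omega2"] = float(self.omega2)
            d["tau2"] = float(self.tau2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            Sigma=np.asarray(d["Sigma"], dtype=float),
            sigma2=d["sigma2"],
            delta2=d["delta2"],
            omega2=d.get("omega2"),
            tau2=d.get("tau2"),
        )

    def with_zero_cross(self) -> "HyperParams":
        """Copy with the cross-platform block of Sigma forced to zero."""
        if self.p != 4:
            return self
        s = self.Sigma.copy()
        s[:2, 2:4] = 0.0
        s[2:4, :2] = 0.0
        return HyperParams(self.mu.copy(), s, self.sigma2, self.delta2, self.omega2, self.tau2)
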