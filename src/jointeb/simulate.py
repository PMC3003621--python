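"""Synthetic probe-level datasets with known ground truth.

Samples the generative model exactly: per gene a 4-vector of condition
means (expression, methylation) from N(mu, Sigma), probe effects from
N(0, sigma2) / N(0, omega2), and measurement errors from N(0, delta2) /
N(0, tau2); expression gets K replicates per condition, methylation a
single measurement.  Optionally a fraction of genes is shifted in the
second condition to plant true regulation categories, for calibration
studies.

Defaults mimic a two-color promoter methylation array paired with a
short-oligo expression array: ~log2-scale intensities around 7 (expression)
and 9.5 (methylation), 2-4 probes per gene per platform, 4 expression
replicates, and a weak negative cross-platform coupling of the gene
effects (about -0.1 on the correlation scale), the regime reported for
promoter methylation versus transcript abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import LABELS, RegionGrid
from .data import (
    ExpressionTable,
    MethylationTable,
    intensity_columns,
    write_expression,
    write_methylation,
)
from .exceptions import ValidationError
from .params import HyperParams


def default_theta() -> HyperParams:
    """Realistic generator setting (see module docstring)."""
    s1 = np.array([[2.0, 1.8], [1.8, 2.0]])
    s2 = np.array([[1.5, 1.35], [1.35, 1.5]])
    cross = -0.1 * np.sqrt(np.outer(np.diag(s1), np.diag(s2)))
    sigma = np.block([[s1, cross], [cross.T, s2]])
    return HyperParams(
        mu=np.array([7.0, 7.0, 9.5, 9.5]),
        Sigma=sigma,
        sigma2=0.35,
        delta2=0.12,
        omega2=0.30,
        tau2=0.20,
    )


@dataclass
class ShiftSpec:
    """Plant a gene fraction at shifted condition-2 means (truth categories)."""

    fraction: float
    shift_ge: float
    shift_m: float


@dataclass
class SimConfig:
    """Generator settings; ``seed`` is mandatory for reproducibility."""

    n_genes: int
    seed: int
    K: int = 4
    probe_range: tuple[int, int] = (2, 4)        # J_i and H_i drawn uniformly
    theta: HyperParams = field(default_factory=default_theta)
    shifts: list[ShiftSpec] = field(default_factory=list)
    absent_rate: float = 0.0                     # fraction of calls marked "A"
    log2_scale: bool = True                      # False: emit 2**value intensities
    conditions: tuple[str, str] = ("cond1", "cond2")

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.K < 1:
            raise ValidationError("n_genes and K must be >= 1")
        lo, hi = self.probe_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid probe_range {self.probe_range}")
        if sum(s.fraction for s in self.shifts) > 1.0 + 1e-12:
            raise ValidationError("shift fractions must sum to at most 1")
        if not 0.0 <= self.absent_rate < 1.0:
            raise ValidationError("absent_rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene effect 4-vectors, probe effects, shift groups."""

    genes: pd.DataFrame            # gene_id, mu1, mu2, eta1, eta2, shift_group
    expr_probe_effects: pd.DataFrame
    meth_probe_effects: pd.DataFrame

    def change_pairs(self) -> np.ndarray:
        """True (expression change, methylation change) per gene."""
        g = self.genes
        return np.column_stack(
            [g["mu2"] - g["mu1"], g["eta2"] - g["eta1"]]
        )


def generate(
    config: SimConfig,
) -> tuple[ExpressionTable, MethylationTable, SyntheticTruth]:
    """Draw one dataset; byte-identical across runs with the same config."""
    rng = np.random.default_rng(config.seed)
    theta = config.theta
    I = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(1, I + 1)]

    g = rng.multivariate_normal(theta.mu, theta.Sigma, size=I, method="cholesky")
    shift_group = np.full(I, "none", dtype=object)
    cursor = 0
    for s_idx, spec in enumerate(config.shifts):
        n = int(round(spec.fraction * I))
        sel = slice(cursor, cursor + n)
        g[sel, 1] += spec.shift_ge
        g[sel, 3] += spec.shift_m
        shift_group[sel] = f"shift{s_idx}"
        cursor += n

    lo, hi = config.probe_range
    J = rng.integers(lo, hi + 1, size=I)
    H = rng.integers(lo, hi + 1, size=I)
    K = config.K

    expr_rows, call_rows, meth_rows = [], [], []
    eb_rows, ab_rows = [], []
    ecols = intensity_columns(config.conditions, K)
    for i, gene in enumerate(gene_ids):
        b = rng.normal(0.0, np.sqrt(theta.sigma2), size=J[i])
        a = rng.normal(0.0, np.sqrt(theta.omega2), size=H[i])
        for j in range(J[i]):
            eps = rng.normal(0.0, np.sqrt(theta.delta2), size=(2, K))
            vals = g[i, :2][:, None] + b[j] + eps  # condition x replicate
            expr_rows.append((f"{gene}_ep{j + 1}", gene, *vals.reshape(-1)))
            eb_rows.append((gene, j + 1, b[j]))
        for h in range(H[i]):
            d = rng.normal(0.0, np.sqrt(theta.tau2), size=2)
            vals = g[i, 2:4] + a[h] + d
            meth_rows.append((f"{gene}_mp{h + 1}", gene, *vals))
            ab_rows.append((gene, h + 1, a[h]))

    expr_df = pd.DataFrame(expr_rows, columns=["probe_id", "gene_id", *ecols])
    meth_df = pd.DataFrame(
        meth_rows, columns=["probe_id", "gene_id", *config.conditions]
    )
    calls = np.full((len(expr_df), 2 * K), "P", dtype=object)
    if config.absent_rate > 0:
        calls[rng.random(calls.shape) < config.absent_rate] = "A"
    calls_df = pd.DataFrame(calls, columns=ecols)
    calls_df.insert(0, "gene_id", expr_df["gene_id"])
    calls_df.insert(0, "probe_id", expr_df["probe_id"])

    if not config.log2_scale:
        expr_df[ecols] = 2.0 ** expr_df[ecols]
        meth_df[list(config.conditions)] = 2.0 ** meth_df[list(config.conditions)]

    expr = ExpressionTable(
        data=expr_df, calls=calls_df, n_replicates=K,
        conditions=config.conditions, is_log2=config.log2_scale,
    )
    meth = MethylationTable(
        data=meth_df, conditions=config.conditions, is_log2=config.log2_scale
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "mu1": g[:, 0], "mu2": g[:, 1],
                "eta1": g[:, 2], "eta2": g[:, 3],
                "shift_group": shift_group,
            }
        ),
        expr_probe_effects=pd.DataFrame(
            eb_rows, columns=["gene_id", "probe", "effect"]
        ),
        meth_probe_effects=pd.DataFrame(
            ab_rows, columns=["gene_id", "probe", "effect"]
        ),
    )
    return expr, meth, truth


def truth_categories(truth: SyntheticTruth, grid: RegionGrid) -> pd.Series:
    """True nine-way label per gene: region membership of the true change pair."""
    pairs = truth.change_pairs()
    labels = [grid.classify_point(x, y) for x, y in pairs]
    assert set(labels) <= set(LABELS)
    return pd.Series(labels, index=truth.genes["gene_id"].to_numpy(), name="true_category")


def write_dataset(
    expr: ExpressionTable, meth: MethylationTable, truth: SyntheticTruth, outdir
) -> dict[str, Path]:
    """Write the dataset in the package's TSV dialects plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "calls": outdir / "expression_calls.tsv",
        "methylation": outdir / "methylation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(expr, paths["expression"], paths["calls"])
    write_methylation(meth, paths["methylation"])
    truth.genes.to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    return paths
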