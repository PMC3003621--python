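"""Global and gene-level association summaries.

Covers three questions the fitted model answers beyond classification:

* how strongly expression and methylation track each other across genes,
  both within each condition and for the cross-condition changes
  (Pearson correlations of posterior means);
* how the per-gene posterior correlations are distributed (the
  gene-specific, "local" view);
* whether two analyses (e.g. two resistant lines against the same wild
  type) call the same genes, restricted to a methylation stratum;
* whether an external per-gene score (e.g. a histone-mark level) differs
  between two category-defined gene groups, as a bootstrap fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import EXPR_LEVELS, UNASSIGNED, CategoryCall
from .exceptions import ValidationError
from .posterior import DiffPosterior, GenePosterior


@dataclass
class CorrelationSummary:
    """Across-gene (global) and per-gene (local) correlation views."""

    global_within_condition: dict[str, float]   # condition label -> Pearson r
    global_of_differences: float
    gene_specific: pd.DataFrame                 # per-gene posterior correlations

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("global_within_cond1", self.global_within_condition["cond1"]),
            ("global_within_cond2", self.global_within_condition["cond2"]),
            ("global_of_differences", self.global_of_differences),
        ]
        return pd.DataFrame(rows, columns=["quantity", "pearson_r"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def correlations(
    posteriors: list[GenePosterior], diffs: list[DiffPosterior]
) -> CorrelationSummary:
    """Correlation summaries from fitted posteriors.

    Global values are Pearson correlations across genes of posterior means:
    expression vs methylation level within each condition, and expression
    change vs methylation change.  Gene-specific values are read off each
    gene's posterior covariance (off-diagonal over the square root of the
    diagonal product), both for the changes and within each condition.
    """
    if len(posteriors) < 3:
        raise ValidationError("need at least 3 genes for correlation summaries")
    if len(posteriors) != len(diffs):
        raise ValidationError("posteriors and diffs must cover the same genes")
    mu = np.array([p.mean[:4] for p in posteriors])  # mu1, mu2, eta1, eta2
    dmeans = np.array([d.mean for d in diffs])
    global_within = {
        "cond1": _pearson(mu[:, 0], mu[:, 2]),
        "cond2": _pearson(mu[:, 1], mu[:, 3]),
    }
    global_diff = _pearson(dmeans[:, 0], dmeans[:, 1])

    rows = []
    for p, d in zip(posteriors, diffs):
        v = p.cov
        rows.append(
            (
                p.gene_id,
                d.correlation,
                v[0, 2] / np.sqrt(v[0, 0] * v[2, 2]),  # corr(mu_1, eta_1)
                v[1, 3] / np.sqrt(v[1, 1] * v[3, 3]),  # corr(mu_2, eta_2)
            )
        )
    gene_df = pd.DataFrame(
        rows, columns=["gene_id", "corr_of_changes", "corr_cond1", "corr_cond2"]
    )
    return CorrelationSummary(
        global_within_condition=global_within,
        global_of_differences=global_diff,
        gene_specific=gene_df,
    )


def overlap(
    calls_a: list[CategoryCall],
    calls_b: list[CategoryCall],
    stratum: str = "HO",
) -> pd.DataFrame:
    """Cross-tabulate expression direction between two analyses within a stratum.

    A gene qualifies in an analysis when it is assigned and its methylation
    label equals ``stratum``; the table counts the intersection of the two
    qualifying sets by expression direction (rows: analysis A, columns:
    analysis B).  Cells sum to the intersection size.
    """
    a_map = {c.gene_id: c.assigned for c in calls_a}
    b_map = {c.gene_id: c.assigned for c in calls_b}
    if not set(a_map) & set(b_map):
        raise ValidationError("the two analyses share no genes")

    def qualifying(mapping):
        out = {}
        for gene, label in mapping.items():
            if label == UNASSIGNED:
                continue
            e, m = label.split("/")
            if m == stratum:
                out[gene] = e
        return out

    qa, qb = qualifying(a_map), qualifying(b_map)
    shared = sorted(set(qa) & set(qb))
    table = pd.DataFrame(0, index=list(EXPR_LEVELS), columns=list(EXPR_LEVELS), dtype=int)
    for gene in shared:
        table.loc[qa[gene], qb[gene]] += 1
    return table


@dataclass
class ContrastReport:
    """Bootstrap fold change of a per-gene score between two gene groups."""

    fold_change: float
    ci_low: float
    ci_high: float
    group_a: str
    group_b: str
    n_a: int
    n_b: int


def contrast(
    scores: pd.Series,
    group_a: set[str],
    group_b: set[str],
    n_boot: int = 10_000,
    seed: int = 0,
    label_a: str = "A",
    label_b: str = "B",
) -> ContrastReport:
    """Fold change mean(scores_a)/mean(scores_b) with a percentile bootstrap CI.

    Groups must be disjoint with at least 2 scored genes each.  The CI
    resamples genes within each group independently (95%, ``n_boot``
    replicates, seeded).
    """
    if group_a & group_b:
        raise ValidationError("score groups must be disjoint")
    a = scores.loc[scores.index.intersection(sorted(group_a))].to_numpy(dtype=float)
    b = scores.loc[scores.index.intersection(sorted(group_b))].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 genes with scores")
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("scores must be nonnegative")
    if b.mean() == 0:
        raise ValidationError("denominator group has zero mean score")
    fold = float(a.mean() / b.mean())
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    boots = a[ia].mean(axis=1) / b[ib].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ContrastReport(
        fold_change=fold, ci_low=float(lo), ci_high=float(hi),
        group_a=label_a, group_b=label_b, n_a=len(a), n_b=len(b),
    )
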