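"""Nine-category regulation calls and posterior-probability FDR.

The plane of per-gene changes (expression change, methylation change) is
cut into a 3 × 3 grid by thresholds at +-C * sd, where sd is the standard
deviation across genes of the posterior mean change on each axis
(C defaults to 1.5).  Axis levels:

* expression: DN (down-regulated), NG (no change), UP (up-regulated);
* methylation: HO (hypomethylated), NM (no change), HR (hypermethylated),

both relative to the reference condition.  Each gene's bivariate-normal
posterior assigns a probability to every rectangle; genes are then
assigned by the maximum-probability rule, optionally with a cutoff (0.6
or 0.7) below which the gene stays unassigned.  The FDR of selecting
genes whose category probability passes kappa is estimated as the mean of
(1 - probability) over the selected genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .exceptions import NumericalError, ValidationError
from .posterior import DiffPosterior

EXPR_LEVELS = ("DN", "NG", "UP")
METH_LEVELS = ("HO", "NM", "HR")
#: fixed label order — also the deterministic argmax tie-break order
LABELS = tuple(f"{e}/{m}" for e in EXPR_LEVELS for m in METH_LEVELS)
UNASSIGNED = "UNASSIGNED"

#: assignment rules and their max-probability cutoffs
RULES = {"max": 0.0, "0.6": 0.6, "0.7": 0.7}


@dataclass
class RegionGrid:
    """Axis thresholds +-c_mult * sd defining the nine rectangles."""

    c_mult: float
    sd_ge: float
    sd_m: float

    def __post_init__(self) -> None:
        if self.c_mult <= 0:
            raise ValidationError("c_mult must be > 0")
        if self.sd_ge <= 0 or self.sd_m <= 0:
            raise ValidationError("axis standard deviations must be > 0")

    @property
    def t_ge(self) -> float:
        return self.c_mult * self.sd_ge

    @property
    def t_m(self) -> float:
        return self.c_mult * self.sd_m

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([-np.inf, -self.t_ge, self.t_ge, np.inf]),
            np.array([-np.inf, -self.t_m, self.t_m, np.inf]),
        )

    def classify_point(self, ge: float, meth: float) -> str:
        """Deterministic region membership of a point (half-open [low, high) bins)."""
        ex, em = self.edges()
        i = int(np.searchsorted(ex[1:3], ge, side="right"))
        j = int(np.searchsorted(em[1:3], meth, side="right"))
        return f"{EXPR_LEVELS[i]}/{METH_LEVELS[j]}"


def build_grid(diffs: list[DiffPosterior], c_mult: float = 1.5) -> RegionGrid:
    """Thresholds from the spread of posterior mean changes across genes (sample SD)."""
    if len(diffs) < 2:
        raise ValidationError("need at least 2 genes to build the region grid")
    means = np.array([d.mean for d in diffs])
    sd = means.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("posterior mean changes are constant across genes")
    return RegionGrid(c_mult=c_mult, sd_ge=float(sd[0]), sd_m=float(sd[1]))


def region_probs(diff: DiffPosterior, grid: RegionGrid) -> np.ndarray:
    """Posterior probability of each of the nine rectangles (sums to 1).

    Rectangle probabilities come from the bivariate normal CDF over each
    axis-aligned cell; for 2-d integrands scipy evaluates these essentially
    exactly (absolute error well below 1e-7).
    """
    ex, em = grid.edges()
    probs = np.empty(9)
    idx = 0
    for i in range(3):
        for j in range(3):
            try:
                probs[idx] = multivariate_normal.cdf(
                    [ex[i + 1], em[j + 1]],
                    mean=diff.mean,
                    cov=diff.cov,
                    lower_limit=[ex[i], em[j]],
                )
            except Exception as exc:  # pragma: no cover
                raise NumericalError(
                    f"gene {diff.gene_id}: bivariate CDF failed ({exc})"
                ) from exc
            idx += 1
    probs = np.clip(probs, 0.0, 1.0)
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise NumericalError(
            f"gene {diff.gene_id}: region probabilities sum to {total:.8f}"
        )
    return probs


@dataclass
class CategoryCall:
    """One gene's nine region probabilities and its category under one rule."""

    gene_id: str
    probs: np.ndarray
    assigned: str
    rule: str
    max_prob: float

    def prob(self, label: str) -> float:
        return float(self.probs[LABELS.index(label)])


def assign(
    gene_ids: list[str], probs: np.ndarray, rule: str = "max"
) -> list[CategoryCall]:
    """Assign each gene to its maximum-probability category.

    A gene stays UNASSIGNED when its maximum falls below the rule cutoff
    (0 for "max", 0.6, 0.7).  Ties resolve to the first label in the
    fixed label order.
    """
    if rule not in RULES:
        raise ValidationError(f"unknown rule {rule!r}; choose from {sorted(RULES)}")
    cutoff = RULES[rule]
    probs = np.atleast_2d(probs)
    out = []
    for gene, p in zip(gene_ids, probs):
        k = int(np.argmax(p))
        mp = float(p[k])
        label = LABELS[k] if mp >= cutoff else UNASSIGNED
        out.append(CategoryCall(gene, p, label, rule, mp))
    return out


@dataclass
class FdrReport:
    """Posterior-probability FDR for one (category, kappa) selection."""

    category: str
    kappa: float
    n_selected: int
    d_kappa: float
    fdr_hat: float | None

    def as_row(self) -> tuple:
        return (self.category, self.kappa, self.n_selected, self.d_kappa, self.fdr_hat)


def fdr(calls: list[CategoryCall], category: str, kappa: float) -> FdrReport:
    """FDR of selecting genes with category probability >= kappa.

    D(kappa) sums (1 - P) over the selected genes; the estimate is
    D(kappa) divided by the selected-gene count (undefined when no gene
    passes, reported as fdr_hat=None).
    """
    if not 0 < kappa <= 1:
        raise ValidationError("kappa must lie in (0, 1]")
    if category not in LABELS:
        raise ValidationError(f"unknown category {category!r}")
    k = LABELS.index(category)
    ps = np.array([c.probs[k] for c in calls])
    sel = ps >= kappa
    n = int(sel.sum())
    d = float((1.0 - ps[sel]).sum())
    return FdrReport(
        category=category, kappa=kappa, n_selected=n, d_kappa=d,
        fdr_hat=(d / n) if n else None,
    )


def category_counts(calls: list[CategoryCall]) -> pd.DataFrame:
    """3 × 3 table of assigned-gene counts (methylation rows, expression columns)."""
    table = pd.DataFrame(
        0, index=list(reversed(METH_LEVELS)), columns=list(EXPR_LEVELS), dtype=int
    )
    for c in calls:
        if c.assigned == UNASSIGNED:
            continue
        e, m = c.assigned.split("/")
        table.loc[m, e] += 1
    return table


def category_table(calls_by_rule: dict[str, list[CategoryCall]]) -> pd.DataFrame:
    """Slash-separated per-rule counts, e.g. "101/45/17", in a 3 × 3 grid.

    Rows run HR (hypermethylated), NM, HO top to bottom; columns DN, NG, UP.
    All rules must cover the same genes.
    """
    gene_sets = {
        rule: tuple(c.gene_id for c in calls) for rule, calls in calls_by_rule.items()
    }
    if len(set(gene_sets.values())) != 1:
        raise ValidationError("rules were applied to different gene sets")
    counts = {rule: category_counts(calls) for rule, calls in calls_by_rule.items()}
    rules = list(calls_by_rule)
    out = pd.DataFrame(
        "", index=list(reversed(METH_LEVELS)), columns=list(EXPR_LEVELS), dtype=object
    )
    for m in out.index:
        for e in out.columns:
            out.loc[m, e] = "/".join(str(counts[r].loc[m, e]) for r in rules)
    return out


@dataclass
class ClassificationResult:
    """Full classification output for one fitted model."""

    grid: RegionGrid
    gene_ids: list[str]
    probs: np.ndarray                       # n_genes x 9
    calls: dict[str, list[CategoryCall]]    # per rule
    fdr_reports: list[FdrReport]

    def table(self) -> pd.DataFrame:
        return category_table(self.calls)

    def frame(self) -> pd.DataFrame:
        """Per-gene table: probabilities, max, assignment under each rule."""
        df = pd.DataFrame(self.probs, columns=[l.replace("/", "_") for l in LABELS])
        df.insert(0, "gene_id", self.gene_ids)
        df["max_prob"] = self.probs.max(axis=1)
        for rule, calls in self.calls.items():
            df[f"assigned_{rule}"] = [c.assigned for c in calls]
        return df


def classify_genes(
    diffs: list[DiffPosterior],
    c_mult: float = 1.5,
    rules=("max", "0.6", "0.7"),
    kappa: float = 0.9,
) -> ClassificationResult:
    """Grid construction, region probabilities, assignment and FDR in one pass."""
    grid = build_grid(diffs, c_mult=c_mult)
    gene_ids = [d.gene_id for d in diffs]
    probs = np.vstack([region_probs(d, grid) for d in diffs])
    calls = {rule: assign(gene_ids, probs, rule) for rule in rules}
    base_rule = list(rules)[0]
    reports = [fdr(calls[base_rule], label, kappa) for label in LABELS]
    return ClassificationResult(
        grid=grid, gene_ids=gene_ids, probs=probs, calls=calls, fdr_reports=reports
    )
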