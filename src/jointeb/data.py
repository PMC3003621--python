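"""Probe-level input tables and per-gene model blocks.

Expression data are probe × (replicate, condition) intensity matrices with
MAS5-style present/absent detection calls; methylation data are probe ×
condition intensities with a single measurement per condition.  After
filtering and log2 transformation, the two platforms are merged gene by
gene into stacked observation vectors with their 0/1 design matrices,
the form consumed by the hierarchical model.

Stacking convention (fixed so the design matrix is reproducible):

* expression rows ordered by (probe j outer, condition l middle,
  replicate k inner) — i.e. each probe contributes its condition-1
  replicates followed by its condition-2 replicates;
* methylation rows ordered by (probe h outer, condition l inner);
* coefficient vector ordered (mu_1, mu_2, eta_1, eta_2, b_1..b_J,
  a_1..a_H) for the joint model, (mu_1, mu_2, b_1..b_J) for the
  expression-only marginal model.

With J probes, K replicates and H methylation probes a gene contributes
N = 2*K*J expression rows and M = 2*H methylation rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DEFAULT_CONDITIONS = ("cond1", "cond2")

#: detection-call codes; "M" (marginal) counts as not present
PRESENT = "P"
CALL_CODES = frozenset({"P", "M", "A"})


def intensity_columns(conditions: tuple[str, str], n_replicates: int) -> list[str]:
    """Column names ``<cond>_rep<k>`` in (condition outer, replicate inner) order."""
    return [f"{c}_rep{k}" for c in conditions for k in range(1, n_replicates + 1)]


@dataclass
class ExpressionTable:
    """Probe-level expression intensities plus detection calls.

    ``data`` has columns ``probe_id, gene_id`` followed by the 2K intensity
    columns; ``calls`` mirrors it with single-character P/M/A cells.
    """

    data: pd.DataFrame
    calls: pd.DataFrame
    n_replicates: int
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    is_log2: bool = False

    def __post_init__(self) -> None:
        cols = intensity_columns(self.conditions, self.n_replicates)
        for name, df in (("intensities", self.data), ("calls", self.calls)):
            missing = [c for c in ["probe_id", "gene_id", *cols] if c not in df.columns]
            if missing:
                raise ValidationError(f"expression {name} table missing columns {missing}")
        if len(self.data) != len(self.calls) or not np.array_equal(
            self.data["probe_id"].to_numpy(), self.calls["probe_id"].to_numpy()
        ):
            raise ValidationError(
                "expression calls do not align with intensities probe-for-probe"
            )
        bad = set(np.unique(self.calls[cols].to_numpy())) - CALL_CODES
        if bad:
            raise ValidationError(f"unknown detection call codes {sorted(bad)}")

    @property
    def value_columns(self) -> list[str]:
        return intensity_columns(self.conditions, self.n_replicates)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.data["probe_id"].to_numpy()

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data["gene_id"].to_numpy()

    def intensities(self) -> np.ndarray:
        """Probe × 2K float matrix, columns in (condition outer, replicate inner) order."""
        return self.data[self.value_columns].to_numpy(dtype=float)


@dataclass
class MethylationTable:
    """Probe-level promoter methylation intensities, one value per condition."""

    data: pd.DataFrame
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    is_log2: bool = False

    def __post_init__(self) -> None:
        missing = [
            c for c in ["probe_id", "gene_id", *self.conditions] if c not in self.data.columns
        ]
        if missing:
            raise ValidationError(f"methylation table missing columns {missing}")

    @property
    def value_columns(self) -> list[str]:
        return list(self.conditions)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.data["probe_id"].to_numpy()

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data["gene_id"].to_numpy()

    def intensities(self) -> np.ndarray:
        return self.data[self.value_columns].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# filtering and transformation


def filter_present(
    expr: ExpressionTable, min_present: int, per_condition: bool = True
) -> ExpressionTable:
    """Keep probes with enough "present" (P) detection calls.

    With ``per_condition=True`` (default) each condition's replicate set must
    contain at least ``min_present`` P calls, so both condition means remain
    estimable; with ``per_condition=False`` the rule pools all 2K replicates.
    Probe order is preserved and the operation is idempotent.
    """
    if min_present < 0:
        raise ValidationError("min_present must be >= 0")
    calls = expr.calls
    if per_condition:
        keep = np.ones(len(calls), dtype=bool)
        for cond in expr.conditions:
            cols = [f"{cond}_rep{k}" for k in range(1, expr.n_replicates + 1)]
            keep &= (calls[cols].to_numpy() == PRESENT).sum(axis=1) >= min_present
    else:
        cols = expr.value_columns
        keep = (calls[cols].to_numpy() == PRESENT).sum(axis=1) >= min_present
    return ExpressionTable(
        data=expr.data.loc[keep].reset_index(drop=True),
        calls=expr.calls.loc[keep].reset_index(drop=True),
        n_replicates=expr.n_replicates,
        conditions=expr.conditions,
        is_log2=expr.is_log2,
    )


def log2_transform(table, floor: float | None = None):
    """Return a copy of the table with intensities replaced by log2(intensity).

    Raw intensities must be strictly positive; when ``floor`` is given,
    values below it are raised to the floor first.  A table already on the
    log2 scale is rejected rather than silently transformed twice.
    """
    if table.is_log2:
        raise ValidationError("table is already log2 transformed")
    cols = table.value_columns
    values = table.data[cols].to_numpy(dtype=float)
    if floor is not None:
        if floor <= 0:
            raise ValidationError("intensity floor must be > 0")
        values = np.maximum(values, floor)
    if np.any(values <= 0):
        rows, col_idx = np.nonzero(values <= 0)
        probes = table.data["probe_id"].to_numpy()
        offending = [(probes[r], cols[c]) for r, c in zip(rows[:10], col_idx[:10])]
        raise ValidationError(
            f"nonpositive intensities (no floor configured), e.g. {offending}"
        )
    new_data = table.data.copy()
    new_data[cols] = np.log2(values)
    return replace(table, data=new_data, is_log2=True)


def drop_multi_gene_probes(df: pd.DataFrame, platform: str) -> pd.DataFrame:
    """Drop probes listed under more than one gene (the model assumes one gene/probe)."""
    counts = df.groupby("probe_id")["gene_id"].nunique()
    multi = counts.index[counts > 1]
    if len(multi):
        warnings.warn(
            f"dropping {len(multi)} {platform} probe(s) mapped to multiple genes: "
            f"{list(multi[:5])}...",
            stacklevel=2,
        )
        df = df[~df["probe_id"].isin(multi)]
    dup = df.duplicated("probe_id")
    if dup.any():
        df = df[~dup]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene blocks


@dataclass
class GeneBlock:
    """One gene's stacked data and design matrix.

    ``G`` holds the 2*K*J log2 expression values and ``M`` the 2*H log2
    methylation values in the fixed stacking order; ``Delta`` is the
    (N+M) × (p+J+H) 0/1 design with exactly two ones per row (one
    condition-mean column, one probe-effect column).  ``p`` is 4 for the
    joint model and 2 for the expression-only marginal model (H = 0).
    """

    gene_id: str
    G: np.ndarray
    M: np.ndarray
    J: int
    H: int
    K: int
    Delta: np.ndarray = field(repr=False)
    p: int = 4

    @property
    def n_expr(self) -> int:
        return 2 * self.K * self.J

    @property
    def n_meth(self) -> int:
        return 2 * self.H

    @property
    def n_obs(self) -> int:
        return self.n_expr + self.n_meth

    @property
    def dim(self) -> int:
        """Length of the coefficient vector (p + J + H)."""
        return self.p + self.J + self.H

    @property
    def D(self) -> np.ndarray:
        """Stacked observation vector (expression rows then methylation rows)."""
        return np.concatenate([self.G, self.M])

    @property
    def shape_key(self) -> tuple[int, int, int, int]:
        return (self.J, self.H, self.K, self.p)


def build_delta(J: int, H: int, K: int, p: int = 4) -> np.ndarray:
    """Design matrix for the fixed stacking order (see module docstring)."""
    if p == 2 and H != 0:
        raise ValidationError("expression-only blocks (p=2) cannot carry methylation probes")
    n = 2 * K * J + 2 * H
    q = p + J + H
    delta = np.zeros((n, q))
    r = 0
    for j in range(J):
        for l in range(2):
            for _ in range(K):
                delta[r, l] = 1.0          # mu_{l+1}
                delta[r, p + j] = 1.0      # b_j
                r += 1
    for h in range(H):
        for l in range(2):
            delta[r, 2 + l] = 1.0          # eta_{l+1}
            delta[r, p + J + h] = 1.0      # a_h
            r += 1
    return delta


def build_gene_blocks(
    expr: ExpressionTable, meth: MethylationTable
) -> tuple[list[GeneBlock], dict[str, str]]:
    """Merge the two platforms into per-gene blocks.

    Only genes present on both platforms (with >= 1 probe each after
    filtering) are modeled; the returned skip report maps each excluded
    gene to the platform it is missing from.  Both tables must already be
    log2 transformed.
    """
    for t, name in ((expr, "expression"), (meth, "methylation")):
        if not t.is_log2:
            raise ValidationError(f"{name} table must be log2 transformed first")
    edf = drop_multi_gene_probes(expr.data, "expression")
    mdf = drop_multi_gene_probes(meth.data, "methylation")
    expr_genes = dict(iter(edf.groupby("gene_id", sort=True)))
    meth_genes = dict(iter(mdf.groupby("gene_id", sort=True)))

    skip: dict[str, str] = {}
    for g in expr_genes.keys() - meth_genes.keys():
        skip[g] = "no methylation probes"
    for g in meth_genes.keys() - expr_genes.keys():
        skip[g] = "no expression probes"

    K = expr.n_replicates
    ecols = expr.value_columns
    mcols = meth.value_columns
    blocks = []
    for gene in sorted(expr_genes.keys() & meth_genes.keys()):
        ev = expr_genes[gene][ecols].to_numpy(dtype=float)
        mv = meth_genes[gene][mcols].to_numpy(dtype=float)
        if np.isnan(ev).any() or np.isnan(mv).any():
            raise ValidationError(f"gene {gene}: missing values are not supported")
        J, H = len(ev), len(mv)
        blocks.append(
            GeneBlock(
                gene_id=gene,
                G=ev.reshape(-1),
                M=mv.reshape(-1),
                J=J,
                H=H,
                K=K,
                Delta=build_delta(J, H, K, p=4),
            )
        )
    return blocks, skip


def build_expression_blocks(expr: ExpressionTable) -> list[GeneBlock]:
    """Expression-only blocks (p = 2) for the marginal expression model."""
    if not expr.is_log2:
        raise ValidationError("expression table must be log2 transformed first")
    edf = drop_multi_gene_probes(expr.data, "expression")
    K = expr.n_replicates
    ecols = expr.value_columns
    blocks = []
    for gene, sub in edf.groupby("gene_id", sort=True):
        ev = sub[ecols].to_numpy(dtype=float)
        J = len(ev)
        blocks.append(
            GeneBlock(
                gene_id=gene,
                G=ev.reshape(-1),
                M=np.empty(0),
                J=J,
                H=0,
                K=K,
                Delta=build_delta(J, 0, K, p=2),
                p=2,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# TSV serialization (17 significant digits so a write/read round trip is exact)

_FLOAT_FMT = "%.17g"


def read_expression(
    intensities_path,
    calls_path,
    conditions: tuple[str, str] = DEFAULT_CONDITIONS,
    is_log2: bool = False,
) -> ExpressionTable:
    data = pd.read_csv(
        intensities_path, sep="\t", dtype={"probe_id": str, "gene_id": str},
        float_precision="round_trip",
    )
    calls = pd.read_csv(calls_path, sep="\t", dtype=str)
    n_value_cols = len(data.columns) - 2
    if n_value_cols < 2 or n_value_cols % 2:
        raise ValidationError(
            f"expression table must have 2K intensity columns, found {n_value_cols}"
        )
    return ExpressionTable(
        data=data, calls=calls, n_replicates=n_value_cols // 2,
        conditions=conditions, is_log2=is_log2,
    )


def read_methylation(
    path, conditions: tuple[str, str] = DEFAULT_CONDITIONS, is_log2: bool = False
) -> MethylationTable:
    data = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "gene_id": str},
        float_precision="round_trip",
    )
    return MethylationTable(data=data, conditions=conditions, is_log2=is_log2)


def write_expression(expr: ExpressionTable, intensities_path, calls_path) -> None:
    expr.data.to_csv(intensities_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    expr.calls.to_csv(calls_path, sep="\t", index=False)


def write_methylation(meth: MethylationTable, path) -> None:
    meth.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
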