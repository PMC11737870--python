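"""Single-cell preprocessing: QC filters, library-size normalization,
log10 transform, and mean-CV noise-model variable-gene selection.

The processing order is fixed: cell QC -> gene filter -> size factors ->
normalization -> class exclusions -> variable genes, so that removed cells
never influence the size factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, _check_unique

__all__ = [
    "QCReport",
    "SizeFactors",
    "ExpressionMatrix",
    "VariableGeneResult",
    "qc_filter",
    "compute_size_factors",
    "normalize_log10",
    "select_variable_genes",
]


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_removed: int
    removed_ids: list[str]
    n_genes_removed: int
    total_umi: np.ndarray  # per retained cell
    n_genes_detected: np.ndarray  # per retained cell
    median_total_umi: float
    median_genes_per_cell: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"total_umi": self.total_umi,
                             "n_genes_detected": self.n_genes_detected})


@dataclass
class SizeFactors:
    """Per-cell library-size factors: total UMI / median of totals.

    By construction the median factor is 1.
    """

    factor: np.ndarray
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.factor = np.asarray(self.factor, dtype=float)
        if (self.factor <= 0).any():
            raise ValueError("size factors must be strictly positive")
        if abs(float(np.median(self.factor)) - 1.0) > 1e-9:
            raise ValueError("median size factor must be 1")
        if len(self.factor) != len(self.column_ids):
            raise ValueError("factor vector and column ids disagree in length")


@dataclass
class ExpressionMatrix:
    """Real-valued normalized/log matrix, genes x columns.

    ``transform_tag`` records how the values were produced (normalization,
    log base, pseudocount, order of operations).
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    transform_tag: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError("shape does not match label vectors")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if not self.transform_tag:
            raise ValueError("transform_tag must be populated")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(self.values[idx], list(genes), list(self.column_ids),
                                dict(self.transform_tag))


@dataclass
class VariableGeneResult:
    selected: list[str]
    table: pd.DataFrame  # per eligible gene: mean, cv, score
    excluded_by_class: list[str]


def qc_filter(counts: CountMatrix, min_cell_umi: int = 200) -> tuple[CountMatrix, QCReport]:
    """Remove low-coverage cells, then undetected genes.

    Cells with total UMI strictly below ``min_cell_umi`` are excluded; genes
    with zero total count across the retained cells are then dropped.  The
    report's medians are computed over retained cells (mid-mean convention
    for even counts).
    """
    totals = counts.values.sum(axis=0)
    keep_cells = totals >= min_cell_umi
    if not keep_cells.any():
        raise ValueError("no cells pass QC: every cell is below the UMI threshold")
    removed = [c for c, k in zip(counts.column_ids, keep_cells) if not k]
    vals = counts.values[:, keep_cells]
    keep_genes = vals.sum(axis=1) > 0
    vals = vals[keep_genes]
    out = CountMatrix(
        vals,
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
        [c for c, k in zip(counts.column_ids, keep_cells) if k],
        layer_tag=counts.layer_tag,
    )
    cell_totals = out.values.sum(axis=0)
    genes_detected = (out.values > 0).sum(axis=0)
    report = QCReport(
        n_cells_in=len(counts.column_ids),
        n_cells_removed=len(removed),
        removed_ids=removed,
        n_genes_removed=int((~keep_genes).sum()),
        total_umi=cell_totals,
        n_genes_detected=genes_detected,
        median_total_umi=float(np.median(cell_totals)),
        median_genes_per_cell=float(np.median(genes_detected)),
    )
    return out, report


def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """factor_c = total UMI of cell c / median total UMI across cells."""
    totals = counts.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        zero = counts.column_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {zero!r} has zero total count; run qc_filter first")
    return SizeFactors(totals / np.median(totals), list(counts.column_ids))


def normalize_log10(counts: CountMatrix, factors: SizeFactors) -> ExpressionMatrix:
    """value_gc = log10(count_gc / factor_c + 1)."""
    if factors.column_ids != counts.column_ids:
        raise ValueError("size-factor vector is not aligned to the matrix columns")
    vals = np.log10(counts.values / factors.factor[np.newaxis, :] + 1.0)
    tag = {"normalization": "library_size_median", "log_base": 10,
           "pseudocount": 1, "order": "normalize_then_log"}
    return ExpressionMatrix(vals, list(counts.gene_ids), list(counts.column_ids), tag)


def _delog(expr: ExpressionMatrix) -> np.ndarray:
    base = expr.transform_tag.get("log_base", 10)
    pc = expr.transform_tag.get("pseudocount", 1)
    return np.power(float(base), expr.values) - pc


def select_variable_genes(
    expr: ExpressionMatrix,
    n: int,
    exclusion_patterns: Sequence[str] = (),
    cell_cycle_genes: Sequence[str] = (),
    noise_model: str = "rolling_median",
) -> VariableGeneResult:
    """Select the ``n`` most variable genes under a mean-CV noise model.

    Per-gene mean and coefficient of variation (SD/mean) are computed on
    de-logged normalized values.  The expected log CV at a given log mean is
    estimated by a rolling median over mean-ordered genes (window
    ``max(25, 1% of eligible genes)``); a gene's score is its observed log CV
    minus that expectation.  With ``noise_model='poisson'`` the expectation
    is the Poisson baseline ``CV = mean**-0.5`` instead.  Genes matching an
    exclusion prefix (ribosomal classes by default) or the explicit
    cell-cycle list are ineligible.  Ties in score break lexicographically.
    """
    excluded = []
    cc = set(cell_cycle_genes)
    for g in expr.gene_ids:
        if g in cc or any(g.startswith(p) for p in exclusion_patterns):
            excluded.append(g)
    excluded_set = set(excluded)
    eligible = [g for g in expr.gene_ids if g not in excluded_set]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} variable genes but only {len(eligible)} eligible "
            f"({len(excluded)} excluded by class)"
        )
    lin = _delog(expr)
    idx = [i for i, g in enumerate(expr.gene_ids) if g not in excluded_set]
    sub = lin[idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    if (mean <= 0).any():
        raise ValueError("gene with zero mean among eligible genes; run qc_filter first")
    with np.errstate(divide="ignore"):
        log_cv = np.log(sd / mean)  # -inf for constant genes; they can never win
        log_mean = np.log(mean)
    tab = pd.DataFrame({"gene": eligible, "mean": mean, "cv": sd / mean,
                        "log_mean": log_mean, "log_cv": log_cv})
    if noise_model == "poisson":
        tab["expected_log_cv"] = -0.5 * tab["log_mean"]
    elif noise_model == "rolling_median":
        window = max(25, int(np.ceil(0.01 * len(eligible))))
        order = tab.sort_values(["log_mean", "gene"], kind="stable")
        finite = order["log_cv"].replace(-np.inf, np.nan)
        rolled = finite.rolling(window, center=True, min_periods=1).median()
        tab["expected_log_cv"] = rolled.reindex(tab.index)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    tab["score"] = tab["log_cv"] - tab["expected_log_cv"]
    tab.loc[~np.isfinite(tab["score"]), "score"] = -np.inf
    ranked = tab.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    selected = ranked["gene"].head(n).tolist()
    if not np.isfinite(ranked["score"].iloc[n - 1]):
        warnings.warn("variable-gene selection reached genes with degenerate scores")
    return VariableGeneResult(selected=selected,
                              table=tab.set_index("gene")[["mean", "cv", "score"]],
                              excluded_by_class=excluded)
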