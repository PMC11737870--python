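"""Differential expression: two-sided t-tests and one-way ANOVA with
Benjamini-Hochberg FDR control and fold-change filters.

All tests operate on log-transformed expression (log2 for bulk, log10 for
single cell); fold changes are reported on the log2 scale regardless of the
matrix's own log base.  Zero-variance genes with equal group means get
p = 1 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .kinetics import TimeCourseMatrix
from .preprocess import ExpressionMatrix

__all__ = [
    "DEGResult",
    "bh_adjust",
    "ttest_deg",
    "anova_deg",
    "multi_contrast_union",
]


@dataclass
class DEGResult:
    table: pd.DataFrame  # per gene: statistic, p_value, q_value, log2_fold_change, pass
    contrast: str
    fdr_q: float
    min_fold: float | None = None

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])

    def __len__(self) -> int:
        return len(self.table)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values).

    Rejecting genes with ``q <= alpha`` is equivalent to the step-up rule at
    level ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_scale_factor(mat) -> float:
    """Multiplier converting the matrix's log base to log2."""
    base = 2
    if isinstance(mat, ExpressionMatrix):
        base = mat.transform_tag.get("log_base", 2)
    return float(np.log2(float(base)))


def _values_and_genes(mat) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(mat, ExpressionMatrix):
        return mat.values, list(mat.gene_ids), list(mat.column_ids)
    if isinstance(mat, TimeCourseMatrix):
        return mat.values, list(mat.gene_ids), list(mat.sample_ids)
    if isinstance(mat, pd.DataFrame):
        return mat.to_numpy(dtype=float), list(mat.index.astype(str)), list(mat.columns.astype(str))
    raise TypeError(f"unsupported matrix type {type(mat).__name__}")


def _column_index(column_ids: list[str], cols: Sequence[str]) -> np.ndarray:
    pos = {c: i for i, c in enumerate(column_ids)}
    missing = [c for c in cols if c not in pos]
    if missing:
        raise ValueError(f"column(s) not in matrix: {missing[:5]}")
    return np.array([pos[c] for c in cols])


def ttest_deg(mat, group_a: Sequence[str], group_b: Sequence[str],
              fdr_q: float = 0.05, min_fold: float | None = None,
              equal_var: bool = True, contrast: str | None = None) -> DEGResult:
    """Per-gene two-sided two-sample t-test (pooled variance by default,
    Welch with ``equal_var=False``) of group_a vs group_b, BH-adjusted
    across genes.

    ``log2_fold_change`` is mean(a) − mean(b) on the log2 scale; with
    ``min_fold`` set, passing additionally requires
    ``|log2_fold_change| >= log2(min_fold)``.
    """
    values, genes, columns = _values_and_genes(mat)
    ia = _column_index(columns, group_a)
    ib = _column_index(columns, group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    a, b = values[:, ia], values[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    # zero pooled variance: equal means -> no evidence (p=1); unequal -> certain (p~0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    q = bh_adjust(p)
    lfc = diff * _log2_scale_factor(mat)
    ok = q <= fdr_q
    if min_fold is not None:
        ok &= np.abs(lfc) >= np.log2(min_fold)
    table = pd.DataFrame({"statistic": t, "p_value": p, "q_value": q,
                          "log2_fold_change": lfc, "pass": ok}, index=genes)
    return DEGResult(table=table, contrast=contrast or "group_a_vs_group_b",
                     fdr_q=fdr_q, min_fold=min_fold)


def anova_deg(mat, groups: Mapping[str, Sequence[str]], fdr_q: float = 0.05,
              min_fold: float = 2.0) -> DEGResult:
    """Per-gene one-way ANOVA across >= 3 groups with BH FDR and a
    fold-change filter.

    The fold filter de-logs the per-group mean log2 expression and requires
    max/min group mean >= ``min_fold``.
    """
    if len(groups) < 3:
        raise ValueError("ANOVA needs >= 3 groups; use ttest_deg for two groups")
    values, genes, columns = _values_and_genes(mat)
    blocks = []
    for name, cols in groups.items():
        idx = _column_index(columns, cols)
        if len(idx) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        blocks.append(values[:, idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = scipy.stats.f_oneway(*blocks, axis=1)
    degenerate = ~np.isfinite(p)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    log2_scale = _log2_scale_factor(mat)
    group_means_log2 = np.column_stack([blk.mean(axis=1) * log2_scale for blk in blocks])
    linear = np.power(2.0, group_means_log2)
    fold = linear.max(axis=1) / linear.min(axis=1)
    lfc = group_means_log2.max(axis=1) - group_means_log2.min(axis=1)
    ok = (q <= fdr_q) & (fold >= min_fold)
    table = pd.DataFrame({"statistic": f, "p_value": p, "q_value": q,
                          "log2_fold_change": lfc, "pass": ok}, index=genes)
    return DEGResult(table=table, contrast="anova:" + "|".join(groups),
                     fdr_q=fdr_q, min_fold=min_fold)


def multi_contrast_union(mat, contrasts: Mapping[str, tuple[Sequence[str], Sequence[str]]],
                         fdr_q: float = 0.05, min_fold: float | None = None,
                         equal_var: bool = True) -> pd.DataFrame:
    """Union of t-test DEGs over several contrasts.

    Each contrast is tested (and BH-adjusted) separately at ``fdr_q``; the
    result lists every gene passing at least one contrast, annotated with
    the contrasts it passed.
    """
    if not contrasts:
        raise ValueError("empty contrast list")
    passed: dict[str, list[str]] = {}
    for name, (ga, gb) in contrasts.items():
        res = ttest_deg(mat, ga, gb, fdr_q=fdr_q, min_fold=min_fold,
                        equal_var=equal_var, contrast=name)
        for g in res.passing:
            passed.setdefault(g, []).append(name)
    rows = [{"gene": g, "n_contrasts": len(cs), "contrasts": ",".join(cs)}
            for g, cs in sorted(passed.items())]
    return pd.DataFrame(rows, columns=["gene", "n_contrasts", "contrasts"]).set_index("gene")
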