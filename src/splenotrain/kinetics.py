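"""Bulk time-course processing and the integral-difference training-gene
caller.

A bulk experiment profiles whole-spleen (or sorted-population) RNA at a
series of days post-vaccination, in two conditions (``control`` vs
``trained``), with replicates.  Genes whose trained-condition trajectory
encloses more area than the control trajectory — the per-gene integral
difference ``D``, in log2·days — are candidate training-induced genes.  The
bulk of genes are unaffected by training, so the distribution of ``D``
across all genes serves as an empirical null: a normal is fitted by sample
moments and genes exceeding ``mean + k·SD`` (``k`` = 3 by default) are
called up-regulated due to training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, _check_unique

__all__ = [
    "TimeCourseMatrix",
    "AveragedTrajectories",
    "TrainingCallResult",
    "prepare_bulk",
    "average_replicates",
    "integral_difference",
    "call_training_genes",
    "bulk_pca",
]


@dataclass
class TimeCourseMatrix:
    """log2-scale bulk expression with per-sample design annotations."""

    values: np.ndarray  # genes x samples, log2 scale
    gene_ids: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame  # condition, timepoint_days, replicate per sample
    floor_applied: float = 0.0
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("shape does not match label vectors")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if list(self.metadata["column_id"]) != list(self.sample_ids):
            raise ValueError("metadata rows are not aligned to samples")
        if np.isnan(self.values).any():
            raise ValueError("time-course matrix contains NaN")
        if self.values.min() < self.floor_applied - 1e-9:
            raise ValueError("values below the applied expression floor")
        counts = self.metadata.groupby(["condition", "timepoint_days"]).size()
        if (counts < 1).any():  # pragma: no cover - groupby cannot emit 0
            raise ValueError("a condition x timepoint cell has no samples")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class AveragedTrajectories:
    """Replicate-averaged log2 trajectories per condition."""

    mean_log2: dict[str, np.ndarray]  # condition -> genes x timepoints
    timepoints_days: list[float]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_days, dtype=float)
        if len(tp) >= 2 and not (np.diff(tp) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        for cond, arr in self.mean_log2.items():
            if arr.shape != (len(self.gene_ids), len(tp)):
                raise ValueError(f"trajectory block for {cond!r} has wrong shape")
            if np.isnan(arr).any():
                raise ValueError(f"NaN in averaged trajectories for {cond!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.mean_log2)


@dataclass
class TrainingCallResult:
    D: pd.Series  # per-gene integral difference, log2*days
    null_mean: float
    null_sd: float
    sd_multiplier: float
    threshold: float
    upregulated: list[str]
    downregulated: list[str] | None = None


def prepare_bulk(
    counts: CountMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    floor: float = 3.0,
    exclusions: Sequence[tuple[str, str]] = (),
    already_log2: bool = False,
) -> TimeCourseMatrix:
    """Normalize, log2-transform and floor a bulk count matrix.

    Library scaling divides each sample by (its total count / median of
    totals), log2(x+1) is applied, and values below ``floor`` are raised to
    ``floor``.  ``exclusions`` is a list of ``(sample_id, reason)`` pairs
    removed before normalization (e.g. low-coverage replicates); the
    removals are recorded on the result.  With ``already_log2`` the input is
    taken as log2 values and only flooring/exclusion applies.
    """
    if isinstance(counts, CountMatrix):
        frame = counts.to_frame().astype(float)
    else:
        frame = counts.astype(float)
    meta = metadata.set_index("column_id", drop=False)
    missing = [c for c in frame.columns if c not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for sample(s): {missing[:5]}")
    drop = {s for s, _ in exclusions}
    unknown = drop - set(frame.columns)
    if unknown:
        raise ValueError(f"excluded sample(s) not in matrix: {sorted(unknown)}")
    kept = [c for c in frame.columns if c not in drop]
    before = meta.loc[list(frame.columns)].groupby(["condition", "timepoint_days"]).size()
    after = meta.loc[kept].groupby(["condition", "timepoint_days"]).size() if kept else before.iloc[:0]
    emptied = set(before.index) - set(after.index)
    if emptied:
        raise ValueError(f"exclusions empty condition x timepoint cell(s): {sorted(emptied)}")
    frame = frame[kept]
    vals = frame.to_numpy()
    if not already_log2:
        totals = vals.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        factors = totals / np.median(totals)
        vals = np.log2(vals / factors[np.newaxis, :] + 1.0)
    vals = np.maximum(vals, floor)
    return TimeCourseMatrix(
        values=vals,
        gene_ids=list(frame.index.astype(str)),
        sample_ids=kept,
        metadata=meta.loc[kept].reset_index(drop=True),
        floor_applied=floor,
        exclusions=list(exclusions),
    )


def average_replicates(tc: TimeCourseMatrix) -> AveragedTrajectories:
    """Arithmetic mean per gene for every condition x timepoint."""
    if np.isnan(tc.values).any():
        raise ValueError("NaN entries in time-course matrix")
    timepoints = sorted(tc.metadata["timepoint_days"].unique())
    conditions = list(dict.fromkeys(tc.metadata["condition"]))
    blocks: dict[str, np.ndarray] = {}
    for cond in conditions:
        cols = []
        for t in timepoints:
            sel = (tc.metadata["condition"] == cond) & (tc.metadata["timepoint_days"] == t)
            if not sel.any():
                raise ValueError(f"condition {cond!r} has no samples at day {t}")
            cols.append(tc.values[:, sel.to_numpy()].mean(axis=1))
        blocks[cond] = np.column_stack(cols)
    return AveragedTrajectories(blocks, [float(t) for t in timepoints], list(tc.gene_ids))


def integral_difference(avg: AveragedTrajectories, treated: str = "trained",
                        control: str = "control") -> pd.Series:
    """Per-gene difference of trapezoidal areas under the log2 trajectories.

    ``D_g = ∫ treated_g(t) dt − ∫ control_g(t) dt`` over the observed days
    (unequal spacing respected, no extrapolation); units are log2·days.
    """
    for cond in (treated, control):
        if cond not in avg.mean_log2:
            raise ValueError(f"condition {cond!r} absent from averaged trajectories")
    if len(avg.timepoints_days) < 2:
        raise ValueError("integral difference needs at least 2 timepoints")
    t = np.asarray(avg.timepoints_days, dtype=float)
    area_t = np.trapezoid(avg.mean_log2[treated], x=t, axis=1)
    area_c = np.trapezoid(avg.mean_log2[control], x=t, axis=1)
    return pd.Series(area_t - area_c, index=avg.gene_ids, name="D")


def call_training_genes(D: pd.Series, sd_multiplier: float = 3.0,
                        call_down: bool = False,
                        robust: bool = False) -> TrainingCallResult:
    """Call training-up-regulated genes by a fitted-normal tail rule.

    The null is fitted to *all* genes by sample moments (mean, SD); genes
    with ``D`` strictly above ``mean + sd_multiplier·SD`` are called.  With
    ``robust=True`` the fit uses median and 1.4826·MAD instead.  A symmetric
    down-call (``mean − k·SD``) is available behind ``call_down``.
    """
    if len(D) < 2:
        raise ValueError("need at least 2 genes to fit the null")
    vals = D.to_numpy(dtype=float)
    if robust:
        mu = float(np.median(vals))
        sd = float(1.4826 * np.median(np.abs(vals - mu)))
    else:
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
    threshold = mu + sd_multiplier * sd
    if sd == 0.0:
        warnings.warn("integral differences have zero spread; no genes called")
        up: list[str] = []
        down: list[str] = []
    else:
        up = list(D.index[vals > threshold])
        down = list(D.index[vals < mu - sd_multiplier * sd])
    return TrainingCallResult(
        D=D, null_mean=mu, null_sd=sd, sd_multiplier=sd_multiplier,
        threshold=threshold, upregulated=up,
        downregulated=down if call_down else None,
    )


def bulk_pca(tc: TimeCourseMatrix, gene_subset: Sequence[str] | None = None,
             n_pcs: int | None = None):
    """PCA of samples after per-gene z-scoring (mean 0, SD 1 across samples).

    Zero-variance genes are dropped with a warning.  Returns an
    :class:`~splenotrain.cluster.Embedding` whose coordinates are samples x
    components.
    """
    from .cluster import _pca_embed  # local import avoids a cycle

    if len(tc.sample_ids) < 2:
        raise ValueError("bulk PCA needs at least 2 samples")
    vals = tc.values
    genes = list(tc.gene_ids)
    if gene_subset is not None:
        pos = {g: i for i, g in enumerate(genes)}
        missing = [g for g in gene_subset if g not in pos]
        if missing:
            raise ValueError(f"gene_subset not in matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_subset]
        vals = vals[idx]
        genes = list(gene_subset)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance across samples")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance gene(s) before PCA")
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, np.newaxis]
    genes = [g for g, k in zip(genes, keep) if k]
    if n_pcs is None:
        n_pcs = min(len(tc.sample_ids) - 1, len(genes))
    return _pca_embed(z.T, n_pcs, obs_ids=list(tc.sample_ids), feature_ids=genes)
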