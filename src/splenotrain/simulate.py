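"""Synthetic data with known ground truth.

Two generators emulate the statistical structure of a BCG trained-immunity
study in the mouse spleen:

* ``simulate_sc_counts`` — a two-condition (control / trained) MARS-seq-like
  scRNA-seq experiment: ~768 sorted myeloid cells per condition drawn from
  6 cell types, gamma-distributed per-gene baseline expression, log-normal
  library sizes, gamma-Poisson (negative binomial) counts, per-type marker
  genes, and a "training program" gene module induced only in
  trained-condition cells of the target type(s) (the CM-T phenomenon:
  STAT1-driven genes such as Gbp2/Ly6a/Cxcl9/Irg1 restricted to trained
  classical monocytes).

* ``simulate_bulk_timecourse`` — bulk expression at days 3/14/30/45/60 post
  vaccination with replicates per condition x timepoint, a Gaussian log2
  baseline shared by both conditions, planted training-responsive genes
  following early-transient / sustained / delayed piecewise-linear
  profiles, and additive Gaussian noise on the log2 scale.

Both are fully reproducible from their spec's ``rng_seed``; the emitted
truth is the only record of the planted signal and is written beside the
data by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix
from .kinetics import TimeCourseMatrix

__all__ = [
    "ScSimSpec",
    "BulkSimSpec",
    "SimTruth",
    "ScSimResult",
    "BulkSimResult",
    "simulate_sc_counts",
    "simulate_bulk_timecourse",
    "PROFILE_SHAPES",
    "profile_template",
]


def _default_proportions() -> dict[str, float]:
    # splenic CD11b+ myeloid compartment: monocytes, DC2 subsets, neutrophils, NK
    return {"CM": 0.30, "NCM": 0.20, "cDC2": 0.15, "mcDC2": 0.12,
            "Neutrophil": 0.13, "NK": 0.10}


@dataclass
class ScSimSpec:
    """Parameters of the synthetic two-condition scRNA-seq experiment."""

    n_cells_per_condition: int = 768
    cell_type_proportions: dict[str, float] = field(default_factory=_default_proportions)
    n_genes: int = 2000
    markers_per_type: int = 12
    marker_log_fold: float = 2.5  # log2 units
    training_program_genes: int = 25
    training_log_fold: float = 2.0  # log2 units
    training_target_types: tuple[str, ...] = ("CM",)
    libsize_log_mean: float = 7.3  # natural log; median library ~1480 UMIs
    libsize_log_sd: float = 0.35
    baseline_shape: float = 0.5  # gamma prior on per-gene expression weight
    baseline_rate: float = 1.0
    nb_dispersion: float = 0.25  # gamma-Poisson overdispersion
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions sum to {total}, not 1")
        for name in ("n_cells_per_condition", "n_genes", "markers_per_type",
                     "training_program_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.training_target_types) - set(self.cell_type_proportions)
        if unknown:
            raise ValueError(f"unknown training target type(s): {sorted(unknown)}")


#: piecewise-linear profile templates on the day axis (value in [0, 1]);
#: early_transient peaks at day 14 and is back to baseline by day 30,
#: sustained rises by day 14 and stays, delayed rises only from day 30
PROFILE_SHAPES: dict[str, tuple[list[float], list[float]]] = {
    "early_transient": ([0.0, 14.0, 30.0], [0.0, 1.0, 0.0]),
    "sustained": ([0.0, 14.0], [0.0, 1.0]),
    "delayed": ([30.0, 45.0], [0.0, 1.0]),
}


def profile_template(shape: str, days: np.ndarray | list[float]) -> np.ndarray:
    """Evaluate a response-profile template at the given days."""
    xp, fp = PROFILE_SHAPES[shape]
    return np.interp(np.asarray(days, dtype=float), xp, fp)


@dataclass
class BulkSimSpec:
    """Parameters of the synthetic bulk vaccination time course."""

    timepoints_days: tuple[float, ...] = (3.0, 14.0, 30.0, 45.0, 60.0)
    replicates: int = 3
    n_genes: int = 5000
    responsive_fraction: float = 0.05
    profile_shapes: tuple[str, ...] = ("early_transient", "sustained", "delayed")
    effect_log2: float = 3.0
    noise_sd_log2: float = 0.3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_days, dtype=float)
        if len(tp) < 2 or not (np.diff(tp) > 0).all():
            raise ValueError("timepoints must be >= 2 and strictly increasing")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (downstream tests need them)")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        unknown = set(self.profile_shapes) - set(PROFILE_SHAPES)
        if unknown:
            raise ValueError(f"unknown profile shape(s): {sorted(unknown)}")
        if self.responsive_fraction > 0 and not self.profile_shapes:
            raise ValueError("profile_shapes empty but responsive_fraction > 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``responsive_genes`` carries one row per planted bulk gene (gene, shape,
    effect_log2); ``marker_genes_of`` maps each simulated cell type to its
    planted marker panel.
    """

    cell_type_of: dict[str, str] = field(default_factory=dict)
    responsive_genes: pd.DataFrame | None = None
    program_genes: list[str] = field(default_factory=list)
    marker_genes_of: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class ScSimResult:
    counts: CountMatrix
    metadata: pd.DataFrame
    truth: SimTruth


@dataclass
class BulkSimResult:
    timecourse: TimeCourseMatrix  # log2 scale, the pipeline's native entry
    counts: CountMatrix  # rounded linear-scale counts for pipeline-entry testing
    metadata: pd.DataFrame
    truth: SimTruth


def simulate_sc_counts(spec: ScSimSpec) -> ScSimResult:
    """Draw a two-condition scRNA-seq count matrix with known truth.

    Counts are gamma-Poisson per gene x cell around ``p_g * libsize_c``,
    where the per-gene weights ``p`` are gamma-distributed and renormalized
    per cell type after marker/program fold boosts.  Marker genes are
    boosted ``2**marker_log_fold``-fold in their own type; program genes are
    boosted ``2**training_log_fold``-fold only in trained-condition cells of
    the target types.  Markers and program genes are drawn from
    above-median-weight genes so the planted panels are robustly detected,
    as real marker genes are.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    types = list(spec.cell_type_proportions)
    w = rng.gamma(spec.baseline_shape, 1.0 / spec.baseline_rate, size=spec.n_genes)
    w = np.maximum(w, 1e-12)
    well_expressed = np.flatnonzero(w >= np.median(w))
    n_special = spec.markers_per_type * len(types) + spec.training_program_genes
    if n_special > len(well_expressed):
        raise ValueError("too few well-expressed genes for the requested markers/program")
    special = rng.choice(well_expressed, size=n_special, replace=False)
    marker_of: dict[str, list[int]] = {}
    for i, t in enumerate(types):
        marker_of[t] = list(special[i * spec.markers_per_type:(i + 1) * spec.markers_per_type])
    program_idx = list(special[spec.markers_per_type * len(types):])

    # per (type, condition) expected expression fractions
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for t in types:
        base = w.copy()
        base[marker_of[t]] *= 2.0 ** spec.marker_log_fold
        for cond in ("control", "trained"):
            p = base.copy()
            if cond == "trained" and t in spec.training_target_types:
                p[program_idx] *= 2.0 ** spec.training_log_fold
            profiles[(t, cond)] = p / p.sum()

    prop = np.array([spec.cell_type_proportions[t] for t in types])
    columns: list[str] = []
    cond_of: list[str] = []
    type_of: list[str] = []
    blocks: list[np.ndarray] = []
    disp = spec.nb_dispersion
    for cond, tag in (("control", "ctrl"), ("trained", "trn")):
        assigned = rng.choice(len(types), size=spec.n_cells_per_condition, p=prop)
        libs = rng.lognormal(spec.libsize_log_mean, spec.libsize_log_sd,
                             size=spec.n_cells_per_condition)
        counts_cond = np.empty((spec.n_genes, spec.n_cells_per_condition), dtype=np.int64)
        for ti, t in enumerate(types):
            cells = np.flatnonzero(assigned == ti)
            if cells.size == 0:
                continue
            mu = np.outer(profiles[(t, cond)], libs[cells])
            if disp > 0:
                lam = rng.gamma(1.0 / disp, mu * disp)
            else:
                lam = mu
            counts_cond[:, cells] = rng.poisson(lam)
        columns += [f"{tag}_{i:04d}" for i in range(spec.n_cells_per_condition)]
        cond_of += [cond] * spec.n_cells_per_condition
        type_of += [types[a] for a in assigned]
        blocks.append(counts_cond)

    cm = CountMatrix(np.concatenate(blocks, axis=1), genes, columns, layer_tag="umi")
    metadata = pd.DataFrame({
        "column_id": columns,
        "condition": cond_of,
        "replicate": 1,
        "population": "CD11b+",
    })
    truth = SimTruth(
        cell_type_of=dict(zip(columns, type_of)),
        program_genes=[genes[i] for i in program_idx],
        marker_genes_of={t: [genes[i] for i in idx] for t, idx in marker_of.items()},
    )
    return ScSimResult(counts=cm, metadata=metadata, truth=truth)


def simulate_bulk_timecourse(spec: BulkSimSpec) -> BulkSimResult:
    """Draw a bulk vaccination time course with planted responsive genes.

    Per-sample log2 value = gene baseline + profile(t)·effect (responsive
    genes, trained condition only) + N(0, noise_sd_log2), truncated at 0.
    The same data is also emitted as rounded linear-scale counts so the
    full normalization path can be exercised from raw input.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    days = np.asarray(spec.timepoints_days, dtype=float)
    baseline = np.maximum(
        rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=spec.n_genes), 0.0)

    n_resp = int(round(spec.responsive_fraction * spec.n_genes))
    resp_idx = rng.choice(spec.n_genes, size=n_resp, replace=False) if n_resp else np.array([], dtype=int)
    shapes = ([spec.profile_shapes[i % len(spec.profile_shapes)] for i in range(n_resp)]
              if n_resp else [])
    effect = np.zeros((spec.n_genes, len(days)))
    for idx, shape in zip(resp_idx, shapes):
        effect[idx] = profile_template(shape, days) * spec.effect_log2

    sample_ids: list[str] = []
    rows_meta: list[dict] = []
    cols: list[np.ndarray] = []
    for cond in ("control", "trained"):
        for ti, day in enumerate(days):
            for rep in range(1, spec.replicates + 1):
                sid = f"{cond}_d{int(day) if day == int(day) else day}_r{rep}"
                mean = baseline + (effect[:, ti] if cond == "trained" else 0.0)
                vals = mean + rng.normal(0.0, spec.noise_sd_log2, size=spec.n_genes)
                cols.append(np.maximum(vals, 0.0))
                sample_ids.append(sid)
                rows_meta.append({"column_id": sid, "condition": cond,
                                  "timepoint_days": float(day), "replicate": rep})
    values = np.column_stack(cols)
    metadata = pd.DataFrame(rows_meta)
    tc = TimeCourseMatrix(values=values, gene_ids=genes, sample_ids=sample_ids,
                          metadata=metadata, floor_applied=0.0)
    counts = CountMatrix(np.round(np.power(2.0, values) - 1.0).astype(np.int64),
                         genes, sample_ids, layer_tag="reads")
    resp_table = pd.DataFrame({
        "gene": [genes[i] for i in resp_idx],
        "shape": shapes,
        "effect_log2": spec.effect_log2,
    })
    truth = SimTruth(responsive_genes=resp_table)
    return BulkSimResult(timecourse=tc, counts=counts, metadata=metadata, truth=truth)
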