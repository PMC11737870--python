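"""End-to-end single-cell pipeline: QC -> normalization -> variable genes
-> PCA -> KNN graph -> Louvain -> marker annotation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cluster import (Clustering, Embedding, KNNGraph, annotate_clusters,
                      build_knn_graph, louvain_cluster, run_pca)
from .io import AnalysisConfig, CountMatrix
from .preprocess import (ExpressionMatrix, QCReport, VariableGeneResult,
                         compute_size_factors, normalize_log10, qc_filter)
from .preprocess import select_variable_genes

__all__ = ["ScPipelineResult", "sc_pipeline"]


@dataclass
class ScPipelineResult:
    counts: CountMatrix  # post-QC
    qc: QCReport
    expr: ExpressionMatrix
    variable_genes: VariableGeneResult
    embedding: Embedding
    graph: KNNGraph
    clustering: Clustering  # annotated when markers were given


def sc_pipeline(counts: CountMatrix, config: AnalysisConfig | None = None,
                markers: Mapping[str, Sequence[str]] | None = None) -> ScPipelineResult:
    """Run the full single-cell analysis under one config.

    Stages: cell/gene QC, median-library-size normalization with log10
    transform, mean-CV variable-gene selection, PCA on the variable genes,
    Euclidean KNN graph in PC space, Louvain community detection, and
    (when a marker table is supplied) cluster annotation.
    """
    cfg = config or AnalysisConfig()
    filtered, qc = qc_filter(counts, cfg.min_cell_umi)
    factors = compute_size_factors(filtered)
    expr = normalize_log10(filtered, factors)
    n_var = min(cfg.n_variable_genes, len(expr.gene_ids) - sum(
        1 for g in expr.gene_ids
        if g in set(cfg.cell_cycle_genes) or any(g.startswith(p) for p in cfg.exclusion_patterns)))
    hv = select_variable_genes(expr, n_var, cfg.exclusion_patterns, cfg.cell_cycle_genes)
    n_pcs = min(cfg.n_pcs, min(len(hv.selected), len(expr.column_ids)) - 1)
    emb = run_pca(expr, n_pcs=n_pcs, genes=hv.selected)
    graph = build_knn_graph(emb, k=min(cfg.knn_k, len(expr.column_ids) - 1))
    clust = louvain_cluster(graph, resolution=cfg.louvain_resolution, seed=cfg.rng_seed)
    if markers is not None:
        clust = annotate_clusters(clust, expr, markers)
    return ScPipelineResult(counts=filtered, qc=qc, expr=expr, variable_genes=hv,
                            embedding=emb, graph=graph, clustering=clust)
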