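"""splenotrain: transcriptomic analysis of trained immunity in the spleen.

A reusable pipeline for the downstream analysis of a BCG trained-immunity
study: MARS-seq-style scRNA-seq preprocessing and Louvain clustering, bulk
vaccination time-course processing with an integral-difference statistic
for calling training-induced genes, t-test/ANOVA differential expression
with BH-FDR control, hypergeometric gene-set over-representation, and
synthetic-data generators with known ground truth for end-to-end testing.
"""

from importlib import resources

import pandas as pd

from .cluster import (Clustering, Embedding, KNNGraph, annotate_clusters,
                      build_knn_graph, louvain_cluster, run_pca)
from .differential import (DEGResult, anova_deg, bh_adjust,
                           multi_contrast_union, ttest_deg)
from .enrichment import EnrichmentResult, ora
from .io import (AnalysisConfig, CountMatrix, GeneSetCollection, load_config,
                 read_count_matrix, read_gene_sets, read_sample_metadata,
                 write_count_matrix, write_gene_sets, write_run_manifest)
from .kinetics import (AveragedTrajectories, TimeCourseMatrix,
                       TrainingCallResult, average_replicates, bulk_pca,
                       call_training_genes, integral_difference, prepare_bulk)
from .pipeline import ScPipelineResult, sc_pipeline
from .preprocess import (ExpressionMatrix, QCReport, SizeFactors,
                         VariableGeneResult, compute_size_factors,
                         normalize_log10, qc_filter, select_variable_genes)
from .simulate import (BulkSimResult, BulkSimSpec, ScSimResult, ScSimSpec,
                       SimTruth, profile_template, simulate_bulk_timecourse,
                       simulate_sc_counts)

__version__ = "0.1.0"


def default_cell_cycle_genes() -> list[str]:
    """Mouse cell-cycle gene symbols shipped with the package."""
    text = resources.files("splenotrain.data").joinpath("cell_cycle_mouse.txt").read_text()
    return [g for g in text.split() if g]


def default_marker_table() -> dict[str, list[str]]:
    """Mouse splenic myeloid marker panels shipped with the package."""
    with resources.as_file(resources.files("splenotrain.data").joinpath("myeloid_markers.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return {t: g["gene"].tolist() for t, g in df.groupby("type", sort=False)}


def demo_gene_sets() -> GeneSetCollection:
    """Small illustrative hallmark-style gene sets shipped for tests/demos."""
    with resources.as_file(resources.files("splenotrain.data").joinpath("demo_hallmark.gmt")) as p:
        return read_gene_sets(p, source_tag="demo_hallmark")
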