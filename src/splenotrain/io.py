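"""Core domain types and file I/O.

Count matrices are always oriented genes-as-rows, observations-as-columns
(cells or bulk samples).  Two on-disk dialects are supported: a plain TSV
with a header row of column ids and gene symbols in the first column, and
MatrixMarket MTX with sibling ``<stem>.genes.txt`` / ``<stem>.cols.txt``
label files.  Gene identifiers are opaque case-sensitive strings; no
symbol-alias resolution is attempted.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "AnalysisConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_metadata",
    "read_gene_sets",
    "write_gene_sets",
    "load_config",
    "write_run_manifest",
]

CONDITIONS = ("control", "trained")

METADATA_COLUMNS = ("column_id", "condition", "timepoint_days", "replicate", "population")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer UMI (or read) counts, genes x columns, with label vectors."""

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    layer_tag: str = "umi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            g, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, column {self.column_ids[c]!r}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.column_ids)} columns)"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if self.layer_tag not in ("umi", "reads"):
            raise ValueError(f"layer_tag must be 'umi' or 'reads', got {self.layer_tag!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.sets)


#: ribosomal-protein symbol prefixes excluded from variable-gene selection
DEFAULT_EXCLUSION_PATTERNS = ["Rps", "Rpl", "Mrps", "Mrpl"]


@dataclass
class AnalysisConfig:
    """Resolved analysis parameters; defaults follow the study protocol."""

    min_cell_umi: int = 200
    n_variable_genes: int = 425
    n_pcs: int = 40
    knn_k: int = 20
    louvain_resolution: float = 1.0
    sc_log_base: int = 10
    bulk_log_base: int = 2
    bulk_floor: float = 3.0
    fdr_q: float = 0.05
    min_fold: float = 2.0
    sd_multiplier: float = 3.0
    rng_seed: int = 0
    exclusion_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_EXCLUSION_PATTERNS))
    cell_cycle_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("min_cell_umi", "n_variable_genes", "n_pcs", "knn_k",
                     "louvain_resolution", "bulk_floor", "sd_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config key {name} must be strictly positive")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError(f"fdr_q must lie in (0, 1), got {self.fdr_q}")
        if self.min_fold < 1.0:
            raise ValueError(f"min_fold must be >= 1, got {self.min_fold}")
        if self.sc_log_base != 10:
            raise ValueError("sc_log_base is fixed at 10")
        if self.bulk_log_base != 2:
            raise ValueError("bulk_log_base is fixed at 2")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Unspecified keys take the documented defaults.  Unknown keys are fatal
    (typo guard), as are out-of-range values.  ``overrides`` are applied on
    top of the file, with the same checks.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# count matrices


def _mtx_siblings(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cols.txt")


def read_count_matrix(path: str | Path, format: str | None = None,
                      layer_tag: str = "umi") -> CountMatrix:
    """Read a genes x columns count matrix from TSV or MTX.

    For ``mtx``, sibling ``<stem>.genes.txt`` and ``<stem>.cols.txt`` files
    (one id per line) supply the row and column labels.  Ordering is
    preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValueError(f"malformed TSV count matrix {path}: {exc}") from exc
        return CountMatrix(df.to_numpy(), list(df.index.astype(str)),
                           list(df.columns.astype(str)), layer_tag=layer_tag)
    if format == "mtx":
        genes_path, cols_path = _mtx_siblings(path)
        for p in (genes_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"missing label file {p} for {path}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().split()
        cols = cols_path.read_text().split()
        return CountMatrix(np.asarray(mat), genes, cols, layer_tag=layer_tag)
    raise ValueError(f"unknown count-matrix format {format!r}")


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx":
        genes_path, cols_path = _mtx_siblings(path)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(cm.values))
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        cols_path.write_text("\n".join(cm.column_ids) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample/cell metadata TSV.

    Requires a ``column_id`` column; ``condition``, ``timepoint_days``,
    ``replicate`` and ``population`` are recognised when present, anything
    else rides along untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"column_id": str})
    if "column_id" not in df.columns:
        raise ValueError(f"metadata file {path} lacks a 'column_id' column")
    if df["column_id"].duplicated().any():
        dup = df.loc[df["column_id"].duplicated(), "column_id"].iloc[0]
        raise ValueError(f"duplicate column_id in metadata: {dup!r}")
    return df


def align_metadata(meta: pd.DataFrame, column_ids: Sequence[str]) -> pd.DataFrame:
    """Subset and order metadata rows to match a matrix's columns.

    Every matrix column must have exactly one metadata row.
    """
    idx = meta.set_index("column_id", drop=False)
    missing = [c for c in column_ids if c not in idx.index]
    if missing:
        raise ValueError(f"metadata missing for column(s): {missing[:5]}")
    return idx.loc[list(column_ids)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path, source_tag: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: tab-separated set-name, description, member genes.

    The description field is ignored.  Duplicate genes within one line are
    dropped (first occurrence wins) with a warning; an empty file yields an
    empty collection with a warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(parts)} field(s); "
                    "expected set-name, description, >=1 gene"
                )
            name = parts[0]
            genes: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                warnings.warn(f"{path}:{lineno}: set {name!r} had {dups} duplicate gene(s); deduplicated")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets")
    return GeneSetCollection(sets, source_tag=source_tag or path.name)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            fh.write("\t".join([name, gsc.source_tag or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# run manifests


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(out_dir: str | Path, command: str, config: AnalysisConfig | None,
                       inputs: Sequence[str | Path] = (), seed: int | None = None) -> Path:
    """Write a machine-readable record of a run: resolved config, input
    checksums and the seed used."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "inputs": {str(p): _md5(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
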