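"""Readers, writers and the pipeline configuration.

All genomic coordinates are 0-based half-open internally; conversions from
1-based inclusive ("GTF-like") inputs happen here and only here. Strand is
used solely to locate the TSS (body_start on '+', body_end - 1 on '-') when a
TSS column is absent; all distances downstream are unsigned.

Gzip is transparent for every text format (pandas dispatches on the ``.gz``
suffix).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .errors import ConfigError, DataIntegrityError, ParseError

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: distance-to-TSS bin edges (bp), half-open [lo, hi)
DISTANCE_BIN_EDGES = [0, 1_500, 10_000, 100_000, 1_000_000, np.inf]
DISTANCE_BIN_LABELS = ["<1.5kb", "1.5k-10k", "10k-100k", "100k-1M", ">1Mb"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with documented defaults.

    Defaults reproduce the screen-analysis thresholds: FDR 0.1, 1.5 kb
    proximal window, 1 Mb maximum enhancer distance, cascade gates
    adjusted-p < 0.1 with |log2FC| >= 0.2 ('map' preset; the 'network' preset
    uses 0.1).
    """

    seed: int = 0

    # QC / gRNA assignment
    min_umi: int = 100
    min_genes: int = 10
    min_cells_per_grna: int = 10
    norm_scale: float = 1e4
    kd_alpha: float = 0.05

    # differential expression
    min_cells_per_group: int = 10
    dispersion_shrink_weight: float = 0.5
    fdr: float = 0.1
    min_abs_lfc: float = 0.0
    n_variable_genes: int = 8000

    # link classification
    proximal_window: int = 1500

    # enhancer prioritization
    max_distance: float = 1_000_000.0

    # cascade
    cascade_adj_p_max: float = 0.1
    cascade_min_abs_lfc: float = 0.2   # 'map' preset; 'network' preset = 0.1
    cascade_top_k: int | None = None
    min_shared_diseases: int = 5
    geneset_alpha: float = 0.05

    # TF-target enrichment
    tf_min_targets: int = 50
    tf_min_degs: int = 5
    tf_deg_adj_p: float = 0.1
    tf_deg_min_abs_lfc: float = 0.5

    # cascade |log2FC| gate presets named in the figures
    CASCADE_LFC_PRESETS = {"map": 0.2, "network": 0.1}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ["min_cells_per_grna", "min_cells_per_group", "norm_scale",
                    "proximal_window", "max_distance", "n_variable_genes",
                    "tf_min_targets", "tf_min_degs"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        for name in ["min_umi", "min_genes", "min_shared_diseases"]:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        unit = ["kd_alpha", "fdr", "cascade_adj_p_max", "geneset_alpha",
                "tf_deg_adj_p", "dispersion_shrink_weight"]
        for name in unit:
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ["min_abs_lfc", "cascade_min_abs_lfc", "tf_deg_min_abs_lfc"]:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if self.cascade_top_k is not None and self.cascade_top_k <= 0:
            raise ConfigError(f"cascade_top_k must be positive or null, got {self.cascade_top_k!r}")

    @classmethod
    def valid_keys(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; missing keys take defaults, unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    valid = set(PipelineConfig.valid_keys())
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# intervals (BED / TSV)
# ---------------------------------------------------------------------------

def _validate_intervals(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise DataIntegrityError(
            f"{source}: start >= end for record(s) {list(df.loc[bad, 'name'].head())}"
        )
    if (df["start"] < 0).any():
        raise DataIntegrityError(f"{source}: negative coordinates")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_intervals(path: str | Path, format: str = "bed",
                   coords: str = "zero-half-open") -> pd.DataFrame:
    """Read an interval table into a sorted 0-based half-open DataFrame.

    Parameters
    ----------
    format
        ``"bed"`` (headerless, tab-separated, >=3 columns) or ``"tsv"``
        (tab-separated with header; must contain chrom/start/end).
    coords
        ``"zero-half-open"`` (BED convention) or ``"one-based-inclusive"``
        (GTF-like); the latter is converted on load.
    """
    path = Path(path)
    if format == "bed":
        rows = []
        import gzip
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >=3 BED fields, got {len(parts)}")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                rows.append({
                    "chrom": parts[0], "start": start, "end": end,
                    "name": parts[3] if len(parts) > 3 else f"iv{lineno}",
                    "score": parts[4] if len(parts) > 4 else ".",
                    "strand": parts[5] if len(parts) > 5 else ".",
                })
        df = pd.DataFrame(rows, columns=BED_COLUMNS)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing required columns {sorted(missing)}")
        if "name" not in df.columns:
            df["name"] = [f"iv{i}" for i in range(len(df))]
    else:
        raise ConfigError(f"unknown interval format {format!r}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if coords == "one-based-inclusive":
        df["start"] = df["start"] - 1
    elif coords != "zero-half-open":
        raise ConfigError(f"unknown coordinate convention {coords!r}")
    return _validate_intervals(df, str(path))


def write_intervals(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED (0-based half-open)."""
    out = df.copy()
    for col, default in [("name", "."), ("score", "."), ("strand", ".")]:
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annotations and plain tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (TSV with header).

    Requires gene_id, chrom, strand, body_start, body_end; tss is derived from
    strand when absent. Validates the coordinate invariants.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "body_start", "body_end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    if "tss" not in df.columns:
        df["tss"] = np.where(df["strand"] == "+", df["body_start"], df["body_end"] - 1)
    return validate_annotation(df, str(path))


def validate_annotation(df: pd.DataFrame, source: str = "annotation") -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise DataIntegrityError(f"{source}: duplicated gene_ids {dups}")
    if (df["body_start"] >= df["body_end"]).any():
        raise DataIntegrityError(f"{source}: body_start >= body_end")
    inside = (df["tss"] >= df["body_start"]) & (df["tss"] < df["body_end"])
    if not inside.all():
        raise DataIntegrityError(f"{source}: tss outside gene body for "
                                 f"{df.loc[~inside, 'gene_id'].head().tolist()}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sparse count matrices (MTX triplet + label files)
# ---------------------------------------------------------------------------

def read_count_matrix(mtx_path: str | Path, genes_path: str | Path,
                      barcodes_path: str | Path) -> ad.AnnData:
    """Load an MTX matrix (genes x cells on disk) into cells x genes AnnData."""
    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise DataIntegrityError(
            f"MTX dimensions {mat.shape} do not match labels "
            f"({len(genes)} genes x {len(barcodes)} barcodes)"
        )
    data = mat.T.tocsr()
    if data.nnz and not np.allclose(data.data, np.round(data.data)):
        raise DataIntegrityError("count matrix has non-integer entries")
    adata = ad.AnnData(X=data.astype(np.int64))
    adata.obs_names = barcodes
    adata.var_names = genes
    return adata


def write_count_matrix(adata: ad.AnnData, mtx_path: str | Path,
                       genes_path: str | Path, barcodes_path: str | Path) -> None:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(mtx_path), X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(barcodes_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# screen dataset bundle (counts + cell metadata + assignments)
# ---------------------------------------------------------------------------

def write_screen_dataset(adata: ad.AnnData, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = (lambda name: outdir / f"{prefix}{name}")
    write_count_matrix(adata, p("matrix.mtx"), p("genes.tsv"), p("barcodes.tsv"))
    obs = adata.obs.reset_index(names="cell_id")
    write_table(obs, p("cells.tsv"))
    if "assignments" in adata.uns:
        write_table(adata.uns["assignments"], p("assignments.tsv"))
    if "grna_table" in adata.uns:
        write_table(adata.uns["grna_table"], p("grnas.tsv"))


def read_screen_dataset(outdir: str | Path, prefix: str = "") -> ad.AnnData:
    outdir = Path(outdir)
    p = (lambda name: outdir / f"{prefix}{name}")
    adata = read_count_matrix(p("matrix.mtx"), p("genes.tsv"), p("barcodes.tsv"))
    obs = read_table(p("cells.tsv")).set_index("cell_id")
    obs.index = obs.index.astype(str)
    if not obs.index.equals(pd.Index(adata.obs_names)):
        raise DataIntegrityError("cells.tsv barcodes do not match matrix barcodes")
    adata.obs = obs
    if p("assignments.tsv").exists():
        adata.uns["assignments"] = read_table(p("assignments.tsv"))
    if p("grnas.tsv").exists():
        adata.uns["grna_table"] = read_table(p("grnas.tsv"))
    return adata


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
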