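"""Cell QC, unique gRNA assignment, and per-gRNA knockdown quantification.

A cell is retained only if it passes UMI/gene thresholds and carries exactly
one identified gRNA; gRNAs detected in fewer than ``min_cells_per_grna``
retained cells are dropped along with their cells. On-target knockdown for a
gRNA is the ratio of mean log-normalized target-gene expression in cells
carrying that gRNA versus non-targeting control cells, with a two-sided
Wilcoxon rank-sum test and BH correction across gRNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError, StageError

__all__ = ["filter_and_assign", "knockdown_efficiency", "knockdown_table"]


def filter_and_assign(adata, min_umi: int = 100, min_genes: int = 10,
                      min_cells_per_grna: int = 10):
    """Apply cell QC and the unique-assignment rule; drop under-covered gRNAs.

    Returns a filtered copy; a QC summary (fractions retained at each step)
    lands in ``.uns['qc_summary']``.
    """
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    umi = np.asarray(X.sum(axis=1)).ravel()
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    pass_counts = (umi >= min_umi) & (genes_detected >= min_genes)
    unique = (adata.obs["n_grnas"].to_numpy() == 1)
    keep = pass_counts & unique
    n_total = adata.n_obs
    sub = adata[keep].copy()
    if sub.n_obs:
        grna_counts = sub.obs["grna_id"].value_counts()
        good_grnas = set(grna_counts.index[grna_counts >= min_cells_per_grna])
        sub = sub[sub.obs["grna_id"].isin(good_grnas)].copy()
    if sub.n_obs == 0:
        raise StageError("no cells survive QC (check min_umi/min_genes thresholds)")
    sub.uns["qc_summary"] = {
        "n_cells_in": int(n_total),
        "n_cells_out": int(sub.n_obs),
        "frac_pass_counts": float(pass_counts.mean()),
        "frac_uniquely_assigned": float(unique.mean()),
        "n_grnas_retained": int(sub.obs["grna_id"].nunique()),
    }
    for key in ("grna_table", "assignments", "mode", "screen_config"):
        if key in adata.uns:
            sub.uns[key] = adata.uns[key]
    return sub


def _lognorm_expression(adata, gene: str, scale: float) -> np.ndarray:
    """log1p(count / library_size * scale) for one gene across all cells."""
    if gene not in adata.var_names:
        raise DataIntegrityError(f"target gene {gene!r} absent from count matrix")
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    lib = np.asarray(X.sum(axis=1)).ravel().astype(float)
    lib[lib == 0] = 1.0
    col = np.asarray(X[:, adata.var_names.get_loc(gene)].todense()).ravel()
    return np.log1p(col / lib * scale)


def knockdown_efficiency(adata, grna_id: str, target_gene: str,
                         norm_scale: float = 1e4) -> dict:
    """Knockdown record for one gRNA (p-value unadjusted; see knockdown_table)."""
    is_pert = (adata.obs["grna_id"] == grna_id).to_numpy()
    is_ctrl = (adata.obs["target_id"] == "non-targeting").to_numpy()
    if not is_pert.any():
        raise DataIntegrityError(f"gRNA {grna_id!r} has no cells")
    if not is_ctrl.any():
        raise DataIntegrityError("non-targeting control pool is empty")
    expr = _lognorm_expression(adata, target_gene, norm_scale)
    pert, ctrl = expr[is_pert], expr[is_ctrl]
    mean_p, mean_c = float(pert.mean()), float(ctrl.mean())
    if np.ptp(expr[is_pert | is_ctrl]) == 0:
        p_value = 1.0
    else:
        p_value = float(scipy.stats.ranksums(pert, ctrl).pvalue)
    return {
        "grna_id": grna_id,
        "target_gene": target_gene,
        "n_cells": int(is_pert.sum()),
        "mean_lognorm_perturbed": mean_p,
        "mean_lognorm_control": mean_c,
        "kd_ratio": mean_p / mean_c if mean_c > 0 else np.nan,
        "p_value": p_value,
    }


def knockdown_table(adata, norm_scale: float = 1e4, alpha: float = 0.05) -> pd.DataFrame:
    """Knockdown records for every targeting gRNA whose target is measured.

    ``significant`` applies BH across all tested gRNAs at level ``alpha``.
    """
    grnas = adata.uns["grna_table"]
    rows = []
    for _, g in grnas.iterrows():
        if g["target_kind"] not in ("promoter", "control_promoter"):
            continue
        target_gene = g["target_id"].removeprefix("ctrlprom_") \
            if g["target_kind"] == "control_promoter" else g["target_id"]
        if target_gene not in adata.var_names:
            continue
        if not (adata.obs["grna_id"] == g["grna_id"]).any():
            continue
        rows.append(knockdown_efficiency(adata, g["grna_id"], target_gene, norm_scale))
    table = pd.DataFrame(rows)
    if len(table):
        reject, adj, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["adj_p"] = adj
        table["significant"] = reject
    return table
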