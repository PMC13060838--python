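"""CRE-gene link calling, interaction classification, and prediction benchmarks.

A perturbed CRE is classified by genomic context — *promoter* if it overlaps
any TSS ± the proximal window (1.5 kb default), else *intragenic* if its
center lies inside a gene body, else *intergenic* — and each tested CRE-gene
pair by the unsigned distance from the CRE center to the gene's nearest TSS
(*proximal* < window, *distal* otherwise). Context x position gives five
interaction classes; intergenic-proximal cannot occur because a CRE within
the window of a TSS is promoter-context by definition.

Significant links from control-promoter perturbations and cross-chromosome
pairs are excluded from the cis set (kept in an audit table) before any
downstream analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataIntegrityError

__all__ = ["classify_cre_context", "classify_interaction", "cre_gene_distance",
           "call_links", "benchmark_predictions", "INTERACTION_CLASSES"]

INTERACTION_CLASSES = [
    "promoter-proximal", "promoter-distal",
    "intragenic-proximal", "intragenic-distal",
    "intergenic-distal",
]


def _tss_by_chrom(annotation: pd.DataFrame) -> dict[str, np.ndarray]:
    return {c: np.sort(sub["tss"].to_numpy())
            for c, sub in annotation.groupby("chrom")}


def classify_cre_context(cre: pd.Series | dict, annotation: pd.DataFrame,
                         proximal_window: int = 1500) -> str:
    """Context of one CRE interval: promoter > intragenic > intergenic."""
    chrom, start, end = cre["chrom"], int(cre["start"]), int(cre["end"])
    center = int(cre["center"]) if "center" in cre else (start + end) // 2
    sub = annotation[annotation["chrom"] == chrom]
    tss = sub["tss"].to_numpy()
    # CRE [start, end) overlaps window [tss - w, tss + w + 1)
    if np.any((start < tss + proximal_window + 1) & (end > tss - proximal_window)):
        return "promoter"
    inside = (sub["body_start"].to_numpy() <= center) & (center < sub["body_end"].to_numpy())
    if inside.any():
        return "intragenic"
    return "intergenic"


def cre_gene_distance(cre: pd.Series | dict, gene_rows: pd.DataFrame) -> float:
    """Unsigned bp distance from CRE center to the gene's nearest TSS.

    ``gene_rows`` may hold several rows for multi-TSS genes; the minimum is
    taken. Cross-chromosome pairs return inf.
    """
    center = int(cre["center"]) if "center" in cre else (int(cre["start"]) + int(cre["end"])) // 2
    same = gene_rows[gene_rows["chrom"] == cre["chrom"]]
    if same.empty:
        return float("inf")
    return float(np.min(np.abs(same["tss"].to_numpy() - center)))


def classify_interaction(context: str, distance: float,
                         proximal_window: int = 1500) -> str:
    """Five-way interaction class from CRE context and center-to-TSS distance."""
    if not np.isfinite(distance):
        raise DataIntegrityError("interaction class undefined for cross-chromosome pair")
    position = "proximal" if distance < proximal_window else "distal"
    if context == "intergenic" and position == "proximal":
        # cannot occur under the context precedence; guard against misuse
        raise DataIntegrityError(
            "intergenic-proximal is impossible: a CRE within the proximal window "
            "of a TSS is promoter-context")
    return f"{context}-{position}"


def annotate_links(de_results: pd.DataFrame, cre_table: pd.DataFrame,
                   annotation: pd.DataFrame, proximal_window: int = 1500) -> pd.DataFrame:
    """Attach distance, context, class and direction to CRE-perturbation DE rows."""
    cres = cre_table.set_index("cre_id")
    missing = set(de_results["perturbation"]) - set(cres.index)
    if missing:
        raise DataIntegrityError(f"CRE ids absent from cre_table: {sorted(missing)[:5]}")
    gene_groups = dict(tuple(annotation.groupby("gene_id")))
    context_cache: dict[str, str] = {}
    rows = []
    for _, r in de_results.iterrows():
        cre_id, gene_id = r["perturbation"], r["response_gene"]
        cre = cres.loc[cre_id]
        gene_rows = gene_groups.get(gene_id)
        if gene_rows is None:
            raise DataIntegrityError(f"response gene {gene_id!r} absent from annotation")
        if cre_id not in context_cache:
            context_cache[cre_id] = classify_cre_context(
                {"chrom": cre["chrom"], "start": cre["start"], "end": cre["end"],
                 "center": cre.get("center", (cre["start"] + cre["end"]) // 2)},
                annotation, proximal_window)
        dist = cre_gene_distance(
            {"chrom": cre["chrom"], "start": cre["start"], "end": cre["end"],
             "center": cre.get("center", (cre["start"] + cre["end"]) // 2)}, gene_rows)
        same_chrom = np.isfinite(dist)
        rows.append({
            "cre_id": cre_id, "gene_id": gene_id,
            "log2fc": r["log2fc"], "adj_p": r["adj_p"], "wald_p": r["wald_p"],
            "distance": dist if same_chrom else np.nan,
            "same_chromosome": same_chrom,
            "cre_context": context_cache[cre_id],
            "position": ("proximal" if same_chrom and dist < proximal_window else "distal"),
            "interaction_class": (classify_interaction(context_cache[cre_id], dist, proximal_window)
                                  if same_chrom else ""),
            "direction": "up" if r["log2fc"] > 0 else "down",
        })
    return pd.DataFrame(rows)


def call_links(de_results: pd.DataFrame, cre_table: pd.DataFrame,
               annotation: pd.DataFrame, control_promoter_ids: list[str] | None = None,
               fdr: float = 0.1, min_abs_lfc: float = 0.0,
               proximal_window: int = 1500,
               prediction_sources: dict[str, pd.DataFrame] | None = None):
    """Call classified cis links from CRE-mode DE results.

    Returns ``(links, audit, summary)``: the cis link table, an audit table of
    excluded associations (control-promoter perturbations, cross-chromosome
    pairs), and per-CRE / per-gene degree summaries of the significant set.
    """
    control_promoter_ids = set(control_promoter_ids or [])
    is_ctrl = de_results["perturbation"].isin(control_promoter_ids)
    cre_de = de_results.loc[~is_ctrl].reset_index(drop=True)

    table = annotate_links(cre_de, cre_table, annotation, proximal_window)
    table["significant"] = ((table["adj_p"] < fdr)
                            & (table["log2fc"].abs() >= min_abs_lfc)
                            & table["adj_p"].notna())

    cross = table.loc[~table["same_chromosome"]].assign(exclusion="cross_chromosome")
    ctrl_rows = de_results.loc[is_ctrl].assign(exclusion="control_promoter")
    audit = pd.concat([ctrl_rows, cross], ignore_index=True)
    links = table.loc[table["same_chromosome"]].reset_index(drop=True)

    if prediction_sources:
        key = list(zip(links["cre_id"], links["gene_id"]))
        labels = []
        for pair in key:
            hits = [name for name, df in prediction_sources.items()
                    if pair in set(zip(df["cre_id"], df["gene_id"]))]
            labels.append(";".join(sorted(hits)))
        links["prediction_sources"] = labels

    sig = links[links["significant"]]
    summary = {
        "n_cis_links": int(sig.shape[0]),
        "n_tested_pairs": int(links.shape[0]),
        "mean_targets_per_cre": float(sig.groupby("cre_id")["gene_id"].nunique().mean())
        if len(sig) else 0.0,
        "mean_cres_per_gene": float(sig.groupby("gene_id")["cre_id"].nunique().mean())
        if len(sig) else 0.0,
        "frac_upregulated": float((sig["log2fc"] > 0).mean()) if len(sig) else np.nan,
        "n_excluded_control_promoter": int(is_ctrl.sum()),
        "n_excluded_cross_chromosome": int((~table["same_chromosome"]).sum()),
    }
    _assert_partition(links)
    return links, audit, summary


def _assert_partition(links: pd.DataFrame) -> None:
    """The five classes partition all same-chromosome links (checked each run)."""
    sc = links[links["same_chromosome"]]
    bad = set(sc["interaction_class"]) - set(INTERACTION_CLASSES)
    if bad:
        raise DataIntegrityError(f"unexpected interaction classes {sorted(bad)}")
    if sc["interaction_class"].eq("").any():
        raise DataIntegrityError("same-chromosome link with empty interaction class")


def benchmark_predictions(links: pd.DataFrame,
                          prediction_sources: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Validation rate of each prediction source against the tested cis pairs.

    precision = validated / predicted among *tested* pairs; the ``any_source``
    and ``no_source`` rows give the pooled rates whose ratio is the
    fold-enrichment of predicted over unpredicted links. ``distal_fraction``
    is the share of each source's validated links that are distal.
    """
    tested = set(zip(links["cre_id"], links["gene_id"]))
    sig = set(zip(links.loc[links["significant"], "cre_id"],
                  links.loc[links["significant"], "gene_id"]))
    distal = set(zip(links.loc[links["position"] == "distal", "cre_id"],
                     links.loc[links["position"] == "distal", "gene_id"]))
    rows = []
    union: set = set()
    for name, df in prediction_sources.items():
        pred = set(zip(df["cre_id"], df["gene_id"])) & tested
        union |= pred
        val = pred & sig
        rows.append({
            "source": name, "n_predicted": len(pred), "n_validated": len(val),
            "precision": len(val) / len(pred) if pred else np.nan,
            "distal_fraction": (len(val & distal) / len(val)) if val else np.nan,
        })
    unpred = tested - union
    p_any = len(union & sig) / len(union) if union else np.nan
    p_none = len(unpred & sig) / len(unpred) if unpred else np.nan
    for name, pred in [("any_source", union), ("no_source", unpred)]:
        val = pred & sig
        rows.append({"source": name, "n_predicted": len(pred), "n_validated": len(val),
                     "precision": len(val) / len(pred) if pred else np.nan,
                     "distal_fraction": (len(val & distal) / len(val)) if val else np.nan})
    out = pd.DataFrame(rows)
    if np.isfinite(p_none) and p_none > 0:
        out["fold_vs_unpredicted"] = np.where(
            out["source"] != "no_source", out["precision"] / p_none, np.nan)
    else:
        out["fold_vs_unpredicted"] = np.nan
    return out
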