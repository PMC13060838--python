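"""Refinement of significant distal links into high-confidence enhancer-like
interactions.

The filters mirror the evidence chain a CRISPRi screen needs to distinguish
genuine distal regulation from indirect or technical effects:

* **mediation filter** — a distal effect of CRE *c* is discarded when *c* also
  has a significant proximal effect (on any gene) that could mediate it;
* **distance bins** — half-open [0,1.5k), [1.5k,10k), [10k,100k), [100k,1M),
  [1M, inf) from CRE center to the target's nearest TSS;
* **Hi-C comparison** — per-bin rank-sum test of contact frequency,
  significant versus distance-matched non-significant pairs;
* **TAD test** — Fisher's exact test of same-TAD co-localization, where
  "same TAD" means no TAD boundary lies strictly between the CRE center and
  the target TSS;
* **prioritize** — high-confidence = significant, distal, mediation-pass and
  within the maximum distance (1 Mb default; beyond that distal CREs are
  indistinguishable from non-significant elements), labelled *enhancer* when
  CRISPRi lowers the target (log2FC < 0) and *silencer* when it raises it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataIntegrityError
from .io import DISTANCE_BIN_EDGES, DISTANCE_BIN_LABELS
from .enrich import fisher_or

__all__ = ["mediation_filter", "assign_distance_bins", "hic_comparison",
           "tad_test", "same_tad", "prioritize_links"]


def mediation_filter(links: pd.DataFrame) -> pd.DataFrame:
    """Set ``mediation_pass`` on each link.

    A distal link passes iff its CRE has no significant proximal link at all;
    proximal links themselves never pass (they are not enhancer candidates).
    """
    sig_prox = links.loc[links["significant"] & (links["position"] == "proximal"), "cre_id"]
    blocked = set(sig_prox)
    out = links.copy()
    out["mediation_pass"] = (out["position"] == "distal") & ~out["cre_id"].isin(blocked)
    return out


def assign_distance_bins(links: pd.DataFrame) -> pd.DataFrame:
    """Attach the distance-to-TSS bin label to every same-chromosome link."""
    out = links.copy()
    dist = out["distance"].to_numpy(float)
    idx = np.digitize(dist, DISTANCE_BIN_EDGES[1:-1], right=False)
    labels = np.array(DISTANCE_BIN_LABELS, dtype=object)
    out["distance_bin"] = np.where(np.isfinite(dist), labels[np.clip(idx, 0, 4)], None)
    return out


def closest_per_cre(links: pd.DataFrame) -> pd.DataFrame:
    """Keep only each CRE's interaction with the closest TSS (bin summaries)."""
    return (links.sort_values("distance", kind="mergesort")
            .groupby("cre_id", as_index=False).head(1))


def hic_comparison(links: pd.DataFrame, contacts: pd.DataFrame) -> pd.DataFrame:
    """Per-distance-bin comparison of Hi-C contact, significant vs NS pairs.

    ``contacts`` maps (cre_id, gene_id) to a contact value; pairs without a
    contact are excluded and counted. Bins with no significant pairs give an
    NA row with no test.
    """
    if "distance_bin" not in links.columns:
        links = assign_distance_bins(links)
    cmap = {(c, g): v for c, g, v in
            zip(contacts["cre_id"], contacts["gene_id"], contacts["contact"])}
    vals = [cmap.get((c, g), np.nan) for c, g in zip(links["cre_id"], links["gene_id"])]
    df = links.assign(hic_contact=vals)
    rows = []
    for label in DISTANCE_BIN_LABELS:
        sub = df[df["distance_bin"] == label]
        missing = int(sub["hic_contact"].isna().sum())
        sub = sub.dropna(subset=["hic_contact"])
        sig = sub.loc[sub["significant"], "hic_contact"].to_numpy()
        ns = sub.loc[~sub["significant"], "hic_contact"].to_numpy()
        row = {"distance_bin": label, "n_sig": len(sig), "n_ns": len(ns),
               "n_missing_contact": missing,
               "median_sig": float(np.median(sig)) if len(sig) else np.nan,
               "median_ns": float(np.median(ns)) if len(ns) else np.nan,
               "ranksum_p": np.nan}
        if len(sig) and len(ns):
            row["ranksum_p"] = float(scipy.stats.ranksums(sig, ns).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def same_tad(chrom: str, pos_a: int, pos_b: int, tads: pd.DataFrame) -> bool:
    """True iff no TAD boundary lies strictly between the two positions."""
    bounds = np.sort(tads.loc[tads["chrom"] == chrom, "start"].to_numpy())
    lo, hi = min(pos_a, pos_b), max(pos_a, pos_b)
    return not np.any((bounds > lo) & (bounds <= hi))


def annotate_same_tad(links: pd.DataFrame, cre_table: pd.DataFrame,
                      annotation: pd.DataFrame, tads: pd.DataFrame) -> pd.DataFrame:
    centers = cre_table.set_index("cre_id")
    tss = annotation.set_index("gene_id")[["tss", "chrom"]]
    flags = []
    for c, g in zip(links["cre_id"], links["gene_id"]):
        cre = centers.loc[c]
        center = int(cre["center"]) if "center" in cre.index else (int(cre["start"]) + int(cre["end"])) // 2
        if cre["chrom"] != tss.loc[g, "chrom"]:
            flags.append(False)
            continue
        flags.append(same_tad(cre["chrom"], center, int(tss.loc[g, "tss"]), tads))
    out = links.copy()
    out["same_tad"] = flags
    return out


def tad_test(links: pd.DataFrame) -> dict:
    """Fisher's exact test of {significant} x {same TAD} over distal pairs."""
    if "same_tad" not in links.columns:
        raise DataIntegrityError("links lack same_tad annotation; run annotate_same_tad")
    sub = links[links["position"] == "distal"]
    a = int((sub["significant"] & sub["same_tad"]).sum())
    b = int((sub["significant"] & ~sub["same_tad"]).sum())
    c = int((~sub["significant"] & sub["same_tad"]).sum())
    d = int((~sub["significant"] & ~sub["same_tad"]).sum())
    res = fisher_or([[a, b], [c, d]])
    res.update({"a": a, "b": b, "c": c, "d": d})
    return res


def prioritize_links(links: pd.DataFrame, contacts: pd.DataFrame | None = None,
               max_distance: float = 1_000_000.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the prioritized link table and the per-bin monotonicity summary.

    Requires ``mediation_pass`` and ``distance_bin`` columns (``hic_contact``
    and ``same_tad`` are carried through when present). Returns
    ``(prioritized, bin_summary)`` where the bin summary reports per-bin
    medians of |log2FC| and chromatin signals for the high-confidence set.
    """
    for col in ("mediation_pass", "distance_bin"):
        if col not in links.columns:
            raise DataIntegrityError(f"prioritize requires the {col!r} annotation")
    out = links.copy()
    out["high_confidence"] = (out["significant"]
                              & (out["position"] == "distal")
                              & out["mediation_pass"]
                              & (out["distance"] <= max_distance))
    out["label"] = np.where(out["log2fc"] < 0, "enhancer", "silencer")
    out.loc[~out["high_confidence"], "label"] = ""

    hc = out[out["high_confidence"]]
    rows = []
    signal_cols = [c for c in ("atac", "h3k27ac", "h3k4me1", "h3k4me3") if c in out.columns]
    for label in DISTANCE_BIN_LABELS:
        sub = hc[hc["distance_bin"] == label]
        row = {"distance_bin": label, "n": len(sub),
               "median_abs_log2fc": float(sub["log2fc"].abs().median()) if len(sub) else np.nan}
        for col in signal_cols:
            row[f"median_{col}"] = float(sub[col].median()) if len(sub) else np.nan
        rows.append(row)
    return out, pd.DataFrame(rows)
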