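"""Hop-wise propagation of CRE effects through the promoter-screen network.

Layer 0 connects enhancer-like CREs to their target genes; hop 1 contains the
differentially expressed genes (DEGs) observed when a layer-0 target is
itself perturbed in the promoter screen; hop 2 the DEGs of hop-1 genes. Edges
pass a threshold gate (adjusted p and |log2FC|, optionally truncated to the
top-k strongest per source). Layer membership follows BFS semantics: a gene
belongs to the first layer that reaches it, even when later edges also point
at it. Disease programs aggregate, per disease label, the layer-0 targets and
hop-1 genes of that disease's CREs and are tested for gene-set enrichment;
terms are partitioned into shared (enriched in more than ``min_shared``
diseases) and unique (exactly one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import geneset_test

__all__ = ["CascadeNetwork", "build_cascade", "reachable_fraction", "disease_programs"]


@dataclass
class CascadeNetwork:
    cre_targets: set
    hop1: set
    hop2: set
    edges: pd.DataFrame          # source, sink, log2fc, adj_p, hop_level
    untested_targets: set        # layer-0 targets never perturbed in the promoter screen
    cre_edges: pd.DataFrame      # cre_id, gene_id (layer 0)
    thresholds: dict = field(default_factory=dict)


def _degs_by_perturbation(promoter_de: pd.DataFrame, adj_p_max: float,
                          min_abs_lfc: float, top_k: int | None) -> dict[str, pd.DataFrame]:
    ok = promoter_de.dropna(subset=["adj_p"])
    ok = ok[(ok["adj_p"] < adj_p_max) & (ok["log2fc"].abs() >= min_abs_lfc)]
    ok = ok[ok["perturbation"] != ok["response_gene"]]   # no self-edges
    out = {}
    for pert, sub in ok.groupby("perturbation"):
        if top_k is not None:
            sub = sub.reindex(sub["log2fc"].abs().sort_values(ascending=False).index).head(top_k)
        out[pert] = sub
    return out


def build_cascade(enhancer_links: pd.DataFrame, promoter_de: pd.DataFrame,
                  adj_p_max: float = 0.1, min_abs_lfc: float = 0.2,
                  top_k: int | None = None) -> CascadeNetwork:
    """Build the CRE -> target -> hop-1 -> hop-2 network.

    ``enhancer_links`` needs cre_id/gene_id rows (the high-confidence set);
    ``promoter_de`` is the promoter-screen DE table. Empty layers are allowed.
    """
    degs = _degs_by_perturbation(promoter_de, adj_p_max, min_abs_lfc, top_k)
    perturbed = set(promoter_de["perturbation"])

    cre_edges = enhancer_links[["cre_id", "gene_id"]].drop_duplicates().reset_index(drop=True)
    targets = set(cre_edges["gene_id"])
    untested = targets - perturbed

    edge_rows = []
    hop1: set = set()
    for g in sorted(targets & perturbed):
        for _, e in degs.get(g, pd.DataFrame()).iterrows():
            sink = e["response_gene"]
            edge_rows.append({"source": g, "sink": sink, "log2fc": e["log2fc"],
                              "adj_p": e["adj_p"], "hop_level": 1})
            if sink not in targets:
                hop1.add(sink)
    hop2: set = set()
    for g in sorted(hop1 & perturbed):
        for _, e in degs.get(g, pd.DataFrame()).iterrows():
            sink = e["response_gene"]
            edge_rows.append({"source": g, "sink": sink, "log2fc": e["log2fc"],
                              "adj_p": e["adj_p"], "hop_level": 2})
            if sink not in targets and sink not in hop1:
                hop2.add(sink)
    edges = pd.DataFrame(edge_rows, columns=["source", "sink", "log2fc", "adj_p", "hop_level"])
    return CascadeNetwork(
        cre_targets=targets, hop1=hop1, hop2=hop2, edges=edges,
        untested_targets=untested, cre_edges=cre_edges,
        thresholds={"adj_p_max": adj_p_max, "min_abs_lfc": min_abs_lfc, "top_k": top_k},
    )


def reachable_fraction(network: CascadeNetwork, n_tested_genes: int) -> float:
    """|cre_targets ∪ hop1 ∪ hop2| / n_tested_genes (set semantics)."""
    reached = network.cre_targets | network.hop1 | network.hop2
    return len(reached) / n_tested_genes


def disease_programs(network: CascadeNetwork, cre_diseases: pd.DataFrame,
                     gene_sets: dict[str, set], universe: set,
                     min_shared: int = 5, alpha: float = 0.05):
    """Per-disease gene programs with gene-set enrichment and shared/unique terms.

    ``cre_diseases`` maps cre_id -> semicolon-joined disease labels. A
    disease's program is the union of layer-0 targets and hop-1 genes reached
    from CREs carrying that label (hop 2 stays out of programs). Returns
    ``(programs, enrichments, partition)``.
    """
    # hop-1 genes reachable from each layer-0 target
    hop1_of: dict[str, set] = {}
    h1 = network.edges[network.edges["hop_level"] == 1]
    for src, sub in h1.groupby("source"):
        hop1_of[src] = set(sub["sink"]) & network.hop1

    label_map: dict[str, set] = {}
    for _, r in cre_diseases.iterrows():
        labels = [l for l in str(r.get("disease_labels", "") or "").split(";") if l]
        for l in labels:
            label_map.setdefault(l, set()).add(r["cre_id"])

    cre_to_targets: dict[str, set] = {}
    for _, e in network.cre_edges.iterrows():
        cre_to_targets.setdefault(e["cre_id"], set()).add(e["gene_id"])

    programs: dict[str, set] = {}
    enrich_frames = []
    for disease in sorted(label_map):
        genes: set = set()
        for cre in label_map[disease]:
            for t in cre_to_targets.get(cre, ()):  # local CRE-gene effects
                genes.add(t)
                genes |= hop1_of.get(t, set())     # downstream hop-1 effects
        genes &= universe
        programs[disease] = genes
        if genes:
            res = geneset_test(genes, universe, gene_sets, alpha=alpha)
            res.insert(0, "disease", disease)
            enrich_frames.append(res)
    enrichments = (pd.concat(enrich_frames, ignore_index=True)
                   if enrich_frames else pd.DataFrame(
                       columns=["disease", "name", "n_set", "n_overlap", "p", "adj_p", "enriched"]))

    if len(enrichments):
        counts = (enrichments[enrichments["enriched"]]
                  .groupby("name")["disease"].nunique())
    else:
        counts = pd.Series(dtype=int)
    partition = pd.DataFrame({
        "term": counts.index,
        "n_diseases_enriched": counts.to_numpy(),
    })
    partition["status"] = np.where(partition["n_diseases_enriched"] > min_shared, "shared",
                                   np.where(partition["n_diseases_enriched"] == 1, "unique", "other"))
    return programs, enrichments, partition
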