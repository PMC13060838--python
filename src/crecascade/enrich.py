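"""Shared 2x2 and gene-set enrichment statistics.

Odds ratios are sample cross-ratios (a*d)/(b*c) with a Haldane-Anscombe +0.5
correction (flagged) whenever a cell is zero; exact p-values always come from
the uncorrected table (two-sided Fisher via the conditional hypergeometric
distribution, one-sided where the test is directional). Gene-set tests are
hypergeometric upper-tail with BH across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError

__all__ = ["fisher_or", "eqtl_enrichment", "tf_target_enrichment",
           "pair_enrichment", "geneset_test"]


def fisher_or(table: list[list[int]] | np.ndarray, alternative: str = "two-sided") -> dict:
    """Fisher's exact test plus the cross-ratio odds ratio for a 2x2 table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataIntegrityError("fisher_or expects a nonnegative 2x2 table")
    a, b, c, d = t.ravel()
    corrected = bool((t == 0).any())
    if corrected:
        af, bf, cf, df = (x + 0.5 for x in (a, b, c, d))
    else:
        af, bf, cf, df = (float(x) for x in (a, b, c, d))
    odds = (af * df) / (bf * cf)
    p = float(scipy.stats.fisher_exact(t, alternative=alternative).pvalue)
    return {"odds_ratio": float(odds), "log_or": float(np.log(odds)),
            "p": p, "zero_cell_corrected": corrected}


def _pairs_result(name: str, sig_pairs: set, all_pairs: set, support: set,
                  direction: pd.Series | None = None) -> dict:
    ns_pairs = all_pairs - sig_pairs
    a = len(sig_pairs & support)
    b = len(sig_pairs - support)
    c = len(ns_pairs & support)
    d = len(ns_pairs - support)
    res = fisher_or([[a, b], [c, d]])
    res.update({"name": name, "a": a, "b": b, "c": c, "d": d, "n_overlap": a})
    return res


def eqtl_enrichment(links: pd.DataFrame, eqtl_catalogs: dict[str, pd.DataFrame],
                    universe: str = "prioritized") -> pd.DataFrame:
    """Per-catalog 2x2 enrichment of eQTL support in significant vs NS links.

    ``universe="prioritized"`` restricts the tested pairs to those predicted
    by at least one source (requires a ``prediction_sources`` column);
    ``"all"`` uses every tested same-chromosome pair. A per-class overlap
    breakdown accompanies each catalog row.
    """
    df = links[links["same_chromosome"]].copy()
    if universe == "prioritized":
        if "prediction_sources" in df.columns:
            df = df[df["prediction_sources"].astype(str).str.len() > 0]
    elif universe != "all":
        raise DataIntegrityError(f"unknown eQTL universe {universe!r}")
    all_pairs = set(zip(df["cre_id"], df["gene_id"]))
    sig_pairs = set(zip(df.loc[df["significant"], "cre_id"],
                        df.loc[df["significant"], "gene_id"]))
    rows = []
    for name, cat in eqtl_catalogs.items():
        support = set(zip(cat["cre_id"], cat["gene_id"])) & all_pairs
        res = _pairs_result(name, sig_pairs, all_pairs, support)
        by_class = (df.assign(supported=[p in support for p in zip(df["cre_id"], df["gene_id"])])
                    .loc[df["significant"].to_numpy()]
                    .groupby("interaction_class", observed=True)["supported"].sum())
        res["class_breakdown"] = ";".join(f"{k}={int(v)}" for k, v in by_class.items())
        rows.append(res)
    return pd.DataFrame(rows)


def pair_enrichment(observed_pairs: set, reference_pairs: set, universe_pairs: set) -> dict:
    """Enrichment of significant perturbation-response pairs in a reference set.

    All sets must live inside the tested-pair universe.
    """
    observed_pairs, reference_pairs = set(observed_pairs), set(reference_pairs)
    universe_pairs = set(universe_pairs)
    for name, s in [("observed", observed_pairs), ("reference", reference_pairs)]:
        if not s <= universe_pairs:
            raise DataIntegrityError(f"{name} pairs are not a subset of the universe")
    return _pairs_result("pair_enrichment", observed_pairs, universe_pairs, reference_pairs)


def tf_target_enrichment(de_results: pd.DataFrame, tf_target_sets: dict[str, pd.DataFrame],
                         min_targets: int = 50, min_degs: int = 5,
                         deg_adj_p: float = 0.1, deg_min_abs_lfc: float = 0.5) -> pd.DataFrame:
    """Per-TF one-sided Fisher enrichment of the TF's DEGs in its target set.

    ``tf_target_sets`` maps TF -> DataFrame(target, mor) where ``mor`` (mode
    of regulation) is +1 activating, -1 repressing, 0/NaN unsigned. TFs with
    fewer than ``min_targets`` annotated targets or fewer than ``min_degs``
    DEGs are excluded. DEGs are split concordant / discordant / unsigned by
    comparing the observed sign with the expectation under TF knockdown
    (activating target of a knocked-down TF should go down).
    """
    rows = []
    for tf, targets in tf_target_sets.items():
        sub = de_results[de_results["perturbation"] == tf]
        if sub.empty or len(targets) < min_targets:
            continue
        tested = sub.dropna(subset=["adj_p"])
        degs = tested[(tested["adj_p"] < deg_adj_p)
                      & (tested["log2fc"].abs() > deg_min_abs_lfc)]
        if len(degs) < min_degs:
            continue
        tset = set(targets["target"])
        deg_set = set(degs["response_gene"])
        nondeg_set = set(tested["response_gene"]) - deg_set
        a = len(deg_set & tset)
        b = len(deg_set - tset)
        c = len(nondeg_set & tset)
        d = len(nondeg_set - tset)
        res = fisher_or([[a, b], [c, d]], alternative="greater")
        mor = dict(zip(targets["target"], targets.get("mor", pd.Series(dtype=float))))
        conc = disc = unsigned = 0
        for _, g in degs.iterrows():
            m = mor.get(g["response_gene"])
            if g["response_gene"] not in tset:
                continue
            if m is None or pd.isna(m) or m == 0:
                unsigned += 1
            # knocked-down TF: activating (+1) target expected down, repressed (-1) up
            elif (m > 0) == (g["log2fc"] < 0):
                conc += 1
            else:
                disc += 1
        res.update({
            "name": tf, "a": a, "b": b, "c": c, "d": d,
            "n_overlap": a, "n_degs": len(deg_set), "n_targets": len(tset),
            "observed_frac": a / len(deg_set),
            "expected_frac": (a + c) / max(len(deg_set) + len(nondeg_set), 1),
            "concordant": conc, "discordant": disc, "unsigned": unsigned,
        })
        rows.append(res)
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def geneset_test(query_genes: set, universe: set, gene_sets: dict[str, set],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per gene set, BH across sets."""
    query = set(query_genes)
    universe = set(universe)
    if not query <= universe:
        raise DataIntegrityError("query genes are not a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & universe)
        k = len(set(members) & query)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"name": name, "n_set": K, "n_overlap": k, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
        out["enriched"] = out["adj_p"] < alpha
    return out
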