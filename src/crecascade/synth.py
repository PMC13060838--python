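"""Synthetic CRISPRi screen generator.

Produces a fully specified regulatory "world" (gene annotation, CREs, true
CRE-gene links, a sparse directed trans-regulatory network, TADs, Hi-C
contacts, chromatin signals, eQTL catalogs, prediction-source link lists) and
then simulates observed single-cell UMI screens against it:

* a *CRE screen* — TAP-seq-style targeted readout of candidate genes under
  CRISPRi perturbation of CREs (weak enhancer/silencer effects, strong
  promoter effects), and
* a *promoter screen* — genome-wide readout under direct gene knockdowns,
  whose differential effects come from the trans network.

Counts follow a negative-binomial hierarchy:

    count(cell i, gene g) ~ NB(mean = s_i * d(donor_i, g) * base_g * 2**eff,
                               dispersion alpha_g)

with lognormal library sizes s_i, gene-wise lognormal donor multipliers, and
``eff`` the summed log2 effects of the cell's assigned perturbation (direct
link effects; optionally one multiplicative trans hop). Roughly 80% of cells
carry exactly one identified gRNA; the rest carry zero or two.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, DataIntegrityError
from . import io as cio

__all__ = [
    "AnnotationParams", "RegulatoryParams", "ScreenConfig", "RegulatoryTruth",
    "generate_truth", "simulate_screen", "write_fixture_set", "make_gene_sets",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class AnnotationParams:
    """Controls the synthetic gene annotation.

    Baseline means are drawn lognormal (heavy-tailed expression, TPM-like
    role) and later rescaled per screen so the realized depth matches the
    screen's mean UMI per cell. Dispersions are lognormal around ~0.5, the
    typical per-cell NB overdispersion of UMI data.
    """
    n_genes: int = 300
    n_chroms: int = 4
    chrom_length: int = 30_000_000
    gene_length_meanlog: float = np.log(20_000.0)
    gene_length_sdlog: float = 0.6
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.2
    dispersion_meanlog: float = np.log(0.5)
    dispersion_sdlog: float = 0.4

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_chroms <= 0:
            raise ConfigError("n_chroms must be positive")
        if self.chrom_length < self.n_genes // self.n_chroms * 50_000:
            raise ConfigError("chrom_length too small for requested gene density")


@dataclass
class RegulatoryParams:
    """Controls CREs, true links, the trans network and the evidence layers.

    Defaults encode the regime the analysis expects: weak enhancer/silencer
    effects (|log2FC| in 0.05-0.3), strong promoter knockdowns, ~27% of true
    cis links repressive (silencers, positive log2FC under CRISPRi), ~1.6
    targets per active CRE, chromatin and Hi-C signal decaying with
    CRE-TSS distance, contacts elevated within TADs.
    """
    n_cres: int = 60
    promoter_cre_fraction: float = 0.15
    inactive_cre_fraction: float = 0.25
    extra_targets_mean: float = 0.6          # targets per active CRE = 1 + Poisson(.)
    silencer_fraction: float = 0.27
    enhancer_lfc_range: tuple[float, float] = (0.05, 0.3)
    promoter_lfc_range: tuple[float, float] = (1.0, 3.0)
    max_link_distance: float = 2_000_000.0
    local_link_fraction: float = 0.8         # fraction of enhancer links placed <100 kb

    # trans network
    trans_out_degree_mean: float = 2.0
    trans_lfc_range: tuple[float, float] = (0.1, 0.8)
    trans_silencer_fraction: float = 0.3     # fraction of trans edges with positive lfc
    allow_cycles: bool = False

    # TADs and Hi-C
    tad_size_meanlog: float = np.log(500_000.0)
    tad_size_sdlog: float = 0.4
    hic_decay_exponent: float = 0.8
    hic_tad_boost: float = 3.0
    hic_link_boost: float = 2.0
    hic_noise_sdlog: float = 0.5

    # chromatin signal (class-conditional lognormals x distance decay)
    chromatin_decay_exponent: float = 0.25
    chromatin_sdlog: float = 0.4
    # enhancer strength (|lfc|) decays mildly with CRE-TSS distance
    lfc_decay_exponent: float = 0.15

    # evidence layers
    n_diseases: int = 6
    disease_labels_per_cre_mean: float = 1.2
    eqtl_catalogs: dict = field(default_factory=lambda: {
        "cd4_t_cells": (0.5, 0.02),
        "whole_blood": (0.35, 0.04),
        "other_tissue": (0.08, 0.04),
    })
    # name -> (recall of true links, target precision) for sampled sources
    sampled_sources: dict = field(default_factory=lambda: {
        "grn": (0.40, 0.15),
        "re2g": (0.45, 0.32),
        "eqtl_links": (0.20, 0.35),
    })
    n_control_promoters: int = 5
    n_panels: int = 1

    def validate(self) -> None:
        if self.n_cres <= 0:
            raise ConfigError("n_cres must be positive")
        for name in ["promoter_cre_fraction", "inactive_cre_fraction",
                     "silencer_fraction", "local_link_fraction",
                     "trans_silencer_fraction"]:
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ["enhancer_lfc_range", "promoter_lfc_range", "trans_lfc_range"]:
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ConfigError(f"{name} must satisfy 0 <= lo < hi, got {(lo, hi)!r}")
        if self.n_panels <= 0:
            raise ConfigError("n_panels must be positive")


@dataclass
class ScreenConfig:
    """Scale and noise structure of one simulated screen.

    ``grna_per_target`` defaults to 8 for CRE perturbations and 3 for
    promoter (gene) perturbations when left as None.
    """
    n_cells: int = 10_000
    n_donors: int = 3
    grna_per_target: int | None = None
    n_nontargeting: int = 30
    unique_assignment_rate: float = 0.8
    mean_umi_per_cell: float = 5_000.0
    library_size_cv: float = 0.5
    donor_effect_sd: float = 0.10
    grna_active_fraction: float = 0.85
    propagate_trans: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ["n_cells", "n_donors", "n_nontargeting"]:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.unique_assignment_rate <= 1):
            raise ConfigError("unique_assignment_rate must lie in (0, 1]")
        if not (0 <= self.grna_active_fraction <= 1):
            raise ConfigError("grna_active_fraction must lie in [0, 1]")
        if self.mean_umi_per_cell <= 0 or self.library_size_cv < 0:
            raise ConfigError("invalid library-size parameters")
        if self.grna_per_target is not None and self.grna_per_target <= 0:
            raise ConfigError("grna_per_target must be positive")


@dataclass
class RegulatoryTruth:
    """Ground truth for one synthetic world; all tables are DataFrames."""
    cres: pd.DataFrame            # cre_id chrom start end center disease_labels atac h3k27ac h3k4me1 h3k4me3 cre_class panel
    true_cre_links: pd.DataFrame  # cre_id gene_id lfc mechanism
    trans_edges: pd.DataFrame     # src dst lfc
    tads: pd.DataFrame            # chrom start end name
    hic_contacts: pd.DataFrame    # cre_id gene_id contact
    eqtl_catalogs: dict           # name -> DataFrame(cre_id, gene_id)
    prediction_sources: dict      # name -> DataFrame(cre_id, gene_id)
    candidates: pd.DataFrame      # cre_id gene_id distance (the tested universe)
    control_promoters: pd.DataFrame  # target_id gene_id  (positive-control promoter perturbations)

    def validate(self, annotation: pd.DataFrame) -> None:
        genes = set(annotation["gene_id"])
        cres = set(self.cres["cre_id"])
        for name, df, id_cols in [
            ("true_cre_links", self.true_cre_links, [("cre_id", cres), ("gene_id", genes)]),
            ("hic_contacts", self.hic_contacts, [("cre_id", cres), ("gene_id", genes)]),
            ("candidates", self.candidates, [("cre_id", cres), ("gene_id", genes)]),
            ("trans_edges", self.trans_edges, [("src", genes), ("dst", genes)]),
        ]:
            for col, universe in id_cols:
                unknown = set(df[col]) - universe
                if unknown:
                    raise DataIntegrityError(f"{name}.{col} references unknown ids "
                                             f"{sorted(unknown)[:5]}")


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def _make_annotation(p: AnnotationParams, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(p.n_chroms, p.n_genes // p.n_chroms)
    per_chrom[: p.n_genes % p.n_chroms] += 1
    rows = []
    gi = 0
    for ci in range(p.n_chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = np.exp(rng.normal(p.gene_length_meanlog, p.gene_length_sdlog, n))
        lengths = np.clip(lengths, 1_000, p.chrom_length // max(n, 1)).astype(np.int64)
        # random non-overlapping placement: distribute leftover space as gaps
        free = p.chrom_length - int(lengths.sum())
        gaps = rng.dirichlet(np.ones(n + 1)) * free
        starts = (np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])).astype(np.int64)
        strands = rng.choice(["+", "-"], n)
        for j in range(n):
            s, e = int(starts[j]), int(starts[j] + lengths[j])
            rows.append({
                "gene_id": f"G{gi:04d}", "chrom": f"chr{ci + 1}", "strand": strands[j],
                "body_start": s, "body_end": e,
                "tss": s if strands[j] == "+" else e - 1,
            })
            gi += 1
    df = pd.DataFrame(rows)
    base = np.exp(rng.normal(p.baseline_meanlog, p.baseline_sdlog, len(df)))
    df["baseline_mean"] = base
    df["dispersion"] = np.clip(
        np.exp(rng.normal(p.dispersion_meanlog, p.dispersion_sdlog, len(df))), 0.05, 3.0)
    return cio.validate_annotation(df, "synthetic annotation")


def _make_tads(p: RegulatoryParams, chroms: list[str], chrom_length: int,
               rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in chroms:
        pos, k = 0, 0
        while pos < chrom_length:
            size = int(np.exp(rng.normal(p.tad_size_meanlog, p.tad_size_sdlog)))
            end = min(pos + max(size, 50_000), chrom_length)
            rows.append({"chrom": chrom, "start": pos, "end": end,
                         "name": f"{chrom}_tad{k}"})
            pos, k = end, k + 1
    return pd.DataFrame(rows)


def _chromatin_decay(dist: np.ndarray, exponent: float) -> np.ndarray:
    return (1.0 + np.asarray(dist, float) / 10_000.0) ** (-exponent)


def _nearest_tss_distance(center: int, chrom: str, annotation: pd.DataFrame) -> float:
    sub = annotation.loc[annotation["chrom"] == chrom, "tss"]
    if sub.empty:
        return np.inf
    return float(np.min(np.abs(sub.to_numpy() - center)))


def generate_truth(annotation_params: AnnotationParams | None = None,
                   regulatory_params: RegulatoryParams | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, RegulatoryTruth]:
    """Generate a synthetic regulatory world. Deterministic for a fixed seed."""
    ap = annotation_params or AnnotationParams()
    rp = regulatory_params or RegulatoryParams()
    ap.validate()
    rp.validate()
    rng = np.random.default_rng(seed)

    annotation = _make_annotation(ap, rng)
    tss = annotation.set_index("gene_id")["tss"]
    gene_chrom = annotation.set_index("gene_id")["chrom"]
    chroms = sorted(annotation["chrom"].unique(), key=lambda c: int(c[3:]))

    # --- CRE placement and true links -------------------------------------
    n_promoter = int(round(rp.n_cres * rp.promoter_cre_fraction))
    n_other = rp.n_cres - n_promoter
    cre_rows, link_rows = [], []
    diseases = [f"disease{d + 1}" for d in range(rp.n_diseases)]

    # CREs anchor to expressed genes: targeted screens select candidate genes
    # with detectable expression in the assayed cell type
    pool = annotation[annotation["baseline_mean"]
                      >= annotation["baseline_mean"].quantile(0.4)]
    anchor_genes = pool.sample(n=rp.n_cres, replace=rp.n_cres > len(pool),
                               weights=np.sqrt(pool["baseline_mean"]),
                               random_state=int(rng.integers(2 ** 31)))
    for k in range(rp.n_cres):
        g = anchor_genes.iloc[k]
        cre_id = f"CRE{k:04d}"
        width = int(rng.integers(300, 1200))
        if k < n_promoter:
            cre_class = "promoter"
            center = int(g["tss"] + rng.integers(-400, 401))
            mech, n_targets = "promoter", 1
        else:
            cre_class = "enhancer"
            if rng.random() < rp.local_link_fraction:
                dist = float(np.exp(rng.uniform(np.log(2_000), np.log(100_000))))
            else:
                dist = float(np.exp(rng.uniform(np.log(100_000), np.log(rp.max_link_distance))))
            center = int(g["tss"] + rng.choice([-1, 1]) * dist)
            center = int(np.clip(center, width, ap.chrom_length - width))
            mech = "enhancer"
            n_targets = 0 if rng.random() < rp.inactive_cre_fraction \
                else 1 + int(rng.poisson(rp.extra_targets_mean))
        start = max(0, center - width // 2)
        n_labels = min(int(rng.poisson(rp.disease_labels_per_cre_mean)), rp.n_diseases)
        labels = sorted(rng.choice(diseases, size=n_labels, replace=False)) if n_labels else []
        cre_rows.append({
            "cre_id": cre_id, "chrom": g["chrom"], "start": start,
            "end": start + width, "center": start + width // 2,
            "disease_labels": ";".join(labels), "cre_class": cre_class,
        })
        # primary target is the anchor gene; extra targets: nearby genes
        targets = [g["gene_id"]]
        if n_targets > 1:
            same = annotation[annotation["chrom"] == g["chrom"]]
            near = same.iloc[np.argsort(np.abs(same["tss"].to_numpy() - center))]
            for extra in near["gene_id"]:
                if extra not in targets:
                    targets.append(extra)
                if len(targets) >= n_targets:
                    break
        if mech == "promoter":
            lo, hi = rp.promoter_lfc_range
            link_rows.append({"cre_id": cre_id, "gene_id": g["gene_id"],
                              "lfc": -float(rng.uniform(lo, hi)), "mechanism": "promoter"})
        else:
            lo, hi = rp.enhancer_lfc_range
            for t in targets[:n_targets]:
                d_t = abs(int(tss[t]) - (start + width // 2))
                strength = float(rng.uniform(lo, hi)) * float(
                    _chromatin_decay(d_t, rp.lfc_decay_exponent))
                if rng.random() < rp.silencer_fraction:
                    link_rows.append({"cre_id": cre_id, "gene_id": t,
                                      "lfc": strength, "mechanism": "silencer"})
                else:
                    link_rows.append({"cre_id": cre_id, "gene_id": t,
                                      "lfc": -strength, "mechanism": "enhancer"})
    cres = pd.DataFrame(cre_rows)
    links = pd.DataFrame(link_rows, columns=["cre_id", "gene_id", "lfc", "mechanism"])

    # --- trans network (acyclic by topological order unless allowed) -------
    order = rng.permutation(len(annotation))
    rank = {annotation["gene_id"].iloc[order[i]]: i for i in range(len(order))}
    trans_rows = []
    lo, hi = rp.trans_lfc_range
    for gid in annotation["gene_id"]:
        deg = int(rng.poisson(rp.trans_out_degree_mean))
        if deg == 0:
            continue
        others = annotation["gene_id"][annotation["gene_id"] != gid]
        if not rp.allow_cycles:
            others = others[[rank[o] > rank[gid] for o in others]]
        if len(others) == 0:
            continue
        dsts = rng.choice(others, size=min(deg, len(others)), replace=False)
        for d in dsts:
            sign = 1.0 if rng.random() < rp.trans_silencer_fraction else -1.0
            trans_rows.append({"src": gid, "dst": d, "lfc": sign * float(rng.uniform(lo, hi))})
    trans_edges = pd.DataFrame(trans_rows, columns=["src", "dst", "lfc"])

    # --- TADs --------------------------------------------------------------
    tads = _make_tads(rp, chroms, ap.chrom_length, rng)

    # --- prediction sources and the tested candidate universe --------------
    sources: dict[str, pd.DataFrame] = {}
    pair_rows = []
    for _, c in cres.iterrows():
        same = annotation[annotation["chrom"] == c["chrom"]]
        d = np.abs(same["tss"].to_numpy() - c["center"])
        within = same.loc[d < 100_000, "gene_id"]
        for gid in within:
            pair_rows.append({"cre_id": c["cre_id"], "gene_id": gid, "source": "within_100kb"})
        # nearest up/downstream genes outside the window
        up = same[(same["tss"] < c["center"]) & (np.abs(same["tss"] - c["center"]) >= 100_000)]
        dn = same[(same["tss"] >= c["center"]) & (np.abs(same["tss"] - c["center"]) >= 100_000)]
        for block in (up.tail(1) if not up.empty else None,
                      dn.head(1) if not dn.empty else None):
            if block is not None:
                pair_rows.append({"cre_id": c["cre_id"],
                                  "gene_id": block["gene_id"].iloc[0],
                                  "source": "nearest_gene"})
    det = pd.DataFrame(pair_rows)
    for name in ["within_100kb", "nearest_gene"]:
        sources[name] = (det.loc[det["source"] == name, ["cre_id", "gene_id"]]
                         .drop_duplicates().reset_index(drop=True))

    enhancer_links = links[links["mechanism"] != "promoter"]
    same_chrom_pool = det[["cre_id", "gene_id"]].drop_duplicates()
    truth_keys = set(zip(links["cre_id"], links["gene_id"]))
    noise_pool = same_chrom_pool[
        [k not in truth_keys for k in zip(same_chrom_pool["cre_id"], same_chrom_pool["gene_id"])]
    ]
    for name, (recall, precision) in rp.sampled_sources.items():
        n_true = int(round(recall * len(enhancer_links)))
        picked = enhancer_links.sample(n=n_true, random_state=int(rng.integers(2 ** 31))) \
            if n_true else enhancer_links.iloc[:0]
        n_noise = int(round(n_true * (1 - precision) / max(precision, 1e-9)))
        n_noise = min(n_noise, len(noise_pool))
        noise = noise_pool.sample(n=n_noise, random_state=int(rng.integers(2 ** 31))) \
            if n_noise else noise_pool.iloc[:0]
        sources[name] = (pd.concat([picked[["cre_id", "gene_id"]], noise])
                         .drop_duplicates().reset_index(drop=True))

    candidates = (pd.concat([s for s in sources.values()])
                  .drop_duplicates().reset_index(drop=True))
    cre_center = cres.set_index("cre_id")["center"]
    cre_chr = cres.set_index("cre_id")["chrom"]
    candidates["distance"] = [
        abs(int(cre_center[c]) - int(tss[g])) if cre_chr[c] == gene_chrom[g] else -1
        for c, g in zip(candidates["cre_id"], candidates["gene_id"])
    ]

    # --- Hi-C contacts over candidates ∪ true links ------------------------
    hic_pairs = pd.concat([candidates[["cre_id", "gene_id"]],
                           links[["cre_id", "gene_id"]]]).drop_duplicates()
    tad_bounds = {ch: np.sort(tads.loc[tads["chrom"] == ch, "start"].to_numpy())
                  for ch in chroms}
    contacts = []
    for c, g in zip(hic_pairs["cre_id"], hic_pairs["gene_id"]):
        if cre_chr[c] != gene_chrom[g]:
            contacts.append(0.0)
            continue
        a, b = int(cre_center[c]), int(tss[g])
        dist = abs(a - b)
        bounds = tad_bounds[cre_chr[c]]
        same_tad = not np.any((bounds > min(a, b)) & (bounds <= max(a, b)))
        val = 1e4 * (dist + 5_000.0) ** (-rp.hic_decay_exponent)
        if same_tad:
            val *= rp.hic_tad_boost
        if (c, g) in truth_keys:
            val *= rp.hic_link_boost
        val *= float(np.exp(rng.normal(0.0, rp.hic_noise_sdlog)))
        contacts.append(val)
    hic = hic_pairs.assign(contact=contacts).reset_index(drop=True)

    # --- chromatin signals (class-conditional, distance-decayed) -----------
    n = len(cres)
    dists = np.array([
        _nearest_tss_distance(int(r["center"]), r["chrom"], annotation)
        for _, r in cres.iterrows()
    ])
    decay = _chromatin_decay(dists, rp.chromatin_decay_exponent)
    is_prom = (cres["cre_class"] == "promoter").to_numpy()
    active = cres["cre_id"].isin(enhancer_links["cre_id"]).to_numpy() | is_prom
    ln = lambda mean: np.exp(rng.normal(np.log(mean), rp.chromatin_sdlog, n))
    # promoter-like: H3K4me3-high; enhancer-like: H3K27ac/H3K4me1-high, H3K4me3-low
    cres["atac"] = np.where(is_prom, ln(8.0), np.where(active, ln(6.0) * decay, ln(1.5)))
    cres["h3k27ac"] = np.where(is_prom, ln(5.0), np.where(active, ln(8.0) * decay, ln(1.0)))
    cres["h3k4me1"] = np.where(is_prom, ln(2.0), np.where(active, ln(8.0) * decay, ln(1.5)))
    cres["h3k4me3"] = np.where(is_prom, ln(10.0), np.where(active, ln(1.0) * decay, ln(0.5)))

    # --- panels and positive-control promoters ------------------------------
    cres["panel"] = [f"panel{k % rp.n_panels}" for k in range(len(cres))]
    expressed = annotation.sort_values("baseline_mean", ascending=False)
    ctrl_genes = expressed["gene_id"].head(rp.n_control_promoters).tolist()
    control_promoters = pd.DataFrame({
        "target_id": [f"ctrlprom_{g}" for g in ctrl_genes],
        "gene_id": ctrl_genes,
    })

    # --- eQTL catalogs ------------------------------------------------------
    catalogs = {}
    for name, (link_rate, bg_rate) in rp.eqtl_catalogs.items():
        keep_true = enhancer_links[rng.random(len(enhancer_links)) < link_rate]
        keep_bg = noise_pool[rng.random(len(noise_pool)) < bg_rate]
        catalogs[name] = (pd.concat([keep_true[["cre_id", "gene_id"]], keep_bg])
                          .drop_duplicates().reset_index(drop=True))

    truth = RegulatoryTruth(
        cres=cres, true_cre_links=links, trans_edges=trans_edges, tads=tads,
        hic_contacts=hic, eqtl_catalogs=catalogs, prediction_sources=sources,
        candidates=candidates, control_promoters=control_promoters,
    )
    truth.validate(annotation)
    return annotation, truth


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

def _effect_table(annotation: pd.DataFrame, truth: RegulatoryTruth,
                  targets: pd.DataFrame, propagate_trans: bool) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per perturbation target: (gene index array, summed log2 effect array)."""
    gene_index = {g: i for i, g in enumerate(annotation["gene_id"])}
    out_edges: dict[str, list[tuple[str, float]]] = {}
    if propagate_trans:
        for _, e in truth.trans_edges.iterrows():
            out_edges.setdefault(e["src"], []).append((e["dst"], e["lfc"]))

    effects: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for _, t in targets.iterrows():
        acc: dict[int, float] = {}

        def add(gid: str, lfc: float) -> None:
            gi = gene_index.get(gid)
            if gi is not None:
                acc[gi] = acc.get(gi, 0.0) + lfc

        direct: list[tuple[str, float]] = []
        if t["target_kind"] == "cre":
            sub = truth.true_cre_links[truth.true_cre_links["cre_id"] == t["target_id"]]
            direct = list(zip(sub["gene_id"], sub["lfc"]))
        elif t["target_kind"] in ("promoter", "control_promoter"):
            direct = [(t["gene_id"], t["direct_lfc"])]
        for gid, lfc in direct:
            add(gid, lfc)
            if propagate_trans:
                for dst, elfc in out_edges.get(gid, []):
                    add(dst, elfc)   # one multiplicative hop
        if acc:
            idx = np.array(sorted(acc), dtype=np.int64)
            effects[t["target_id"]] = (idx, np.array([acc[i] for i in idx]))
        else:
            effects[t["target_id"]] = (np.empty(0, np.int64), np.empty(0))
    return effects


def _build_grna_table(targets: pd.DataFrame, config: ScreenConfig, mode: str,
                      rng: np.random.Generator) -> pd.DataFrame:
    per = config.grna_per_target or (8 if mode == "cre" else 3)
    rows = []
    for _, t in targets.iterrows():
        for j in range(per):
            active = bool(rng.random() < config.grna_active_fraction)
            rows.append({"grna_id": f"{t['target_id']}_g{j}",
                         "target_id": t["target_id"],
                         "target_kind": t["target_kind"],
                         "panel": t["panel"], "active": active})
    panels = sorted(targets["panel"].unique())
    for j in range(config.n_nontargeting):
        rows.append({"grna_id": f"NT_g{j}", "target_id": "non-targeting",
                     "target_kind": "non-targeting",
                     "panel": panels[j % len(panels)], "active": False})
    return pd.DataFrame(rows)


def simulate_screen(annotation: pd.DataFrame, truth: RegulatoryTruth,
                    config: ScreenConfig, mode: str = "cre",
                    promoter_targets: list[str] | None = None,
                    promoter_lfc: float | dict | None = None) -> ad.AnnData:
    """Simulate one observed screen dataset (cells x genes AnnData).

    ``mode="cre"`` perturbs every CRE plus the positive-control promoters and
    measures only the TAP panel genes (off-panel counts are zero for each
    cell's panel). ``mode="promoter"`` perturbs genes directly (default: every
    CRE target gene and every trans-network source) and measures all genes.
    """
    config.validate()
    if mode not in ("cre", "promoter"):
        raise ConfigError(f"unknown screen mode {mode!r}")
    truth.validate(annotation)
    rng = np.random.default_rng(config.seed)

    gene_ids = annotation["gene_id"].to_numpy()
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    # perturbation target table
    if mode == "cre":
        t1 = truth.cres[["cre_id", "panel"]].rename(columns={"cre_id": "target_id"})
        t1["target_kind"] = "cre"
        t1["gene_id"] = ""
        t1["direct_lfc"] = 0.0
        lo, hi = 1.0, 3.0
        t2 = truth.control_promoters.copy()
        t2["target_kind"] = "control_promoter"
        t2["panel"] = [sorted(truth.cres["panel"].unique())[i % truth.cres["panel"].nunique()]
                       for i in range(len(t2))]
        t2["direct_lfc"] = -rng.uniform(lo, hi, size=len(t2))
        targets = pd.concat([t1, t2], ignore_index=True)
    else:
        if promoter_targets is None:
            promoter_targets = sorted(
                set(truth.true_cre_links["gene_id"]) | set(truth.trans_edges["src"]))
        missing = [g for g in promoter_targets if g not in gene_index]
        if missing:
            raise DataIntegrityError(f"promoter targets absent from annotation: {missing[:5]}")
        if promoter_lfc is None:
            lfcs = -rng.uniform(1.0, 3.0, size=len(promoter_targets))
        elif isinstance(promoter_lfc, dict):
            lfcs = [promoter_lfc[g] for g in promoter_targets]
        else:
            lfcs = float(promoter_lfc)
        targets = pd.DataFrame({
            "target_id": promoter_targets,
            "gene_id": promoter_targets,
            "target_kind": "promoter",
            "panel": "genomewide",
            "direct_lfc": lfcs,
        })

    grnas = _build_grna_table(targets, config, mode, rng)
    # inactive gRNAs exert no effect
    effects = _effect_table(annotation, truth, targets, config.propagate_trans)
    effects["non-targeting"] = (np.empty(0, np.int64), np.empty(0))

    # panel gene sets (TAP readout); promoter screen reads everything
    panel_genes: dict[str, np.ndarray] = {}
    if mode == "cre":
        cand = truth.candidates.merge(truth.cres[["cre_id", "panel"]], on="cre_id")
        for panel, sub in cand.groupby("panel"):
            gset = set(sub["gene_id"]) | set(truth.control_promoters["gene_id"])
            panel_genes[panel] = np.array(sorted(gene_index[g] for g in gset))
    # measured gene mask per panel
    all_idx = np.arange(n_genes)

    # cell-level structure
    n = config.n_cells
    donors = rng.integers(config.n_donors, size=n)
    sigma = np.sqrt(np.log1p(config.library_size_cv ** 2))
    base = annotation["baseline_mean"].to_numpy().astype(float)
    base = base / base.sum() * config.mean_umi_per_cell
    s = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=n))  # mean 1 lognormal
    donor_mult = np.exp(rng.normal(
        -config.donor_effect_sd ** 2 / 2, config.donor_effect_sd,
        size=(config.n_donors, n_genes)))
    alpha = annotation["dispersion"].to_numpy().astype(float)

    # gRNA assignment: unique_assignment_rate of cells get exactly one gRNA;
    # the remainder split evenly between zero and two detected gRNAs.
    u = rng.random(n)
    n_grnas_per_cell = np.where(u < config.unique_assignment_rate, 1,
                                np.where(u < (1 + config.unique_assignment_rate) / 2, 0, 2))
    grna_ids = grnas["grna_id"].to_numpy()
    assign_rows = []
    cell_grnas: list[list[int]] = []
    for i in range(n):
        k = int(n_grnas_per_cell[i])
        picks = list(rng.choice(len(grna_ids), size=k, replace=False)) if k else []
        cell_grnas.append(picks)
    cell_ids = np.array([f"cell{i:06d}" for i in range(n)])
    for i, picks in enumerate(cell_grnas):
        for gi in picks:
            assign_rows.append({"cell_id": cell_ids[i], "grna_id": grna_ids[gi],
                                "target_id": grnas["target_id"].iloc[gi]})
    assignments = pd.DataFrame(assign_rows, columns=["cell_id", "grna_id", "target_id"])

    grna_panel = grnas["panel"].to_numpy()
    grna_target = grnas["target_id"].to_numpy()
    grna_active = grnas["active"].to_numpy()
    panels_avail = sorted(set(grna_panel))
    cell_panel = np.array([
        grna_panel[picks[0]] if picks else panels_avail[int(rng.integers(len(panels_avail)))]
        for picks in cell_grnas
    ])

    # simulate counts in chunks
    chunks = []
    chunk_size = max(1, int(2_000_000 // max(n_genes, 1)))
    log2 = np.log(2.0)
    for lo_i in range(0, n, chunk_size):
        hi_i = min(lo_i + chunk_size, n)
        m = hi_i - lo_i
        mu = np.outer(s[lo_i:hi_i], base)
        mu *= donor_mult[donors[lo_i:hi_i], :]
        for i in range(lo_i, hi_i):
            for gi in cell_grnas[i]:
                if not grna_active[gi] and grna_target[gi] != "non-targeting":
                    continue
                idx, lfc = effects[grna_target[gi]]
                if len(idx):
                    mu[i - lo_i, idx] *= np.exp(log2 * lfc)
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        counts = rng.poisson(lam)
        if mode == "cre" and panel_genes:
            # TAP readout: zero out genes not on the cell's panel
            mask = np.zeros((m, n_genes), dtype=bool)
            for panel, idx in panel_genes.items():
                rows_sel = np.nonzero(cell_panel[lo_i:hi_i] == panel)[0]
                if len(rows_sel):
                    mask[np.ix_(rows_sel, idx)] = True
            counts = np.where(mask, counts, 0)
        chunks.append(sp.csr_matrix(counts.astype(np.int64)))
    X = sp.vstack(chunks).tocsr()

    obs = pd.DataFrame({
        "donor": [f"donor{d + 1}" for d in donors],
        "panel": cell_panel,
        "n_grnas": n_grnas_per_cell,
        "grna_id": [grna_ids[picks[0]] if len(picks) == 1 else "" for picks in cell_grnas],
        "target_id": [grna_target[picks[0]] if len(picks) == 1 else "" for picks in cell_grnas],
    }, index=pd.Index(cell_ids, name="cell_id"))

    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = gene_ids
    adata.var["chrom"] = annotation["chrom"].to_numpy()
    adata.var["baseline_mean"] = base
    adata.var["dispersion"] = alpha
    adata.uns["assignments"] = assignments
    adata.uns["grna_table"] = grnas
    adata.uns["mode"] = mode
    adata.uns["screen_config"] = {k: (v if not isinstance(v, np.generic) else v.item())
                                  for k, v in vars(config).items()}
    return adata


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixture_set(outdir: str | Path, annotation: pd.DataFrame,
                      truth: RegulatoryTruth, screens: dict[str, ad.AnnData],
                      manifest_extra: dict | None = None) -> None:
    """Write the complete fixture set for a synthetic world to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_table(annotation, outdir / "annotation.tsv")
    cio.write_intervals(truth.cres.rename(columns={"cre_id": "name"}), outdir / "cres.bed")
    cio.write_table(truth.cres, outdir / "cres.tsv")
    cio.write_table(truth.true_cre_links, outdir / "truth_links.tsv")
    cio.write_table(truth.trans_edges, outdir / "trans_edges.tsv")
    cio.write_intervals(truth.tads, outdir / "tads.bed")
    cio.write_table(truth.hic_contacts, outdir / "hic.tsv")
    cio.write_table(truth.candidates, outdir / "candidates.tsv")
    cio.write_table(truth.control_promoters, outdir / "control_promoters.tsv")
    for name, df in truth.eqtl_catalogs.items():
        cio.write_table(df, outdir / f"eqtl_{name}.tsv")
    for name, df in truth.prediction_sources.items():
        cio.write_table(df, outdir / f"predictions_{name}.tsv")
    write_gene_sets(make_gene_sets(annotation, truth), outdir / "gene_sets.tsv")
    for prefix, adata in screens.items():
        cio.write_screen_dataset(adata, outdir, prefix=f"{prefix}_")
    manifest = {"screens": {k: dict(v.uns.get("screen_config", {})) for k, v in screens.items()}}
    if manifest_extra:
        manifest.update(manifest_extra)
    cio.write_manifest(manifest, outdir / "manifest.json")


def make_gene_sets(annotation: pd.DataFrame, truth: RegulatoryTruth,
                   n_random_sets: int = 15, seed: int = 0) -> dict[str, set]:
    """GO-like gene sets for program enrichment on a synthetic world.

    'Regulon' sets are the trans-network targets of the highest out-degree
    genes (real structure the cascades can enrich for); random sets provide
    the null background.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, set] = {}
    if len(truth.trans_edges):
        deg = truth.trans_edges.groupby("src").size().sort_values(ascending=False)
        for src in deg.index[:10]:
            members = set(truth.trans_edges.loc[truth.trans_edges["src"] == src, "dst"])
            if len(members) >= 5:
                sets[f"regulon_{src}"] = members | {src}
    genes = annotation["gene_id"].to_numpy()
    for k in range(n_random_sets):
        size = int(rng.integers(10, 40))
        sets[f"random_set{k}"] = set(rng.choice(genes, size=min(size, len(genes)),
                                                replace=False))
    return sets


def write_gene_sets(sets: dict[str, set], path: str | Path) -> None:
    rows = [{"set_name": name, "gene_id": g} for name in sorted(sets)
            for g in sorted(sets[name])]
    cio.write_table(pd.DataFrame(rows), path)


def read_gene_sets(path: str | Path) -> dict[str, set]:
    df = cio.read_table(path)
    return {name: set(sub["gene_id"]) for name, sub in df.groupby("set_name")}


def read_truth(outdir: str | Path) -> tuple[pd.DataFrame, RegulatoryTruth]:
    """Round-trip loader for a written fixture set (ground-truth tables only)."""
    outdir = Path(outdir)
    annotation = cio.read_annotation(outdir / "annotation.tsv")
    cres = cio.read_table(outdir / "cres.tsv")
    cres["disease_labels"] = cres["disease_labels"].fillna("")
    catalogs = {p.stem[len("eqtl_"):]: cio.read_table(p)
                for p in sorted(outdir.glob("eqtl_*.tsv"))}
    sources = {p.stem[len("predictions_"):]: cio.read_table(p)
               for p in sorted(outdir.glob("predictions_*.tsv"))}
    truth = RegulatoryTruth(
        cres=cres,
        true_cre_links=cio.read_table(outdir / "truth_links.tsv"),
        trans_edges=cio.read_table(outdir / "trans_edges.tsv"),
        tads=cio.read_intervals(outdir / "tads.bed", format="bed"),
        hic_contacts=cio.read_table(outdir / "hic.tsv"),
        eqtl_catalogs=catalogs, prediction_sources=sources,
        candidates=cio.read_table(outdir / "candidates.tsv"),
        control_promoters=cio.read_table(outdir / "control_promoters.tsv"),
    )
    truth.validate(annotation)
    return annotation, truth
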