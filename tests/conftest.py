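import numpy as np
import pandas as pd
import pytest

from crecascade import synth


@pytest.fixture(scope="session")
def small_world():
    """Default-size synthetic world shared across read-only tests."""
    return synth.generate_truth(seed=7)


@pytest.fixture(scope="session")
def cre_screen(small_world):
    ann, truth = small_world
    cfg = synth.ScreenConfig(n_cells=6000, seed=8)
    return synth.simulate_screen(ann, truth, cfg, mode="cre")


@pytest.fixture()
def tiny_annotation():
    """Three genes on two chromosomes with known coordinates."""
    return pd.DataFrame({
        "gene_id": ["A", "B", "C"],
        "chrom": ["chr1", "chr1", "chr2"],
        "strand": ["+", "-", "+"],
        "body_start": [100_000, 200_000, 50_000],
        "body_end": [150_000, 260_000, 80_000],
        "tss": [100_000, 259_999, 50_000],
        "baseline_mean": [5.0, 2.0, 1.0],
        "dispersion": [0.5, 0.5, 0.5],
    })


def random_link_fixture(seed: int, n_cres: int = 20, n_genes: int = 20):
    """Random CRE/gene layout for classification property tests."""
    rng = np.random.default_rng(seed)
    L = 5_000_000
    genes = []
    pos = 0
    for i in range(n_genes):
        pos += int(rng.integers(10_000, 200_000))
        length = int(rng.integers(2_000, 80_000))
        strand = rng.choice(["+", "-"])
        genes.append({"gene_id": f"g{i}", "chrom": "chr1", "strand": strand,
                      "body_start": pos, "body_end": pos + length,
                      "tss": pos if strand == "+" else pos + length - 1,
                      "baseline_mean": 1.0, "dispersion": 0.5})
        pos += length
    ann = pd.DataFrame(genes)
    cres = []
    for j in range(n_cres):
        start = int(rng.integers(0, max(pos, L)))
        width = int(rng.integers(200, 1500))
        cres.append({"cre_id": f"c{j}", "chrom": "chr1", "start": start,
                     "end": start + width, "center": start + width // 2})
    return ann, pd.DataFrame(cres)

def minimal_truth(ann: pd.DataFrame) -> synth.RegulatoryTruth:
    empty_links = pd.DataFrame(columns=["cre_id", "gene_id", "lfc", "mechanism"])
    cres = pd.DataFrame({"cre_id": ["CREX"], "chrom": [ann["chrom"].iloc[0]],
                         "start": [0], "end": [100], "center": [50],
                         "disease_labels": [""], "cre_class": ["enhancer"],
                         "panel": ["panel0"],
                         "atac": [1.0], "h3k27ac": [1.0], "h3k4me1": [1.0],
                         "h3k4me3": [1.0]})
    return synth.RegulatoryTruth(
        cres=cres, true_cre_links=empty_links,
        trans_edges=pd.DataFrame(columns=["src", "dst", "lfc"]),
        tads=pd.DataFrame({"chrom": [ann["chrom"].iloc[0]], "start": [0],
                           "end": [10_000_000], "name": ["t0"]}),
        hic_contacts=pd.DataFrame(columns=["cre_id", "gene_id", "contact"]),
        eqtl_catalogs={}, prediction_sources={},
        candidates=pd.DataFrame(columns=["cre_id", "gene_id", "distance"]),
        control_promoters=pd.DataFrame(columns=["target_id", "gene_id"]),
    )
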