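import math

import numpy as np
import pandas as pd
import pytest

from crecascade import prioritize as pr
from crecascade.errors import DataIntegrityError


def _links(rows):
    defaults = {"log2fc": -0.3, "adj_p": 0.01, "significant": True,
                "position": "distal", "same_chromosome": True,
                "interaction_class": "intergenic-distal"}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestMediationFilter:
    def test_lone_distal_link_passes(self):
        links = _links([{"cre_id": "c1", "gene_id": "gD", "distance": 50_000}])
        out = pr.mediation_filter(links)
        assert out["mediation_pass"].all()

    def test_distal_fails_when_proximal_hit_exists(self):
        links = _links([
            {"cre_id": "c1", "gene_id": "gP", "distance": 300, "position": "proximal"},
            {"cre_id": "c1", "gene_id": "gD", "distance": 50_000},
        ])
        out = pr.mediation_filter(links).set_index("gene_id")
        assert not out.loc["gD", "mediation_pass"]
        assert not out.loc["gP", "mediation_pass"]   # proximal never a candidate

    def test_nonsignificant_proximal_does_not_block(self):
        links = _links([
            {"cre_id": "c1", "gene_id": "gP", "distance": 300,
             "position": "proximal", "significant": False},
            {"cre_id": "c1", "gene_id": "gD", "distance": 50_000},
        ])
        out = pr.mediation_filter(links).set_index("gene_id")
        assert out.loc["gD", "mediation_pass"]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_set_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        links = _links([
            {"cre_id": f"c{rng.integers(10)}", "gene_id": f"g{i}",
             "distance": float(rng.integers(100, 200_000)),
             "position": rng.choice(["proximal", "distal"]),
             "significant": bool(rng.random() < 0.5)}
            for i in range(n)
        ])
        out = pr.mediation_filter(links)
        distal = {(r.cre_id, r.gene_id) for r in links.itertuples()
                  if r.position == "distal"}
        blocked_cres = {r.cre_id for r in links.itertuples()
                        if r.position == "proximal" and r.significant}
        oracle = distal - {(c, g) for c, g in distal if c in blocked_cres}
        got = {(r.cre_id, r.gene_id) for r in out.itertuples() if r.mediation_pass}
        assert got == oracle


class TestDistanceBins:
    @pytest.mark.parametrize("distance,label", [
        (0, "<1.5kb"), (1_499, "<1.5kb"), (1_500, "1.5k-10k"),
        (9_999, "1.5k-10k"), (10_000, "10k-100k"), (99_999, "10k-100k"),
        (100_000, "100k-1M"), (999_999, "100k-1M"), (1_000_000, ">1Mb"),
        (2_000_000, ">1Mb"),
    ])
    def test_half_open_boundaries(self, distance, label):
        links = _links([{"cre_id": "c", "gene_id": "g", "distance": float(distance)}])
        assert pr.assign_distance_bins(links)["distance_bin"].iloc[0] == label

    def test_closest_per_cre(self):
        links = _links([
            {"cre_id": "c1", "gene_id": "gA", "distance": 5_000.0},
            {"cre_id": "c1", "gene_id": "gB", "distance": 2_000.0},
            {"cre_id": "c2", "gene_id": "gC", "distance": 70_000.0},
        ])
        kept = pr.closest_per_cre(links)
        assert set(kept["gene_id"]) == {"gB", "gC"}


class TestHicComparison:
    def _contacts(self, pairs, values):
        return pd.DataFrame({"cre_id": [p[0] for p in pairs],
                             "gene_id": [p[1] for p in pairs],
                             "contact": values})

    def test_identical_distributions_not_enriched(self):
        rng = np.random.default_rng(3)
        rows, pairs, vals = [], [], []
        for i in range(200):
            sig = i < 100
            rows.append({"cre_id": f"c{i}", "gene_id": f"g{i}",
                         "distance": 50_000.0, "significant": sig})
            pairs.append((f"c{i}", f"g{i}"))
            vals.append(float(rng.lognormal(0, 1)))
        out = pr.hic_comparison(_links(rows), self._contacts(pairs, vals))
        row = out.set_index("distance_bin").loc["10k-100k"]
        assert row["ranksum_p"] > 0.001

    def test_shifted_contacts_detected_in_each_bin(self):
        rng = np.random.default_rng(4)
        rows, pairs, vals = [], [], []
        dists = {"1.5k-10k": 5_000.0, "10k-100k": 50_000.0, "100k-1M": 500_000.0}
        i = 0
        for label, d in dists.items():
            for sig in (True, False):
                for _ in range(60):
                    rows.append({"cre_id": f"c{i}", "gene_id": f"g{i}",
                                 "distance": d, "significant": sig})
                    pairs.append((f"c{i}", f"g{i}"))
                    vals.append(float(rng.lognormal(np.log(2.0) if sig else 0.0, 0.4)))
                    i += 1
        out = pr.hic_comparison(_links(rows), self._contacts(pairs, vals))
        for label in dists:
            row = out.set_index("distance_bin").loc[label]
            assert row["ranksum_p"] < 0.05
            assert row["median_sig"] > row["median_ns"]

    def test_empty_bin_gives_na_row(self):
        links = _links([{"cre_id": "c", "gene_id": "g", "distance": 5_000.0,
                         "significant": False}])
        out = pr.hic_comparison(links, self._contacts([("c", "g")], [1.0]))
        row = out.set_index("distance_bin").loc[">1Mb"]
        assert row["n_sig"] == 0 and np.isnan(row["ranksum_p"])


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestTadTest:
    def _links_with_tad(self, table):
        (a, b), (c, d) = table
        rows = []
        i = 0
        for sig, tad, count in [(True, True, a), (True, False, b),
                                (False, True, c), (False, False, d)]:
            for _ in range(count):
                rows.append({"cre_id": f"c{i}", "gene_id": f"g{i}",
                             "distance": 50_000.0, "significant": sig,
                             "same_tad": tad})
                i += 1
        return _links(rows)

    def test_cross_ratio(self):
        res = pr.tad_test(self._links_with_tad([[3, 1], [2, 4]]))
        assert res["odds_ratio"] == pytest.approx(6.0)

    def test_null_table(self):
        res = pr.tad_test(self._links_with_tad([[5, 5], [5, 5]]))
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_p_matches_enumeration_oracle(self):
        res = pr.tad_test(self._links_with_tad([[3, 1], [2, 4]]))
        assert res["p"] == pytest.approx(fisher_enumeration_oracle(3, 1, 2, 4), rel=1e-9)

    def test_requires_same_tad_annotation(self):
        with pytest.raises(DataIntegrityError):
            pr.tad_test(_links([{"cre_id": "c", "gene_id": "g", "distance": 1.0}]))


class TestSameTad:
    def test_boundary_strictly_between(self):
        tads = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 1000],
                             "end": [1000, 2000], "name": ["t0", "t1"]})
        assert pr.same_tad("chr1", 100, 900, tads)
        assert not pr.same_tad("chr1", 900, 1100, tads)
        assert pr.same_tad("chr1", 1000, 1500, tads)   # boundary at lo is not between


class TestPrioritize:
    def test_definition_assembly(self):
        links = _links([
            {"cre_id": "c1", "gene_id": "gD", "distance": 50_000.0,
             "interaction_class": "intergenic-distal"},
        ])
        links = pr.mediation_filter(links)
        links = pr.assign_distance_bins(links)
        out, _ = pr.prioritize_links(links)
        assert out["high_confidence"].iloc[0]
        assert out["label"].iloc[0] == "enhancer"

    def test_distance_cut_at_one_megabase(self):
        links = _links([
            {"cre_id": "c1", "gene_id": "gFar", "distance": 2_000_000.0},
        ])
        links = pr.mediation_filter(links)
        links = pr.assign_distance_bins(links)
        out, _ = pr.prioritize_links(links)
        assert not out["high_confidence"].any()

    def test_silencer_label_for_positive_lfc(self):
        links = _links([
            {"cre_id": "c1", "gene_id": "gS", "distance": 40_000.0, "log2fc": 0.2},
        ])
        links = pr.assign_distance_bins(pr.mediation_filter(links))
        out, _ = pr.prioritize_links(links)
        assert out["label"].iloc[0] == "silencer"

    def test_subset_chain_and_label_partition(self):
        rng = np.random.default_rng(6)
        links = _links([
            {"cre_id": f"c{rng.integers(15)}", "gene_id": f"g{i}",
             "distance": float(rng.integers(100, 3_000_000)),
             "position": rng.choice(["proximal", "distal"]),
             "significant": bool(rng.random() < 0.6),
             "log2fc": float(rng.normal(0, 0.3))}
            for i in range(200)
        ])
        links = pr.assign_distance_bins(pr.mediation_filter(links))
        out, _ = pr.prioritize_links(links)
        hc = out[out["high_confidence"]]
        sig_distal = out[out["significant"] & (out["position"] == "distal")]
        assert set(hc.index) <= set(sig_distal.index) <= set(out.index)
        assert (hc["label"].isin(["enhancer", "silencer"])).all()
        assert len(hc) == (hc["label"] == "enhancer").sum() + (hc["label"] == "silencer").sum()

    def test_planted_decay_monotone_in_bins(self):
        """Generator worlds plant decaying strength: per-bin medians decrease."""
        from crecascade import synth
        rp = synth.RegulatoryParams(n_cres=400, promoter_cre_fraction=0.0,
                                    inactive_cre_fraction=0.0,
                                    local_link_fraction=0.5,
                                    extra_targets_mean=0.0)
        ap = synth.AnnotationParams(n_genes=500, n_chroms=2, chrom_length=80_000_000)
        ann, truth = synth.generate_truth(ap, rp, seed=41)
        tl = truth.true_cre_links.merge(truth.cres, on="cre_id")
        tss = ann.set_index("gene_id")["tss"]
        tl["distance"] = [abs(int(tss[g]) - int(c)) for g, c
                          in zip(tl["gene_id"], tl["center"])]
        tl = pr.assign_distance_bins(tl)
        med_lfc = tl.groupby("distance_bin", observed=True)["lfc"].apply(
            lambda s: s.abs().median())
        med_k27 = tl.groupby("distance_bin", observed=True)["h3k27ac"].median()
        order = ["1.5k-10k", "10k-100k", "100k-1M"]
        assert all(med_lfc[a] >= med_lfc[b] for a, b in zip(order, order[1:]))
        assert all(med_k27[a] >= med_k27[b] for a, b in zip(order, order[1:]))
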