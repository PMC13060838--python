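import numpy as np
import pandas as pd
import pytest

from crecascade import synth
from crecascade.errors import ConfigError
from conftest import minimal_truth


class TestGenerateTruth:
    def test_deterministic_for_fixed_seed(self):
        a1, t1 = synth.generate_truth(seed=3)
        a2, t2 = synth.generate_truth(seed=3)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1.true_cre_links, t2.true_cre_links)
        pd.testing.assert_frame_equal(t1.cres, t2.cres)
        pd.testing.assert_frame_equal(t1.hic_contacts, t2.hic_contacts)

    def test_silencer_fraction_zero_gives_negative_lfc(self):
        rp = synth.RegulatoryParams(silencer_fraction=0.0)
        _, truth = synth.generate_truth(regulatory_params=rp, seed=4)
        assert (truth.true_cre_links["lfc"] < 0).all()

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ConfigError, match="silencer_fraction"):
            synth.RegulatoryParams(silencer_fraction=1.5).validate()
        with pytest.raises(ConfigError, match="n_genes"):
            synth.AnnotationParams(n_genes=0).validate()

    def test_contact_decay_with_distance(self):
        """Monte-Carlo check: near pairs have higher Hi-C contact than far pairs."""
        rp = synth.RegulatoryParams(n_cres=300, local_link_fraction=0.5,
                                    inactive_cre_fraction=0.0)
        ap = synth.AnnotationParams(n_genes=400, n_chroms=2, chrom_length=60_000_000)
        ann, truth = synth.generate_truth(ap, rp, seed=5)
        hic = truth.hic_contacts.merge(truth.candidates, on=["cre_id", "gene_id"])
        hic = hic[hic["distance"] >= 0]
        near = hic.loc[hic["distance"] <= 10_000, "contact"]
        far = hic.loc[hic["distance"] > 1_000_000, "contact"]
        assert len(near) > 10 and len(far) > 10
        assert near.mean() > far.mean()

    def test_within_tad_contacts_elevated(self):
        """Same distance range, within-TAD pairs carry more contact on average."""
        rp = synth.RegulatoryParams(n_cres=300, local_link_fraction=0.3,
                                    inactive_cre_fraction=0.0)
        ap = synth.AnnotationParams(n_genes=400, n_chroms=2, chrom_length=60_000_000)
        ann, truth = synth.generate_truth(ap, rp, seed=6)
        from crecascade.prioritize import same_tad
        hic = truth.hic_contacts.merge(truth.candidates, on=["cre_id", "gene_id"])
        hic = hic[(hic["distance"] > 100_000) & (hic["distance"] <= 1_000_000)]
        centers = truth.cres.set_index("cre_id")
        tssmap = ann.set_index("gene_id")
        flags = [same_tad(centers.loc[c, "chrom"], int(centers.loc[c, "center"]),
                          int(tssmap.loc[g, "tss"]), truth.tads)
                 for c, g in zip(hic["cre_id"], hic["gene_id"])]
        hic = hic.assign(same_tad=flags)
        within = hic.loc[hic["same_tad"], "contact"]
        across = hic.loc[~hic["same_tad"], "contact"]
        assert len(within) > 10 and len(across) > 10
        assert within.mean() > across.mean()

    def test_fixture_round_trip(self, tmp_path, small_world):
        ann, truth = small_world
        synth.write_fixture_set(tmp_path, ann, truth, screens={})
        ann2, truth2 = synth.read_truth(tmp_path)
        pd.testing.assert_frame_equal(
            ann.reset_index(drop=True), ann2.reset_index(drop=True))
        pd.testing.assert_frame_equal(truth.true_cre_links, truth2.true_cre_links)
        pd.testing.assert_frame_equal(truth.candidates, truth2.candidates)
        assert set(truth.eqtl_catalogs) == set(truth2.eqtl_catalogs)


class TestSimulateScreen:
    def test_deterministic_for_fixed_seed(self, small_world):
        ann, truth = small_world
        cfg = synth.ScreenConfig(n_cells=800, seed=9)
        d1 = synth.simulate_screen(ann, truth, cfg, mode="cre")
        d2 = synth.simulate_screen(ann, truth, cfg, mode="cre")
        assert (d1.X != d2.X).nnz == 0
        pd.testing.assert_frame_equal(d1.obs, d2.obs)

    def test_unique_assignment_rate(self, cre_screen):
        frac = (cre_screen.obs["n_grnas"] == 1).mean()
        assert abs(frac - 0.8) < 0.03

    def test_null_world_no_perturbation_signal(self, small_world):
        """With all effects zeroed, perturbed and control cells match."""
        ann, truth = small_world
        truth0 = synth.RegulatoryTruth(**{**vars(truth)})
        truth0.true_cre_links = truth.true_cre_links.assign(lfc=0.0)
        cfg = synth.ScreenConfig(n_cells=8000, seed=10, n_nontargeting=60)
        ds = synth.simulate_screen(ann, truth0, cfg, mode="cre")
        lib = np.asarray(ds.X.sum(axis=1)).ravel().astype(float)
        lib[lib == 0] = 1
        is_nt = (ds.obs["target_id"] == "non-targeting").to_numpy()
        is_pert = (~is_nt) & (ds.obs["n_grnas"] == 1).to_numpy()
        panel_genes = set(truth0.candidates["gene_id"])
        measured = np.array([g in panel_genes for g in ds.var_names])
        base = np.where(measured, ds.var["baseline_mean"].to_numpy(), -1)
        top = np.argsort(base)[-10:]
        for gi in top:
            col = np.asarray(ds.X[:, gi].todense()).ravel() / lib
            ratio = col[is_pert].mean() / col[is_nt].mean()
            assert abs(ratio - 1.0) < 0.12

    def test_single_knockdown_halves_expression(self):
        """A -1 log2 promoter effect halves normalized counts (2,000 cells/arm).

        The target is a small share of the library so the compositional shift
        in per-cell normalization stays inside the Monte-Carlo band.
        """
        n = 20
        ann = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(n)],
            "chrom": "chr1", "strand": "+",
            "body_start": np.arange(n) * 100_000,
            "body_end": np.arange(n) * 100_000 + 10_000,
            "tss": np.arange(n) * 100_000,
            "baseline_mean": 10.0, "dispersion": 0.5,
        })
        truth = minimal_truth(ann)
        cfg = synth.ScreenConfig(n_cells=5000, seed=11, n_nontargeting=3,
                                 grna_per_target=3, grna_active_fraction=1.0,
                                 library_size_cv=0.0, donor_effect_sd=0.0)
        ds = synth.simulate_screen(ann, truth, cfg, mode="promoter",
                                   promoter_targets=["G0"], promoter_lfc=-1.0)
        lib = np.asarray(ds.X.sum(axis=1)).ravel().astype(float)
        colA = np.asarray(ds.X[:, 0].todense()).ravel() / lib
        pert = (ds.obs["target_id"] == "G0") & (ds.obs["n_grnas"] == 1)
        ctrl = (ds.obs["target_id"] == "non-targeting") & (ds.obs["n_grnas"] == 1)
        assert pert.sum() > 1000 and ctrl.sum() > 1000
        ratio = colA[pert.to_numpy()].mean() / colA[ctrl.to_numpy()].mean()
        # knocking down A shifts its share of a fixed library; the normalized
        # ratio is 0.5 up to that compositional factor
        assert ratio == pytest.approx(0.5, rel=0.10)

    def test_nb_variance_mean_identity(self, tiny_annotation):
        """var/mean over control cells matches 1 + alpha*mean at alpha = 0.5."""
        ann = tiny_annotation.copy()
        ann["baseline_mean"] = [40.0, 25.0, 15.0]
        ann["dispersion"] = 0.5
        truth = minimal_truth(ann)
        cfg = synth.ScreenConfig(n_cells=12000, seed=12, n_nontargeting=5,
                                 library_size_cv=0.0, donor_effect_sd=0.0,
                                 n_donors=1, mean_umi_per_cell=200.0)
        ds = synth.simulate_screen(ann, truth, cfg, mode="promoter",
                                   promoter_targets=["A"])
        nt = (ds.obs["target_id"] == "non-targeting").to_numpy()
        X = np.asarray(ds.X[nt].todense()).astype(float)
        for gi in range(3):
            m, v = X[:, gi].mean(), X[:, gi].var()
            assert v / m == pytest.approx(1 + 0.5 * m, rel=0.15)

    def test_panel_readout_restricted_to_panel_genes(self, small_world):
        ann, truth = small_world
        rp = synth.RegulatoryParams(n_panels=2)
        ann2, truth2 = synth.generate_truth(regulatory_params=rp, seed=13)
        cfg = synth.ScreenConfig(n_cells=500, seed=14)
        ds = synth.simulate_screen(ann2, truth2, cfg, mode="cre")
        cand = truth2.candidates.merge(truth2.cres[["cre_id", "panel"]], on="cre_id")
        gene_pos = {g: i for i, g in enumerate(ds.var_names)}
        for panel in ("panel0", "panel1"):
            allowed = set(cand.loc[cand["panel"] == panel, "gene_id"]) \
                | set(truth2.control_promoters["gene_id"])
            cells = (ds.obs["panel"] == panel).to_numpy()
            sub = ds.X[cells]
            nz_genes = {ds.var_names[j] for j in np.unique(sub.nonzero()[1])}
            assert nz_genes <= allowed


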