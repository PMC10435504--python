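"""Generator correctness: tree invariants, read-sampling means, determinism."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spaceclone.genome import default_genome
from spaceclone.synthetic import (
    SimulationConfig,
    add_artifact_subclone,
    expected_vaf,
    fragments_from_counts,
    simulate_bulk_reads,
    simulate_clone_tree,
    simulate_peak_matrix,
    simulate_sc_counts,
    simulate_tcr,
    simulate_tme_annotations,
)


class TestCloneTree:
    def test_prevalences_sum_to_one_per_site(self):
        tree = simulate_clone_tree(4, 2, seed=1)
        for site in tree.sites:
            assert sum(tree.prevalence[site].values()) == pytest.approx(1.0)

    def test_same_seed_same_tree(self):
        a = simulate_clone_tree(4, 2, seed=1)
        b = simulate_clone_tree(4, 2, seed=1)
        assert a.prevalence == b.prevalence
        assert {k: v for k, v in a.snvs.items()} == {k: v for k, v in b.snvs.items()}
        assert a.cnas == b.cnas

    def test_site_unique_subclone_absent_elsewhere(self):
        tree = simulate_clone_tree(4, 2, [False, False, False, True], seed=3)
        prevs = [tree.prevalence[s][3] for s in tree.sites]
        assert sorted(p == 0 for p in prevs) == [False, True]

    def test_site_unique_subclone_is_leaf(self):
        for seed in range(5):
            tree = simulate_clone_tree(5, 2, [False, False, True, False, True], seed=seed)
            for unique_id in (2, 4):
                assert tree.descendants(unique_id) == set()

    def test_every_event_owned_once_and_inherited(self):
        tree = simulate_clone_tree(3, 2, seed=5)
        owners = [s for sub in tree.subclones for s in sub.snv_ids]
        assert len(owners) == len(set(owners))
        sub = tree.subclones[-1]
        carried = tree.carried_events(sub.subclone_id)
        assert set(tree.root.snv_ids) <= carried

    def test_invalid_subclone_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_clone_tree(0, 2, seed=1)


class TestBulkReads:
    def test_clonal_het_diploid_mean_vaf(self, small_genome):
        """Clonal heterozygous diploid SNV at purity 0.5: mean VAF -> 0.25."""
        tree = simulate_clone_tree(
            1, 2, seed=7, genome=small_genome, n_truncal_snvs=600, n_truncal_cnas=0
        )
        cfg = SimulationConfig(seed=7, genome=small_genome, purity={"RBM": 0.5, "FL": 0.5})
        variants, _ = simulate_bulk_reads(tree, cfg, "RBM")
        het = variants[variants["TRUE_M"] == 1]
        vaf = het["ALT_READS_RBM"] / het["TOTAL_READS_RBM"]
        # binomial mean oracle: E[VAF] = 1*1*0.5 / (0.5*2 + 2*0.5) = 0.25
        se = vaf.std(ddof=1) / np.sqrt(len(vaf))
        assert abs(vaf.mean() - 0.25) < 3 * se + 1e-3  # error-rate shift < 1e-3

    def test_full_purity_single_copy_expected_vaf_is_one(self):
        assert expected_vaf(m=1, ccf=1.0, purity=1.0, n_locus=1) == 1.0

    def test_absent_clone_yields_error_level_alt_reads(self, two_clone_tree, small_genome):
        tree = two_clone_tree
        tree.prevalence["RBM"] = {0: 1.0, 1: 0.0}
        cfg = SimulationConfig(seed=9, genome=small_genome, purity={"RBM": 0.6, "FL": 0.6})
        variants, _ = simulate_bulk_reads(tree, cfg, "RBM")
        sub = variants[variants["variant_id"] == "s_sub"].iloc[0]
        assert sub["TRUE_CCF_RBM"] == 0.0
        assert sub["ALT_READS_RBM"] <= 3  # ~ depth * error_rate

    def test_segment_ccf_equals_carrier_prevalence(self, two_clone_tree, small_genome):
        cfg = SimulationConfig(seed=9, genome=small_genome)
        _, segs = simulate_bulk_reads(two_clone_tree, cfg, "FL")
        row = segs[segs["event_id"] == "gain_1"].iloc[0]
        assert row["SEG_CCF"] == pytest.approx(0.6)

    def test_determinism(self, small_genome):
        tree = simulate_clone_tree(2, 2, seed=4, genome=small_genome)
        cfg = SimulationConfig(seed=4, genome=small_genome)
        v1, s1 = simulate_bulk_reads(tree, cfg, "RBM")
        v2, s2 = simulate_bulk_reads(tree, cfg, "RBM")
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(s1, s2)


class TestSingleCellCounts:
    def test_gain_dosage_ratio(self, two_clone_tree, small_genome):
        """Carrier/non-carrier mean count ratio over a 1.5x gain region."""
        cfg = SimulationConfig(
            seed=11, genome=small_genome, n_cells_rna=500, n_ref_cells=50,
            qc_fail_fraction=0.0,
        )
        adata = simulate_sc_counts(two_clone_tree, cfg, "RBM", "rna")
        gain = two_clone_tree.cnas["gain_1"]
        in_region = (
            (adata.var["chrom"] == gain.chrom)
            & (adata.var["start"] >= gain.start)
            & (adata.var["start"] < gain.end)
        ).to_numpy()
        X = adata.X.toarray()
        carrier = adata.obs["subclone"].to_numpy() == 1
        noncarrier = adata.obs["subclone"].to_numpy() == 0
        ratio = X[carrier][:, in_region].mean() / X[noncarrier][:, in_region].mean()
        assert 1.4 <= ratio <= 1.6

    def test_reference_cells_are_neutral(self, two_clone_tree, small_genome):
        cfg = SimulationConfig(seed=12, genome=small_genome, n_cells_rna=200, n_ref_cells=200)
        adata = simulate_sc_counts(two_clone_tree, cfg, "RBM", "rna")
        gain = two_clone_tree.cnas["gain_1"]
        in_region = (
            (adata.var["chrom"] == gain.chrom)
            & (adata.var["start"] >= gain.start)
            & (adata.var["start"] < gain.end)
        ).to_numpy()
        out_region = ~in_region
        X = adata.X.toarray()
        ref = adata.obs["is_reference"].to_numpy()
        # neutral reference: region/background mean ratio ~ 1
        r = X[ref][:, in_region].mean() / X[ref][:, out_region].mean()
        assert 0.9 <= r <= 1.1

    def test_every_cell_has_one_label(self, two_clone_tree, base_config):
        adata = simulate_sc_counts(two_clone_tree, base_config, "FL", "rna")
        assert adata.obs["subclone"].notna().all()
        assert len(adata) == base_config.n_cells_rna + base_config.n_ref_cells

    def test_zero_cells_rejected(self, two_clone_tree, small_genome):
        cfg = SimulationConfig(seed=1, genome=small_genome, n_cells_rna=0)
        with pytest.raises(ValueError):
            simulate_sc_counts(two_clone_tree, cfg, "RBM", "rna")

    def test_atac_fragments_round_trip(self, two_clone_tree, base_config):
        adata = simulate_sc_counts(two_clone_tree, base_config, "RBM", "atac")
        frags = fragments_from_counts(adata)
        assert frags["count"].sum() == adata.X.sum()
        assert set(frags["barcode"]) <= set(adata.obs_names)


class TestTcr:
    def _config(self, small_genome, freqs, seed=21, single_chain=0.15):
        return SimulationConfig(
            seed=seed,
            genome=small_genome,
            clonotype_freqs=np.asarray(freqs),
            single_chain_fraction=single_chain,
        )

    def test_multinomial_mean_recovery(self, small_genome):
        freqs = np.r_[0.06, np.full(47, 0.02)]
        cfg = self._config(small_genome, freqs)
        _, truth = simulate_tcr(cfg, "RBM", 1000)
        n0 = truth.loc[truth["clonotype_id"] == "ct0", "n_cells"].iloc[0]
        se = np.sqrt(1000 * 0.06 * 0.94)
        assert abs(n0 - 60) <= 3 * se

    def test_same_seed_identical_tables(self, small_genome):
        cfg = self._config(small_genome, [0.5, 0.5])
        c1, t1 = simulate_tcr(cfg, "FL", 300)
        c2, t2 = simulate_tcr(cfg, "FL", 300)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_single_chain_fraction_gives_both_chains(self, small_genome):
        cfg = self._config(small_genome, [0.5, 0.5], single_chain=0.0)
        contigs, _ = simulate_tcr(cfg, "RBM", 200)
        per_cell = contigs.groupby("cell_id")["locus"].agg(set)
        assert all(chains == {"TRA", "TRB"} for chains in per_cell)

    def test_frequencies_must_sum_to_one(self, small_genome):
        cfg = self._config(small_genome, [0.5, 0.4])
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_tcr(cfg, "RBM", 100)

    def test_cdr3_unique_per_clonotype(self, small_genome):
        cfg = self._config(small_genome, np.full(50, 0.02))
        _, truth = simulate_tcr(cfg, "RBM", 500)
        assert truth["tra_cdr3"].is_unique and truth["trb_cdr3"].is_unique


class TestArtifactAndAnnotations:
    def test_artifact_subclone_prevalence_and_events(self, two_clone_tree):
        aug = add_artifact_subclone(two_clone_tree, ["gain_1"], 0.2, "FL")
        new_id = max(s.subclone_id for s in aug.subclones)
        assert aug.prevalence["FL"][new_id] == pytest.approx(0.2)
        assert aug.prevalence["RBM"][new_id] == 0.0
        assert sum(aug.prevalence["FL"].values()) == pytest.approx(1.0)
        art = [c for c in aug.cnas.values() if c.owner == new_id]
        assert len(art) == 1 and art[0].start == two_clone_tree.cnas["gain_1"].start

    def test_tme_annotation_proportions(self, small_genome):
        cfg = SimulationConfig(
            seed=31,
            genome=small_genome,
            cell_type_proportions={
                "RBM": {"mono": 0.5, "T": 0.5},
                "FL": {"mono": 0.1, "T": 0.9},
            },
        )
        ann = simulate_tme_annotations(cfg, "P01", n_cells_per_site=2000)
        fl_mono = (
            (ann["site"] == "FL") & (ann["cell_type"] == "mono")
        ).sum() / (ann["site"] == "FL").sum()
        assert abs(fl_mono - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 2000)


def test_peak_matrix_planted_pair_correlates():
    adata = simulate_peak_matrix(n_cells=400, n_peaks=10, planted_pairs=[(0, 1)], seed=5)
    X = adata.X.toarray()
    r_planted = np.corrcoef((X[:, 0] > 0), (X[:, 1] > 0))[0, 1]
    r_null = np.corrcoef((X[:, 4] > 0), (X[:, 5] > 0))[0, 1]
    assert r_planted > 0.5 and abs(r_null) < 0.2
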