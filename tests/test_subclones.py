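"""Single-cell QC, region signals, clustering, confirmation, site tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from spaceclone.subclones import (
    SubclonalRegion,
    SubcloneAssignment,
    SubcloneGenotype,
    cluster_subclones,
    confirm_subclones,
    qc_filter_cells,
    region_signal_atac,
    region_signal_rna,
    sc_snv_site_test,
    site_composition,
)
from spaceclone.synthetic import SimulationConfig, fragments_from_counts, simulate_sc_counts

from conftest import make_adata


def _rna_obs(n, mito=0.02, genes=1000, doublet=0.1):
    return pd.DataFrame(
        {
            "mito_fraction": [mito] * n,
            "n_detected_features": [genes] * n,
            "doublet_score": [doublet] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )


class TestQc:
    def test_high_mito_cell_removed(self):
        obs = _rna_obs(2)
        obs.loc["c1", "mito_fraction"] = 0.06
        adata = make_adata(np.ones((2, 3)), obs=obs)
        out = qc_filter_cells(adata, "rna")
        assert list(out.obs_names) == ["c0"]
        assert out.uns["qc_removed"].loc["c1", "reason"] == "high_mito;"

    def test_cell_inside_all_bounds_kept(self):
        adata = make_adata(np.ones((1, 3)), obs=_rna_obs(1, mito=0.03, genes=250, doublet=0.1))
        assert qc_filter_cells(adata, "rna").n_obs == 1

    def test_atac_low_tss_removed(self):
        obs = pd.DataFrame(
            {
                "tss_score": [7.5, 12.0],
                "fragment_count": [5000, 5000],
                "doublet_enrichment": [1.0, 1.0],
                "predicted_doublet_score": [10.0, 10.0],
            },
            index=["c0", "c1"],
        )
        out = qc_filter_cells(make_adata(np.ones((2, 3)), obs=obs), "atac")
        assert list(out.obs_names) == ["c1"]

    def test_missing_qc_column_names_it(self):
        adata = make_adata(np.ones((1, 3)), obs=pd.DataFrame(index=["c0"]))
        with pytest.raises(ValueError, match="mito_fraction"):
            qc_filter_cells(adata, "rna")


def _region_fixture(two_clone_tree):
    ev = two_clone_tree.cnas["gain_1"]
    return [SubclonalRegion(ev.event_id, ev.chrom, ev.start, ev.end, ev.direction)]


class TestRegionSignalRna:
    def test_reference_cells_center_at_zero(self, two_clone_tree, base_config):
        adata = simulate_sc_counts(two_clone_tree, base_config, "RBM", "rna")
        sig = region_signal_rna(adata, _region_fixture(two_clone_tree))
        ref_mean = sig[adata.obs["is_reference"].to_numpy()].mean()
        assert abs(float(ref_mean.iloc[0])) < 0.02

    def test_gain_carriers_exceed_noncarriers_and_match_oracle(
        self, two_clone_tree, base_config
    ):
        adata = simulate_sc_counts(two_clone_tree, base_config, "RBM", "rna")
        regions = _region_fixture(two_clone_tree)
        sig = region_signal_rna(adata, regions)
        lab = adata.obs["subclone"].to_numpy()
        carrier = sig[lab == 1].mean().iloc[0]
        noncarrier = sig[lab == 0].mean().iloc[0]
        assert carrier > noncarrier
        # oracle: unsmoothed centered log means over the same genes
        X = adata.X.toarray().astype(float)
        depth = X.sum(axis=1, keepdims=True)
        logX = np.log1p(X / depth * 1e4)
        ref = adata.obs["is_reference"].to_numpy()
        centered = logX - logX[ref].mean(axis=0)
        reg = regions[0]
        member = (
            (adata.var["chrom"] == reg.chrom)
            & (adata.var["start"] >= reg.start)
            & (adata.var["start"] < reg.end)
        ).to_numpy()
        oracle_diff = centered[lab == 1][:, member].mean() - centered[lab == 0][:, member].mean()
        assert oracle_diff > 0

    def test_small_region_dropped(self, two_clone_tree, base_config):
        adata = simulate_sc_counts(two_clone_tree, base_config, "RBM", "rna")
        tiny = SubclonalRegion("tiny", "1", 0, 100_000, "gain")
        sig = region_signal_rna(adata, [tiny])
        assert "tiny" not in sig.columns


class TestRegionSignalAtac:
    def test_reference_bins_standardized(self, two_clone_tree, base_config):
        adata = simulate_sc_counts(two_clone_tree, base_config, "RBM", "atac")
        frags = fragments_from_counts(adata)
        ref = set(adata.obs_names[adata.obs["is_reference"]])
        regions = _region_fixture(two_clone_tree)
        sig = region_signal_atac(
            frags, regions, base_config.genome.chrom_lengths, ref
        )
        ref_rows = sig.loc[[c for c in sig.index if c in ref]]
        assert abs(float(ref_rows.mean().iloc[0])) < 0.3  # mean z over region bins

    def test_loss_carriers_have_negative_z(self, two_clone_tree, base_config):
        from spaceclone.synthetic import CnaEvent

        tree = two_clone_tree
        loss = CnaEvent("loss_1", "2", 5_000_000, 45_000_000, delta=-1, owner=1)
        tree.cnas["loss_1"] = loss
        tree.subclones[1].cna_ids.append("loss_1")
        adata = simulate_sc_counts(tree, base_config, "RBM", "atac")
        frags = fragments_from_counts(adata)
        ref = set(adata.obs_names[adata.obs["is_reference"]])
        regions = [SubclonalRegion("loss_1", "2", loss.start, loss.end, "loss")]
        sig = region_signal_atac(frags, regions, base_config.genome.chrom_lengths, ref)
        sig = sig.loc[adata.obs_names]
        lab = adata.obs["subclone"].to_numpy()
        assert sig[lab == 1].mean().iloc[0] < -1.0

    def test_fragment_beyond_chromosome_end_rejected(self, base_config):
        frags = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [10**12], "barcode": ["x"], "count": [1]}
        )
        with pytest.raises(ValueError, match="beyond chromosome end"):
            region_signal_atac(
                frags,
                [SubclonalRegion("r", "1", 0, 10_000_000, "gain")],
                base_config.genome.chrom_lengths,
                {"x"},
            )


class TestClusterSubclones:
    def _make_signal(self, n_per_group, means, noise, seed=0):
        rng = np.random.default_rng(seed)
        blocks, labels = [], []
        for g, mu in enumerate(means):
            blocks.append(rng.normal(mu, noise, size=(n_per_group, len(mu))))
            labels += [g] * n_per_group
        X = np.vstack(blocks)
        idx = [f"cell{i}" for i in range(len(X))]
        cols = ["ev_a", "ev_b"]
        return pd.DataFrame(X, index=idx, columns=cols), np.array(labels)

    def _regions(self):
        return [
            SubclonalRegion("ev_a", "1", 0, 10**7, "gain"),
            SubclonalRegion("ev_b", "2", 0, 10**7, "loss"),
        ]

    def test_two_planted_genotypes_recovered_exactly(self):
        sig, truth = self._make_signal(250, [(0.0, 0.0), (0.4, -0.4)], noise=0.05)
        cands = [SubcloneGenotype("wt", (0, 0)), SubcloneGenotype("mut", (1, 1))]
        asgn = cluster_subclones(sig, self._regions(), cands)
        assert adjusted_rand_score(truth, asgn.labels) == 1.0
        assert set(asgn.genotypes) == {"wt", "mut"}
        assert not any(asgn.provisional.values())

    def test_four_genotypes_recovered_distinct(self):
        means = [(0.0, 0.0), (0.4, 0.0), (0.0, -0.4), (0.4, -0.4)]
        sig, truth = self._make_signal(150, means, noise=0.05, seed=1)
        cands = [
            SubcloneGenotype("g00", (0, 0)),
            SubcloneGenotype("g10", (1, 0)),
            SubcloneGenotype("g01", (0, 1)),
            SubcloneGenotype("g11", (1, 1)),
        ]
        asgn = cluster_subclones(sig, self._regions(), cands)
        assert asgn.k == 4
        assert adjusted_rand_score(truth, asgn.labels) >= 0.99

    def test_identical_signal_degenerates_to_single_cluster(self):
        sig = pd.DataFrame(
            np.zeros((60, 2)), columns=["ev_a", "ev_b"],
            index=[f"c{i}" for i in range(60)],
        )
        asgn = cluster_subclones(sig, self._regions(), [])
        assert asgn.k == 1 and np.isnan(asgn.silhouette)

    def test_too_few_cells_rejected(self):
        sig = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)), columns=["ev_a", "ev_b"])
        with pytest.raises(ValueError):
            cluster_subclones(sig, self._regions(), [])


def _assignment(genotypes, provisional, region_ids=("e1", "e2")):
    labels = pd.Series(
        {f"cell{i}": lbl for i, lbl in enumerate(list(genotypes) * 30)}
    )
    return SubcloneAssignment(
        labels=labels,
        genotypes=dict(genotypes),
        provisional=dict(provisional),
        k=len(genotypes),
        silhouette=0.5,
        region_ids=tuple(region_ids),
    )


class TestConfirmSubclones:
    def _wgs(self):
        return [
            SubclonalRegion("e1", "1", 0, 10**7, "gain"),
            SubclonalRegion("e2", "2", 0, 10**7, "loss"),
        ]

    def test_one_modality_artifact_excluded(self):
        rna = _assignment(
            {"sub0": (0, 0), "sub1": (1, 0), "provisional_0": (1, 1)},
            {"sub0": False, "sub1": False, "provisional_0": True},
        )
        atac = _assignment(
            {"sub0": (0, 0), "sub1": (1, 0)}, {"sub0": False, "sub1": False}
        )
        confirmed = confirm_subclones(rna, atac, self._wgs())
        assert "provisional_0" not in confirmed
        assert {"sub0", "sub1"} <= set(confirmed)

    def test_wgs_backed_genotype_confirmed_without_atac(self):
        rna = _assignment({"sub1": (1, 0)}, {"sub1": False})
        confirmed = confirm_subclones(rna, None, self._wgs())
        assert confirmed["sub1"] >= {"WGS", "RNA"}

    def test_identical_genotype_in_both_modalities_confirmed(self):
        rna = _assignment({"provisional_0": (1, 1)}, {"provisional_0": True})
        atac = _assignment({"provisional_0": (1, 1)}, {"provisional_0": True})
        confirmed = confirm_subclones(rna, atac, self._wgs())
        assert "provisional_0" in confirmed
        assert confirmed["provisional_0"] >= {"RNA", "ATAC"}


class TestSiteComposition:
    def _asgn_with_sites(self, counts):
        """counts: dict label -> (n_RBM, n_FL)."""
        rows = []
        for lbl, (na, nb) in counts.items():
            rows += [(f"{lbl}_r{i}", lbl, "RBM") for i in range(na)]
            rows += [(f"{lbl}_f{i}", lbl, "FL") for i in range(nb)]
        cells, labels, sites = zip(*rows)
        asgn = SubcloneAssignment(
            labels=pd.Series(labels, index=cells),
            genotypes={lbl: (0,) for lbl in counts},
            provisional={lbl: False for lbl in counts},
            k=len(counts),
            silhouette=0.5,
            region_ids=("e1",),
            confirmed={lbl: {"WGS"} for lbl in counts},
        )
        return asgn, pd.Series(sites, index=cells)

    def test_site_unique_flag(self):
        asgn, sites = self._asgn_with_sites({"a": (300, 300), "b": (0, 300)})
        comp = site_composition(asgn, sites)
        row = comp[(comp["subclone"] == "b") & (comp["site"] == "FL")].iloc[0]
        assert row["site_unique"]

    def test_plasticity_eligible_over_50_cells_both_sites(self):
        asgn, sites = self._asgn_with_sites({"a": (60, 60), "b": (40, 60)})
        comp = site_composition(asgn, sites)
        a_fl = comp[(comp["subclone"] == "a") & (comp["site"] == "FL")].iloc[0]
        b_fl = comp[(comp["subclone"] == "b") & (comp["site"] == "FL")].iloc[0]
        assert a_fl["plasticity_eligible"] and not b_fl["plasticity_eligible"]

    def test_proportions_sum_to_one_per_site(self):
        asgn, sites = self._asgn_with_sites({"a": (100, 50), "b": (50, 150)})
        comp = site_composition(asgn, sites)
        sums = comp.groupby("site")["proportion"].sum()
        assert np.allclose(sums, 1.0)


class TestScSnvSiteTest:
    def _calls(self, mut_fl, cov_fl, mut_rbm, cov_rbm, variant="v1"):
        rows = []
        for i in range(cov_fl):
            rows.append((f"fl{i}", variant, 0 if i < mut_fl else 1, 1 if i < mut_fl else 0, "FL"))
        for i in range(cov_rbm):
            rows.append((f"r{i}", variant, 0 if i < mut_rbm else 1, 1 if i < mut_rbm else 0, "RBM"))
        return pd.DataFrame(rows, columns=["cell", "variant", "ref_reads", "alt_reads", "site"])

    def test_focal_lesion_enriched_variant_matches_hypergeometric_oracle(self):
        """651/1442 FL vs 3/814 RBM mutant cells: strong FL enrichment."""
        calls = self._calls(651, 1442, 3, 814)
        out = sc_snv_site_test(calls)
        row = out.iloc[0]
        assert row["site_enriched"]
        # oracle: two-sided Fisher p by hypergeometric enumeration
        M, n, N = 1442 + 814, 651 + 3, 1442
        rv = stats.hypergeom(M, n, N)
        p_obs = rv.pmf(651)
        p_exact = sum(rv.pmf(k) for k in range(max(0, n - 814), min(n, N) + 1)
                      if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert row["p"] == pytest.approx(p_exact, rel=1e-6)
        assert row["p"] < 1e-100

    def test_no_mutant_cells_not_enriched(self):
        calls = self._calls(0, 100, 0, 100)
        out = sc_snv_site_test(calls)
        assert out.iloc[0]["p"] == 1.0 and not out.iloc[0]["site_enriched"]

    def test_equal_proportions_odds_ratio_one(self):
        calls = self._calls(10, 100, 10, 100)
        out = sc_snv_site_test(calls)
        assert out.iloc[0]["odds_ratio"] == pytest.approx(1.0)
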