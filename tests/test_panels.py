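"""LD pruning, SNP-effect backsolving and panel sweeps."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.ldpopgen import _composite_pairs

VC = sg.VarianceComponents(0.25, 0.10, 0.65)


def geno_of(dosages):
    d = np.asarray(dosages, dtype=float)
    return sg.GenotypeMatrix(
        animal_ids=[f"A{i}" for i in range(d.shape[0])],
        snp_ids=[f"s{j}" for j in range(d.shape[1])],
        dosages=d,
    )


def map_for(geno, chrom="1"):
    return sg.MarkerMap(
        snp_id=list(geno.snp_ids),
        chromosome=np.array([chrom] * geno.n_snps),
        position_bp=np.arange(1, geno.n_snps + 1) * 1000,
    )


def brute_force_window_audit(geno, mmap, kept, window, r2_max):
    """Independent check: no surviving within-window pair exceeds r2_max."""
    order = mmap.sorted_within_chromosome()
    kept_set = set(kept)
    X = geno.subset_snps(order.snp_id).dosages
    worst = 0.0
    for chrom in pd.unique(order.chromosome):
        idx = np.flatnonzero(order.chromosome == chrom)
        for start in range(0, len(idx), 1):
            win = [j for j in idx[start : start + window]
                   if order.snp_id[j] in kept_set]
            if len(win) < 2:
                continue
            ia, ib = np.triu_indices(len(win), k=1)
            _, r2, _, _, ok = _composite_pairs(X[:, win], ia, ib)
            if ok.any():
                worst = max(worst, float(np.max(r2[ok])))
    return worst


class TestLDPrune:
    def test_perfect_ld_pair_keeps_exactly_one(self):
        col = np.tile([0.0, 1.0, 2.0], 10)
        g = geno_of(np.column_stack([col, col]))
        subset = sg.ld_prune_windowed(g, map_for(g), r2_max=0.7)
        assert subset.n_snps == 1

    def test_weak_ld_panel_untouched(self):
        rng = np.random.default_rng(0)
        g = geno_of(rng.choice([0.0, 1.0, 2.0], size=(200, 10), p=[0.25, 0.5, 0.25]))
        subset = sg.ld_prune_windowed(g, map_for(g), r2_max=0.7)
        assert subset.snp_ids == list(g.snp_ids)

    def test_brute_force_window_audit(self, small_sim):
        # one simulated chromosome, ~100 SNPs with real LD structure
        mm = small_sim.marker_map
        chr1 = [s for s, c in zip(mm.snp_id, mm.chromosome) if c == "1"]
        geno = small_sim.genotypes.subset_snps(chr1)
        mmap = mm.subset(chr1)
        for r2_max in (0.4, 0.1):
            subset = sg.ld_prune_windowed(geno, mmap, window=50, step=5,
                                          r2_max=r2_max)
            worst = brute_force_window_audit(geno, mmap, subset.snp_ids, 50, r2_max)
            assert worst <= r2_max + 1e-12

    def test_pruning_is_idempotent(self, small_sim):
        geno, mmap = small_sim.genotypes, small_sim.marker_map
        first = sg.ld_prune_windowed(geno, mmap, r2_max=0.4)
        again = sg.ld_prune_windowed(
            geno.subset_snps(first.snp_ids), mmap.subset(first.snp_ids), r2_max=0.4
        )
        assert again.snp_ids == first.snp_ids

    def test_lower_threshold_prunes_harder(self, small_sim):
        geno, mmap = small_sim.genotypes, small_sim.marker_map
        sizes = [
            sg.ld_prune_windowed(geno, mmap, r2_max=t).n_snps
            for t in (0.7, 0.4, 0.1)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_window_validation(self, small_sim):
        with pytest.raises(ValueError, match="window"):
            sg.ld_prune_windowed(
                small_sim.genotypes, small_sim.marker_map, window=1, r2_max=0.5
            )


class TestBacksolve:
    def test_backsolve_reconstructs_gebv(self):
        # M u_hat = a_hat exactly when G is the unblended VanRaden matrix
        # (external allele frequencies keep G full rank; sample frequencies
        # would center every row sum to zero)
        rng = np.random.default_rng(1)
        g = geno_of(rng.choice([0.0, 1.0, 2.0], size=(5, 30), p=[0.3, 0.4, 0.3]))
        p = rng.uniform(0.2, 0.8, size=30)
        G = sg.build_G(g, p=p)
        assert np.linalg.matrix_rank(G) == 5
        a_hat = rng.normal(size=5)
        sv = sg.backsolve_snp_effects(
            a_hat, G, g.centered(p), p, snp_ids=g.snp_ids
        )
        np.testing.assert_allclose(g.centered(p) @ sv.u_hat, a_hat, atol=1e-8)
        assert sv.pct_additive_variance.sum() == pytest.approx(100.0)

    def test_zero_gebv_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        g = geno_of(rng.choice([0.0, 1.0, 2.0], size=(5, 20), p=[0.3, 0.4, 0.3]))
        sv = sg.backsolve_snp_effects(
            np.zeros(5), sg.build_G(g), g.centered(), g.allele_freq
        )
        assert sv.degenerate
        np.testing.assert_array_equal(sv.u_hat, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            sg.select_by_variance(sv, 0.5)

    def test_qtl_linked_snps_rank_in_top_decile(self):
        # 5 dominant QTLs among ~2000 SNPs: their back-solved variance shares
        # land in the top 10%
        sim = sg.simulate_population(
            sg.SimConfig(
                seed=31,
                n_founders=80,
                n_generations=2,
                families_per_generation=40,
                offspring_per_family=10,
                snps_per_chromosome=69,
                n_qtl_per_trait=5,
            )
        )
        data = sg.EvalData(sim.pedigree, sim.phenotypes, sim.genotypes,
                           sim.marker_map)
        fit = sg.run_evaluation(data, "fillet_yield", VC, model="ssgblup")
        geno = sim.genotypes
        A22, _ = sg.build_A22_and_inverse(sim.pedigree, geno.animal_ids)
        G = sg.blend_and_tune_G(sg.build_G(geno), A22)
        sv = sg.backsolve_snp_effects(
            fit.ebv.loc[geno.animal_ids].to_numpy(), G, geno.centered(),
            geno.allele_freq, snp_ids=geno.snp_ids,
        )
        ranks = pd.Series(sv.pct_additive_variance, index=sv.snp_ids).rank(
            pct=True
        )
        qtl = sim.true_qtl.loc[sim.true_qtl["trait"] == "fillet_yield", "snp_id"]
        # enrichment, not perfection: a QTL can draw a near-zero effect
        assert (ranks.loc[qtl] > 0.9).mean() >= 0.8


class TestSelectByVariance:
    def sv(self, pct):
        pct = np.asarray(pct, dtype=float)
        return sg.SnpVariance(
            snp_ids=[f"s{j}" for j in range(len(pct))],
            u_hat=np.sqrt(pct),
            d_weight=pct,
            pct_additive_variance=pct,
        )

    def test_zero_threshold_full_panel(self):
        sv = self.sv([50.0, 30.0, 20.0])
        assert sg.select_by_variance(sv, 0.0).n_snps == 3

    def test_planted_percentages(self):
        sv = self.sv([2.0, 0.6, 0.4, 0.3, 0.2, 96.5])
        subset = sg.select_by_variance(sv, 0.5)
        assert sorted(subset.snp_ids) == ["s0", "s1", "s5"]

    def test_uniform_percentages_above_threshold_error(self):
        sv = self.sv([25.0, 25.0, 25.0, 25.0])
        with pytest.raises(ValueError, match="no SNP"):
            sg.select_by_variance(sv, 30.0)


class TestSweep:
    def test_row_count_and_pairing(self, small_sim):
        data = sg.EvalData(small_sim.pedigree, small_sim.phenotypes,
                           small_sim.genotypes, small_sim.marker_map)
        rep = sg.panel_sweep(
            data, "fillet_yield", VC, thresholds=[0.4, 0.1], mode="ld",
            k=5, seed=1,
        )
        assert len(rep) == 3  # full panel + one row per threshold
        assert rep["tag"].iloc[0] == "full"
        assert rep["n_snps"].iloc[1] >= rep["n_snps"].iloc[2]
        assert rep["p_vs_full"].iloc[1:].notna().all()

    def test_no_op_threshold_equals_full_row(self):
        # LD-free data: pruning removes nothing, so the reduced row must
        # reproduce the full-panel row exactly (same folds contract)
        rng = np.random.default_rng(3)
        n, m = 120, 40
        g = geno_of(rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.25, 0.5, 0.25]))
        ped = sg.Pedigree.from_records(
            [(f"A{i}", "0", "0") for i in range(n)]
        )
        tab = sg.PhenotypeTable(
            data=pd.DataFrame(
                {
                    "animal_id": [f"A{i}" for i in range(n)],
                    "t": rng.normal(size=n),
                    "hatch_year": "y1",
                    "harvest_group": rng.choice(["h1", "h2"], size=n),
                    "family": rng.choice([f"f{k}" for k in range(20)], size=n),
                }
            )
        )
        data = sg.EvalData(ped, tab, g, map_for(g))
        rep = sg.panel_sweep(data, "t", VC, thresholds=[0.99], mode="ld",
                             k=5, seed=2)
        assert rep["n_snps"].iloc[1] == m
        assert rep["predictive_ability"].iloc[1] == pytest.approx(
            rep["predictive_ability"].iloc[0]
        )
        assert rep["b1"].iloc[1] == pytest.approx(rep["b1"].iloc[0])

    def test_variance_mode_sweep(self, small_sim):
        data = sg.EvalData(small_sim.pedigree, small_sim.phenotypes,
                           small_sim.genotypes, small_sim.marker_map)
        rep = sg.panel_sweep(
            data, "fillet_yield", VC, thresholds=[0.05], mode="variance",
            k=5, seed=1,
        )
        assert len(rep) == 2
        assert rep["n_snps"].iloc[1] <= small_sim.genotypes.n_snps

    def test_empty_thresholds_rejected(self, small_sim):
        data = sg.EvalData(small_sim.pedigree, small_sim.phenotypes,
                           small_sim.genotypes, small_sim.marker_map)
        with pytest.raises(ValueError, match="thresholds"):
            sg.panel_sweep(data, "fillet_yield", VC, thresholds=[], mode="ld")
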