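"""Oracle and property tests for condFDR/conjFDR, pruning, clumping, mapping."""

import numpy as np
import pandas as pd
import pytest

import pleiopwas as pp
from pleiopwas.config import ScenarioConfig
from tests.conftest import gwas_from_p, gwas_from_z, toy_panel


def brute_force_lookup(p1, p2, weights, x):
    """Independent double-loop implementation of the binned condFDR lookup:
    per-cell weighted counting on the p scale, cap at 1, empty cells 1,
    then a cumulative minimum down each p2 column of increasing -log10 p1."""
    n_nodes = len(x)
    vals = np.ones((n_nodes, n_nodes))
    for i in range(n_nodes):
        t1 = 10.0 ** -x[i]
        for j in range(n_nodes):
            t2 = 10.0 ** -x[j]
            w2 = 0.0
            w12 = 0.0
            for a, b, w in zip(p1, p2, weights):
                if b <= t2:
                    w2 += w
                    if a <= t1:
                        w12 += w
            vals[i, j] = min(1.0, t1 * w2 / w12) if w12 > 0 else 1.0
    for j in range(n_nodes):
        for i in range(1, n_nodes):
            vals[i, j] = min(vals[i, j], vals[i - 1, j])
    return vals


class TestConditionalQq:
    def test_null_curves_on_diagonal(self):
        """Independent uniform traits: every stratum curve hugs the diagonal.

        The rank-i order statistic of -log10 p has standard deviation about
        0.434/sqrt(i), so the extreme tail (ranks < 25) is individually
        noisier than the 0.3 band being checked; the comparison covers all
        other ranks of every adequately sized stratum over 20 seeds.
        """
        cfg = ScenarioConfig(n_variants=20000, n_blocks=200, block_rho=0.0,
                             pi_shared=0, pi1=0, pi2=0, seed=50)
        ld = pp.simulate_ld_panel(cfg)
        worst = 0.0
        for s in range(20):
            g1, g2, _ = pp.simulate_bivariate_gwas(ld, cfg, seed=600 + s)
            qq = pp.conditional_qq(g1, g2)
            for stratum in qq.strata:
                if stratum.n < 100:
                    continue
                # observed/expected are sorted ascending; the last entries are
                # the smallest p-values (ranks 1, 2, ...): drop ranks < 25
                k = stratum.n - 24
                dev = np.abs(stratum.observed[:k] - stratum.expected[:k]).max()
                worst = max(worst, dev)
        assert worst < 0.3

    def test_enrichment_orders_strata(self):
        """Planted polygenic overlap: the strictest stratum shows the largest
        mean leftward shift."""
        cfg = ScenarioConfig(n_variants=20000, n_blocks=200, block_rho=0.0,
                             pi_shared=0.01, pi1=0, pi2=0, seed=51)
        ld = pp.simulate_ld_panel(cfg)
        g1, g2, _ = pp.simulate_bivariate_gwas(ld, cfg)
        shift = pp.conditional_qq(g1, g2).mean_shift()
        assert shift[0.001] > shift[1.0]

    def test_stratum_counts_nested(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        qq = pp.conditional_qq(g1, g2)
        counts = [s.n for s in qq.strata]
        assert counts == sorted(counts, reverse=True)
        assert qq.strata[0].n == len(g1)

    def test_bad_strata_rejected(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        with pytest.raises(ValueError):
            pp.conditional_qq(g1, g2, strata=(0.1, 0.01))  # must start at 1
        with pytest.raises(ValueError):
            pp.conditional_qq(g1, g2, strata=(1.0, 0.01, 0.1))  # not descending


class TestRandomPrune:
    def test_no_pruning_at_r2_one(self):
        ld = toy_panel(12, block_sizes=[6, 6], rho=0.9)
        w = pp.random_prune(ld, r2_max=1.0, n_iter=10, seed=0)
        assert (w == 1.0).all()

    def test_symmetric_cluster_weights(self):
        """4 variants all in mutual conflict: one survivor per iteration,
        weights ~ 1/4 each."""
        R = np.full((4, 4), 0.95)
        np.fill_diagonal(R, 1.0)
        ld = toy_panel(4)
        ld.blocks = [R]
        w = pp.random_prune(ld, r2_max=0.5, n_iter=100, seed=3)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)  # exactly one kept per iter
        assert np.allclose(w, 0.25, atol=0.1)

    def test_seeded_determinism(self, small_ld):
        a = pp.random_prune(small_ld, 0.1, 20, seed=5)
        b = pp.random_prune(small_ld, 0.1, 20, seed=5)
        assert a.equals(b)

    def test_kept_sets_are_valid(self):
        """Every weight is an inclusion fraction and high-LD neighbours are
        down-weighted relative to isolated variants."""
        ld = toy_panel(40, block_sizes=[20, 20], rho=0.9)
        w = pp.random_prune(ld, r2_max=0.1, n_iter=50, seed=1)
        assert ((w >= 0) & (w <= 1)).all()
        assert w.mean() < 0.6


class TestCondfdrLookup:
    def test_unconditional_case_hand_counted(self):
        """Conditioning on everything (p2 threshold 1, unit weights) reduces
        to the plain empirical FDR p1 * M / #{trait-1 p <= p1}.

        Hand count on 10 variants: at threshold 0.1 exactly 3 of 10 pass, so
        condFDR = 0.1 * 10 / 3 (the raw values at looser thresholds are all
        larger, so the monotonicity pass leaves the node untouched).
        """
        ld = toy_panel(10)
        p1 = np.array([0.9, 0.7, 0.5, 0.35, 0.25, 0.18, 0.13, 0.09, 0.06, 0.04])
        p2 = np.full(10, 1.0)
        g1, g2 = gwas_from_p(ld, p1), gwas_from_p(ld, p2)
        lookup = pp.build_condfdr_lookup(g1, g2, grid_max=4.0, grid_n=41)
        i = np.where(np.isclose(lookup.x, 1.0))[0][0]
        assert lookup.values[i, 0] == pytest.approx(1.0 / 3.0, abs=1e-12)
        # a variant sitting exactly at the node gets the same value via assign
        probe1 = gwas_from_p(ld, np.concatenate([[0.1], p1[1:]]))
        vals = pp.assign_condfdr(probe1, g2, pp.build_condfdr_lookup(probe1, g2, grid_max=4.0, grid_n=41))
        assert vals[ld.panel.snp_ids.iloc[0]] == pytest.approx(0.1 * 10 / 4, abs=1e-12)

    def test_single_variant(self):
        ld = toy_panel(1)
        g1 = gwas_from_p(ld, [0.001])
        g2 = gwas_from_p(ld, [1.0])
        lookup = pp.build_condfdr_lookup(g1, g2)
        i = np.where(np.isclose(lookup.x, 3.0))[0][0]
        assert lookup.values[i, 0] == pytest.approx(0.001, abs=1e-12)

    def test_matches_bruteforce_cell_for_cell(self):
        """Vectorized lookup equals the independent double-loop oracle to
        1e-12 on every cell, with and without pruning weights."""
        rng = np.random.default_rng(8)
        n = 120
        ld = toy_panel(n)
        p1 = 10 ** -(rng.uniform(0, 5, n))
        p2 = 10 ** -(rng.uniform(0, 5, n))
        g1, g2 = gwas_from_p(ld, p1), gwas_from_p(ld, p2)
        for weights in (np.ones(n), rng.uniform(0.1, 1.0, n)):
            wser = pd.Series(weights, index=ld.panel.snp_ids.to_numpy())
            lookup = pp.build_condfdr_lookup(g1, g2, wser, grid_max=6.0, grid_n=25)
            oracle = brute_force_lookup(p1, p2, weights, lookup.x)
            np.testing.assert_allclose(lookup.values, oracle, atol=1e-12)

    def test_unit_weights_equal_unweighted(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        w = pp.random_prune(small_ld, r2_max=1.0, n_iter=5, seed=0)
        a = pp.build_condfdr_lookup(g1, g2, w)
        b = pp.build_condfdr_lookup(g1, g2, None)
        np.testing.assert_array_equal(a.values, b.values)


class TestAssignCondfdr:
    def test_exact_node_queries_hit_cell_values(self):
        """Variants whose p-values sit on grid nodes get the node value."""
        rng = np.random.default_rng(9)
        n = 200
        ld = toy_panel(n)
        grid_n, grid_max = 41, 10.0
        x = np.linspace(0, grid_max, grid_n)
        xi = rng.integers(0, 30, n)
        xj = rng.integers(0, 30, n)
        p1 = 10.0 ** -x[xi]
        p2 = 10.0 ** -x[xj]
        g1, g2 = gwas_from_p(ld, p1), gwas_from_p(ld, p2)
        lookup = pp.build_condfdr_lookup(g1, g2, grid_max=grid_max, grid_n=grid_n)
        got = pp.assign_condfdr(g1, g2, lookup)
        oracle = brute_force_lookup(p1, p2, np.ones(n), lookup.x)
        for k, sid in enumerate(ld.panel.snp_ids):
            assert got[sid] == pytest.approx(oracle[xi[k], xj[k]], abs=1e-12)

    def test_monotone_in_p1_after_interpolation(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        lookup = pp.build_condfdr_lookup(g1, g2)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((lookup.x, lookup.x), lookup.values)
        for x2 in (0.0, 1.3, 2.7):
            probes = np.linspace(0.0, 9.9, 100)
            vals = interp(np.column_stack([probes, np.full(100, x2)]))
            assert (np.diff(vals) <= 1e-12).all()

    def test_values_in_unit_interval(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        lookup = pp.build_condfdr_lookup(g1, g2)
        vals = pp.assign_condfdr(g1, g2, lookup)
        assert ((vals >= 0) & (vals <= 1)).all()


class TestConjfdr:
    def test_max_of_pair(self):
        a = pd.Series([0.002], index=["s1"])
        b = pd.Series([0.005], index=["s1"])
        assert pp.conjfdr(a, b)["s1"] == 0.005
        assert pp.conjfdr(a, a)["s1"] == 0.002

    def test_mismatched_sets_rejected(self):
        a = pd.Series([0.1], index=["s1"])
        b = pd.Series([0.1], index=["s2"])
        with pytest.raises(ValueError):
            pp.conjfdr(a, b)

    def test_dominates_both_inputs_in_scenario(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        c12 = pp.assign_condfdr(g1, g2, pp.build_condfdr_lookup(g1, g2))
        c21 = pp.assign_condfdr(g2, g1, pp.build_condfdr_lookup(g2, g1))
        conj = pp.conjfdr(c12, c21)
        assert (conj >= c12).all() and (conj >= c21.loc[conj.index]).all()
        passing = conj[conj < 0.01].index
        assert (c12.loc[passing] < 0.01).all()
        assert (c21.loc[passing] < 0.01).all()


class TestDefineLoci:
    def _conj(self, ld, values):
        return pd.Series(values, index=ld.panel.snp_ids.to_numpy()[: len(values)])

    def test_empty_passing_set(self, small_ld, small_config):
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, small_config)
        conj = pd.Series(1.0, index=small_ld.panel.snp_ids.to_numpy())
        assert pp.define_loci(conj, small_ld, g1, g2) == []

    def test_singleton_locus(self):
        ld = toy_panel(5)
        g1 = gwas_from_z(ld, [1, 2, 3, 4, 5])
        g2 = gwas_from_z(ld, [1, 2, 3, 4, 5])
        conj = pd.Series([1, 1, 0.001, 1, 1], index=ld.panel.snp_ids.to_numpy())
        loci = pp.define_loci(conj, ld, g1, g2)
        assert len(loci) == 1
        assert loci[0].lead_snp == "snp003" and loci[0].members == ["snp003"]

    def test_34_snps_in_5_clusters_give_5_loci(self):
        """34 passing variants in 5 mutually uncorrelated LD clusters clump
        to exactly 5 loci with disjoint member sets."""
        sizes = [7, 7, 7, 7, 6]
        ld = toy_panel(34, block_sizes=sizes, rho=0.9)
        rng = np.random.default_rng(2)
        z = rng.normal(6, 0.3, 34) * rng.choice([-1, 1])
        g1, g2 = gwas_from_z(ld, z), gwas_from_z(ld, z)
        conj = pd.Series(rng.uniform(1e-6, 9e-3, 34),
                         index=ld.panel.snp_ids.to_numpy())
        loci = pp.define_loci(conj, ld, g1, g2, r2_clump=0.1)
        assert len(loci) == 5
        members = [set(l.members) for l in loci]
        assert sum(len(m) for m in members) == 34
        for i in range(5):
            for j in range(i + 1, 5):
                assert not members[i] & members[j]

    def test_strongest_lead_has_minimum_conjfdr(self):
        """Across five single-variant loci, the lead with the minimum conjFDR
        is the globally strongest association."""
        conj_values = [5.74e-03, 1.94e-03, 8.51e-04, 4.17e-06, 6.27e-03]
        ld = toy_panel(5, block_sizes=[1] * 5)
        z = np.array([4.07, 4.90, 4.32, -5.52, -3.82])
        g1 = gwas_from_z(ld, z)
        g2 = gwas_from_z(ld, [3.88, 4.16, 7.04, -5.48, -4.04])
        conj = pd.Series(conj_values, index=ld.panel.snp_ids.to_numpy())
        loci = pp.define_loci(conj, ld, g1, g2)
        assert len(loci) == 5
        assert loci[0].lead_conjfdr == pytest.approx(4.17e-06)
        assert loci[0].lead_snp == "snp004"

    def test_lead_attains_member_minimum(self, small_ld, small_config):
        cfg = small_config.replace(pi_shared=0.02, seed=60)
        g1, g2, _ = pp.simulate_bivariate_gwas(small_ld, cfg)
        c12 = pp.assign_condfdr(g1, g2, pp.build_condfdr_lookup(g1, g2))
        c21 = pp.assign_condfdr(g2, g1, pp.build_condfdr_lookup(g2, g1))
        conj = pp.conjfdr(c12, c21)
        loci = pp.define_loci(conj, small_ld, g1, g2, threshold=0.05)
        seen = set()
        for locus in loci:
            assert locus.lead_conjfdr == min(conj[m] for m in locus.members)
            assert not seen & set(locus.members)
            seen |= set(locus.members)


class TestMapGenes:
    annotation = pd.DataFrame(
        {
            "gene": ["TMEM175", "DGKQ", "FAR"],
            "chrom": [4, 4, 4],
            "start": [950_000, 951_000, 2_000_000],
            "end": [952_000, 951_500, 2_001_000],
        }
    )

    def _locus(self, pos, chrom=4):
        return pp.SharedLocus(1, ["rs1"], "rs1", 1e-3, chrom, pos, 1.0, 1.0)

    def test_containment_single_gene(self):
        loci = pp.map_genes([self._locus(950_500)], self.annotation)
        assert loci[0].mapped_genes == ["TMEM175"]

    def test_overlapping_genes_both_returned(self):
        # position 951,179 lies in two overlapping gene intervals
        loci = pp.map_genes([self._locus(951_179)], self.annotation)
        assert set(loci[0].mapped_genes) == {"TMEM175", "DGKQ"}

    def test_one_bp_outside_is_intergenic(self):
        assert pp.map_genes([self._locus(952_001)], self.annotation)[0].mapped_genes == []
        assert pp.map_genes([self._locus(949_999)], self.annotation)[0].mapped_genes == []
        # flank rescues the boundary miss
        assert pp.map_genes([self._locus(952_001)], self.annotation, flank=1)[0].mapped_genes == ["TMEM175"]

    def test_malformed_annotation_rejected(self):
        bad = self.annotation.copy()
        bad.loc[0, "start"] = bad.loc[0, "end"] + 1
        with pytest.raises(ValueError):
            pp.map_genes([self._locus(950_500)], bad)


class TestConcordance:
    def _loci_with_z(self, z1, z2):
        ld = toy_panel(1)
        g1, g2 = gwas_from_z(ld, [z1]), gwas_from_z(ld, [z2])
        locus = pp.SharedLocus(1, ["snp001"], "snp001", 1e-3, 1, 1000, z1, z2)
        return pp.concordance_check([locus], g1, g2)[0]

    @pytest.mark.parametrize(
        "z1,z2,expected",
        [
            (4.07, 3.88, True),     # both risk-increasing
            (-5.52, -5.48, True),   # both protective
            (2.0, -2.0, False),
            (0.0, 1.0, False),      # zero z has sign 0: discordant
        ],
    )
    def test_sign_agreement(self, z1, z2, expected):
        assert self._loci_with_z(z1, z2).concordant is expected
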