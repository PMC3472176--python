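"""The synthetic-data generator: pedigree shape, gene dropping, QTL, phenotypes."""

import numpy as np
import pandas as pd
import pytest

import gvarpart as gv
from gvarpart.errors import ConfigError


def cfg(**kw):
    base = dict(n_founders=20, n_generations=2, sires_per_generation=2,
                offspring_per_sire=5, n_chromosomes=2, markers_per_chromosome=40,
                n_qtl=20, var_polygenic=0.0, seed=123)
    base.update(kw)
    return gv.SimConfig(**base)


class TestSimulatePedigree:
    def test_founders_only(self):
        ped = gv.simulate_pedigree(cfg(n_generations=0, n_founders=10))
        assert ped.n == 10
        assert ped.is_founder().all()

    def test_generation_counts(self):
        ped = gv.simulate_pedigree(cfg())
        assert ped.n == 20 + 2 * (2 * 5)
        gen = ped.meta["generation"]
        assert (np.bincount(gen) == [20, 10, 10]).all()

    def test_sires_come_from_previous_generation(self):
        ped = gv.simulate_pedigree(cfg(n_generations=3))
        gen = ped.meta["generation"]
        for i in np.flatnonzero(gen > 0):
            s = ped.sire_idx[i]
            assert gen[s] == gen[i] - 1
            assert ped.sex[s] == "M"

    def test_dam_policy_founder(self):
        ped = gv.simulate_pedigree(cfg(dam_policy="founder"))
        gen = ped.meta["generation"]
        for i in np.flatnonzero(gen > 0):
            d = ped.dam_idx[i]
            assert gen[d] == 0 and ped.sex[d] == "F"

    def test_seeded_determinism(self):
        a = gv.simulate_pedigree(cfg())
        b = gv.simulate_pedigree(cfg())
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.sire_idx, b.sire_idx)
        np.testing.assert_array_equal(a.dam_idx, b.dam_idx)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigError):
            gv.SimConfig(n_founders=0).validate()
        with pytest.raises(ConfigError):
            gv.SimConfig(maf_low=0.0).validate()
        with pytest.raises(ConfigError):
            gv.SimConfig(var_genomic=-1).validate()


class TestSimulateGenotypes:
    def test_codes_and_metadata(self):
        c = cfg()
        ped = gv.simulate_pedigree(c)
        geno = gv.simulate_genotypes(ped, c)
        assert geno.codes.shape == (ped.n, 80)
        assert set(np.unique(geno.codes)) <= {0.0, 1.0, 2.0}
        assert list(np.unique(geno.chrom)) == [1, 2]

    def test_mendelian_consistency_with_known_trios(self):
        c = cfg(dam_policy="founder", markers_per_chromosome=60)
        ped = gv.simulate_pedigree(c)
        geno = gv.simulate_genotypes(ped, c)
        gen = ped.meta["generation"]
        for i in np.flatnonzero(gen > 0):
            o = geno.codes[i]
            s = geno.codes[ped.sire_idx[i]]
            d = geno.codes[ped.dam_idx[i]]
            # an offspring code must be reachable by one allele per parent
            lo = np.where(s == 2, 1, 0) + np.where(d == 2, 1, 0)
            hi = np.where(s >= 1, 1, 0) + np.where(d >= 1, 1, 0)
            assert np.all(o >= lo) and np.all(o <= hi)

    @pytest.mark.parametrize("length, expect_linked", [(0.0, True), (20.0, False)])
    def test_zero_recombination_transmits_intact_haplotypes(self, length, expect_linked):
        """With L=0, one sire transmits only its two intact haplotypes.

        For a sire heterozygous at markers j and k, intact transmission makes
        the paternal contributions at j and k perfectly co-vary across many
        offspring, so |corr(o_j, o_k)| = 0.25/(0.25 + p(1-p)) = 0.5 at
        p = 0.5; with many crossovers the correlation collapses toward 0.
        """
        c = gv.SimConfig(n_founders=2, n_generations=1, sires_per_generation=1,
                         offspring_per_sire=300, n_chromosomes=1,
                         markers_per_chromosome=30, chromosome_length_morgans=length,
                         maf_low=0.5, maf_high=0.5, n_qtl=1, seed=77)
        ped = gv.simulate_pedigree(c)
        geno = gv.simulate_genotypes(ped, c)
        gen = ped.meta["generation"]
        sire = ped.sire_idx[np.flatnonzero(gen == 1)[0]]
        het = np.flatnonzero(geno.codes[sire] == 1)
        kids = geno.codes[gen == 1][:, het]
        corr = np.corrcoef(kids.T)
        pair_corrs = np.abs(corr[np.triu_indices(len(het), k=1)])
        if expect_linked:
            assert pair_corrs.mean() > 0.35
        else:
            assert pair_corrs.mean() < 0.15

    def test_founder_frequencies_match_binomial_sampling(self):
        c = gv.SimConfig(n_founders=500, n_generations=0, n_chromosomes=5,
                         markers_per_chromosome=2000, n_qtl=1, seed=9)
        ped = gv.simulate_pedigree(c)
        geno = gv.simulate_genotypes(ped, c)
        p_true = geno.meta["founder_freqs"]
        p_hat = gv.allele_frequencies(geno)
        dev = np.abs(p_hat - p_true)
        sd = np.sqrt(p_true * (1 - p_true) / (2 * 500))
        # mean absolute deviation of a normal is sd*sqrt(2/pi)
        assert dev.mean() <= 3 * sd.mean()
        assert dev.mean() >= sd.mean() * np.sqrt(2 / np.pi) / 3

    def test_half_sib_genomic_relationship_near_quarter(self):
        c = gv.SimConfig(n_founders=40, n_generations=1, sires_per_generation=4,
                         offspring_per_sire=12, n_chromosomes=10,
                         markers_per_chromosome=500, n_qtl=1, seed=21)
        ped = gv.simulate_pedigree(c)
        geno = gv.simulate_genotypes(ped, c)
        # center with the true base-population frequencies so the expected
        # half-sib relationship is 0.25 (sample-frequency centering shifts
        # every relationship down by the mean relatedness)
        G = gv.build_G(geno, freqs=geno.meta["founder_freqs"])
        gen = ped.meta["generation"]
        vals = []
        kids = np.flatnonzero(gen == 1)
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                i, j = kids[a], kids[b]
                if (ped.sire_idx[i] == ped.sire_idx[j]
                        and ped.dam_idx[i] == ped.dam_idx[j] == -1):
                    vals.append(G.values[i, j])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.25) <= 3 * se

    def test_seeded_determinism(self):
        c = cfg()
        ped = gv.simulate_pedigree(c)
        g1 = gv.simulate_genotypes(ped, c)
        g2 = gv.simulate_genotypes(ped, c)
        np.testing.assert_array_equal(g1.codes, g2.codes)


class TestQtlAndTbv:
    def test_pure_marker_tbv_is_linear_in_genotypes(self):
        c = cfg(var_polygenic=0.0)
        sim = gv.simulate_dataset(c)
        assert np.allclose(sim.truth.tbv_polygenic, 0.0)
        eff = sim.truth.qtl.set_index("locus")["effect"]
        cols = [sim.genotypes.marker_ids.index(m) for m in eff.index]
        recon = sim.genotypes.codes[:, cols] @ eff.to_numpy()
        recon -= recon[sim.pedigree.is_founder()].mean()
        np.testing.assert_allclose(recon, sim.truth.tbv, atol=1e-9)

    def test_component_variances_hit_targets_exactly(self):
        c = cfg(var_polygenic=30.0, n_qtl=40, qtl_hidden_fraction=0.25)
        sim = gv.simulate_dataset(c)
        gen = sim.pedigree.meta["generation"]
        final = gen == gen.max()
        assert np.var(sim.truth.tbv_genomic[final], ddof=1) == pytest.approx(100.0)
        assert np.var(sim.truth.tbv_polygenic[final], ddof=1) == pytest.approx(30.0)

    def test_single_qtl_differences_proportional_to_alleles(self):
        c = cfg(n_qtl=1, var_polygenic=0.0)
        sim = gv.simulate_dataset(c)
        q = sim.truth.qtl.iloc[0]
        j = sim.genotypes.marker_ids.index(q["locus"])
        codes = sim.genotypes.codes[:, j]
        diff_tbv = sim.truth.tbv[:, None] - sim.truth.tbv[None, :]
        diff_code = codes[:, None] - codes[None, :]
        np.testing.assert_allclose(diff_tbv, q["effect"] * diff_code, atol=1e-9)

    def test_no_qtl_with_positive_variance_rejected(self):
        c = cfg(n_qtl=0)
        ped = gv.simulate_pedigree(c)
        geno = gv.simulate_genotypes(ped, c)
        with pytest.raises(ConfigError):
            gv.assign_qtl_and_tbv(geno, c, ped)

    def test_planted_chromosome_restriction(self):
        c = cfg(qtl_chromosomes=[2], n_qtl=15)
        sim = gv.simulate_dataset(c)
        assert (sim.truth.qtl["chrom"] == 2).all()


class TestSimulateDrp:
    def test_infinite_information_limit(self):
        c = cfg(weight_low=1e9, weight_high=1e9, phenotype_cohort="all")
        sim = gv.simulate_dataset(c)
        resid = sim.phenotypes["y"].to_numpy() - c.mu - sim.truth.tbv
        assert np.var(resid) < 1e-6 * c.var_residual

    def test_residual_variance_scales_with_weight(self):
        # 10,000 replicate records at fixed w=4, sigma_e^2=100 => var(e) ~ 25
        c = cfg(var_residual=100.0, weight_low=4.0, weight_high=4.0)
        rng = np.random.default_rng(5)
        tv = gv.TrueValues(ids=list(range(10000)), tbv=np.zeros(10000),
                           tbv_genomic=np.zeros(10000), tbv_polygenic=np.zeros(10000),
                           qtl=pd.DataFrame())
        phen = gv.simulate_drp(tv, c, rng=rng)
        e = phen["y"].to_numpy() - c.mu
        mc_se = 25.0 * np.sqrt(2 / (10000 - 1))
        assert abs(np.var(e, ddof=1) - 25.0) <= 3 * mc_se

    def test_final_cohort_only_by_default(self):
        sim = gv.simulate_dataset(cfg())
        gen = sim.pedigree.meta["generation"]
        assert len(sim.phenotypes) == int((gen == gen.max()).sum())

    def test_seeded_determinism(self):
        a = gv.simulate_dataset(cfg()).phenotypes
        b = gv.simulate_dataset(cfg()).phenotypes
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_residual_variance_rejected(self):
        sim = gv.simulate_dataset(cfg())
        with pytest.raises(ConfigError):
            gv.simulate_drp(sim.truth, cfg(var_residual=0.0))
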