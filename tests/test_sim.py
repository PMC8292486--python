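"""Generator contracts: determinism, LD structure, phenotype decomposition."""

import numpy as np
import pytest

import socgwas
from socgwas.sim import (SimConfig, SimConfigError, analytic_phenotypic_variance,
                         sim_effects_and_phenotypes, sim_feeder_records,
                         sim_genotypes)


def _pairwise_r2(dos, pairs):
    out = []
    for i, j in pairs:
        a, b = dos[:, i], dos[:, j]
        if a.std() == 0 or b.std() == 0:
            continue
        out.append(np.corrcoef(a, b)[0, 1] ** 2)
    return np.array(out)


class TestGenotypes:
    def test_seeded_determinism(self, small_config):
        g1 = sim_genotypes(small_config)
        g2 = sim_genotypes(small_config)
        assert np.array_equal(g1.dosage, g2.dosage)
        assert np.array_equal(g1.phase, g2.phase)
        assert g1.markers.equals(g2.markers)

    def test_single_founder_pool_rejected(self):
        cfg = SimConfig(founder_haplotypes_per_block=1)
        with pytest.raises(SimConfigError):
            sim_genotypes(cfg)

    def test_two_identical_founder_draws_fix_blocks(self):
        # with 2 founders and uniform copying, some individuals draw the same
        # founder twice and are then homozygous across the whole block
        cfg = SimConfig(n_individuals=50, n_snps=40, n_ld_blocks=4,
                        founder_haplotypes_per_block=2,
                        founder_weighting="uniform", seed=4)
        g = sim_genotypes(cfg)
        blocks = g.markers["ld_block"].to_numpy()
        s1, s2 = g.phase
        for b in np.unique(blocks):
            cols = blocks == b
            same = (s1[:, cols] == s2[:, cols]).all(axis=1)
            # an individual whose strands agree anywhere in the block copied
            # one founder twice, hence is homozygous at every block marker
            hom = (g.dosage[:, cols] % 2 == 0).all(axis=1)
            assert np.all(hom[same])

    def test_phase_sums_to_dosage(self, small_sim):
        g = small_sim[0]
        assert np.array_equal(g.phase.sum(axis=0), g.dosage.astype(np.int8))

    def test_positions_strictly_increasing_within_chromosome(self, small_sim):
        mk = small_sim[0].markers
        for _, grp in mk.groupby("chrom"):
            assert (np.diff(grp["pos"].to_numpy()) > 0).all()

    def test_within_block_ld_exceeds_between_block_ld(self):
        cfg = SimConfig(n_individuals=2000, n_snps=200, n_ld_blocks=20,
                        founder_haplotypes_per_block=6, seed=9)
        g = sim_genotypes(cfg)
        rng = np.random.default_rng(1)
        blocks = g.markers["ld_block"].to_numpy()
        within, between = [], []
        for _ in range(400):
            i, j = rng.integers(0, cfg.n_snps, 2)
            if i == j:
                continue
            (within if blocks[i] == blocks[j] else between).append((i, j))
        r2_w = _pairwise_r2(g.dosage, within)
        r2_b = _pairwise_r2(g.dosage, between)
        assert r2_w.mean() > r2_b.mean()


class TestPhenotypes:
    def test_zero_variances_give_pure_fixed_plus_noise(self):
        cfg = SimConfig(n_individuals=80, n_snps=100, n_ld_blocks=10,
                        n_litters=8, group_size=8, var_direct=0.0,
                        var_social=0.0, cov_direct_social=0.0,
                        var_litter=0.0, var_group=0.0, n_qtl_direct=0,
                        n_qtl_social=0, seed=2)
        g = sim_genotypes(cfg)
        _, _, truth = sim_effects_and_phenotypes(g, cfg)
        np.testing.assert_allclose(
            truth.latent_y, truth.fixed_part + truth.residuals, atol=1e-12)
        assert np.all(truth.true_a_D == 0) and np.all(truth.true_a_S == 0)

    def test_phenotype_decomposition_identity(self, small_sim):
        g, cohort, traits, visits, truth = small_sim
        pen = cohort["pen"].to_numpy()
        litter = cohort["litter"].to_numpy()
        resid_social = (
            truth.latent_y - truth.fixed_part - truth.true_a_D
            - truth.litter_effects[litter] - truth.group_effects[pen]
            - truth.residuals
        )
        np.testing.assert_allclose(resid_social, truth.sge_sum, atol=1e-10)
        # and the sge_sum is literally the pen mates' social effects
        for i in range(len(pen)):
            mates = (pen == pen[i]) & (np.arange(len(pen)) != i)
            assert resid_social[i] == pytest.approx(truth.true_a_S[mates].sum())

    def test_non_psd_genetic_covariance_rejected(self):
        cfg = SimConfig(var_direct=0.1, var_social=0.1, cov_direct_social=0.2)
        with pytest.raises(SimConfigError):
            cfg.validate()

    def test_pen_assignment_partitions_cohort(self, small_sim):
        cohort = small_sim[1]
        sizes = cohort.groupby("pen").size()
        assert sizes.sum() == len(cohort)
        assert (sizes <= 6).all()

    def test_last_incomplete_pen_kept(self):
        cfg = SimConfig(n_individuals=62, n_snps=60, n_ld_blocks=6,
                        n_litters=6, group_size=12, seed=3)
        g = sim_genotypes(cfg)
        cohort, _, _ = sim_effects_and_phenotypes(g, cfg)
        sizes = cohort.groupby("pen").size().sort_values()
        assert sizes.iloc[0] == 2 and (sizes.iloc[1:] == 12).all()

    def test_realized_variance_matches_analytic_budget(self):
        cfg = SimConfig(n_individuals=2000, n_snps=400, n_ld_blocks=40,
                        group_size=10, n_litters=200)
        target = analytic_phenotypic_variance(cfg)
        ratios = []
        for rep in range(20):
            c = SimConfig(**{**cfg.to_dict(), "seed": 500 + rep})
            g = sim_genotypes(c)
            _, _, truth = sim_effects_and_phenotypes(g, c)
            ratios.append(truth.latent_y.var() / target)
        assert abs(np.mean(ratios) - 1) < 0.10

    def test_effect_variance_matches_sigma_across_seeds(self):
        # realized Var(a_D)/sigma2_D concentrates near 1 (exact rescale)
        ratios = []
        for rep in range(50):
            cfg = SimConfig(n_individuals=1000, n_snps=200, n_ld_blocks=20,
                            n_litters=100, seed=3000 + rep)
            g = sim_genotypes(cfg)
            _, _, truth = sim_effects_and_phenotypes(g, cfg)
            ratios.append(truth.true_a_D.var() / cfg.var_direct)
        ratios = np.array(ratios)
        assert np.all((ratios > 0.8) & (ratios < 1.2))


class TestFeederRecords:
    def test_adfi_and_tpd_recovered_exactly(self, small_sim):
        g, cohort, traits, visits, truth = small_sim
        for rec in cohort.itertuples(index=False):
            v = visits[visits["id"] == rec.id]
            adfi = v["feed"].sum() / rec.feed_days
            tpd = v["time"].sum() / rec.feed_days
            assert adfi == pytest.approx(rec.tfi / rec.feed_days, abs=1e-9)
            assert tpd == pytest.approx(rec.total_time / rec.feed_days, abs=1e-9)

    def test_every_pig_has_at_least_two_visits(self, small_sim):
        visits = small_sim[3]
        assert (visits.groupby("id")["day"].nunique() >= 2).all()

    def test_seeded_determinism(self, small_config, small_sim):
        cohort = small_sim[1]
        v1 = sim_feeder_records(cohort, small_config)
        v2 = sim_feeder_records(cohort, small_config)
        assert v1.equals(v2)
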