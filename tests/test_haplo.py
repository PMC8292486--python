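"""LD confidence intervals, Gabriel blocks, haplotype alleles and their GWAS."""

import itertools

import numpy as np
import pandas as pd
import pytest

import socgwas
from socgwas.genio import GenotypeMatrix
from socgwas.gwas import fit_mlm_null, wald_scan
from socgwas.haplo import (HaplotypeBlock, _em_hap_freqs, _unphased_grid_loglik,
                           classify_pairs, gabriel_blocks, hap_allele_dosage,
                           hap_gwas, ld_ci)


def _phased_panel(strands, chrom=None, pos=None):
    """Build a GenotypeMatrix from a (2, n, p) strand array."""
    phase = np.asarray(strands, dtype=np.int8)
    _, n, p = phase.shape
    markers = pd.DataFrame(
        {"id": [f"s{j}" for j in range(p)],
         "chrom": chrom if chrom is not None else [1] * p,
         "pos": pos if pos is not None else (np.arange(p) + 1) * 1000,
         "a1": ["G"] * p, "a2": ["A"] * p, "quality": 1.0}
    )
    return GenotypeMatrix(dosage=phase.sum(axis=0).astype(float), phase=phase,
                          markers=markers, samples=[f"i{k}" for k in range(n)])


class TestLDCI:
    def test_complete_disequilibrium(self):
        h = np.array([1] * 30 + [0] * 70)
        est = ld_ci(h, h, phased=True)
        assert est.dprime == pytest.approx(1.0)
        assert est.ci_high >= 0.98
        assert est.ci_low > 0.8
        assert est.is_strong()

    def test_exact_independence(self):
        a = np.array([1, 1, 0, 0] * 25)
        b = np.array([1, 0, 1, 0] * 25)
        est = ld_ci(a, b, phased=True)
        assert est.dprime == pytest.approx(0.0, abs=1e-12)
        assert est.r2 == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_is_uninformative(self):
        a = np.ones(100)
        b = np.array([1, 0] * 50)
        assert not ld_ci(a, b, phased=True).informative

    def test_em_matches_exhaustive_ml_on_small_fixture(self):
        rng = np.random.default_rng(5)
        p_true = np.array([0.45, 0.15, 0.05, 0.35])
        haps = rng.choice(4, size=(20, 2), p=p_true)
        a_of = np.array([1, 1, 0, 0])
        b_of = np.array([1, 0, 1, 0])
        ga = a_of[haps].sum(1).astype(float)
        gb = b_of[haps].sum(1).astype(float)
        em = _em_hap_freqs(ga, gb)
        # exhaustive grid over p11 at the EM margins (the only free parameter)
        pa, pb = ga.mean() / 2, gb.mean() / 2
        lo = max(0.0, pa + pb - 1.0)
        hi = min(pa, pb)
        grid = np.linspace(lo, hi, 200001)
        cells = np.clip(
            np.stack([grid, pa - grid, pb - grid, 1 - pa - pb + grid]),
            1e-12, None)
        ll = _unphased_grid_loglik(ga, gb, cells)
        best_p11 = grid[np.argmax(ll)]
        assert em[0] == pytest.approx(best_p11, abs=1e-6)


def exhaustive_block_oracle(geno, max_kb=1000.0, strong_low=0.8,
                            strong_high=0.98, recomb_high=0.90,
                            strong_frac=0.95):
    """Brute force: evaluate every contiguous span against the pair rules,
    then resolve overlaps longest-first (independent of gabriel_blocks'
    span bookkeeping)."""
    pos = geno.markers["pos"].to_numpy()
    chrom = geno.markers["chrom"].to_numpy()
    spans = []
    p = geno.n_markers
    for s in range(p):
        for e in range(s + 1, p):
            if chrom[s] != chrom[e] or pos[e] - pos[s] > max_kb * 1000:
                continue
            n_strong = n_inf = 0
            for u, v in itertools.combinations(range(s, e + 1), 2):
                est = ld_ci(geno.phase[:, :, u].ravel(),
                            geno.phase[:, :, v].ravel(), phased=True)
                if est.is_strong(strong_low, strong_high):
                    n_strong += 1
                    n_inf += 1
                elif est.is_recomb(recomb_high):
                    n_inf += 1
            if n_inf and n_strong / n_inf >= strong_frac:
                spans.append((s, e))
    spans.sort(key=lambda se: (-(pos[se[1]] - pos[se[0]]),
                               -(se[1] - se[0]), pos[se[0]]))
    taken = np.zeros(p, dtype=bool)
    chosen = []
    for s, e in spans:
        if taken[s:e + 1].any():
            continue
        taken[s:e + 1] = True
        chosen.append(tuple(range(s, e + 1)))
    return sorted(chosen)


class TestGabrielBlocks:
    def _planted_panel(self, seed=0, n=200):
        """6 SNPs: a perfect-LD triple (0-2) and three independent SNPs."""
        rng = np.random.default_rng(seed)
        hap_core = rng.random(2 * n) < 0.4
        strands = np.empty((2, n, 6), dtype=np.int8)
        core = hap_core.astype(np.int8).reshape(2, n)
        for j in range(3):
            strands[:, :, j] = core  # identical strands: pairwise D' = 1
        for j in range(3, 6):
            strands[:, :, j] = (rng.random((2, n)) < 0.4)
        pos = [1000, 2000, 3000, 200000, 400000, 600000]
        return _phased_panel(strands, pos=pos)

    def test_planted_triple_matches_exhaustive_oracle(self):
        g = self._planted_panel()
        blocks = gabriel_blocks(g)
        got = sorted(tuple(b.snp_indices) for b in blocks)
        assert got == exhaustive_block_oracle(g)
        assert (0, 1, 2) in got

    def test_distant_pair_never_blocks(self):
        rng = np.random.default_rng(3)
        core = (rng.random((2, 150)) < 0.5).astype(np.int8)
        strands = np.stack([core, core], axis=2)  # perfect LD but 2 Mb apart
        g = _phased_panel(strands, pos=[1000, 2_001_000])
        assert gabriel_blocks(g) == []

    def test_single_snp_never_a_block(self):
        rng = np.random.default_rng(4)
        strands = (rng.random((2, 100, 1)) < 0.5).astype(np.int8)
        g = _phased_panel(strands)
        assert gabriel_blocks(g) == []

    def test_full_strong_span_is_one_maximal_block(self):
        rng = np.random.default_rng(6)
        core = (rng.random((2, 200)) < 0.35).astype(np.int8)
        strands = np.stack([core] * 5, axis=2)
        g = _phased_panel(strands, pos=[1000, 2000, 3000, 4000, 5000])
        blocks = gabriel_blocks(g)
        assert len(blocks) == 1 and blocks[0].n_snps == 5

    def test_blocks_never_overlap_on_simulated_panel(self, small_sim):
        g = small_sim[0]
        blocks = gabriel_blocks(g)
        for chrom in {b.chrom for b in blocks}:
            idx = sorted(
                i for b in blocks if b.chrom == chrom for i in b.snp_indices)
            assert len(idx) == len(set(idx))
        for b in blocks:
            assert b.n_snps >= 2
            assert b.span_bp <= 1000 * 1000
            assert list(b.snp_indices) == sorted(b.snp_indices)
            assert sum(b.frequencies) == pytest.approx(1.0, abs=1e-9)
            assert len(b.alleles) <= min(2 ** b.n_snps, 2 * g.n_samples)


class TestHapAlleles:
    def test_hand_tallied_fixture(self):
        # 4 individuals, 3 SNPs; haplotypes listed by hand
        strands = np.array([
            [[1, 1, 1], [0, 0, 0], [1, 0, 1], [0, 0, 0]],   # strand 1
            [[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]],   # strand 2
        ], dtype=np.int8)
        g = _phased_panel(strands)
        block = HaplotypeBlock(chrom=1, start_bp=1000, end_bp=3000,
                               snp_indices=[0, 1, 2])
        dos, kept, freqs = hap_allele_dosage(g, block, allele_freq_min=0.0)
        # a1 = G, a2 = A; per-individual haplotype pairs read off the strands:
        # i0: GGG/GGG, i1: AAA/GGG, i2: GAG/AAA, i3: AAA/AAA
        assert freqs == {"AAA": 4 / 8, "GGG": 3 / 8, "GAG": 1 / 8}
        k = {a: i for i, a in enumerate(kept)}
        np.testing.assert_array_equal(dos[:, k["GGG"]], [2, 1, 0, 0])
        np.testing.assert_array_equal(dos[:, k["AAA"]], [0, 1, 1, 2])
        np.testing.assert_array_equal(dos[:, k["GAG"]], [0, 0, 1, 0])

    def test_homozygote_scores_two(self):
        strands = np.array([[[1, 1, 1]], [[1, 1, 1]]], dtype=np.int8)
        g = _phased_panel(strands)
        block = HaplotypeBlock(chrom=1, start_bp=1000, end_bp=3000,
                               snp_indices=[0, 1, 2])
        dos, kept, _ = hap_allele_dosage(g, block, allele_freq_min=0.0)
        assert kept == ["GGG"]
        assert dos[0, 0] == 2

    def test_diploid_conservation(self, small_sim):
        g = small_sim[0]
        blocks = gabriel_blocks(g)[:5]
        for b in blocks:
            dos, kept, freqs = hap_allele_dosage(g, b, allele_freq_min=-1.0)
            np.testing.assert_array_equal(dos.sum(axis=1), np.full(g.n_samples, 2))

    def test_rare_alleles_dropped_from_testing_only(self, small_sim):
        g = small_sim[0]
        blocks = gabriel_blocks(g)
        b = max(blocks, key=lambda blk: len(blk.alleles))
        dos, kept, freqs = hap_allele_dosage(g, b, allele_freq_min=0.01)
        assert all(freqs[a] > 0.01 for a in kept)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_unphased_input_rejected(self, small_sim):
        g = small_sim[0]
        unphased = GenotypeMatrix(dosage=g.dosage, markers=g.markers,
                                  samples=g.samples)
        block = HaplotypeBlock(chrom=1, start_bp=1, end_bp=2001,
                               snp_indices=[0, 1, 2])
        with pytest.raises(ValueError, match="phased"):
            hap_allele_dosage(unphased, block)


class TestHapGWAS:
    def test_allele_matching_causal_snp_gives_same_p(self, rng):
        n = 150
        core = (rng.random((2, n)) < 0.3).astype(np.int8)
        strands = np.stack([core, core, core], axis=2)
        g = _phased_panel(strands, pos=[1000, 2000, 3000])
        x = g.dosage[:, 0]
        y = 0.4 * x + rng.standard_normal(n)
        null = fit_mlm_null(y, np.zeros((n, n)))
        blocks = gabriel_blocks(g)
        assert len(blocks) == 1
        tab = hap_gwas(g, blocks, null)
        snp_tab = wald_scan(x[:, None], null)
        # the GGG allele dosage is exactly the SNP dosage
        row = tab.loc[tab["allele"] == "GGG"]
        assert float(row["p"].iloc[0]) == pytest.approx(
            float(snp_tab["p"].iloc[0]), rel=1e-10)

    def test_null_alleles_roughly_uniform(self, small_sim, rng):
        g = small_sim[0]
        blocks = gabriel_blocks(g)
        y = rng.standard_normal(g.n_samples)
        null = fit_mlm_null(y, np.zeros((g.n_samples, g.n_samples)))
        tab = hap_gwas(g, blocks, null)
        p = tab["p"].dropna()
        assert len(p) > 30
        # crude uniformity check: no gross inflation of small p-values
        assert (p < 0.05).mean() < 0.15
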