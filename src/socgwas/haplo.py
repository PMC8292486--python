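"""Haplotype-block detection and multi-allelic haplotype association.

Blocks follow the confidence-interval method of Gabriel et al.: for every
marker pair close enough on the chromosome, a likelihood-based confidence
interval on |D'| classifies the pair as *strong LD* (CI lower bound >= 0.8 by
default, upper bound >= 0.98), *strong recombination* (upper bound < 0.90) or
non-informative. A run of markers whose informative pairs are at least 95%
strong, spanning at most 1 Mb, forms a block of two or more SNPs; overlapping
candidate spans are resolved longest-first.

Each block's distinct haplotype strings over its member SNPs become the
alleles of one multi-allelic locus; each allele is tested as a biallelic
pseudo-marker (dosage = number of copies carried) in the same mixed model as
the single-SNP scan, after dropping alleles at frequency <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .gwas import MLMNull, wald_scan

_DPRIME_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class LDEstimate:
    """Pairwise LD summary: D' with a 90% likelihood CI, plus r^2."""

    dprime: float
    ci_low: float
    ci_high: float
    r2: float
    informative: bool

    def is_strong(self, low: float = 0.8, high: float = 0.98) -> bool:
        return self.informative and self.ci_low >= low and self.ci_high >= high

    def is_recomb(self, high: float = 0.90) -> bool:
        return self.informative and self.ci_high < high


@dataclass
class HaplotypeBlock:
    """A run of SNPs in strong LD treated as one multi-allelic locus."""

    chrom: object
    start_bp: int
    end_bp: int
    snp_indices: list[int]
    snp_ids: list[str] = field(default_factory=list)
    alleles: list[str] = field(default_factory=list)
    frequencies: list[float] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------


def _em_hap_freqs(ga: np.ndarray, gb: np.ndarray,
                  tol: float = 1e-10, maxiter: int = 2000) -> np.ndarray:
    """Two-locus EM haplotype frequencies [p11, p10, p01, p00] from dosages.

    Dosages count allele '1' at each locus; only the double heterozygote is
    phase-ambiguous.
    """
    ok = np.isfinite(ga) & np.isfinite(gb)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    n = ga.size
    counts = np.zeros((3, 3))
    for a, b in zip(ga, gb):
        counts[a, b] += 1
    pa, pb = ga.mean() / 2.0, gb.mean() / 2.0
    p = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    p = np.maximum(p, 1e-6)
    p /= p.sum()
    n_dh = counts[1, 1]
    # unambiguous haplotype counts
    base = np.array([
        2 * counts[2, 2] + counts[2, 1] + counts[1, 2],          # 11
        2 * counts[2, 0] + counts[2, 1] + counts[1, 0],          # 10
        2 * counts[0, 2] + counts[0, 1] + counts[1, 2],          # 01
        2 * counts[0, 0] + counts[0, 1] + counts[1, 0],          # 00
    ], dtype=float)
    for _ in range(maxiter):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        tot = cis + trans
        f_cis = 0.5 if tot == 0 else cis / tot
        hap = base + n_dh * np.array([f_cis, 1 - f_cis, 1 - f_cis, f_cis])
        p_new = hap / (2.0 * n)
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    return p


def _phased_hap_freqs(ha: np.ndarray, hb: np.ndarray) -> tuple[np.ndarray, int]:
    """Haplotype frequencies from phased strands (each shape (2n,))."""
    n11 = float(np.sum((ha == 1) & (hb == 1)))
    n10 = float(np.sum((ha == 1) & (hb == 0)))
    n01 = float(np.sum((ha == 0) & (hb == 1)))
    n00 = float(np.sum((ha == 0) & (hb == 0)))
    tot = n11 + n10 + n01 + n00
    return np.array([n11, n10, n01, n00]) / tot, int(tot)


def _dprime_of(p: np.ndarray) -> tuple[float, float, float]:
    """(D, Dmax, D') from [p11, p10, p01, p00]."""
    pa = p[0] + p[1]
    pb = p[0] + p[2]
    D = p[0] - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dp = 0.0 if dmax <= 0 else abs(D) / dmax
    return D, dmax, min(dp, 1.0)


def _ci_from_profile(loglik: np.ndarray, coverage: float = 0.90
                     ) -> tuple[float, float]:
    """Central CI on the D' grid from a normalized likelihood profile."""
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    tail = (1.0 - coverage) / 2.0
    low = float(_DPRIME_GRID[int(np.searchsorted(cdf, tail))])
    high = float(_DPRIME_GRID[min(int(np.searchsorted(cdf, 1.0 - tail)),
                                  len(_DPRIME_GRID) - 1)])
    return low, high


def ld_ci(a, b, phased: bool = True, min_haplotypes: int = 20) -> LDEstimate:
    """D' point estimate with a 90% likelihood-profile confidence interval.

    ``a`` and ``b`` are haplotype strands of shape (2n,) when ``phased``,
    or dosage vectors of shape (n,) otherwise (two-locus EM resolves the
    double-heterozygote ambiguity). The profile fixes the allele frequencies
    at their estimates and evaluates the data likelihood on a D' grid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if phased:
        p, n_chrom = _phased_hap_freqs(a.astype(int), b.astype(int))
    else:
        ok = np.isfinite(a) & np.isfinite(b)
        p = _em_hap_freqs(a, b)
        n_chrom = 2 * int(ok.sum())
    pa = p[0] + p[1]
    pb = p[0] + p[2]
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDEstimate(0.0, 0.0, 1.0, 0.0, informative=False)
    D, dmax, dp = _dprime_of(p)
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = float(D * D / denom)
    sign = 1.0 if D >= 0 else -1.0

    # likelihood profile over D' at fixed margins
    p11 = pa * pb + sign * _DPRIME_GRID * dmax
    p10 = pa - p11
    p01 = pb - p11
    p00 = 1.0 - pa - pb + p11
    cells = np.clip(np.stack([p11, p10, p01, p00]), 1e-12, None)
    if phased:
        counts, _ = _phased_hap_freqs(a.astype(int), b.astype(int))
        counts = counts * n_chrom
        ll = (counts[:, None] * np.log(cells)).sum(axis=0)
    else:
        ll = _unphased_grid_loglik(a, b, cells)
    low, high = _ci_from_profile(ll)
    informative = n_chrom >= min_haplotypes
    return LDEstimate(dp, low, high, r2, informative)


def _unphased_grid_loglik(ga: np.ndarray, gb: np.ndarray,
                          cells: np.ndarray) -> np.ndarray:
    """Genotype-table log-likelihood for each column of hap-probability grid."""
    ok = np.isfinite(ga) & np.isfinite(gb)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    counts = np.zeros((3, 3))
    for x, yv in zip(ga, gb):
        counts[x, yv] += 1
    p11, p10, p01, p00 = cells
    # genotype-class probabilities under random union of haplotypes
    probs = {
        (2, 2): p11**2, (2, 1): 2 * p11 * p10, (2, 0): p10**2,
        (1, 2): 2 * p11 * p01, (1, 0): 2 * p10 * p00,
        (0, 2): p01**2, (0, 1): 2 * p01 * p00, (0, 0): p00**2,
        (1, 1): 2 * (p11 * p00 + p10 * p01),
    }
    ll = np.zeros(cells.shape[1])
    for (i, j), pr in probs.items():
        if counts[i, j]:
            ll += counts[i, j] * np.log(np.clip(pr, 1e-300, None))
    return ll


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------


def classify_pairs(
    geno: GenotypeMatrix,
    idx: np.ndarray,
    max_kb: float,
    strong_low_ci: float,
    strong_high_ci: float,
    recomb_high_ci: float,
    min_haplotypes: int = 20,
) -> dict[tuple[int, int], str]:
    """Classify marker pairs within ``max_kb`` as strong/recomb/uninformative.

    ``idx`` holds positional marker indices of one chromosome, sorted by bp.
    """
    pos = geno.markers["pos"].to_numpy()
    out: dict[tuple[int, int], str] = {}
    phased = geno.is_phased
    for ii, gi in enumerate(idx):
        for gj in idx[ii + 1:]:
            if pos[gj] - pos[gi] > max_kb * 1000:
                break
            if phased:
                a = geno.phase[:, :, gi].ravel()
                b = geno.phase[:, :, gj].ravel()
                est = ld_ci(a, b, phased=True, min_haplotypes=min_haplotypes)
            else:
                est = ld_ci(geno.dosage[:, gi], geno.dosage[:, gj],
                            phased=False, min_haplotypes=min_haplotypes)
            if est.is_strong(strong_low_ci, strong_high_ci):
                out[(gi, gj)] = "strong"
            elif est.is_recomb(recomb_high_ci):
                out[(gi, gj)] = "recomb"
            else:
                out[(gi, gj)] = "none"
    return out


def _spans_from_pairs(
    idx: np.ndarray,
    pos: np.ndarray,
    pairs: dict[tuple[int, int], str],
    strong_fraction: float,
    max_kb: float,
) -> list[tuple[int, int]]:
    """Candidate spans (start_pos, end_pos in idx coordinates) meeting the rule."""
    m = len(idx)
    cands = []
    for s in range(m):
        for e in range(s + 1, m):
            gi, gj = idx[s], idx[e]
            if pos[gj] - pos[gi] > max_kb * 1000:
                break
            n_strong = n_inf = 0
            for u in range(s, e + 1):
                for v in range(u + 1, e + 1):
                    cls = pairs.get((idx[u], idx[v]), "none")
                    if cls == "strong":
                        n_strong += 1
                        n_inf += 1
                    elif cls == "recomb":
                        n_inf += 1
            if n_inf == 0:
                continue
            if n_strong / n_inf >= strong_fraction:
                cands.append((s, e))
    return cands


def gabriel_blocks(
    geno: GenotypeMatrix,
    strong_low_ci: float = 0.8,
    strong_high_ci: float = 0.98,
    recomb_high_ci: float = 0.90,
    strong_fraction: float = 0.95,
    max_kb: float = 1000.0,
    marker_missing_max: float = 0.1,
    min_haplotypes: int = 20,
) -> list[HaplotypeBlock]:
    """Detect haplotype blocks per chromosome by the D'-CI rule.

    Markers with missingness above ``marker_missing_max`` are excluded from
    block building. Candidate spans are kept when at least
    ``strong_fraction`` of their informative pairs are in strong LD; overlaps
    are resolved longest-span-first with a leftmost tie-break. Returned
    blocks have two or more member SNPs; the list may be empty.
    """
    mk = geno.markers
    pos = mk["pos"].to_numpy()
    missing = np.isnan(geno.dosage).mean(axis=0)
    usable = missing <= marker_missing_max
    blocks: list[HaplotypeBlock] = []
    for chrom in pd.unique(mk["chrom"]):
        idx = np.flatnonzero((mk["chrom"] == chrom).to_numpy() & usable)
        if idx.size < 2:
            continue
        idx = idx[np.argsort(pos[idx], kind="stable")]
        pairs = classify_pairs(
            geno, idx, max_kb, strong_low_ci, strong_high_ci,
            recomb_high_ci, min_haplotypes,
        )
        cands = _spans_from_pairs(idx, pos, pairs, strong_fraction, max_kb)
        # longest bp span first; ties -> more SNPs, then leftmost
        def _key(se):
            s, e = se
            return (-(pos[idx[e]] - pos[idx[s]]), -(e - s), pos[idx[s]])

        taken = np.zeros(idx.size, dtype=bool)
        for s, e in sorted(cands, key=_key):
            if taken[s : e + 1].any():
                continue
            taken[s : e + 1] = True
            members = [int(g) for g in idx[s : e + 1]]
            blocks.append(
                HaplotypeBlock(
                    chrom=chrom,
                    start_bp=int(pos[idx[s]]),
                    end_bp=int(pos[idx[e]]),
                    snp_indices=members,
                    snp_ids=[mk["id"].iloc[g] for g in members],
                )
            )
    blocks.sort(key=lambda b: (str(b.chrom), b.start_bp))
    if geno.is_phased:
        for b in blocks:
            _fill_alleles(geno, b)
    return blocks


def _haplotype_strings(geno: GenotypeMatrix, block: HaplotypeBlock) -> np.ndarray:
    """(2, n) array of allele-letter strings for the block's member SNPs."""
    idx = np.asarray(block.snp_indices)
    a1 = geno.markers["a1"].to_numpy()[idx]
    a2 = geno.markers["a2"].to_numpy()[idx]
    strands = geno.phase[:, :, idx]  # (2, n, m)
    letters = np.where(strands == 1, a1[None, None, :], a2[None, None, :])
    return np.array([["".join(row) for row in strand] for strand in letters])


def _fill_alleles(geno: GenotypeMatrix, block: HaplotypeBlock) -> None:
    haps = _haplotype_strings(geno, block)
    uniq, counts = np.unique(haps.ravel(), return_counts=True)
    order = np.lexsort((uniq, -counts))
    block.alleles = [str(uniq[k]) for k in order]
    block.frequencies = [float(counts[k] / haps.size) for k in order]


def hap_allele_dosage(
    geno: GenotypeMatrix,
    block: HaplotypeBlock,
    allele_freq_min: float = 0.01,
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Allele-dosage matrix for one block from phased genotypes.

    Returns (dosage n x k for the k retained alleles, retained allele
    strings, full allele-frequency dict). Alleles at frequency <=
    ``allele_freq_min`` are dropped from testing but still counted in the
    frequency table. Rows of the full (unfiltered) dosage matrix sum to 2.
    """
    if not geno.is_phased:
        raise ValueError("haplotype alleles require phased genotypes "
                         "(supply a phased VCF)")
    if not block.alleles:
        _fill_alleles(geno, block)
    haps = _haplotype_strings(geno, block)  # (2, n)
    freqs = dict(zip(block.alleles, block.frequencies))
    kept = [a for a in block.alleles if freqs[a] > allele_freq_min]
    n = geno.n_samples
    dosage = np.zeros((n, len(kept)))
    for k, allele in enumerate(kept):
        dosage[:, k] = (haps[0] == allele).astype(float) + (haps[1] == allele)
    return dosage, kept, freqs


def hap_gwas(
    geno: GenotypeMatrix,
    blocks: list[HaplotypeBlock],
    null: MLMNull,
    allele_freq_min: float = 0.01,
    mode: str = "p3d",
    reference: str = "f",
) -> pd.DataFrame:
    """Test every retained haplotype allele as a biallelic pseudo-marker.

    The number of rows (retained alleles) is the N for Bonferroni thresholds
    of the haplotype scan.
    """
    cols, rows = [], []
    for bi, block in enumerate(blocks):
        dos, kept, freqs = hap_allele_dosage(geno, block, allele_freq_min)
        for k, allele in enumerate(kept):
            cols.append(dos[:, k])
            rows.append(
                {
                    "id": f"HapL{bi}:{allele}",
                    "block": bi,
                    "chrom": block.chrom,
                    "pos": block.start_bp,
                    "end_bp": block.end_bp,
                    "allele": allele,
                    "freq": freqs[allele],
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["id", "block", "chrom", "pos", "end_bp", "allele",
                     "freq", "beta", "se", "p", "reason"]
        )
    M = np.column_stack(cols)
    meta = pd.DataFrame(rows)
    return wald_scan(M, null, mode=mode, markers=meta, reference=reference)


def blocks_table(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """PLINK blocks-style table: chrom, span, size and member SNP ids."""
    return pd.DataFrame(
        {
            "block": range(len(blocks)),
            "chrom": [b.chrom for b in blocks],
            "start_bp": [b.start_bp for b in blocks],
            "end_bp": [b.end_bp for b in blocks],
            "n_snps": [b.n_snps for b in blocks],
            "snps": ["|".join(b.snp_ids) for b in blocks],
        }
    )


def alleles_table(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    rows = []
    for bi, b in enumerate(blocks):
        for allele, freq in zip(b.alleles, b.frequencies):
            rows.append({"block": bi, "allele": allele, "freq": freq})
    return pd.DataFrame(rows, columns=["block", "allele", "freq"])
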