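"""Marker quality control.

Filters mirror standard chip QC for livestock GWAS: drop markers without a
map position or on sex chromosomes, then filter on an optional per-marker
quality score (e.g. imputation R^2), call rate, minor allele frequency and an
exact Hardy-Weinberg test. Removal thresholds are strict inequalities
(a marker with MAF exactly at the threshold is retained), and each removed
marker is attributed to the first filter in the fixed order that rejects it,
so the bookkeeping report is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix

SEX_CHROMOSOMES = {"X", "Y", "XY", "MT", "M", "0"}


class EmptyPanelError(ValueError):
    """All markers were removed by QC."""


@dataclass
class QCReport:
    """Tally of markers removed per filter, in application order."""

    n_input: int
    n_removed_no_position_or_sex_chr: int = 0
    n_removed_quality: int = 0
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_no_position_or_sex_chr
            + self.n_removed_quality
            + self.n_removed_callrate
            + self.n_removed_maf
            + self.n_removed_hwe
        )

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_lines(self) -> list[str]:
        return [
            f"markers input\t{self.n_input}",
            f"removed: no position / sex chromosome\t{self.n_removed_no_position_or_sex_chr}",
            f"removed: quality score\t{self.n_removed_quality}",
            f"removed: call rate\t{self.n_removed_callrate}",
            f"removed: MAF\t{self.n_removed_maf}",
            f"removed: HWE\t{self.n_removed_hwe}",
            f"markers retained\t{self.n_retained}",
        ]


def replay_marker_bookkeeping(n_input: int, n_no_position_or_sex_chr: int,
                              n_qc_failed: int) -> QCReport:
    """Rebuild a QC report from pooled published counts.

    Chip pipelines often report a single pooled count for map/sex-chromosome
    removals and another for the call-rate/MAF/HWE filters; the pooled QC
    failures are attributed to the call-rate field (first QC filter in order)
    since the per-filter split is not published.
    """
    return QCReport(
        n_input=n_input,
        n_removed_no_position_or_sex_chr=n_no_position_or_sex_chr,
        n_removed_callrate=n_qc_failed,
    )


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-Cutler-Abecasis).

    Returns the sum of probabilities, over heterozygote counts compatible with
    the observed allele counts, of all configurations no more probable than
    the observed one. Monomorphic markers return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # probabilities over het counts with the parity of n_rare
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward from the mode
    het, p = mid, 1.0
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        p *= het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        probs[het] = p
    het, p = mid, 1.0
    while het <= n_rare - 2 and n - het - (n_rare - het) // 2 >= 1:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        p *= 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
        probs[het] = p
    total = sum(probs.values())
    p_obs = probs.get(n_Aa, 0.0) / total
    pval = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, pval)


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per marker from hard genotype calls."""
    p = geno.n_markers
    out = np.ones(p)
    d = geno.dosage
    for j in range(p):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        n_aa = int((obs == 0).sum())   # hom a2
        n_het = int((obs == 1).sum())
        n_AA = int((obs == 2).sum())   # hom a1
        out[j] = hwe_exact(n_AA, n_het, n_aa)
    return out


def qc_markers(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_min: float = 1e-6,
    quality_min: float | None = None,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker QC filters in a fixed order and tally removals.

    Order of attribution: position/sex-chromosome -> quality -> call rate ->
    MAF -> HWE. All removal comparisons are strict (`< threshold` removes),
    matching the usual wording of chip QC protocols.
    """
    if not (0 <= call_rate_min <= 1 and 0 <= maf_min <= 0.5 and 0 <= hwe_min <= 1):
        raise ValueError("QC thresholds out of range")
    p = geno.n_markers
    report = QCReport(n_input=p)
    removed = np.zeros(p, dtype=bool)

    if autosomes_only:
        chrom = geno.markers["chrom"].astype(str).str.upper()
        pos = geno.markers["pos"]
        bad = chrom.isin(SEX_CHROMOSOMES) | pos.isna() | (pos <= 0)
        bad = bad.to_numpy()
        report.n_removed_no_position_or_sex_chr = int(bad.sum())
        removed |= bad

    if quality_min is not None:
        q = geno.markers["quality"].to_numpy(dtype=float)
        bad = (~np.isnan(q)) & (q < quality_min) & ~removed
        report.n_removed_quality = int(bad.sum())
        removed |= bad

    bad = (geno.call_rate() < call_rate_min) & ~removed
    report.n_removed_callrate = int(bad.sum())
    removed |= bad

    bad = (geno.maf() < maf_min) & ~removed
    report.n_removed_maf = int(bad.sum())
    removed |= bad

    if hwe_min > 0:
        hwe = hwe_pvalues(geno)
        bad = (hwe < hwe_min) & ~removed
        report.n_removed_hwe = int(bad.sum())
        removed |= bad

    keep = np.flatnonzero(~removed)
    if keep.size == 0:
        raise EmptyPanelError("QC removed every marker")
    return geno.take_markers(keep), report
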