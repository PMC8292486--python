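"""Genotype containers and PLINK/VCF input-output.

The in-memory representation is a :class:`GenotypeMatrix`: an ``n x p`` dosage
matrix counting copies of allele ``a1`` (the A1 column of a .bim file, or the
ALT allele of a VCF), an optional pair of haplotype strands for phased data,
and a marker map (chromosome, 1-based bp position, alleles, optional
per-marker quality score such as an imputation R^2).

PLINK binary files are SNP-major with magic bytes ``0x6c 0x1b 0x01`` and
two-bit genotype codes 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "quality"]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates its format contract."""


def _as_marker_frame(markers: pd.DataFrame) -> pd.DataFrame:
    df = markers.copy().reset_index(drop=True)
    if "quality" not in df.columns:
        df["quality"] = np.nan
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    return df[MARKER_COLUMNS]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (counts of allele a1) with optional phase.

    Attributes
    ----------
    dosage : ndarray, shape (n, p)
        Float matrix with values in {0, 1, 2} or NaN for missing.
    phase : ndarray or None, shape (2, n, p)
        Haplotype strands in {0, 1}; 1 means the strand carries allele a1.
        Wherever present, ``phase.sum(axis=0) == dosage``.
    markers : DataFrame
        Columns id, chrom, pos, a1, a2, quality.
    samples : list of str
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    samples: list[str]
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.markers = _as_marker_frame(self.markers)
        self.samples = list(self.samples)
        n, p = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError("sample list does not match dosage rows")
        if len(self.markers) != p:
            raise ValueError("marker map does not match dosage columns")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (2, n, p):
                raise ValueError("phase must have shape (2, n, p)")
            obs = ~np.isnan(self.dosage)
            if not np.array_equal(self.phase.sum(axis=0)[obs],
                                  self.dosage[obs].astype(np.int8)):
                raise ValueError("strand sum does not equal dosage")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_phased(self) -> bool:
        return self.phase is not None

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the markers at positional ``index`` (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            phase=None if self.phase is None else self.phase[:, :, index],
            markers=self.markers.iloc[index].reset_index(drop=True),
            samples=self.samples,
        )

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele a1 per marker, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit code -> dosage of A1; 1 (binary 01) is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam (SNP-major). Phase is not representable and is dropped."""
    prefix = Path(prefix)
    n, p = geno.dosage.shape
    dos = geno.dosage
    # map dosage -> code: 2->0b00, missing->0b01, 1->0b10, 0->0b11
    codes = np.full((p, n), 1, dtype=np.uint8)  # missing by default
    dt = dos.T
    codes[dt == 2] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (
        (padded.reshape(p, n_bytes, 4) << shifts[None, None, :]).sum(axis=2)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"],
            "id": geno.markers["id"],
            "cm": 0,
            "pos": geno.markers["pos"],
            "a1": geno.markers["a1"],
            "a2": geno.markers["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.samples,
            "iid": geno.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam trio into a GenotypeMatrix (unphased)."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major PLINK bed)"
        )
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != p * n_bytes:
        raise GenotypeFormatError(
            f"bed payload has {body.size} bytes, expected {p * n_bytes} "
            f"for {n} samples x {p} markers"
        )
    body = body.reshape(p, n_bytes)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = ((body[:, :, None] >> shifts[None, None, :]) & 0b11).reshape(p, -1)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T
    markers = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "a1": bim["a1"],
            "a2": bim["a2"],
            "quality": np.nan,
        }
    )
    return GenotypeMatrix(dosage=dosage, markers=markers, samples=list(fam["iid"]))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 with GT fields.

    REF is allele a2 and ALT is allele a1 so that the written genotype codes
    count a1, matching the dosage orientation. Phased data uses ``|``.
    """
    path = Path(path)
    n, p = geno.dosage.shape
    sep = "|" if geno.is_phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        mk = geno.markers
        for j in range(p):
            qual = mk["quality"].iloc[j]
            info = "." if pd.isna(qual) else f"RSQ={qual:g}"
            cells = []
            for i in range(n):
                if geno.is_phased:
                    a, b = geno.phase[0, i, j], geno.phase[1, i, j]
                    cells.append(f"{a}{sep}{b}")
                else:
                    d = geno.dosage[i, j]
                    if np.isnan(d):
                        cells.append("./.")
                    else:
                        d = int(d)
                        cells.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{mk['chrom'].iloc[j]}\t{mk['pos'].iloc[j]}\t{mk['id'].iloc[j]}\t"
                f"{mk['a2'].iloc[j]}\t{mk['a1'].iloc[j]}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path, require_phase: bool = False) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, keeping biallelic SNPs only.

    Dosage counts the ALT allele (stored as a1). Phase is populated only when
    every genotype is phased (``|``); with ``require_phase`` an unphased call
    raises :class:`GenotypeFormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dosages, rows, strands = [], [], []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        gts = var.genotypes  # list of [a, b, phased]
        s1 = np.empty(n, dtype=np.int8)
        s2 = np.empty(n, dtype=np.int8)
        dos = np.empty(n, dtype=float)
        for i, g in enumerate(gts):
            a, b, phased = g[0], g[1], bool(g[2])
            if a < 0 or b < 0:
                dos[i] = np.nan
                s1[i] = s2[i] = 0
                all_phased = False
            else:
                dos[i] = a + b
                s1[i], s2[i] = a, b
                if not phased:
                    all_phased = False
                    if require_phase:
                        raise GenotypeFormatError(
                            f"{path}: unphased genotype '/' at {var.CHROM}:{var.POS} "
                            "but phased input was requested"
                        )
        dosages.append(dos)
        strands.append((s1, s2))
        rsq = var.INFO.get("RSQ")
        rows.append(
            {
                "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "a1": alt,
                "a2": ref,
                "quality": np.nan if rsq is None else float(rsq),
            }
        )
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic SNP records")
    dosage = np.column_stack(dosages)
    markers = pd.DataFrame(rows)
    phase = None
    if all_phased:
        p = len(rows)
        phase = np.zeros((2, n, p), dtype=np.int8)
        for j, (s1, s2) in enumerate(strands):
            phase[0, :, j] = s1
            phase[1, :, j] = s2
    elif require_phase:
        raise GenotypeFormatError(f"{path}: phase requested but file is not fully phased")
    try:
        chrom_sort = markers["chrom"].astype(int)
    except (TypeError, ValueError):
        chrom_sort = markers["chrom"].astype(str)
    order = np.lexsort((markers["pos"].to_numpy(), chrom_sort.to_numpy()))
    geno = GenotypeMatrix(dosage=dosage, markers=markers, samples=samples, phase=phase)
    if not np.array_equal(order, np.arange(len(rows))):
        geno = geno.take_markers(order)
    return geno


def load_genotypes(path: str | Path, format: str | None = None,
                   require_phase: bool = False) -> GenotypeMatrix:
    """Load genotypes from a PLINK prefix or a VCF path.

    ``format`` is ``"plink-bed"`` or ``"vcf"``; when omitted it is inferred
    from the filename.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz"} else "plink-bed"
    if format == "plink-bed":
        if require_phase:
            raise GenotypeFormatError("PLINK bed files carry no phase information")
        return read_plink(path.with_suffix("") if path.suffix == ".bed" else path)
    if format == "vcf":
        return read_vcf(path, require_phase=require_phase)
    raise ValueError(f"unknown genotype format: {format!r}")
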