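"""Reporting: significant hits, 1-Mb QTL windows, DGE/SGE overlap, plot tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def _mb_display(bp: int) -> float:
    """bp -> Mb rounded half-up to 2 decimals (printed-table convention)."""
    mb = Decimal(int(bp)) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class QTLRegion:
    """A 1-Mb window centred on a significant marker."""

    chrom: object
    lower_bp: int
    upper_bp: int
    anchor_id: str
    anchor_bp: int

    @property
    def display(self) -> str:
        return f"{_mb_display(self.lower_bp):.2f}-{_mb_display(self.upper_bp):.2f}"


def qtl_region(chrom, pos: int, anchor_id: str = "") -> QTLRegion:
    """1-Mb window [pos - 500 kb, pos + 500 kb] around a significant marker.

    Positions within 500 kb of the chromosome start are clamped to a lower
    bound of 1 with the 1-Mb width preserved to the right.
    """
    pos = int(pos)
    lower = pos - 500_000
    if lower < 1:
        lower = 1
    upper = lower + 1_000_000
    return QTLRegion(chrom=chrom, lower_bp=lower, upper_bp=upper,
                     anchor_id=anchor_id, anchor_bp=pos)


def qtl_regions_table(hits: pd.DataFrame) -> pd.DataFrame:
    """QTL windows for every row of a significant-hit table."""
    rows = []
    for rec in hits.itertuples(index=False):
        reg = qtl_region(rec.chrom, rec.pos, getattr(rec, "id", ""))
        rows.append(
            {
                "id": reg.anchor_id,
                "chrom": reg.chrom,
                "pos": reg.anchor_bp,
                "lower_bp": reg.lower_bp,
                "upper_bp": reg.upper_bp,
                "range_mb": reg.display,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "lower_bp", "upper_bp", "range_mb"]
    )


def significant_hits(assoc: pd.DataFrame,
                     thresholds: tuple[float, float]) -> pd.DataFrame:
    """Rows below the suggestive threshold, tiered by strict inequality.

    ``thresholds`` is (genome_wide, suggestive) from Bonferroni; a p exactly
    equal to a threshold is not significant. Genome-wide rows are nested
    within the suggestive set. Output is sorted by p.
    """
    gw, sugg = thresholds
    out = assoc.loc[assoc["p"] < sugg].copy()
    out["tier"] = np.where(out["p"] < gw, "genome-wide", "suggestive")
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def overlap_hits(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    key: tuple[str, ...] = ("chrom", "pos"),
) -> dict[str, pd.DataFrame]:
    """Exact set partition of two hit tables by key columns.

    Returns {"common", "a_only", "b_only"}; duplicate keys within one table
    are de-duplicated with a warning. Keyed by coordinates rather than ids,
    since ids differ across marker panels.
    """
    key = list(key)

    def _dedup(df: pd.DataFrame, name: str) -> pd.DataFrame:
        dup = df.duplicated(subset=key)
        if dup.any():
            warnings.warn(f"{name}: {int(dup.sum())} duplicate keys dropped",
                          stacklevel=2)
            df = df.loc[~dup]
        return df

    a = _dedup(hits_a, "first table")
    b = _dedup(hits_b, "second table")
    ka = set(map(tuple, a[key].to_numpy()))
    kb = set(map(tuple, b[key].to_numpy()))
    mask_a = a[key].apply(tuple, axis=1) if len(a) else pd.Series(dtype=object)
    mask_b = b[key].apply(tuple, axis=1) if len(b) else pd.Series(dtype=object)
    common = a.loc[mask_a.isin(kb)] if len(a) else a
    a_only = a.loc[~mask_a.isin(kb)] if len(a) else a
    b_only = b.loc[~mask_b.isin(ka)] if len(b) else b
    return {
        "common": common.reset_index(drop=True),
        "a_only": a_only.reset_index(drop=True),
        "b_only": b_only.reset_index(drop=True),
    }


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: chrom, bp, -log10 p and a cumulative genome coordinate."""
    df = assoc.dropna(subset=["p"]).copy()
    try:
        df["_chrom_sort"] = df["chrom"].astype(int)
    except (TypeError, ValueError):
        df["_chrom_sort"] = df["chrom"].astype(str)
    df = df.sort_values(["_chrom_sort", "pos"], kind="stable")
    offset, offsets = 0, {}
    for chrom, grp in df.groupby("_chrom_sort", sort=True):
        offsets[chrom] = offset
        offset += int(grp["pos"].max()) + 1
    df["cum_pos"] = df["pos"] + df["_chrom_sort"].map(offsets)
    df["neglog10p"] = -np.log10(df["p"])
    return df[["chrom", "pos", "cum_pos", "neglog10p"]].reset_index(drop=True)


def genes_in_region(gff3: pd.DataFrame | str, chrom, lower_bp: int,
                    upper_bp: int, feature: str = "gene") -> pd.DataFrame:
    """Interval-overlap helper against a GFF3 table (annotation lookup only).

    Accepts a path to a GFF3 file or a pre-parsed DataFrame with columns
    seqid/source/type/start/end/score/strand/phase/attributes.
    """
    if isinstance(gff3, (str, bytes)):
        gff3 = pd.read_csv(
            gff3, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
        )
    sel = (
        (gff3["seqid"].astype(str) == str(chrom))
        & (gff3["type"] == feature)
        & (gff3["start"] <= upper_bp)
        & (gff3["end"] >= lower_bp)
    )
    return gff3.loc[sel].reset_index(drop=True)
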