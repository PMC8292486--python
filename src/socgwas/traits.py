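"""Derivation of the eight socially affected performance-test traits.

Raw inputs are the records a pig performance-testing station produces: start
and end weights of the test, total feed intake (TFI) and total feeder
occupation time accumulated over the feed days, ultrasound backfat at test
end (BFT), and the per-visit body-weight series from the electronic feeder.

Derived traits (units as conventionally reported):

* ADG  (kg/d)   - OLS slope of visit body weight on test day
* ADFI (kg/d)   - TFI / feed days
* TPD  (min/d)  - total feeder time / feed days
* FS   (g/min)  - ADFI x 1000 / TPD
* FCR  (kg/kg)  - TFI / (Weight2 - Weight1)
* D100 (d)      - age-to-100kg standardization of tested days
* B100 (mm)     - backfat standardized to 100 kg body weight
* AMW  (kg)     - average metabolic body weight over the test
* RFI           - feed intake residual to growth, backfat and AMW

D100 and B100 use sex-specific constants fitted on a large performance-test
dataset: A = 50.775 (males) / 46.415 (females), B = -7.277 (males) /
-9.440 (females). Both formulas are exact fixed points at Weight2 = 100 kg.

The RFI regression constants (14.1, 2.83, 110.9) come with no published unit
convention: evaluated with ADFI in kg/d, BFT in mm and AMW in kg the result
cannot have a mean of a few grams, while a g/d convention rescales the intake
terms. Both conventions are implemented behind ``convention`` and neither is
asserted as the original one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SexConstants:
    """Sex-specific constants of the D100 and B100 standardizations."""

    A_male: float = 50.775
    A_female: float = 46.415
    B_male: float = -7.277
    B_female: float = -9.440

    def A(self, sex: str) -> float:
        return self.A_male if _is_male(sex) else self.A_female

    def B(self, sex: str) -> float:
        return self.B_male if _is_male(sex) else self.B_female


DEFAULT_SEX_CONSTANTS = SexConstants()


def _is_male(sex: str) -> bool:
    s = str(sex).strip().lower()
    if s in {"m", "male", "boar", "1"}:
        return True
    if s in {"f", "female", "gilt", "sow", "2"}:
        return False
    raise ValueError(f"unrecognized sex code: {sex!r}")


class TraitDomainError(ValueError):
    """An input violates the domain of a trait formula."""


def ols_slope(days: np.ndarray, weights: np.ndarray) -> float:
    """Least-squares slope of weight on day (closed form)."""
    days = np.asarray(days, float)
    weights = np.asarray(weights, float)
    xm = days - days.mean()
    denom = (xm**2).sum()
    if denom == 0:
        raise TraitDomainError("need at least two distinct visit days")
    return float((xm * weights).sum() / denom)


def derive_feeder_traits(
    visits_days: np.ndarray,
    visits_bw: np.ndarray,
    tfi: float,
    total_time: float,
    feed_days: float,
) -> dict[str, float]:
    """ADG, ADFI, TPD and FS from raw feeder records.

    ADG is the regression slope over *all* visit body weights, not the
    endpoint difference. Returns NaN traits (with a warning) when fewer than
    two distinct visit days are available.
    """
    if feed_days <= 0:
        raise TraitDomainError("feed_days must be positive")
    days = np.asarray(visits_days, float)
    if np.unique(days).size < 2:
        warnings.warn("fewer than 2 distinct visit days: ADG undefined", stacklevel=2)
        adg = np.nan
    else:
        adg = ols_slope(days, visits_bw)
    adfi = tfi / feed_days
    tpd = total_time / feed_days
    fs = (adfi * 1000.0) / tpd if tpd > 0 else np.nan
    return {"ADG": adg, "ADFI": adfi, "TPD": tpd, "FS": fs}


def fcr(tfi: float, weight1: float, weight2: float) -> float:
    """Feed conversion ratio: TFI / (Weight2 - Weight1)."""
    if weight2 <= weight1:
        raise TraitDomainError("weight2 must exceed weight1")
    return tfi / (weight2 - weight1)


def d100(tested_days: float, weight2: float, sex: str,
         constants: SexConstants = DEFAULT_SEX_CONSTANTS) -> float:
    """Days to 100 kg: tested_days + (100 - W2) * (tested_days - A_sex) / W2."""
    if weight2 <= 0:
        raise TraitDomainError("weight2 must be positive")
    A = constants.A(sex)
    return tested_days + (100.0 - weight2) * (tested_days - A) / weight2


def b100(bft: float, weight2: float, sex: str,
         constants: SexConstants = DEFAULT_SEX_CONSTANTS) -> float:
    """Backfat at 100 kg: BFT + (100 - W2) * BFT / (W2 - B_sex)."""
    B = constants.B(sex)
    denom = weight2 - B
    if denom == 0:
        raise TraitDomainError("weight2 equals the sex constant B: division by zero")
    return bft + (100.0 - weight2) * bft / denom


def amw(weight1: float, weight2: float) -> float:
    """Average metabolic body weight, (W2^1.6 - W1^1.6) / (1.6 (W2 - W1)).

    At W2 == W1 the analytic limit W1^0.6 is returned (continuity of the
    mean-value form) rather than NaN.
    """
    if weight1 <= 0 or weight2 < weight1:
        raise TraitDomainError("need weight2 >= weight1 > 0")
    if weight2 == weight1:
        return weight1**0.6
    return (weight2**1.6 - weight1**1.6) / (1.6 * (weight2 - weight1))


def rfi(adfi: float, adg: float, bft: float, amw_: float,
        convention: str = "kg") -> float:
    """Residual feed intake: ADFI - 14.1 ADG - 2.83 BFT - 110.9 AMW.

    ``convention="kg"`` evaluates the formula literally on kg/d inputs;
    ``convention="g"`` converts ADFI and ADG to g/d first. The published
    coefficients carry no stated units, so neither convention is asserted as
    canonical (see the package methods note).
    """
    if convention == "g":
        adfi, adg = adfi * 1000.0, adg * 1000.0
    elif convention != "kg":
        raise ValueError(f"unknown RFI unit convention: {convention!r}")
    return adfi - 14.1 * adg - 2.83 * bft - 110.9 * amw_


TRAIT_COLUMNS = ["ADFI", "ADG", "B100", "D100", "FCR", "RFI", "TPD", "FS"]


def derive_trait_table(
    perf: pd.DataFrame,
    visits: pd.DataFrame,
    constants: SexConstants = DEFAULT_SEX_CONSTANTS,
    rfi_convention: str = "kg",
) -> pd.DataFrame:
    """Per-individual trait table from performance and visit records.

    ``perf`` needs columns id, sex, weight1, weight2, tested_days, feed_days,
    tfi, total_time, bft; ``visits`` needs id, day, bw. Traits whose
    prerequisites are missing are left NaN for that pig.
    """
    visits_by_id = dict(tuple(visits.groupby("id", sort=False)))
    rows = []
    for rec in perf.itertuples(index=False):
        out: dict[str, float] = {c: np.nan for c in TRAIT_COLUMNS}
        out["id"] = rec.id
        v = visits_by_id.get(rec.id)
        if v is not None and len(v) >= 2:
            ft = derive_feeder_traits(
                v["day"].to_numpy(), v["bw"].to_numpy(),
                rec.tfi, rec.total_time, rec.feed_days,
            )
            out.update(ft)
        ok_weights = (
            np.isfinite(rec.weight1) and np.isfinite(rec.weight2)
            and 0 < rec.weight1 < rec.weight2
        )
        if ok_weights:
            out["FCR"] = fcr(rec.tfi, rec.weight1, rec.weight2)
            out["D100"] = d100(rec.tested_days, rec.weight2, rec.sex, constants)
            a = amw(rec.weight1, rec.weight2)
            if np.isfinite(rec.bft):
                out["B100"] = b100(rec.bft, rec.weight2, rec.sex, constants)
                if np.isfinite(out["ADG"]):
                    out["RFI"] = rfi(out["ADFI"], out["ADG"], rec.bft, a,
                                     convention=rfi_convention)
        rows.append(out)
    return pd.DataFrame(rows)[["id"] + TRAIT_COLUMNS]
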