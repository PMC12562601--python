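"""Rule-based classification of per-residue NMR observables.

Three pure-function flags, with strict inequalities throughout (boundary
values fall on the non-flagged side):

* fast mobility (ps–ns): order parameter S² < 0.8;
* slow exchange (μs–ms): Rex > 3 s⁻¹, or R1·R2 > 16 s⁻², or HN signal
  broadening (HNCO cross-peak intensity below one fifth of the stable-
  region average, i.e. ratio < 0.2, with an invisible peak encoded as
  ratio 0);
* hydrogen-bond donor: amide temperature gradient Δδ¹Hᴺ/ΔT > −4.5 ppb/K
  AND H/D half-exchange time > 20 min.

A flag is ``None`` (indeterminate) when the observables it needs are
absent.  The broadening intensity ratio is referenced to the mean over
the "stable" residue set (Rex < 3 s⁻¹ and S² > 0.8);
:func:`hnco_intensity_ratio` computes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

S2_FAST_MAX = 0.8
REX_SLOW_MIN = 3.0          # s^-1, at 800 MHz
R1R2_SLOW_MIN = 16.0        # s^-2
BROADENING_RATIO_MAX = 0.2  # "five times less than the average"
TEMP_GRADIENT_MIN = -4.5    # ppb/K
HD_HALF_EXCHANGE_MIN = 20.0  # minutes


@dataclass(frozen=True)
class RelaxationRecord:
    residue: int
    s2: float | None = None
    rex: float | None = None                    # s^-1
    r1: float | None = None                     # s^-1
    r2: float | None = None                     # s^-1
    het_noe: float | None = None
    hnco_intensity_ratio: float | None = None   # intensity / stable-set mean

    def __post_init__(self):
        if self.s2 is not None and not (0.0 <= self.s2 <= 1.0):
            raise ValueError("S2 must lie in [0, 1]")
        for name in ("rex", "r1", "r2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExchangeRecord:
    residue: int
    temp_gradient: float | None = None          # ppb/K
    hd_half_exchange_min: float | None = None   # minutes

    def __post_init__(self):
        if self.hd_half_exchange_min is not None and self.hd_half_exchange_min < 0:
            raise ValueError("half-exchange time must be >= 0")


def flag_fast_mobility(rec: RelaxationRecord) -> bool | None:
    """S² < 0.8 (strict); None when S² is missing."""
    if rec.s2 is None:
        return None
    return rec.s2 < S2_FAST_MAX


def flag_slow_exchange(rec: RelaxationRecord) -> bool | None:
    """Rex > 3 OR R1·R2 > 16 OR broadening (ratio < 0.2); None if nothing
    is measured."""
    checks = []
    if rec.rex is not None:
        checks.append(rec.rex > REX_SLOW_MIN)
    if rec.r1 is not None and rec.r2 is not None:
        checks.append(rec.r1 * rec.r2 > R1R2_SLOW_MIN)
    if rec.hnco_intensity_ratio is not None:
        checks.append(rec.hnco_intensity_ratio < BROADENING_RATIO_MAX)
    if not checks:
        return None
    return any(checks)


def flag_hbond_donor(rec: ExchangeRecord) -> bool | None:
    """Δδ¹Hᴺ/ΔT > −4.5 ppb/K AND t½(H/D) > 20 min (both strict)."""
    if rec.temp_gradient is None or rec.hd_half_exchange_min is None:
        return None
    return (rec.temp_gradient > TEMP_GRADIENT_MIN
            and rec.hd_half_exchange_min > HD_HALF_EXCHANGE_MIN)


# ---------------------------------------------------------------------------
# Table-level API
# ---------------------------------------------------------------------------

def hnco_intensity_ratio(df: pd.DataFrame, intensity_col: str = "hnco_intensity",
                         s2_col: str = "s2", rex_col: str = "rex") -> pd.Series:
    """Intensity / mean-over-stable-set, the broadening rule's input.

    The stable reference set is residues with Rex < 3 s⁻¹ and S² > 0.8.
    Absent peaks should be encoded as intensity 0.
    """
    stable = (df[rex_col] < REX_SLOW_MIN) & (df[s2_col] > S2_FAST_MAX)
    if not stable.any():
        raise ValueError("no stable residues to reference broadening against")
    ref = df.loc[stable, intensity_col].mean()
    return df[intensity_col] / ref


def _get(row, col):
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def flag_table(relax: pd.DataFrame,
               exchange: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply all flags to per-residue observable tables.

    ``relax`` columns: residue, and any of s2, rex, r1, r2, het_noe,
    hnco_ratio.  ``exchange`` columns: residue, dHN_dT, t_half_min.
    Returns one row per residue with boolean (or NA) flag columns.
    """
    rows = []
    for _, r in relax.iterrows():
        rec = RelaxationRecord(
            residue=int(r["residue"]),
            s2=_get(r, "s2"), rex=_get(r, "rex"),
            r1=_get(r, "r1"), r2=_get(r, "r2"),
            het_noe=_get(r, "het_noe"),
            hnco_intensity_ratio=_get(r, "hnco_ratio"),
        )
        rows.append({
            "residue": rec.residue,
            "fast_mobility": flag_fast_mobility(rec),
            "slow_exchange": flag_slow_exchange(rec),
        })
    out = pd.DataFrame(rows)
    if exchange is not None:
        ex_rows = []
        for _, r in exchange.iterrows():
            rec = ExchangeRecord(int(r["residue"]), _get(r, "dHN_dT"),
                                 _get(r, "t_half_min"))
            ex_rows.append({"residue": rec.residue,
                            "hbond_donor": flag_hbond_donor(rec)})
        out = out.merge(pd.DataFrame(ex_rows), on="residue", how="outer")
    return out.sort_values("residue").reset_index(drop=True)
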