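"""Water use efficiency (WUE) and partial factor productivity (PFP).

WUE = Y / IA (kg m^-3): fruit yield per cubic metre of irrigation water.
PFP = Y / F  (kg kg^-1): fruit yield per kilogram of fertilizer applied,
with F the season total across the three stage applications.

Replicate-level records are computed first and then averaged per
treatment; both levels are exposed so two-year means can be reported the
way designed-trial results usually are.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .design import Treatment

__all__ = ["wue", "pfp", "efficiency_records", "treatment_means"]


def wue(yield_kg_ha: float | np.ndarray, irrigation_m3_ha: float | np.ndarray) -> float | np.ndarray:
    """Water use efficiency Y/IA in kg m^-3. IA must be positive."""
    y = np.asarray(yield_kg_ha, dtype=float)
    ia = np.asarray(irrigation_m3_ha, dtype=float)
    if np.any(ia <= 0):
        raise ValueError("irrigation amount must be > 0")
    if np.any(y < 0):
        raise ValueError("yield must be >= 0")
    out = y / ia
    return float(out) if out.ndim == 0 else out


def pfp(yield_kg_ha: float | np.ndarray, fertilizer_kg_ha: float | np.ndarray) -> float | np.ndarray:
    """Partial factor productivity Y/F in kg kg^-1. F must be positive."""
    y = np.asarray(yield_kg_ha, dtype=float)
    f = np.asarray(fertilizer_kg_ha, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fertilizer amount must be > 0")
    if np.any(y < 0):
        raise ValueError("yield must be >= 0")
    out = y / f
    return float(out) if out.ndim == 0 else out


def efficiency_records(
    yields: pd.DataFrame,
    treatments: Sequence[Treatment],
) -> pd.DataFrame:
    """Per-replicate efficiency records from tidy yield rows.

    ``yields`` needs columns (treatment, year, replicate, value) with value
    the plot yield in kg ha^-1. Output adds the year's irrigation volume
    IA, the season fertilizer total F, and the derived WUE and PFP.
    """
    required = {"treatment", "year", "replicate", "value"}
    missing = required - set(yields.columns)
    if missing:
        raise ValueError(f"yield table missing columns {sorted(missing)}")
    by_id = {t.id: t for t in treatments}
    unknown = set(yields["treatment"]) - set(by_id)
    if unknown:
        raise ValueError(f"unknown treatment ids {sorted(unknown)}")
    out = yields.rename(columns={"value": "Y"}).copy()
    out["IA"] = [
        by_id[t].irrigation_volume[int(y)] for t, y in zip(out["treatment"], out["year"])
    ]
    out["F"] = [by_id[t].total_fertilizer for t in out["treatment"]]
    out["WUE"] = wue(out["Y"].to_numpy(), out["IA"].to_numpy())
    out["PFP"] = pfp(out["Y"].to_numpy(), out["F"].to_numpy())
    return out


def treatment_means(records: pd.DataFrame) -> pd.DataFrame:
    """Average replicate records within year, then across years, per treatment."""
    yearly = records.groupby(["treatment", "year"], sort=False)[["Y", "IA", "F", "WUE", "PFP"]].mean()
    return yearly.groupby("treatment", sort=False).mean()
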