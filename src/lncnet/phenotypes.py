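"""Phenotype-derived efficiency traits and group assignment.

Energy-corrected milk for the week before slaughter (ECM_w) summarises cow
performance; residual feed intake (RFI, the residual of energy intake
regressed on average daily gain and metabolic mid-weight) summarises bull
efficiency. Animals are assigned to a high or low metabolic-efficiency group
by the selection rules of the emulated design: bulls by +-1 SD of RFI (with
a daily-gain guard), cows by ECM_w bands combined with carcass fat content
relative to the cow population, subject to calving-interval, age and
pathology exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

ECM_HIGH_MIN_KG = 140.0
ECM_LOW_RANGE_KG = (14.0, 40.0)
MAX_CALVING_INTERVAL_D = 540
MAX_AGE_D = 1510


@dataclass
class PopulationStats:
    """Reference-population moments used by the selection rules."""

    rfi_mean: float
    rfi_sd: float
    adg_mean: float
    adg_sd: float
    cfc_cow_mean: float
    cfc_cow_sd: float


def compute_ecm(fat_pct, protein_pct, milk_yield_7d):
    """ECM_w = ((0.37 F% + 0.21 P% + 0.95) / 3.1) * MY_7d, element-wise."""
    fat_pct = np.asarray(fat_pct, dtype=float)
    protein_pct = np.asarray(protein_pct, dtype=float)
    milk_yield_7d = np.asarray(milk_yield_7d, dtype=float)
    if (fat_pct < 0).any() or (protein_pct < 0).any() or (milk_yield_7d < 0).any():
        raise ValueError("ECM inputs must be non-negative")
    ecm = (0.37 * fat_pct + 0.21 * protein_pct + 0.95) / 3.1 * milk_yield_7d
    return float(ecm) if ecm.ndim == 0 else ecm


def metabolic_midweight(weight_m17, weight_m18):
    """MMW = (mean body weight of months 17-18) ** 0.75."""
    mw = (np.asarray(weight_m17, dtype=float) + np.asarray(weight_m18, dtype=float)) / 2.0
    if (mw <= 0).any():
        raise ValueError("body weights must be positive")
    return mw**0.75


def compute_rfi(intake, adg, mmw) -> np.ndarray:
    """OLS residuals of intake on intercept + ADG + MMW.

    Negative residuals label efficient animals (less intake than predicted
    from gain and metabolic weight). Raises on singular designs.
    """
    intake = np.asarray(intake, dtype=float)
    adg = np.asarray(adg, dtype=float)
    mmw = np.asarray(mmw, dtype=float)
    if not (len(intake) == len(adg) == len(mmw)):
        raise ValueError("intake, adg and mmw must have equal length")
    if len(intake) < 3:
        raise ValueError("RFI regression needs at least 3 animals")
    X = sm.add_constant(np.column_stack([adg, mmw]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: ADG/MMW collinear or constant")
    fit = sm.OLS(intake, X).fit()
    return np.asarray(fit.resid)


def assign_groups(records: pd.DataFrame, population: PopulationStats | None = None) -> pd.DataFrame:
    """Assign each animal to high / low / excluded with a reason.

    ``records`` needs columns: animal_id, sex (male/female), rfi, adg (bulls),
    ecm_w, cfc, calving_interval, age_at_slaughter, pathology_flag (cows).
    Population moments default to the moments of the supplied records.
    Boundary ties satisfy the criteria (at least one SD: <= / >=).
    """
    req = {"animal_id", "sex"}
    if not req <= set(records.columns):
        raise ValueError(f"missing required columns {sorted(req - set(records.columns))}")
    if population is None:
        bulls = records[records["sex"] == "male"]
        cows = records[records["sex"] == "female"]
        population = PopulationStats(
            rfi_mean=float(bulls["rfi"].mean()),
            rfi_sd=float(bulls["rfi"].std(ddof=1)),
            adg_mean=float(bulls["adg"].mean()),
            adg_sd=float(bulls["adg"].std(ddof=1)),
            cfc_cow_mean=float(cows["cfc"].mean()),
            cfc_cow_sd=float(cows["cfc"].std(ddof=1)),
        )

    out = []
    for rec in records.itertuples(index=False):
        group, reason = _assign_one(rec, population)
        out.append({"animal_id": rec.animal_id, "group": group, "reason": reason})
    result = pd.DataFrame(out)
    assert not ((result["group"] == "high") & (result["group"] == "low")).any()
    return result


def _assign_one(rec, pop: PopulationStats) -> tuple[str, str]:
    if rec.sex == "male":
        if not np.isfinite(rec.rfi) or not np.isfinite(rec.adg):
            raise ValueError(f"{rec.animal_id}: missing RFI/ADG for bull")
        if rec.adg <= 0:
            return "excluded", "non-positive daily gain"
        if rec.adg < pop.adg_mean - pop.adg_sd:
            return "excluded", "daily gain below population mean - 1 SD"
        if rec.rfi <= pop.rfi_mean - pop.rfi_sd:
            return "high", "RFI at least 1 SD below average"
        if rec.rfi >= pop.rfi_mean + pop.rfi_sd:
            return "low", "RFI at least 1 SD above average"
        return "excluded", "RFI within 1 SD of average"

    if rec.sex == "female":
        for name in ("ecm_w", "cfc", "calving_interval", "age_at_slaughter"):
            if not np.isfinite(getattr(rec, name)):
                raise ValueError(f"{rec.animal_id}: missing {name} for cow")
        if getattr(rec, "pathology_flag", False):
            return "excluded", "pathological findings with metabolic implications"
        if rec.calving_interval >= MAX_CALVING_INTERVAL_D:
            return "excluded", "calving interval not below 540 days"
        if rec.age_at_slaughter > MAX_AGE_D:
            return "excluded", "age above 1,510 days"
        if rec.ecm_w > ECM_HIGH_MIN_KG and rec.cfc < pop.cfc_cow_mean + pop.cfc_cow_sd:
            return "high", "ECM_w above 140 kg and CFC below cow mean + 1 SD"
        lo, hi = ECM_LOW_RANGE_KG
        if lo <= rec.ecm_w <= hi and rec.cfc > pop.cfc_cow_mean - pop.cfc_cow_sd:
            return "low", "ECM_w within 14-40 kg and CFC above cow mean - 1 SD"
        return "excluded", "efficiency criteria not met"

    raise ValueError(f"{rec.animal_id}: unknown sex {rec.sex!r}")
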