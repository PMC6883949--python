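"""Regulatory impact factors (RIF1 / RIF2) for candidate regulators.

For a regulator i and target j, with within-condition target means e1_j,
e2_j (condition 1 = high, 2 = low), the phenotypic impact factor
PIF_j = 1/2 (e1_j + e2_j)(e1_j - e2_j), within-condition regulator-target
Pearson correlations r1_ij, r2_ij, and differential wiring
DW_ij = r1_ij - r2_ij:

    RIF1_i = (1 / n) sum_j PIF_j * DW_ij^2
    RIF2_i = (1 / n) sum_j [(e1_j r1_ij)^2 - (e2_j r2_ij)^2]

RIF1 rewards regulators whose wiring to abundant, differentially expressed
targets changes most; RIF2 rewards the most altered ability to predict
target abundance between conditions. Scores are z-standardized per metric
within a tissue analysis; |z| >= 1.96 calls a regulator significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_THRESHOLD = 1.96


@dataclass
class ConditionStats:
    regulators: list[str]
    targets: list[str]
    e1: pd.Series  # mean log2 expression of targets, condition 1 (high)
    e2: pd.Series
    pif: pd.Series
    r1: pd.DataFrame  # regulators x targets
    r2: pd.DataFrame

    @property
    def dw(self) -> pd.DataFrame:
        return self.r1 - self.r2


def _corr_block(reg: np.ndarray, tar: np.ndarray) -> np.ndarray:
    """Pearson correlations between regulator rows and target rows.

    Constant vectors yield r = 0 (with a warning) rather than NaN.
    """
    reg_c = reg - reg.mean(axis=1, keepdims=True)
    tar_c = tar - tar.mean(axis=1, keepdims=True)
    reg_sd = np.sqrt((reg_c**2).sum(axis=1))
    tar_sd = np.sqrt((tar_c**2).sum(axis=1))
    if (reg_sd == 0).any() or (tar_sd == 0).any():
        warnings.warn("constant expression vector: correlation set to 0", stacklevel=3)
    denom = np.outer(reg_sd, tar_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (reg_c @ tar_c.T) / denom
    r = np.where(denom == 0, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def condition_stats(
    values: pd.DataFrame,
    groups: pd.Series,
    regulators: list[str],
    targets: list[str],
) -> ConditionStats:
    """Within-condition means and regulator-target correlations.

    ``values`` is log2 expression (genes x samples); ``groups`` maps sample
    to high/low. Each condition needs at least 3 samples. Self-pairs
    (regulator also in targets) are handled downstream.
    """
    groups = groups.reindex(values.columns)
    cols1 = values.columns[groups == "high"]
    cols2 = values.columns[groups == "low"]
    if len(cols1) < 3 or len(cols2) < 3:
        raise ValueError("each condition needs at least 3 samples")
    missing = (set(regulators) | set(targets)) - set(values.index)
    if missing:
        raise KeyError(f"genes absent from the matrix: {sorted(missing)[:5]} ...")

    tar1 = values.loc[targets, cols1].to_numpy(float)
    tar2 = values.loc[targets, cols2].to_numpy(float)
    reg1 = values.loc[regulators, cols1].to_numpy(float)
    reg2 = values.loc[regulators, cols2].to_numpy(float)

    e1 = pd.Series(tar1.mean(axis=1), index=targets)
    e2 = pd.Series(tar2.mean(axis=1), index=targets)
    pif = 0.5 * (e1 + e2) * (e1 - e2)
    r1 = pd.DataFrame(_corr_block(reg1, tar1), index=regulators, columns=targets)
    r2 = pd.DataFrame(_corr_block(reg2, tar2), index=regulators, columns=targets)
    return ConditionStats(list(regulators), list(targets), e1, e2, pif, r1, r2)


def compute_rif_scores(cs: ConditionStats) -> pd.DataFrame:
    """Raw RIF1/RIF2 per regulator (self-pairs excluded from the average)."""
    if len(cs.targets) == 0:
        raise ValueError("empty target set")
    dw2 = (cs.r1.to_numpy() - cs.r2.to_numpy()) ** 2
    term1 = cs.pif.to_numpy()[None, :] * dw2
    term2 = (cs.e1.to_numpy()[None, :] * cs.r1.to_numpy()) ** 2 \
        - (cs.e2.to_numpy()[None, :] * cs.r2.to_numpy()) ** 2

    tindex = {t: j for j, t in enumerate(cs.targets)}
    self_mask = np.zeros(term1.shape, dtype=bool)
    for i, reg in enumerate(cs.regulators):
        if reg in tindex:
            self_mask[i, tindex[reg]] = True
    n_eff = term1.shape[1] - self_mask.sum(axis=1)
    if (n_eff == 0).any():
        raise ValueError("a regulator has no non-self targets")
    term1 = np.where(self_mask, 0.0, term1)
    term2 = np.where(self_mask, 0.0, term2)
    return pd.DataFrame(
        {
            "regulator_id": cs.regulators,
            "rif1_raw": term1.sum(axis=1) / n_eff,
            "rif2_raw": term2.sum(axis=1) / n_eff,
        }
    )


def select_significant_regulators(
    scores: pd.DataFrame, z_threshold: float = Z_THRESHOLD
) -> pd.DataFrame:
    """Z-standardize each metric and call |z| >= threshold significant.

    Degenerate inputs (SD = 0) standardize to all-zero z-scores.
    """
    if len(scores) < 2:
        raise ValueError("standardization needs at least 2 regulators")
    out = scores.copy()
    for metric in ("rif1", "rif2"):
        raw = out[f"{metric}_raw"].to_numpy(float)
        sd = raw.std(ddof=1)
        out[f"{metric}_z"] = 0.0 if sd == 0 else (raw - raw.mean()) / sd
    out["significant"] = (out["rif1_z"].abs() >= z_threshold) | \
        (out["rif2_z"].abs() >= z_threshold)
    return out
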