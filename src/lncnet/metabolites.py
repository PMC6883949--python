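"""Plasma metabolite preprocessing and hub-lncRNA correlation.

Preprocessing follows the emulated protocol: metabolites with more than
``max_missing`` animals missing are dropped, remaining missing values are
imputed with the metabolite's observed minimum (missingness treated as
below-detection), and each metabolite is scaled without centering (divided
by its root mean square with n-1 in the denominator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, PSEUDOCOUNT, tissue_means

P_THRESHOLD = 0.05


def preprocess_metabolites(raw: pd.DataFrame, max_missing: int = 5) -> pd.DataFrame:
    """Drop > max_missing missing, impute minimum, scale without centering."""
    n_missing = raw.isna().sum(axis=1)
    kept = raw.loc[n_missing <= max_missing].copy()
    if (kept.isna().all(axis=1)).any():
        raise ValueError("metabolite with zero observed values")
    mins = kept.min(axis=1, skipna=True)
    kept = kept.apply(lambda row: row.fillna(mins[row.name]), axis=1)
    n = kept.shape[1]
    rms = np.sqrt((kept**2).sum(axis=1) / (n - 1))
    return kept.div(rms, axis=0)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        return 0.0, 1.0
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_with_lncrna(
    em: ExpressionMatrix,
    metabolites: pd.DataFrame,
    hub_lncrnas: list[str],
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Correlate each hub lncRNA with every metabolite across animals.

    Expression is taken in the tissue where the lncRNA is most abundant
    (argmax of mean FPKM over tissues); values are log2(FPKM + 0.001) per
    animal. Only animals present in both datasets are used; selection is
    p <= threshold.
    """
    if em.scale != "fpkm":
        raise ValueError("expected an FPKM-scale expression matrix")
    means = tissue_means(em)
    rows = []
    for lnc in hub_lncrnas:
        if lnc not in em.values.index:
            raise KeyError(f"{lnc} not in the expression matrix")
        best_tissue = means.loc[lnc].idxmax()
        cols = em.tissue_samples(best_tissue)
        expr = np.log2(em.values.loc[lnc, cols] + PSEUDOCOUNT)
        expr.index = em.sample_meta.loc[cols, "animal"]
        common = [a for a in metabolites.columns if a in set(expr.index)]
        if len(common) < 4:
            raise ValueError(f"{lnc}: fewer than 4 animals shared with metabolite data")
        x = expr.loc[common].to_numpy(float)
        for met in metabolites.index:
            r, p = pearson_with_p(x, metabolites.loc[met, common].to_numpy(float))
            rows.append(
                {"lncrna_id": lnc, "metabolite_id": met, "tissue": best_tissue,
                 "r": r, "p": p, "selected": p <= p_threshold}
            )
    return pd.DataFrame(rows, columns=["lncrna_id", "metabolite_id", "tissue",
                                       "r", "p", "selected"])
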