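"""Prioritized gene set: DE, tissue-specific, QTL-overlapping and lncRNA loci.

The built-in differential-expression test is a deliberately simple stand-in
for a count-model tool: Welch's t on covariate-residualized log2 expression
with Benjamini-Hochberg adjustment. External DE tables (gene, tissue,
log2fc, p, q) can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, EXCLUDED_BIOTYPES, filter_above_tissue_average


def residualize(values: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove covariate effects gene-wise by OLS projection (intercept added)."""
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    Xm = X.to_numpy(float)
    Y = values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ beta
    return pd.DataFrame(resid.T, index=values.index, columns=values.columns)


def de_standin_test(
    values: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    tissue: str = "",
) -> pd.DataFrame:
    """Two-group Welch test per gene on (residualized) log2 expression.

    Returns a frame with gene_id, tissue, log2fc (high - low), p, q
    (Benjamini-Hochberg). Constant genes get p = 1.
    """
    groups = groups.reindex(values.columns)
    labels = set(groups.unique())
    if not labels <= {"high", "low"}:
        raise ValueError(f"unexpected group labels {labels}")
    n_high = int((groups == "high").sum())
    n_low = int((groups == "low").sum())
    if n_high < 2 or n_low < 2:
        raise ValueError("each group needs at least 2 samples")

    work = values
    if covariates is not None:
        work = residualize(values, covariates.reindex(values.columns))

    a = work.loc[:, groups == "high"].to_numpy(float)
    b = work.loc[:, groups == "low"].to_numpy(float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    log2fc = values.loc[:, groups == "high"].mean(axis=1) - \
        values.loc[:, groups == "low"].mean(axis=1)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"gene_id": values.index, "tissue": tissue, "log2fc": log2fc.to_numpy(),
         "p": p, "q": q}
    ).reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def select_de(results: pd.DataFrame, q_threshold: float = 0.05) -> tuple[dict[str, set[str]], set[str]]:
    """Significant genes (q strictly below threshold) per tissue, plus the union."""
    per_tissue: dict[str, set[str]] = {}
    for tissue, sub in results.groupby("tissue"):
        per_tissue[tissue] = set(sub.loc[sub["q"] < q_threshold, "gene_id"])
    union = set().union(*per_tissue.values()) if per_tissue else set()
    return per_tissue, union


def select_tissue_specific(em: ExpressionMatrix) -> dict[str, set[str]]:
    """Tissue-enriched genes from log2 tissue means.

    A gene is specific to tissue t when its mean abundance in every other
    tissue is below half the across-tissue average of its tissue means and
    its abundance in t exceeds that average plus one SD (SD across the
    tissue means).
    """
    if em.scale != "log2fpkm":
        raise ValueError("TS selection operates on log2 FPKM")
    groups = em.sample_meta["tissue"]
    tissues = list(dict.fromkeys(groups))
    if len(tissues) < 2:
        raise ValueError("TS selection needs at least two tissues")
    means = em.values.T.groupby(groups, observed=True).mean().T[tissues]
    M = means.mean(axis=1)
    SD = means.std(axis=1, ddof=1)
    out: dict[str, set[str]] = {}
    for t in tissues:
        others = means.drop(columns=t)
        crit = (others.lt(M / 2, axis=0)).all(axis=1) & (means[t] > M + SD)
        out[t] = set(means.index[crit])
    return out


@dataclass
class PrioritizedGeneSet:
    """Gene -> category flags table driving RIF and PCIT input selection."""

    flags: pd.DataFrame  # index gene_id; boolean columns de_<t>, ts_<t>, qtl_<trait>, is_lncrna

    @property
    def gene_ids(self) -> pd.Index:
        return self.flags.index

    def lncrnas(self) -> list[str]:
        return sorted(self.flags.index[self.flags["is_lncrna"]])


def assemble_prioritized_set(
    de_per_tissue: dict[str, set[str]],
    ts_per_tissue: dict[str, set[str]],
    qtl_flags: pd.DataFrame,
    lncrna_ids: set[str] | list[str],
    biotypes: pd.Series,
    expression_keep: pd.Index | set[str],
) -> PrioritizedGeneSet:
    """Union of the four categories, minus excluded biotypes, intersected
    with the PCIT-stage expression filter."""
    lncrna_ids = set(lncrna_ids)
    qtl_genes = {trait: set(qtl_flags.index[qtl_flags[trait]]) for trait in qtl_flags.columns}
    members = set().union(
        *de_per_tissue.values(), *ts_per_tissue.values(), *qtl_genes.values(), lncrna_ids
    )
    excluded = {g for g in members if biotypes.get(g) in EXCLUDED_BIOTYPES}
    members = (members - excluded) & set(expression_keep)

    index = pd.Index(sorted(members), name="gene_id")
    flags = pd.DataFrame(index=index)
    for t, genes in sorted(de_per_tissue.items()):
        flags[f"de_{t}"] = index.isin(list(genes))
    for t, genes in sorted(ts_per_tissue.items()):
        flags[f"ts_{t}"] = index.isin(list(genes))
    for trait, genes in sorted(qtl_genes.items()):
        flags[f"qtl_{trait}"] = index.isin(list(genes))
    flags["is_lncrna"] = index.isin(list(lncrna_ids))
    assert flags.any(axis=1).all(), "every prioritized gene must carry a flag"
    return PrioritizedGeneSet(flags=flags)
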