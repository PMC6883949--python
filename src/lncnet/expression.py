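"""FPKM normalisation, log2 transform, and the pipeline's expression filters.

Three filter stages are used downstream:

* a global minimal-abundance filter (mean FPKM > 0.2 in at least one
  tissue, excluded biotypes removed),
* a per-tissue count filter ahead of differential expression (>= 10
  fragments in >= 10 individuals),
* an above-tissue-average abundance filter (log2 scale) ahead of RIF, with
  an any-tissue OR variant ahead of PCIT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.001
#: Biotypes excluded from the prioritized analyses (structural RNAs).
EXCLUDED_BIOTYPES = frozenset({"rRNA", "snoRNA", "snRNA", "Y_RNA", "SRP_RNA"})


@dataclass
class CountMatrix:
    """Fragment counts (genes x samples) with sample metadata and gene lengths.

    ``sample_meta`` is indexed by sample id (one row per (animal, tissue)
    pair) with columns animal/tissue/sex/group/year; ``gene_lengths`` holds
    exonic lengths in bp.
    """

    fragments: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.fragments.values < 0).any():
            raise ValueError("negative fragment counts")
        if not self.fragments.columns.equals(self.sample_meta.index):
            raise ValueError("sample metadata does not align with matrix columns")
        self.gene_lengths = self.gene_lengths.reindex(self.fragments.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive and cover every gene")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    scale: str  # "fpkm" | "log2fpkm"
    sample_meta: pd.DataFrame

    def tissue_samples(self, tissue: str) -> pd.Index:
        meta = self.sample_meta
        if tissue not in set(meta["tissue"]):
            raise ValueError(f"unknown tissue {tissue!r}")
        return meta.index[meta["tissue"] == tissue]


def compute_fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """fragments * 1e9 / (library size * exonic length in bp)."""
    totals = cm.fragments.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero library size in samples {bad}")
    fpkm = cm.fragments * 1e9
    fpkm = fpkm.div(totals, axis=1).div(cm.gene_lengths, axis=0)
    return ExpressionMatrix(values=fpkm, scale="fpkm", sample_meta=cm.sample_meta)


def log2_with_pseudocount(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 0.001)."""
    if em.scale != "fpkm":
        raise ValueError(f"expected fpkm input, got scale={em.scale!r}")
    return ExpressionMatrix(
        values=np.log2(em.values + PSEUDOCOUNT),
        scale="log2fpkm",
        sample_meta=em.sample_meta,
    )


def tissue_means(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean of the matrix values within each tissue (genes x tissues)."""
    groups = em.sample_meta["tissue"]
    return em.values.T.groupby(groups, observed=True).mean().T


def filter_min_mean_fpkm(
    em: ExpressionMatrix,
    threshold: float = 0.2,
    excluded_biotypes: frozenset[str] | set[str] = EXCLUDED_BIOTYPES,
    biotypes: pd.Series | None = None,
) -> pd.Index:
    """Genes whose mean FPKM exceeds ``threshold`` (strict) in >= 1 tissue.

    Genes whose biotype is in ``excluded_biotypes`` are removed regardless of
    abundance (``biotypes`` maps gene id -> biotype; omit to skip that rule).
    """
    if em.scale != "fpkm":
        raise ValueError("filter operates on the FPKM scale")
    means = tissue_means(em)
    keep = (means > threshold).any(axis=1)
    if biotypes is not None:
        bt = biotypes.reindex(means.index)
        keep &= ~bt.isin(list(excluded_biotypes))
    return means.index[keep]


def filter_counts_for_de(
    counts: pd.DataFrame,
    min_fragments: int = 10,
    min_samples: int = 10,
) -> pd.Index:
    """Within-tissue count filter: >= ``min_fragments`` in >= ``min_samples``."""
    ok = (counts >= min_fragments).sum(axis=1) >= min_samples
    return counts.index[ok]


def filter_above_tissue_average(
    em: ExpressionMatrix,
    tissue: str | None = None,
    any_tissue: bool = False,
) -> pd.Index:
    """Genes with mean log2 abundance above the tissue's gene-average.

    The reference is the grand mean over genes of the per-gene tissue means
    (strict >). With ``any_tissue=True`` the criterion is satisfied if it
    holds in at least one tissue (the PCIT-stage variant); otherwise
    ``tissue`` selects the single tissue of interest (the RIF-stage variant).
    """
    if em.scale != "log2fpkm":
        raise ValueError("filter operates on the log2 FPKM scale")
    means = tissue_means(em)
    if any_tissue:
        above = means > means.mean(axis=0)
        return means.index[above.any(axis=1)]
    if tissue is None:
        raise ValueError("tissue required unless any_tissue=True")
    if tissue not in means.columns:
        raise ValueError(f"unknown tissue {tissue!r}")
    col = means[tissue]
    return means.index[col > col.mean()]
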