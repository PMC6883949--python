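"""End-to-end pipeline over a synthetic cohort, with deterministic reports.

``run_all`` chains every stage: simulate, assign efficiency groups,
normalise and filter expression, call DE / TS / QTL / lncRNA categories,
assemble the prioritized set, score regulators with RIF per tissue, build
PCIT masks per condition across tissues, extract group-exclusive networks
and hubs, correlate hubs with plasma metabolites, and run set
over-representation. Every report is a plain-text table with fixed float
formatting and sorted ordering, so identical seeds give byte-identical
output trees.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import enrich as en
from . import expression as ex
from . import metabolites as mb
from . import network as nw
from . import pcit as pc
from . import prioritize as pr
from . import rif as rf
from .config import SimulationConfig
from .phenotypes import assign_groups
from .simulate import simulate_cohort, write_dataset

_FLOAT_FMT = "%.6g"


def run_all(config: SimulationConfig | None = None,
            out_dir: str | Path = "results/run",
            seed: int | None = None) -> dict:
    """Run the full pipeline; returns a summary dict (also written to disk)."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds = simulate_cohort(config)
    write_dataset(ds, out / "data")
    biotypes = ds.gene_table.set_index("gene_id")["biotype"]

    # --- efficiency groups ---------------------------------------------
    groups_df = assign_groups(ds.phenotypes, ds.population)
    groups_df.to_csv(out / "groups.tsv", sep="\t", index=False)
    group_of = groups_df.set_index("animal_id")["group"]
    included = group_of.index[group_of.isin(["high", "low"])]

    # --- expression -----------------------------------------------------
    cm = ds.to_count_matrix()
    keep_samples = cm.sample_meta.index[cm.sample_meta["animal"].isin(included)]
    cm = ex.CountMatrix(
        fragments=cm.fragments[keep_samples],
        sample_meta=cm.sample_meta.loc[keep_samples].assign(
            group=lambda m: group_of.loc[m["animal"]].to_numpy()),
        gene_lengths=cm.gene_lengths,
    )
    em_fpkm_all = ex.compute_fpkm(cm)
    em_log2_all = ex.log2_with_pseudocount(em_fpkm_all)
    keep_genes = ex.filter_min_mean_fpkm(em_fpkm_all, biotypes=biotypes)
    em_fpkm = ex.ExpressionMatrix(em_fpkm_all.values.loc[keep_genes], "fpkm", cm.sample_meta)
    em_log2 = ex.ExpressionMatrix(em_log2_all.values.loc[keep_genes], "log2fpkm", cm.sample_meta)

    # --- lncRNA candidates and classification ---------------------------
    novel = [m for m in ds.annotation if m.biotype == "novel"]
    reference = [m for m in ds.annotation if m.biotype != "novel"]
    candidates = ann.filter_lncrna_candidates(novel, reference)
    candidate_ids = sorted({c.gene_id for c in candidates})
    coding_ref = [m for m in reference if m.biotype == "protein_coding"]
    classifications = [ann.classify_lncrna(c, coding_ref) for c in candidates]
    ann.classification_report(classifications).sort_values("lncrna_id").to_csv(
        out / "lncrna_classification.tsv", sep="\t", index=False)

    # --- DE / TS / QTL categories ---------------------------------------
    covars = cm.sample_meta[["sex", "year"]].astype(str)
    de_tables = []
    for tissue in config.tissues:
        cols = em_log2_all.tissue_samples(tissue)
        tissue_counts = cm.fragments[cols]
        testable = ex.filter_counts_for_de(tissue_counts)
        testable = testable[~biotypes.loc[testable].eq("rRNA")]
        res = pr.de_standin_test(
            em_log2_all.values.loc[testable, cols],
            cm.sample_meta.loc[cols, "group"],
            covariates=covars.loc[cols],
            tissue=tissue,
        )
        de_tables.append(res)
    de_results = pd.concat(de_tables, ignore_index=True)
    de_results.to_csv(out / "de_results.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    de_sets, de_union = pr.select_de(de_results)

    ts_sets = pr.select_tissue_specific(em_log2)
    qtl_flags = ann.flag_qtl_overlap(ds.gene_table, ds.qtl)
    pcit_keep = ex.filter_above_tissue_average(em_log2, any_tissue=True)

    prioritized = pr.assemble_prioritized_set(
        de_sets, ts_sets, qtl_flags, set(candidate_ids) & set(keep_genes),
        biotypes, pcit_keep)
    prioritized.flags.to_csv(out / "prioritized_set.tsv", sep="\t")

    # --- RIF per tissue --------------------------------------------------
    rif_reports = []
    sig_lncs: set[str] = set()
    prio_lncs = set(prioritized.lncrnas())
    qtl_any = {g for t in qtl_flags.columns for g in qtl_flags.index[qtl_flags[t]]}
    for tissue in config.tissues:
        cols = em_log2.tissue_samples(tissue)
        above = set(ex.filter_above_tissue_average(em_log2, tissue=tissue))
        regulators = sorted(prio_lncs & above)
        targets = sorted(
            ((de_sets.get(tissue, set()) | ts_sets.get(tissue, set()) | qtl_any)
             & set(prioritized.gene_ids) & above) - prio_lncs)
        if len(regulators) < 2 or not targets:
            continue
        cs = rf.condition_stats(em_log2.values[cols],
                                cm.sample_meta.loc[cols, "group"],
                                regulators, targets)
        scores = rf.select_significant_regulators(rf.compute_rif_scores(cs))
        scores.insert(1, "tissue", tissue)
        rif_reports.append(scores)
        sig_lncs |= set(scores.loc[scores["significant"], "regulator_id"])
    rif_report = pd.concat(rif_reports, ignore_index=True) if rif_reports else \
        pd.DataFrame(columns=["regulator_id", "tissue", "rif1_raw", "rif2_raw",
                              "rif1_z", "rif2_z", "significant"])
    rif_report.to_csv(out / "rif_scores.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    # --- PCIT per condition, across tissues ------------------------------
    universe = sorted(set(prioritized.gene_ids) | sig_lncs)
    masks, rmats = {}, {}
    for group in ("high", "low"):
        cols = cm.sample_meta.index[cm.sample_meta["group"] == group]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ids, r = pc.pearson_matrix(em_log2.values.loc[universe, cols])
        masks[group] = pc.pcit_mask(r)
        rmats[group] = r

    edges = nw.group_exclusive_edges(
        masks["high"], masks["low"], rmats["high"], rmats["low"],
        universe, sig_lncs, set(prioritized.gene_ids))
    node_flags = prioritized.flags.reindex(universe).fillna(False)
    networks = {g: nw.build_network(edges[g], g, node_flags) for g in ("high", "low")}
    for g, net in networks.items():
        net.edges.to_csv(out / f"edges_{g}.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        nw.export_network(net, out / f"network_{g}.sif", "sif")
        nw.export_network(net, out / f"network_{g}.graphml", "graphml")
    hubs = nw.connectivity_and_hubs(networks)
    hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)

    # --- metabolite correlation and enrichment ---------------------------
    mets = mb.preprocess_metabolites(ds.metabolites)
    hub_ids = list(hubs["lncrna_id"])
    edge_frames = [n.edges for n in networks.values() if len(n.edges)]
    if not hub_ids and edge_frames:
        # scaled-down runs rarely reach >100 partners; fall back to the
        # best-connected lncRNAs so the downstream stages stay exercised
        degree = pd.concat(edge_frames).groupby("lncrna_id").size() \
            .sort_values(ascending=False, kind="mergesort")
        hub_ids = list(degree.index[:8])
    met_corr = mb.correlate_with_lncrna(em_fpkm, mets, hub_ids) if hub_ids else \
        pd.DataFrame(columns=["lncrna_id", "metabolite_id", "tissue", "r", "p", "selected"])
    met_corr.to_csv(out / "metabolite_correlations.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)

    gmt = en.read_gmt(out / "data" / "pathways.gmt")
    universe_ns = {f"gene:{g}" for g in prioritized.gene_ids} | \
        {f"met:{m}" for m in mets.index}
    enr_rows = []
    all_edges = pd.concat(edge_frames) if edge_frames else \
        pd.DataFrame(columns=["lncrna_id", "gene_id", "r", "group"])
    for lnc in hub_ids:
        partners = set(all_edges.loc[all_edges["lncrna_id"] == lnc, "gene_id"])
        sel_mets = set(met_corr.loc[(met_corr["lncrna_id"] == lnc)
                                    & met_corr["selected"], "metabolite_id"])
        query = {f"gene:{g}" for g in partners} | {f"met:{m}" for m in sel_mets}
        if not query:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = en.hypergeometric_enrichment(query, gmt, universe_ns)
        res.insert(0, "lncrna_id", lnc)
        enr_rows.append(res)
    enrichment = pd.concat(enr_rows, ignore_index=True) if enr_rows else \
        pd.DataFrame(columns=["lncrna_id", "set_name", "k", "n", "K", "N",
                              "p", "ratio", "q"])
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    # --- summary ---------------------------------------------------------
    summary = {
        "seed": config.seed,
        "n_animals_included": int(len(included)),
        "n_genes_expressed": int(len(keep_genes)),
        "n_lncrna_candidates": int(len(candidate_ids)),
        "n_de_union": int(len(de_union)),
        "n_ts_total": int(sum(len(v) for v in ts_sets.values())),
        "n_qtl_genes": int(len(qtl_any)),
        "n_prioritized": int(len(prioritized.gene_ids)),
        "n_rif_significant_lncrna": int(len(sig_lncs)),
        "n_nodes_high": int(len(networks["high"].connectivity)),
        "n_nodes_low": int(len(networks["low"].connectivity)),
        "n_edges_high": int(len(networks["high"].edges)),
        "n_edges_low": int(len(networks["low"].edges)),
        "n_hubs": int(len(hubs)),
        "n_metabolites_retained": int(len(mets)),
        "n_metabolite_correlations_selected": int(met_corr["selected"].sum())
        if len(met_corr) else 0,
    }
    pd.DataFrame(sorted(summary.items()), columns=["key", "value"]).to_csv(
        out / "summary.tsv", sep="\t", index=False)
    return summary
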