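#!/usr/bin/env python
"""Score the pipeline's recovery of the planted ground truth.

Reads the tables written by 03_run_network_pipeline.py, compares them with
the generator's ground truth, and writes results/recovery_summary.tsv:
RIF recovery of planted regulators, precision/recall of the group-exclusive
edges against planted modules, and detection of planted metabolite links.
"""

from pathlib import Path

import pandas as pd

from lncnet.config import SimulationConfig
from lncnet.simulate import read_ground_truth

RUN = Path("results/pipeline")
SEED = 7


def main() -> None:
    gt = read_ground_truth(RUN / "data" / "ground_truth.tsv")
    planted = set(gt.planted_regulator_ids)
    rows = []

    rif = pd.read_csv(RUN / "rif_scores.tsv", sep="\t")
    sig = set(rif.loc[rif["significant"], "regulator_id"])
    rows.append(("rif_planted_recovered", len(planted & sig), len(planted)))
    rows.append(("rif_significant_total", len(sig), rif["regulator_id"].nunique()))

    frames = [f for g in ("high", "low")
              if len(f := pd.read_csv(RUN / f"edges_{g}.tsv", sep="\t"))]
    edges = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["lncrna_id", "gene_id", "r", "group"])
    true_pairs = {(reg, t) for reg, ts in gt.target_map.items() for t in ts}
    got_pairs = set(map(tuple, edges[["lncrna_id", "gene_id"]].to_numpy())) \
        if len(edges) else set()
    tp = len(got_pairs & true_pairs)
    rows.append(("edges_true_positive", tp, len(got_pairs) or 1))
    rows.append(("edges_planted_recalled", tp, len(true_pairs)))

    met = pd.read_csv(RUN / "metabolite_correlations.tsv", sep="\t")
    sel = set(map(tuple, met.loc[met["selected"],
                                 ["lncrna_id", "metabolite_id"]].to_numpy())) \
        if len(met) else set()
    true_links = {(reg, m) for reg, links in gt.metabolite_links.items()
                  for m, _ in links}
    rows.append(("metabolite_links_recovered", len(sel & true_links), len(true_links)))

    out = pd.DataFrame(rows, columns=["metric", "numerator", "denominator"])
    out["fraction"] = (out["numerator"] / out["denominator"]).round(3)
    out.to_csv("results/recovery_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    if len(got_pairs):
        print(f"edge precision vs planted modules: {tp / len(got_pairs):.2f}")


if __name__ == "__main__":
    main()
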