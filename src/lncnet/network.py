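"""Condition-exclusive co-expression networks, connectivity and hubs.

Edges connect a significant-RIF lncRNA to a prioritized gene when the pair
is PCIT-significant in exactly one condition and the correlation in that
condition is strong (|r| > 0.8 by default). Only lncRNA-gene edges are
materialized. Hubs are lncRNAs with more than 100 distinct partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

R_THRESHOLD = 0.8
HUB_THRESHOLD = 100


@dataclass
class GroupNetwork:
    group: str
    edges: pd.DataFrame  # lncrna_id, gene_id, r, group
    node_flags: pd.DataFrame  # index node id; boolean category flags
    connectivity: pd.Series  # node -> degree (distinct partners)


def group_exclusive_edges(
    mask_high: np.ndarray,
    mask_low: np.ndarray,
    r_high: np.ndarray,
    r_low: np.ndarray,
    ids: list[str],
    rif_lncrnas: set[str] | list[str],
    prioritized: set[str] | list[str],
    r_threshold: float = R_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """lncRNA-gene edges significant in exactly one group with |r| above threshold."""
    n = len(ids)
    for m in (mask_high, mask_low, r_high, r_low):
        if np.asarray(m).shape != (n, n):
            raise ValueError("masks/correlations misaligned with the id universe")
    rif_lncrnas = set(rif_lncrnas)
    prioritized = set(prioritized)
    pos = {g: i for i, g in enumerate(ids)}
    lnc_idx = [pos[g] for g in sorted(rif_lncrnas & set(ids))]
    gene_idx = [pos[g] for g in sorted(prioritized & set(ids))]

    out = {}
    for group, mask_in, mask_out, r_in in (
        ("high", mask_high, mask_low, r_high),
        ("low", mask_low, mask_high, r_low),
    ):
        rows = []
        for li in lnc_idx:
            for gi in gene_idx:
                if gi == li:
                    continue
                if mask_in[li, gi] and not mask_out[li, gi] and abs(r_in[li, gi]) > r_threshold:
                    rows.append({"lncrna_id": ids[li], "gene_id": ids[gi],
                                 "r": float(r_in[li, gi]), "group": group})
        out[group] = pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "r", "group"])
    overlap = set(map(tuple, out["high"][["lncrna_id", "gene_id"]].to_numpy())) \
        & set(map(tuple, out["low"][["lncrna_id", "gene_id"]].to_numpy()))
    assert not overlap, "edge sets must be disjoint by exclusivity"
    return out


def build_network(edges: pd.DataFrame, group: str,
                  node_flags: pd.DataFrame | None = None) -> GroupNetwork:
    """Assemble a GroupNetwork; node tables cover edge endpoints only."""
    edges = edges.drop_duplicates(subset=["lncrna_id", "gene_id"]).reset_index(drop=True)
    nodes = sorted(set(edges["lncrna_id"]) | set(edges["gene_id"]))
    degree = pd.Series(0, index=pd.Index(nodes, name="node"), dtype=int)
    for col in ("lncrna_id", "gene_id"):
        counts = edges.groupby(col).size()
        degree.loc[counts.index] = degree.loc[counts.index] + counts
    if node_flags is not None:
        flags = node_flags.reindex(nodes).fillna(False)
    else:
        flags = pd.DataFrame(
            {"is_lncrna": [n in set(edges["lncrna_id"]) for n in nodes]},
            index=pd.Index(nodes, name="node"),
        )
    return GroupNetwork(group=group, edges=edges, node_flags=flags, connectivity=degree)


def connectivity_and_hubs(
    networks: dict[str, GroupNetwork], hub_threshold: int = HUB_THRESHOLD
) -> pd.DataFrame:
    """Hub report: lncRNAs with strictly more than ``hub_threshold`` partners."""
    rows = []
    for group, net in networks.items():
        lncs = set(net.edges["lncrna_id"])
        for lnc in sorted(lncs):
            deg = int(net.edges.loc[net.edges["lncrna_id"] == lnc, "gene_id"].nunique())
            if deg > hub_threshold:
                rows.append({"lncrna_id": lnc, "group": group, "connectivity": deg})
    return pd.DataFrame(rows, columns=["lncrna_id", "group", "connectivity"])


def to_networkx(net: GroupNetwork) -> nx.Graph:
    g = nx.Graph(group=net.group)
    for node, flags in net.node_flags.iterrows():
        g.add_node(node, **{k: bool(v) for k, v in flags.items()})
    for e in net.edges.itertuples(index=False):
        g.add_edge(e.lncrna_id, e.gene_id, r=float(e.r), group=e.group)
    return g


def export_network(net: GroupNetwork, path: str | Path, fmt: str = "sif") -> Path:
    """Write the network as SIF or GraphML (Cytoscape-compatible)."""
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges.itertuples(index=False):
                fh.write(f"{e.lncrna_id}\tcoexpression\t{e.gene_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
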