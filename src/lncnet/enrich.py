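"""Hypergeometric over-representation of annotated sets.

A generic stand-in for proprietary pathway tools: each query list (genes
and/or metabolites, namespaced ``gene:``/``met:``) is tested against GMT
gene sets with the hypergeometric upper tail over a declared universe, with
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from scipy import stats

from .prioritize import bh_adjust


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, tab-separated: name, description, members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def hypergeometric_enrichment(
    query: list[str] | set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric P(X >= k) per set, BH across sets, sorted by p.

    Query members outside the universe are dropped with a warning. ``ratio``
    is overlap / set size, mirroring the usual pathway-report shape.
    """
    if not universe or not collection:
        raise ValueError("universe and collection must be non-empty")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query member(s) outside the universe dropped",
                      stacklevel=2)
    query &= universe
    N, n = len(universe), len(query)

    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        K = len(members)
        k = len(query & members)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "n": n, "K": K, "N": N,
                     "p": min(p, 1.0), "ratio": 0.0 if K == 0 else k / K})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
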