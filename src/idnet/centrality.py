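"""Centrality indices for the signed weighted directed symptom network.

Out-strength ("outdegree") sums the absolute weights of edges leaving a
node — how much a symptom today drives other symptoms tomorrow; in-strength
("indegree") sums absolute weights of edges arriving.  Betweenness counts,
fractionally over co-minimal paths (Brandes), how often a node lies on the
cheapest directed paths between other pairs, with traversal cost 1/|w| so
strong edges are short.  Self-loops never contribute: persistence is
reported separately.  Signs are dropped throughout — the field convention
(Opsahl-style weighted indices) treats a strong negative relation as just
as much "information flow" as a positive one.  Raw indices are
z-standardized across the retained nodes for display.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .network import LagNetwork

__all__ = [
    "strength_centrality",
    "betweenness_centrality",
    "standardize",
    "centrality_table",
]

logger = logging.getLogger(__name__)


def strength_centrality(net: LagNetwork) -> pd.DataFrame:
    """Absolute-weight out/in strengths, diagonal excluded."""
    absW = np.abs(net.W)
    np.fill_diagonal(absW, 0.0)
    return pd.DataFrame({
        "node": net.nodes,
        "outdegree_raw": absW.sum(axis=1),
        "indegree_raw": absW.sum(axis=0),
    })


def betweenness_centrality(net: LagNetwork) -> pd.DataFrame:
    """Directed weighted betweenness with 1/|w| edge costs.

    Node v scores the sum over ordered pairs (s, t), s ≠ t ≠ v, of the
    fraction of minimum-cost s→t paths passing through v.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(net.p))
    for i in range(net.p):
        for j in range(net.p):
            if i != j and net.W[i, j] != 0:
                g.add_edge(i, j, cost=1.0 / abs(net.W[i, j]))
    bc = nx.betweenness_centrality(g, weight="cost", normalized=False)
    return pd.DataFrame({
        "node": net.nodes,
        "betweenness_raw": [bc[i] for i in range(net.p)],
    })


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Append z-score columns (sample SD, n−1) for every ``*_raw`` column.

    A constant raw column yields z = 0 with a warning rather than NaN.
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 nodes")
    out = table.copy()
    for col in [c for c in table.columns if c.endswith("_raw")]:
        vals = table[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        zcol = col.replace("_raw", "_z")
        if sd == 0:
            logger.warning("centrality column %r is constant; z set to 0", col)
            out[zcol] = 0.0
        else:
            out[zcol] = (vals - vals.mean()) / sd
    return out


def centrality_table(net: LagNetwork) -> pd.DataFrame:
    """Full per-node table: raw and z out/in strength and betweenness."""
    table = strength_centrality(net).merge(betweenness_centrality(net), on="node")
    return standardize(table)
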