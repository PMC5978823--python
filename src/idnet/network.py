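"""The signed weighted directed lag-1 network and its bookkeeping.

``W[i, j]`` is the standardized coefficient of node i at day t−1 predicting
node j at day t; the diagonal holds autoregressive self-loops.  Edge counts
are reported on the full pre-pruning node set (p² possible relations,
self-loops included), matching the arithmetic a p-item diary yields.
Dynamically isolated nodes — no off-diagonal in- or out-edges; a self-loop
alone does not count — are pruned before centrality and community analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ratings import RatingMatrix

__all__ = [
    "LagNetwork",
    "prune_isolated_nodes",
    "edge_counts",
    "bivariate_table",
    "to_graph",
    "write_graphml",
]


@dataclass
class LagNetwork:
    """Node-labeled signed weighted directed adjacency of lag-1 coefficients."""

    nodes: list[str]
    W: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        self.W = np.asarray(self.W, dtype=float)
        p = len(self.nodes)
        if self.W.shape != (p, p):
            raise ValueError(f"W shape {self.W.shape} != ({p}, {p})")
        if not np.isfinite(self.W).all():
            raise ValueError("W must be finite")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def subnetwork(self, keep: list[str]) -> "LagNetwork":
        idx = [self.nodes.index(n) for n in keep]
        return LagNetwork(nodes=keep, W=self.W[np.ix_(idx, idx)],
                          provenance=dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.nodes, columns=self.nodes)


def prune_isolated_nodes(net: LagNetwork) -> tuple[LagNetwork, list[str]]:
    """Drop nodes with no off-diagonal edges in either direction.

    A node whose only nonzero entry is its self-loop carries no dynamic
    relation to any other symptom and is removed; removal iterates until
    stable (dropping a node can never isolate another, but the loop keeps
    the rule self-evidently a fixed point).
    """
    nodes = list(net.nodes)
    W = net.W.copy()
    while True:
        p = len(nodes)
        off = W * (1 - np.eye(p))
        isolated = np.flatnonzero((off == 0).all(axis=0) & (off == 0).all(axis=1))
        if isolated.size == 0:
            break
        if isolated.size == p:
            raise ValueError("all nodes are dynamically isolated (degenerate network)")
        keep = [i for i in range(p) if i not in set(isolated.tolist())]
        nodes = [nodes[i] for i in keep]
        W = W[np.ix_(keep, keep)]
    removed = [n for n in net.nodes if n not in set(nodes)]
    return LagNetwork(nodes=nodes, W=W, provenance=dict(net.provenance)), removed


def edge_counts(net: LagNetwork) -> dict:
    """Possible / zeroed / retained lag-1 relation counts (self-loops count)."""
    possible = net.p ** 2
    retained = int(np.count_nonzero(net.W))
    return {"possible": possible, "zeroed": possible - retained,
            "retained": retained}


def bivariate_table(residuals: RatingMatrix, net: LagNetwork,
                    policy: str = "calendar") -> pd.DataFrame:
    """Plain lag-1 Pearson correlations for every retained edge.

    A retained partial coefficient can understate a relation whose variance
    is shared with collinear predictors; the unadjusted lag-1 correlation of
    origin-at-t−1 with destination-at-t over the same pair set makes that
    visible.  Columns: origin, destination, partial_weight, bivariate_r,
    n_pairs.
    """
    from .lagged import build_lag_pairs  # local import avoids a cycle

    ps = build_lag_pairs(residuals, policy=policy)
    col = {item: k for k, item in enumerate(ps.items)}
    rows = []
    for i, origin in enumerate(net.nodes):
        for j, dest in enumerate(net.nodes):
            w = net.W[i, j]
            if w == 0:
                continue
            x = ps.X[:, col[origin]]
            y = ps.Y[:, col[dest]]
            if x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"origin": origin, "destination": dest,
                         "partial_weight": float(w), "bivariate_r": r,
                         "n_pairs": ps.n_pairs})
    return pd.DataFrame(rows, columns=["origin", "destination",
                                       "partial_weight", "bivariate_r", "n_pairs"])


def to_graph(net: LagNetwork, include_self_loops: bool = True) -> nx.DiGraph:
    """networkx DiGraph with weight, sign and lag edge attributes."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for i, u in enumerate(net.nodes):
        for j, v in enumerate(net.nodes):
            w = net.W[i, j]
            if w == 0 or (i == j and not include_self_loops):
                continue
            g.add_edge(u, v, weight=float(w),
                       sign="positive" if w > 0 else "negative", lag=1)
    return g


def write_graphml(net: LagNetwork, path) -> None:
    nx.write_graphml(to_graph(net), path)
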