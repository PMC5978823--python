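"""End-to-end orchestration: ratings in, result bundle out.

Stages: polynomial detrending → lag-pair construction → node-wise
LASSO/AICc estimation → pruning of dynamically isolated nodes → edge
counts → centrality → spin-glass communities → bivariate cross-check →
persistence and feedback-loop summaries → CSV/GraphML/JSON exports.
Every stage logs its parameters; a fixed seed makes the bundle
reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import centrality_table
from .community import CommunityResult, spinglass_communities
from .detrend import PolynomialDetrender
from .lagged import LagNetworkEstimator
from .network import (
    LagNetwork,
    bivariate_table,
    edge_counts,
    prune_isolated_nodes,
    write_graphml,
)
from .ratings import RatingMatrix, coverage_summary, read_ratings

__all__ = [
    "DEFAULT_CONFIG",
    "IdnaResult",
    "run_pipeline",
    "detect_feedback_loops",
    "persistence_table",
    "plot_network",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "detrend": {"max_order": 10, "alpha_ar1": 0.05, "criterion": "bic"},
    "network": {"policy": "calendar", "lambda_grid_size": 100,
                "lambda_min_ratio": 1e-3},
    "community": {"gamma_pos": 1.0, "gamma_neg": 1.0, "seed": 0,
                  "n_restarts": 20},
    "report": {"persistence_threshold": 0.3},
    "plot": {"layout_seed": 0},
}


def _merge_config(user: dict | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        cfg[section].update(values)
    return cfg


@dataclass
class IdnaResult:
    """Machine-readable bundle of every pipeline stage's output."""

    coverage: dict
    detrend_report: pd.DataFrame
    network: LagNetwork          # full, pre-pruning
    pruned_network: LagNetwork
    removed_nodes: list[str]
    counts: dict
    centrality: pd.DataFrame
    community: CommunityResult
    bivariate: pd.DataFrame
    persistence: pd.DataFrame
    feedback_loops: list[dict]
    config: dict = field(default_factory=dict)


def detect_feedback_loops(net: LagNetwork) -> list[dict]:
    """All 2-cycles i→j→i with both edges retained, sign pattern annotated.

    Each unordered pair appears once, as
    ``{"a": node, "b": node, "w_ab": ..., "w_ba": ..., "signs": "(+,−)"}``.
    """
    loops = []
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w_ab, w_ba = net.W[i, j], net.W[j, i]
            if w_ab != 0 and w_ba != 0:
                s = lambda w: "+" if w > 0 else "-"
                loops.append({
                    "a": net.nodes[i], "b": net.nodes[j],
                    "w_ab": float(w_ab), "w_ba": float(w_ba),
                    "signs": f"({s(w_ab)},{s(w_ba)})",
                })
    return loops


def persistence_table(net: LagNetwork, threshold: float = 0.3) -> pd.DataFrame:
    """Autoregressive self-loops, flagging |loop| ≥ threshold as persistent."""
    diag = np.diag(net.W)
    return pd.DataFrame({
        "node": net.nodes,
        "self_loop": diag,
        "persistent": np.abs(diag) >= threshold,
    })


def run_pipeline(ratings, config: dict | None = None,
                 out_dir=None, layout: str = "wide") -> IdnaResult:
    """Run the whole analysis; optionally write the result bundle.

    Parameters
    ----------
    ratings : RatingMatrix or path to a CSV
    config : dict, optional
        Nested overrides of :data:`DEFAULT_CONFIG`.
    out_dir : path, optional
        If given, the bundle directory is written there (CSV tables,
        ``adjacency.csv``, ``network.graphml``, ``communities.json``,
        ``result.json``, and a network plot with layout metadata).
    layout : {"wide", "long"}
        CSV layout when ``ratings`` is a path.
    """
    cfg = _merge_config(config)
    if not isinstance(ratings, RatingMatrix):
        ratings = read_ratings(ratings, layout=layout)

    stage = "coverage"
    try:
        coverage = coverage_summary(ratings)
        logger.info("coverage: %d observed of %d days",
                    coverage["observed_days"], coverage["span_days"])

        stage = "detrend"
        det = PolynomialDetrender(**cfg["detrend"]).fit(ratings)
        residuals = det.transform(ratings)

        stage = "network"
        est = LagNetworkEstimator(**cfg["network"]).fit(residuals)
        net = est.network_

        stage = "prune"
        pruned, removed = prune_isolated_nodes(net)
        counts = edge_counts(net)
        logger.info("edges: %d retained of %d possible; removed nodes: %s",
                    counts["retained"], counts["possible"], removed or "none")

        stage = "centrality"
        cent = centrality_table(pruned)

        stage = "community"
        comm = spinglass_communities(pruned, **cfg["community"])

        stage = "bivariate"
        biv = bivariate_table(residuals, net, policy=cfg["network"]["policy"])

        stage = "report"
        pers = persistence_table(pruned, cfg["report"]["persistence_threshold"])
        loops = detect_feedback_loops(pruned)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = IdnaResult(
        coverage=coverage, detrend_report=det.report_, network=net,
        pruned_network=pruned, removed_nodes=removed, counts=counts,
        centrality=cent, community=comm, bivariate=biv, persistence=pers,
        feedback_loops=loops, config=cfg,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: IdnaResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.detrend_report.to_csv(out / "detrend_report.csv", index=False)
    result.network.to_frame().to_csv(out / "adjacency.csv")
    _edges_frame(result.network).to_csv(out / "edges.csv", index=False)
    result.centrality.to_csv(out / "centrality.csv", index=False)
    result.bivariate.to_csv(out / "bivariate.csv", index=False)
    result.persistence.to_csv(out / "persistence.csv", index=False)
    write_graphml(result.pruned_network, out / "network.graphml")
    comm = result.community
    (out / "communities.json").write_text(json.dumps({
        "membership": comm.membership,
        "modularity": comm.modularity,
        "hamiltonian": comm.hamiltonian,
        "gamma_pos": comm.gamma_pos, "gamma_neg": comm.gamma_neg,
        "seed": comm.seed, "n_restarts": comm.n_restarts,
    }, indent=2, sort_keys=True))
    (out / "result.json").write_text(json.dumps({
        "coverage": result.coverage,
        "edge_counts": result.counts,
        "removed_nodes": result.removed_nodes,
        "feedback_loops": result.feedback_loops,
        "config": result.config,
    }, indent=2, sort_keys=True))
    plot_network(result.pruned_network, out / "network.png",
                 layout_seed=result.config["plot"]["layout_seed"])


def _edges_frame(net: LagNetwork) -> pd.DataFrame:
    rows = [
        {"origin": net.nodes[i], "destination": net.nodes[j],
         "weight": float(net.W[i, j]), "lag": 1}
        for i in range(net.p) for j in range(net.p) if net.W[i, j] != 0
    ]
    return pd.DataFrame(rows, columns=["origin", "destination", "weight", "lag"])


def plot_network(net: LagNetwork, out_path, layout_seed: int = 0) -> dict:
    """Draw the network with Fruchterman–Reingold layout; return metadata.

    Edge width is proportional to |w|, color green for positive and red for
    negative weights, arrowheads show direction, self-loops are drawn as
    loops.  Node positions use |w| as attraction weight and are
    deterministic for a fixed ``layout_seed``.  The returned metadata
    (positions, per-edge color/width) is also written next to the image as
    ``<out>.layout.json`` so figures can be checked without pixel
    comparisons.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    from .network import to_graph

    g = to_graph(net)
    for _, _, d in g.edges(data=True):
        d["abs_weight"] = abs(d["weight"])
    pos = nx.spring_layout(g, weight="abs_weight", seed=layout_seed)

    edge_meta = []
    for u, v, d in g.edges(data=True):
        edge_meta.append({
            "origin": u, "destination": v,
            "color": "green" if d["weight"] > 0 else "red",
            "width": 0.5 + 4.0 * abs(d["weight"]),
            "self_loop": u == v,
        })
    meta = {
        "layout_seed": int(layout_seed),
        "positions": {n: [float(x) for x in xy] for n, xy in pos.items()},
        "edges": edge_meta,
    }

    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#dddddd",
                           edgecolors="black", node_size=900)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    for e, m in zip(g.edges(), edge_meta):
        nx.draw_networkx_edges(
            g, pos, edgelist=[e], ax=ax, edge_color=m["color"],
            width=m["width"], arrows=True,
            connectionstyle="arc3,rad=0.1",
        )
    ax.set_axis_off()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    out_path.with_suffix(out_path.suffix + ".layout.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )
    return meta
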