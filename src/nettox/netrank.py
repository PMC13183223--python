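"""Composite centrality ranking of candidates in a protein-interaction network.

Hub selection mirrors the CentiScaPe-style workflow: degree, betweenness and
stress centrality are computed on the confidence-thresholded network,
min-max normalized, averaged into a composite score, and the top-k nodes are
reported as key targets. Edge confidence is used only for thresholding
(score > 0.4 by default, strict); shortest paths are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_SCORE_MIN = 0.4
DEFAULT_TOP_K = 20


@dataclass
class InteractionNetwork:
    """Undirected simple graph with per-edge confidence scores in [0, 1]."""

    graph: nx.Graph
    score_min: float = DEFAULT_SCORE_MIN

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @classmethod
    def from_edges(
        cls,
        edges: pd.DataFrame,
        score_min: float = DEFAULT_SCORE_MIN,
        nodes: list[str] | None = None,
    ) -> "InteractionNetwork":
        """Build from a (nodeA, nodeB, score) table, keeping score > score_min.

        Parallel records of one edge collapse to the maximum score. ``nodes``
        optionally adds isolated nodes so the node universe is explicit.
        """
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for a, b, s in edges.itertuples(index=False):
            s = float(s)
            if a == b or s <= score_min:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
        return cls(g, score_min)

    def subgraph(self, symbols) -> "InteractionNetwork":
        keep = [n for n in self.graph.nodes if n in set(symbols)]
        return InteractionNetwork(nx.Graph(self.graph.subgraph(keep)), self.score_min)

    def write_tsv(self, path) -> None:
        rows = [(a, b, d.get("score", 1.0)) for a, b, d in self.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["nodeA", "nodeB", "score"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path, score_min: float = DEFAULT_SCORE_MIN) -> "InteractionNetwork":
        return cls.from_edges(pd.read_csv(path, sep="\t"), score_min)


def _shortest_path_counts(graph: nx.Graph):
    """BFS from every node: distance and shortest-path-count matrices."""
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = [[idx[w] for w in graph.neighbors(v)] for v in nodes]
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if np.isinf(dist[s, w]):
                        dist[s, w] = d + 1
                        nxt.append(w)
                    if dist[s, w] == d + 1:
                        sigma[s, w] += sigma[s, v]
            frontier = nxt
            d += 1
    return nodes, dist, sigma


def stress_centrality(graph: nx.Graph) -> dict[str, float]:
    """Stress centrality: number of shortest paths passing through each node.

    Each unordered (s, t) pair with s != v != t contributes the count of
    shortest s-t paths on which v is interior. O(n * n^2); intended for
    candidate-scale networks (hundreds of nodes).
    """
    nodes, dist, sigma = _shortest_path_counts(graph)
    n = len(nodes)
    out: dict[str, float] = {}
    finite = np.isfinite(dist)
    for v in range(n):
        dv = dist[:, v]
        on_path = finite & (dv[:, None] + dv[None, :] == dist)
        paths = sigma[:, v][:, None] * sigma[v, :][None, :]
        contrib = np.where(on_path, paths, 0.0)
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        np.fill_diagonal(contrib, 0.0)
        out[nodes[v]] = float(contrib.sum() / 2.0)
    return out


def centralities(net: InteractionNetwork) -> pd.DataFrame:
    """Degree, betweenness and stress per node (unweighted, per component)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    stress = stress_centrality(g)
    df = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "betweenness": pd.Series(btw, dtype=float),
            "stress": pd.Series(stress, dtype=float),
        }
    )
    df.index.name = "symbol"
    return df.loc[list(g.nodes)]


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if hi == lo:  # constant metric carries no ranking information
        return pd.Series(0.0, index=col.index)
    return (col - lo) / (hi - lo)


def composite_rank(table: pd.DataFrame, top_k: int = DEFAULT_TOP_K) -> list[str]:
    """Top-k symbols by mean min-max-normalized centrality.

    Ties break by higher degree, then lexicographic symbol, so ranked lists
    are reproducible.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > len(table):
        raise ValueError("top_k exceeds number of nodes")
    ranked = rank_table(table)
    return list(ranked.index[:top_k])


def rank_table(table: pd.DataFrame) -> pd.DataFrame:
    """Full ranking table with normalized metrics, composite score and rank."""
    out = table.copy()
    for m in ("degree", "betweenness", "stress"):
        out[f"norm_{m}"] = _minmax(out[m])
    out["composite"] = out[["norm_degree", "norm_betweenness", "norm_stress"]].mean(axis=1)
    out["_symbol"] = out.index.astype(str)
    out = out.sort_values(
        by=["composite", "degree", "_symbol"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_symbol")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def write_ranked_tsv(table: pd.DataFrame, path) -> None:
    cols = ["degree", "betweenness", "stress", "composite", "rank"]
    table.reset_index()[["symbol", *cols]].to_csv(path, sep="\t", index=False)
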