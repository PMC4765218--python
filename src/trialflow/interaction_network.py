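"""Directed participant networks from communication logs, with centralities.

Nodes are process participants (OCR, sponsor, PI, …); a directed tie
``u → v`` with weight *w* records that *u* initiated *w* interactions
toward *v* (emails, document submissions).  Four centrality families
describe a participant's role: degree (volume of distinct partners, or
weighted volume), closeness (geodesic proximity, harmonic by default so
disconnected pairs are well-defined), betweenness (share of directed
geodesics through the node), and the Bonacich power index
``c(β) = α (I − βA)⁻¹ A·1`` on the symmetrized binary adjacency, whose
negative-β variant rewards being connected to otherwise unconnected
neighbors.

Geodesics are computed on binarized ties; weights enter only the weighted
degree variant and diagram line widths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "CommunicationNetwork",
    "build_network",
    "read_log",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "bonacich_power",
    "centrality_report",
]


class CommunicationNetwork:
    """Aggregated directed interaction network with integer tie weights."""

    def __init__(self, graph: nx.DiGraph, label: str | None = None):
        self.graph = graph
        self.label = label

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight(self, source: str, target: str) -> int:
        if self.graph.has_edge(source, target):
            return self.graph[source][target]["weight"]
        return 0

    def out_initiations(self, source: str) -> int:
        """Total interactions initiated by ``source``."""
        return sum(d["weight"] for _, _, d in self.graph.out_edges(source, data=True))

    def edge_list(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "weight": d["weight"]}
                for u, v, d in sorted(self.graph.edges(data=True))]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def write_edge_list(self, path) -> None:
        self.edge_list().to_csv(path, index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(records, allow_self_loops: bool = False,
                  label: str | None = None) -> CommunicationNetwork:
    """Aggregate (timestamp, source, target) interaction records.

    Tie weight = number of records per ordered participant pair; node set
    is the union of endpoints.  Self-loops are dropped unless requested.
    """
    g = nx.DiGraph()
    for rec in records:
        try:
            _, src, tgt = rec[0], str(rec[1]), str(rec[2])
        except (TypeError, IndexError):
            raise ValueError(f"malformed interaction record: {rec!r}") from None
        if not src or not tgt:
            raise ValueError(f"malformed interaction record: {rec!r}")
        if src == tgt and not allow_self_loops:
            continue
        g.add_node(src)
        g.add_node(tgt)
        if g.has_edge(src, tgt):
            g[src][tgt]["weight"] += 1
        else:
            g.add_edge(src, tgt, weight=1)
    return CommunicationNetwork(g, label=label)


def read_log(path, subprocess: str | None = None) -> CommunicationNetwork:
    """Build a network from a CSV log (timestamp, source, target[, subprocess])."""
    df = pd.read_csv(path)
    required = {"timestamp", "source", "target"}
    if not required <= set(df.columns):
        raise ValueError(f"communication log needs columns {sorted(required)}")
    if subprocess is not None:
        if "subprocess" not in df.columns:
            raise ValueError("log has no 'subprocess' column to filter on")
        df = df[df["subprocess"] == subprocess]
    return build_network(df[["timestamp", "source", "target"]].itertuples(index=False),
                         label=subprocess)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------


def degree_centrality(net: CommunicationNetwork,
                      weighted: bool = False) -> dict[str, tuple[float, float]]:
    """Per node (in_degree, out_degree): distinct partners, or tie weights."""
    g = net.graph
    if weighted:
        return {n: (float(g.in_degree(n, weight="weight")),
                    float(g.out_degree(n, weight="weight"))) for n in g.nodes}
    return {n: (float(g.in_degree(n)), float(g.out_degree(n))) for n in g.nodes}


def closeness_centrality(net: CommunicationNetwork,
                         method: str = "harmonic") -> dict[str, tuple[float, float]]:
    """Per node (in_closeness, out_closeness) on the binarized digraph.

    ``harmonic`` (default): sum of reciprocal geodesic distances, an
    unreachable pair contributing zero — well-defined on disconnected
    networks.  ``freeman``: classic (reachable−1)²/((n−1)·Σd) closeness
    (networkx's improved formula), zero for an isolated endpoint.
    """
    g = net.graph
    if method == "harmonic":
        in_c = nx.harmonic_centrality(g)            # distances u -> n
        out_c = nx.harmonic_centrality(g.reverse())  # distances n -> u
    elif method == "freeman":
        in_c = nx.closeness_centrality(g)
        out_c = nx.closeness_centrality(g.reverse())
    else:
        raise ValueError(f"unknown closeness method {method!r}")
    return {n: (float(in_c[n]), float(out_c[n])) for n in g.nodes}


def betweenness_centrality(net: CommunicationNetwork) -> dict[str, float]:
    """Directed geodesic betweenness: Σ_{s≠t≠v} σ_st(v)/σ_st, unnormalized."""
    return {n: float(b) for n, b in
            nx.betweenness_centrality(net.graph, normalized=False).items()}


def bonacich_power(net: CommunicationNetwork, beta: float | None = None,
                   ) -> dict[str, float]:
    """Bonacich power index c(β) = α (I − βA)⁻¹ A·1, Σc² = n.

    A is the symmetrized binary adjacency (an interaction in either
    direction makes a tie).  β defaults to −0.75/λ_max: negative, so a
    participant scores high when its neighbors are otherwise unconnected;
    |β| must stay below 1/λ_max for the series to converge.
    """
    nodes = net.nodes
    n = len(nodes)
    if n == 0:
        return {}
    a = nx.to_numpy_array(net.graph, nodelist=nodes, weight=None)
    a = ((a + a.T) > 0).astype(float)
    np.fill_diagonal(a, 0.0)
    lam = float(np.max(np.abs(np.linalg.eigvalsh(a)))) if a.any() else 0.0
    if beta is None:
        beta = -0.75 / lam if lam > 0 else 0.0
    if lam > 0 and abs(beta) >= 1.0 / lam:
        raise ValueError(f"|beta| must be < 1/λ_max = {1.0 / lam:.4g} for convergence")
    raw = np.linalg.solve(np.eye(n) - beta * a, a @ np.ones(n))
    ssq = float(raw @ raw)
    if ssq == 0.0:
        return {node: 0.0 for node in nodes}
    alpha = np.sqrt(n / ssq)
    return {node: float(alpha * c) for node, c in zip(nodes, raw)}


def centrality_report(net: CommunicationNetwork, beta: float | None = None,
                      closeness_method: str = "harmonic") -> pd.DataFrame:
    """All four centrality families as one table, indexed by participant."""
    deg = degree_centrality(net)
    clo = closeness_centrality(net, method=closeness_method)
    bet = betweenness_centrality(net)
    bon = bonacich_power(net, beta=beta)
    rows = {
        n: {
            "in_degree": deg[n][0],
            "out_degree": deg[n][1],
            "betweenness": bet[n],
            "in_closeness": clo[n][0],
            "out_closeness": clo[n][1],
            "bonacich_power": bon[n],
        }
        for n in net.nodes
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("participant")
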