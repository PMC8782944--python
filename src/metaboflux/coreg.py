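"""Metabolite co-regulation network: nodes are significantly altered
metabolites, edges are Pearson correlations above an absolute threshold,
node importance is eigenvector centrality of the |r|-weighted adjacency."""

from __future__ import annotations

import logging
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .table import ConcentrationTable

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


def load_class_map(path=None) -> dict[str, str]:
    """Metabolite -> functional class from the bundled (editable) mapping."""
    if path is None:
        path = resources.files("metaboflux.data") / "metabolite_classes.csv"
    df = pd.read_csv(path)
    return dict(zip(df["metabolite"], df["class"]))


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    xv, yv = x[ok], y[ok]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return np.nan, n
    return float(np.corrcoef(xv, yv)[0, 1]), n


def build_network(
    table: ConcentrationTable,
    significant: list[str],
    threshold: float = 0.7,
    tissue: str | None = None,
    class_map: dict[str, str] | None = None,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Undirected graph over significant metabolites with |r| > threshold.

    Correlations use pairwise-complete observations within one tissue
    (pass ``tissue=None`` for the opt-in cross-tissue mode). Nodes left
    without a retained edge are dropped ("only strongly correlated nodes")
    but recorded in the graph attribute ``isolated``.
    """
    if not significant:
        raise NetworkError("empty significant-metabolite list")
    if len(significant) < 2:
        raise NetworkError("need at least 2 significant metabolites")
    sub = table.subset(tissue) if tissue is not None else table
    missing = [m for m in significant if m not in sub.data.columns]
    if missing:
        raise NetworkError(f"significant metabolites not in table: {missing}")
    class_map = class_map if class_map is not None else load_class_map()

    graph = nx.Graph()
    for met in significant:
        graph.add_node(met, metabolite_class=class_map.get(met, "unclassified"))
    cols = {m: sub.data[m].to_numpy(dtype=float) for m in significant}
    for i, a in enumerate(significant):
        for b in significant[i + 1:]:
            r, n = _pairwise_pearson(cols[a], cols[b])
            if np.isnan(r):
                logger.warning("skipping pair (%s, %s): %d complete obs", a, b, n)
                continue
            if abs(r) > threshold:
                graph.add_edge(a, b, r=float(r))
    isolated = [n for n, d in graph.degree() if d == 0]
    graph.graph["isolated"] = isolated
    if not keep_isolated:
        graph.remove_nodes_from(isolated)
    if graph.number_of_nodes():
        for met, score in eigenvector_centrality(graph).items():
            graph.nodes[met]["centrality"] = score
    return graph


def eigenvector_centrality(graph: nx.Graph, tol: float = 1e-10,
                           max_iter: int = 100_000) -> dict[str, float]:
    """Power iteration on the |r|-weighted adjacency, per connected
    component, normalized so each component's maximum score is 1."""
    if graph.number_of_nodes() == 0:
        raise NetworkError("empty network")
    scores: dict[str, float] = {}
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            scores[nodes[0]] = 1.0
            continue
        index = {n: i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v, data in graph.subgraph(component).edges(data=True):
            w = abs(data.get("r", 1.0))
            A[index[u], index[v]] = w
            A[index[v], index[u]] = w
        # diagonal shift keeps the Perron eigenvector but makes the
        # iteration matrix primitive (plain power iteration oscillates on
        # bipartite graphs whose extreme eigenvalues tie in magnitude)
        shift = float(A.sum(axis=1).max()) or 1.0
        M = A + shift * np.eye(len(nodes))
        vec = np.ones(len(nodes)) / np.sqrt(len(nodes))
        for _ in range(max_iter):
            nxt = M @ vec
            norm = np.linalg.norm(nxt)
            if norm == 0:
                break
            nxt /= norm
            if np.abs(nxt - vec).max() < tol:
                vec = nxt
                break
            vec = nxt
        vec = np.abs(vec)
        vec /= vec.max()
        for n in nodes:
            scores[n] = float(vec[index[n]])
    return scores


def export_network(graph: nx.Graph, path) -> None:
    """GraphML with node attributes (class, centrality) and edge weight r."""
    out = nx.Graph()
    for n, data in graph.nodes(data=True):
        out.add_node(n, **{k: v for k, v in data.items()})
    for u, v, data in graph.edges(data=True):
        out.add_edge(u, v, r=float(data["r"]))
    nx.write_graphml(out, path)


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"met_a": u, "met_b": v, "r": data["r"]}
        for u, v, data in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["met_a", "met_b", "r"])
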