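"""Graph-theory feature extraction from FC matrices and window stacks.

Static features come from a proportionally thresholded positive-weight graph:
node strength, weighted clustering, local efficiency, characteristic path
length (largest component), global efficiency, and modularity Q. Dynamic
features are the mean and SD of the same metrics across sliding-window
graphs.

The implemented metric set is a documented superset choice; graph
construction uses proportional |z|-thresholding (default density 0.15) with
negative-weight edges dropped afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["GraphFeatureSet", "threshold_graph", "compute_metrics", "dynamic_metrics"]


@dataclass
class GraphFeatureSet:
    """Named per-node and global graph metrics with provenance."""

    node_metrics: pd.DataFrame  # index = node, columns = strength/clustering/local_efficiency
    global_metrics: dict[str, float]
    provenance: str = "static"  # static | dynamic-mean | dynamic-sd
    threshold: float = 1.0
    path_on_largest_component: bool = False

    def to_vector(self) -> pd.Series:
        """Flat feature vector: global metrics plus per-node metrics."""
        parts = {f"{self.provenance}.{k}": v for k, v in self.global_metrics.items()}
        for col in self.node_metrics.columns:
            for node, v in self.node_metrics[col].items():
                parts[f"{self.provenance}.{col}.{node}"] = v
        return pd.Series(parts)


def threshold_graph(values: np.ndarray, density: float) -> np.ndarray:
    """Keep the top ``density`` fraction of edges by |z|; drop negative weights.

    Ties at the cutoff are broken deterministically by (i, j) lexicographic
    order. Returns a symmetric weight matrix (zeros elsewhere).
    """
    A = np.asarray(values, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("matrix must be square")
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    iu, ju = np.triu_indices(n, k=1)
    m = len(iu)
    n_keep = int(density * m)
    if n_keep < 1:
        raise ValueError(f"density {density} keeps < 1 of {m} edges")
    mag = np.abs(A[iu, ju])
    # sort by magnitude desc, then (i, j) asc for deterministic tie-breaks
    order = np.lexsort((ju, iu, -mag))
    keep = order[:n_keep]
    out = np.zeros_like(A)
    for idx in keep:
        i, j = iu[idx], ju[idx]
        if A[i, j] > 0:
            out[i, j] = out[j, i] = A[i, j]
    return out


def _weighted_global_efficiency(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_dijkstra_path_length(G, weight="distance"):
        total += sum(1.0 / d for d in lengths.values() if d > 0)
    return total / (n * (n - 1))


def _local_efficiency(G: nx.Graph) -> dict:
    eff = {}
    for v in G.nodes:
        nbrs = list(G.neighbors(v))
        if len(nbrs) < 2:
            eff[v] = 0.0
        else:
            eff[v] = _weighted_global_efficiency(G.subgraph(nbrs))
    return eff


def compute_metrics(adj: np.ndarray, seed: int = 0, n_restarts: int = 10) -> GraphFeatureSet:
    """Static graph metrics from a symmetric nonnegative weight matrix.

    Shortest-path lengths use distance = 1/weight; the characteristic path
    length is computed on the largest connected component (flagged in the
    result when the graph is disconnected). Modularity is the best of
    ``n_restarts`` seeded Louvain runs.
    """
    A = np.asarray(adj, dtype=float)
    n = A.shape[0]
    if n == 0 or not np.any(A):
        raise ValueError("empty graph")
    G = nx.from_numpy_array(A)
    for _, _, d in G.edges(data=True):
        d["distance"] = 1.0 / d["weight"]

    strength = dict(G.degree(weight="weight"))
    clustering = nx.clustering(G, weight="weight")
    local_eff = _local_efficiency(G)

    components = list(nx.connected_components(G))
    largest = max(components, key=len)
    flagged = len(components) > 1
    H = G.subgraph(largest)
    nh = H.number_of_nodes()
    if nh > 1:
        total = 0.0
        for _, lengths in nx.all_pairs_dijkstra_path_length(H, weight="distance"):
            total += sum(d for d in lengths.values())
        cpl = total / (nh * (nh - 1))
    else:
        cpl = 0.0
    geff = _weighted_global_efficiency(G)

    best_q = -np.inf
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        q = nx.community.modularity(G, comms, weight="weight")
        if q > best_q:
            best_q = q
    node_metrics = pd.DataFrame(
        {
            "strength": pd.Series(strength),
            "clustering": pd.Series(clustering),
            "local_efficiency": pd.Series(local_eff),
        }
    ).sort_index()
    global_metrics = {
        "char_path_length": float(cpl),
        "global_efficiency": float(geff),
        "modularity": float(best_q),
    }
    return GraphFeatureSet(
        node_metrics=node_metrics,
        global_metrics=global_metrics,
        provenance="static",
        path_on_largest_component=flagged,
    )


def dynamic_metrics(
    window_stack: np.ndarray, density: float = 0.15, seed: int = 0, n_restarts: int = 3
) -> tuple[GraphFeatureSet, GraphFeatureSet]:
    """Mean and SD of per-window graph metrics.

    ``window_stack`` is (n_windows, n, n) of window-wise z matrices; each
    window is thresholded and measured with :func:`compute_metrics`, then
    every metric is summarized by its mean and population SD across windows.
    Returns (dynamic-mean feature set, dynamic-sd feature set).
    """
    stack = np.asarray(window_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("window_stack must be (n_windows >= 2, n, n)")
    per_window = []
    flagged = False
    for k in range(stack.shape[0]):
        fs = compute_metrics(threshold_graph(stack[k], density), seed=seed, n_restarts=n_restarts)
        flagged = flagged or fs.path_on_largest_component
        fs.provenance = ""
        vec = fs.to_vector()
        vec.index = [s.lstrip(".") for s in vec.index]
        per_window.append(vec)
    table = pd.DataFrame(per_window)
    mean_fs = _summary_featureset(table.mean(axis=0), "dyn_mean", density, flagged)
    sd_fs = _summary_featureset(table.std(axis=0, ddof=0), "dyn_sd", density, flagged)
    return mean_fs, sd_fs


def _summary_featureset(
    summary: pd.Series, provenance: str, density: float, flagged: bool
) -> GraphFeatureSet:
    global_keys = ["char_path_length", "global_efficiency", "modularity"]
    global_metrics = {k: float(summary[k]) for k in global_keys}
    node_rows: dict[str, dict] = {}
    for key, v in summary.items():
        if key in global_keys:
            continue
        metric, node = key.rsplit(".", 1)
        node_rows.setdefault(metric, {})[int(node)] = float(v)
    node_metrics = pd.DataFrame(node_rows).sort_index()
    return GraphFeatureSet(
        node_metrics=node_metrics,
        global_metrics=global_metrics,
        provenance=provenance,
        threshold=density,
        path_on_largest_component=flagged,
    )
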