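"""Pairwise cell-correlation assay and the thresholded network of correlating cells.

Each cell is described by 14 min-max-normalized features; the similarity of two
cells is their Pearson correlation across those features (population-style
standard deviations, i.e. dividing by 14).  Cells whose correlation reaches a
threshold are linked, producing a "network of correlating cells" whose
connected components group cells of similar geometry and local topology.
Empirically such correlations concentrate near 1 for confluent tissue — the
value is bounded above by 1 and high thresholds (≈0.99+) carve out the
informative structure; negative values are possible in principle but never
survive thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "normalize_cell_matrix",
    "corr_cells",
    "pairwise_edges",
    "build_correlation_network",
    "threshold_sweep",
    "polygon_assortment",
    "CorrelationGraph",
]


def normalize_cell_matrix(X: np.ndarray) -> np.ndarray:
    """Min-max scale each feature column to [0, 1]; constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in cell feature matrix")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros_like(X)
    ok = span > 0
    out[:, ok] = (X[:, ok] - lo[ok]) / span[ok]
    return out


def corr_cells(c1: np.ndarray, c2: np.ndarray) -> float:
    """Correlation of two cells across their 14 normalized features.

    Pearson's r with population standard deviations:
    sum((x - mean(x)) * (y - mean(y))) / (n * sigma_x * sigma_y).
    Self-correlation is exactly 1; any value is <= 1.
    """
    x = np.asarray(c1, dtype=float)
    y = np.asarray(c2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("cell vectors must be 1-D and of equal length")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate cell vector: zero variance across features")
    return float(((x - x.mean()) * (y - y.mean())).sum() / (len(x) * (sx * sy)))


def pairwise_edges(X: np.ndarray, threshold: float,
                   block: int = 512) -> list[tuple[int, int, float]]:
    """All pairs (i < j) with correlation >= threshold, computed in row blocks.

    Avoids materializing the full n x n correlation matrix for large cell sets.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0][:5]
        raise ValueError(f"degenerate cell vector(s) with zero variance: rows {bad}")
    Z = (X - mu) / (sd[:, None] * np.sqrt(X.shape[1]))
    edges: list[tuple[int, int, float]] = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        C = Z[start:stop] @ Z.T
        for bi in range(stop - start):
            i = start + bi
            js = np.nonzero(C[bi, i + 1:] >= threshold)[0] + i + 1
            for j in js:
                edges.append((i, int(j), float(C[bi, j])))
    return edges


@dataclass
class CorrelationGraph:
    """Thresholded network of correlating cells.

    Nodes are cell indices with attributes ``condition`` and ``n_sides``; an
    edge (i, j) is present iff Corr(i, j) >= threshold.
    """

    graph: nx.Graph
    threshold: float

    def component_sizes(self) -> list[int]:
        return sorted((len(c) for c in nx.connected_components(self.graph)),
                      reverse=True)

    @property
    def largest_component_size(self) -> int:
        sizes = self.component_sizes()
        return sizes[0] if sizes else 0

    def largest_component(self) -> nx.Graph:
        comp = max(nx.connected_components(self.graph), key=len)
        return self.graph.subgraph(comp).copy()


def build_correlation_network(
    X: np.ndarray,
    threshold: float,
    conditions: list[str] | None = None,
    n_sides: list[int] | None = None,
) -> CorrelationGraph:
    """Exhaustive pairwise correlation of normalized cell vectors, thresholded.

    ``X`` is (cells x 14), already normalized (see :func:`normalize_cell_matrix`).
    Isolated cells remain as degree-0 nodes.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 cells")
    G = nx.Graph()
    for i in range(len(X)):
        G.add_node(i,
                   condition=(conditions[i] if conditions is not None else ""),
                   n_sides=(int(n_sides[i]) if n_sides is not None else -1))
    for i, j, c in pairwise_edges(X, threshold):
        G.add_edge(i, j, corr=c)
    return CorrelationGraph(graph=G, threshold=float(threshold))


def threshold_sweep(
    X: np.ndarray,
    target_component_size: tuple[int, int],
    bracket: tuple[float, float] = (0.9, 1.0),
    max_iter: int = 40,
    conditions: list[str] | None = None,
    n_sides: list[int] | None = None,
) -> tuple[float, CorrelationGraph]:
    """Find a threshold whose largest component size lands in the target range.

    Uses bisection on the (non-increasing) largest-component size. Returns the
    threshold and the corresponding network; raises with the attainable range
    when the target cannot be reached inside the bracket.
    """
    lo_size, hi_size = target_component_size
    if lo_size > hi_size:
        raise ValueError("target range must satisfy lo <= hi")

    def size_at(t: float) -> tuple[int, CorrelationGraph]:
        g = build_correlation_network(X, t, conditions=conditions, n_sides=n_sides)
        return g.largest_component_size, g

    t_lo, t_hi = bracket  # size decreases from t_lo to t_hi
    s_lo, g_lo = size_at(t_lo)
    s_hi, g_hi = size_at(t_hi)
    if lo_size <= s_lo <= hi_size:
        return t_lo, g_lo
    if lo_size <= s_hi <= hi_size:
        return t_hi, g_hi
    if s_lo < lo_size or s_hi > hi_size:
        raise ValueError(
            f"target component size {target_component_size} unreachable in "
            f"bracket {bracket}: attainable sizes range [{s_hi}, {s_lo}]"
        )
    for _ in range(max_iter):
        t_mid = 0.5 * (t_lo + t_hi)
        s_mid, g_mid = size_at(t_mid)
        if lo_size <= s_mid <= hi_size:
            return t_mid, g_mid
        if s_mid > hi_size:
            t_lo = t_mid
        else:
            t_hi = t_mid
    raise ValueError(
        f"target component size {target_component_size} not hit after "
        f"{max_iter} bisection steps (component sizes jump over the range)"
    )


def polygon_assortment(
    g: CorrelationGraph, n_permutations: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Tendency of same-sided cells to be linked in the correlation network.

    Returns the fraction of edges joining cells of equal polygon class and a
    permutation p-value obtained by shuffling the class labels over nodes
    (add-one correction: p = (1 + #perm >= observed) / (n + 1)).
    """
    G = g.graph
    edges = list(G.edges())
    if len(edges) < 20:
        raise ValueError("need at least 20 edges for the assortment statistic")
    classes = nx.get_node_attributes(G, "n_sides")
    values = np.array([classes[n] for n in G.nodes()])
    if len(np.unique(values)) == 1:
        return {"same_class_edge_fraction": 1.0, "permutation_p": 1.0}
    nodes = list(G.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    eu = np.array([index[u] for u, _ in edges])
    ev = np.array([index[v] for _, v in edges])

    def frac(vals: np.ndarray) -> float:
        return float((vals[eu] == vals[ev]).mean())

    observed = frac(values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if frac(rng.permutation(values)) >= observed:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return {"same_class_edge_fraction": observed, "permutation_p": float(p)}
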