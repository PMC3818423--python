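"""Cell-contact graph construction and network characteristics.

Two cells are adjacent when a disc of radius ``r`` centred on the pixels of one
region reaches the other region, i.e. when the inter-region gap is at most
``r`` px.  The default r = 4 matches segmented membranes a few pixels thick;
the synthetic generator draws 1-px membranes, for which r = 2 already captures
every true contact.  Edge weights count the shared boundary pixels (background
pixels within reach of both regions) and feed only the node "strength"
(weighted degree); every path-based metric is computed on the unweighted graph.

Per-node metrics (strength, clustering coefficient, eccentricity, betweenness
centrality) are evaluated on the full graph — cells outside the region of
interest still contribute as neighbours — while the twelve whole-image metrics
are evaluated on the subgraph induced by the in-ROI nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .geometry import CellRecord
from .synthetic import LabelImage

__all__ = [
    "ContactGraph",
    "build_contact_graph",
    "polygon_class",
    "node_metrics",
    "global_metrics",
    "annotate_network_features",
    "image_feature_vector",
    "cell_feature_vector",
    "ImageFeatureVector",
    "FEATURE_NAMES",
    "CELL_FEATURE_NAMES",
    "write_graphml",
    "read_graphml",
]

logger = logging.getLogger(__name__)

#: Image-level characteristics, in canonical order (1-based indices 1..40).
FEATURE_NAMES: list[str] = [
    "Average Area",                                   # 1
    "S.D. Area",                                      # 2
    "Average Major Axis",                             # 3
    "Average Minor Axis",                             # 4
    "Average Relation Axis",                          # 5
    "S.D. Relation Axis",                             # 6
    "Average Convex Hull",                            # 7
    "S.D. Convex Hull",                               # 8
    "Average Neighbours",                             # 9
    "S.D. Neighbours",                                # 10
    "Average Relation Neighbours Area",               # 11
    "S.D. Relation Neighbours Area",                  # 12
    "Average Relation Neighbours Major Axis",         # 13
    "S.D. Relation Neighbours Major Axis",            # 14
    "Average Relation Neighbours Minor Axis",         # 15
    "S.D. Relation Neighbours Minor Axis",            # 16
    "Average Relation Neighbours Relation Axis",      # 17
    "S.D. Relation Neighbours Relation Axis",         # 18
    "Average Relation Neighbours Convex Hull",        # 19
    "S.D. Relation Neighbours Convex Hull",           # 20
    "Average Strength",                               # 21
    "S.D. Strength",                                  # 22
    "Average Clustering Coefficient",                 # 23
    "S.D. Clustering Coefficient",                    # 24
    "Average Eccentricity",                           # 25
    "S.D. Eccentricity",                              # 26
    "Average Betweenness Centrality",                 # 27
    "S.D. Betweenness Centrality",                    # 28
    "Average Shortest Path Length",                   # 29
    "S.D. Shortest Path Length",                      # 30
    "Radius",                                         # 31
    "Diameter",                                       # 32
    "Efficiency",                                     # 33
    "Pearson Correlation",                            # 34
    "Algebraic Connectivity",                         # 35
    "S Metric",                                       # 36
    "Assortativity",                                  # 37
    "Density",                                        # 38
    "Transitivity",                                   # 39
    "Modularity",                                     # 40
]

#: The 14 per-cell characteristics used by the cell-correlation assay.
CELL_FEATURE_NAMES: list[str] = [
    "area", "major_axis", "minor_axis", "relation_axis", "convex_hull_ratio",
    "rel_neigh_area", "rel_neigh_major", "rel_neigh_minor",
    "rel_neigh_relation_axis", "rel_neigh_convex_hull",
    "strength", "clustering", "eccentricity", "betweenness",
]


@dataclass
class ContactGraph:
    """Cell-adjacency graph.

    ``graph`` is an undirected networkx graph whose nodes are cell ids with
    attributes ``centroid`` ((row, col)), ``in_roi`` (bool) and, once
    assigned, ``n_sides``; edges carry ``weight`` = shared boundary pixel
    count. ``r`` is the neighbour-detection radius in pixels.
    """

    graph: nx.Graph
    r: float = 4.0

    def neighbors(self, cell_id: int) -> list[int]:
        if cell_id not in self.graph:
            raise KeyError(f"cell {cell_id} not in contact graph")
        return list(self.graph.neighbors(cell_id))

    def roi_subgraph(self) -> nx.Graph:
        nodes = [n for n, d in self.graph.nodes(data=True) if d.get("in_roi")]
        return self.graph.subgraph(nodes).copy()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def build_contact_graph(image: LabelImage, r: float = 4.0) -> ContactGraph:
    """Build the contact graph of a label image with neighbour radius ``r``.

    Cells i and j are linked iff the dilation of region i by a disc of radius
    r overlaps region j (single-disc rule: gaps up to r px are bridged). The
    edge weight counts background pixels reachable from both regions. Isolated
    cells are kept as degree-0 nodes and logged.
    """
    labels = image.labels
    n = int(labels.max())
    if n < 1:
        raise ValueError("no cells: label image is empty")
    selem = disk(int(round(r)))
    pad = int(round(r)) + 1
    h, w = labels.shape

    slices = ndimage.find_objects(labels)
    dilated: dict[int, tuple[tuple[slice, slice], np.ndarray]] = {}
    G = nx.Graph()
    roi_label_set = set(int(v) for v in image.roi_labels())
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    for k in range(1, n + 1):
        sl = slices[k - 1]
        if sl is None:
            raise ValueError(f"label {k} missing from image")
        esl = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)),
        )
        mask = labels[esl] == k
        dil = ndimage.binary_dilation(mask, structure=selem)
        dilated[k] = (esl, dil)
        G.add_node(k, centroid=tuple(map(float, centroids[k - 1])),
                   in_roi=(k in roi_label_set))

    # adjacency: dilated region overlaps another region
    for k in range(1, n + 1):
        esl, dil = dilated[k]
        touched = np.unique(labels[esl][dil])
        for j in touched:
            j = int(j)
            if j > k:
                G.add_edge(k, j)

    # weights: background pixels within reach of both regions
    bg = labels == 0
    for i, j in G.edges():
        sli, di = dilated[i]
        slj, dj = dilated[j]
        rs = slice(max(sli[0].start, slj[0].start), min(sli[0].stop, slj[0].stop))
        cs = slice(max(sli[1].start, slj[1].start), min(sli[1].stop, slj[1].stop))
        if rs.start >= rs.stop or cs.start >= cs.stop:
            G.edges[i, j]["weight"] = 0.0
            continue
        di_c = di[rs.start - sli[0].start:rs.stop - sli[0].start,
                  cs.start - sli[1].start:cs.stop - sli[1].start]
        dj_c = dj[rs.start - slj[0].start:rs.stop - slj[0].start,
                  cs.start - slj[1].start:cs.stop - slj[1].start]
        overlap = di_c & dj_c & bg[rs, cs]
        G.edges[i, j]["weight"] = float(overlap.sum())

    isolated = [k for k in G.nodes if G.degree(k) == 0]
    if isolated:
        logger.warning("contact graph has %d isolated cell(s): %s",
                       len(isolated), isolated[:10])
    return ContactGraph(graph=G, r=float(r))


def polygon_class(graph: ContactGraph, cell_id: int) -> int:
    """Number of sides of a cell = its number of contact-graph neighbours."""
    if cell_id not in graph.graph:
        raise KeyError(f"cell {cell_id} not in contact graph")
    return int(graph.graph.degree(cell_id))


def node_metrics(graph: ContactGraph) -> dict[int, dict[str, float]]:
    """Per-node strength, clustering, eccentricity and betweenness.

    Strength sums incident edge weights; the other three are computed on the
    unweighted graph.  Betweenness is normalized by (n-1)(n-2)/2.  Eccentricity
    is evaluated within each node's connected component; a disconnected graph
    is logged.
    """
    G = graph.graph
    n = G.number_of_nodes()
    if n < 3:
        raise ValueError("betweenness undefined for graphs with fewer than 3 nodes")
    strength = dict(G.degree(weight="weight"))
    clustering = nx.clustering(G)
    betweenness = nx.betweenness_centrality(G, normalized=True)
    eccentricity: dict[int, int] = {}
    components = list(nx.connected_components(G))
    if len(components) > 1:
        logger.warning("contact graph is disconnected (%d components); "
                       "eccentricity computed per component", len(components))
    for comp in components:
        sub = G.subgraph(comp)
        if len(comp) == 1:
            eccentricity[next(iter(comp))] = 0
        else:
            eccentricity.update(nx.eccentricity(sub))
    return {
        k: {
            "strength": float(strength[k]),
            "clustering": float(clustering[k]),
            "eccentricity": float(eccentricity[k]),
            "betweenness": float(betweenness[k]),
        }
        for k in G.nodes
    }


def _degree_pearson(G: nx.Graph) -> float:
    """Pearson correlation of end-point degrees over edges; 0 for regular graphs."""
    deg = dict(G.degree())
    x, y = [], []
    for u, v in G.edges():
        x.extend([deg[u], deg[v]])
        y.extend([deg[v], deg[u]])
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def global_metrics(graph: ContactGraph) -> dict[str, float]:
    """The twelve whole-image network characteristics, on the in-ROI subgraph.

    A disconnected in-ROI subgraph falls back to its largest component (with a
    logged warning). Degenerate degree-correlation cases (regular graphs)
    return 0 by convention so that feature vectors stay finite.
    """
    sub = graph.roi_subgraph()
    if sub.number_of_nodes() < 3:
        raise ValueError("need at least 3 in-ROI cells for whole-image metrics")
    if not nx.is_connected(sub):
        comps = sorted(nx.connected_components(sub), key=len, reverse=True)
        logger.warning("in-ROI subgraph disconnected (%d components); using "
                       "largest with %d nodes", len(comps), len(comps[0]))
        sub = sub.subgraph(comps[0]).copy()

    # all-pairs unweighted shortest-path lengths (each unordered pair once)
    plens = []
    nodes_sorted = sorted(sub.nodes)
    index = {v: i for i, v in enumerate(nodes_sorted)}
    for u, dists in nx.all_pairs_shortest_path_length(sub):
        iu = index[u]
        for v, d in dists.items():
            if index[v] > iu:
                plens.append(d)
    plens = np.asarray(plens, dtype=float)

    ecc = nx.eccentricity(sub)
    lap = nx.laplacian_matrix(sub).toarray().astype(float)
    lap_eigs = np.linalg.eigvalsh(lap)
    deg = dict(sub.degree())
    s_metric = float(sum(deg[u] * deg[v] for u, v in sub.edges()))

    try:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assort = float(nx.degree_assortativity_coefficient(sub))
        if not np.isfinite(assort):
            assort = 0.0
    except Exception:
        assort = 0.0

    # node order affects greedy merge tie-breaks; iterate in centroid order so
    # the partition is invariant to cell relabeling
    def _node_key(v):
        d = sub.nodes[v]
        return d.get("centroid", (0.0, 0.0))

    rank = {v: i for i, v in enumerate(sorted(sub.nodes, key=_node_key))}
    canon = nx.Graph()
    canon.add_nodes_from(sorted(rank.values()))
    canon.add_edges_from(sorted((min(rank[u], rank[v]), max(rank[u], rank[v]))
                                for u, v in sub.edges))
    communities = nx.algorithms.community.greedy_modularity_communities(canon)
    modularity = float(nx.algorithms.community.modularity(canon, communities,
                                                          weight=None))

    return {
        "avg_path_length": float(plens.mean()),
        "sd_path_length": float(plens.std(ddof=1)) if len(plens) > 1 else 0.0,
        "radius": float(min(ecc.values())),
        "diameter": float(max(ecc.values())),
        "efficiency": float(nx.global_efficiency(sub)),
        "degree_pearson": _degree_pearson(sub),
        "algebraic_connectivity": float(lap_eigs[1]),
        "s_metric": s_metric,
        "assortativity": assort,
        "density": float(nx.density(sub)),
        "transitivity": float(nx.transitivity(sub)),
        "modularity": modularity,
    }


def annotate_network_features(cells: list[CellRecord], graph: ContactGraph) -> list[CellRecord]:
    """Set n_sides and the four per-node metrics on each cell record."""
    metrics = node_metrics(graph)
    for cell in cells:
        m = metrics[cell.cell_id]
        cell.n_sides = polygon_class(graph, cell.cell_id)
        cell.strength = m["strength"]
        cell.clustering = m["clustering"]
        cell.eccentricity = m["eccentricity"]
        cell.betweenness = m["betweenness"]
        graph.graph.nodes[cell.cell_id]["n_sides"] = cell.n_sides
    return cells


@dataclass
class ImageFeatureVector:
    """The 40 image-level characteristics of one image, in canonical order."""

    values: np.ndarray
    image_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (40,):
            raise ValueError("image feature vector must have exactly 40 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image feature vector contains non-finite entries")


def _require(values: np.ndarray, what: str) -> np.ndarray:
    if np.any(~np.isfinite(values)):
        raise ValueError(f"unset feature: {what} missing for some in-ROI cells")
    return values


def image_feature_vector(
    cells: list[CellRecord], graph: ContactGraph,
    image_id: str = "", condition: str = "",
) -> ImageFeatureVector:
    """Assemble the 40-entry image vector.

    Entries 1–28 are averages and standard deviations (sample s.d., ddof=1)
    over the in-ROI cells of the per-cell quantities; entries 29–40 are the
    whole-image network metrics of the in-ROI subgraph.
    """
    roi = [c for c in cells if c.in_roi]
    if not roi:
        raise ValueError("no in-ROI cells")

    def col(attr: str) -> np.ndarray:
        return _require(np.array([getattr(c, attr) for c in roi], dtype=float), attr)

    if any(c.n_sides < 0 for c in roi):
        raise ValueError("unset feature: n_sides; run annotate_network_features first")
    nsides = np.array([c.n_sides for c in roi], dtype=float)

    def sd(a: np.ndarray) -> float:
        return float(a.std(ddof=1)) if len(a) > 1 else 0.0

    gm = global_metrics(graph)
    area = col("area"); major = col("major_axis"); minor = col("minor_axis")
    relax = col("relation_axis"); chull = col("convex_hull_ratio")
    values = [
        area.mean(), sd(area),
        major.mean(), minor.mean(),
        relax.mean(), sd(relax),
        chull.mean(), sd(chull),
        nsides.mean(), sd(nsides),
    ]
    for attr in ("rel_neigh_area", "rel_neigh_major", "rel_neigh_minor",
                 "rel_neigh_relation_axis", "rel_neigh_convex_hull",
                 "strength", "clustering", "eccentricity", "betweenness"):
        a = col(attr)
        values.extend([a.mean(), sd(a)])
    values.extend([
        gm["avg_path_length"], gm["sd_path_length"], gm["radius"], gm["diameter"],
        gm["efficiency"], gm["degree_pearson"], gm["algebraic_connectivity"],
        gm["s_metric"], gm["assortativity"], gm["density"], gm["transitivity"],
        gm["modularity"],
    ])
    return ImageFeatureVector(values=np.asarray(values), image_id=image_id,
                              condition=condition)


def cell_feature_vector(cell: CellRecord) -> np.ndarray:
    """The ordered 14-entry per-cell vector used by the correlation assay."""
    vec = np.array([getattr(cell, name) for name in CELL_FEATURE_NAMES], dtype=float)
    if np.any(~np.isfinite(vec)):
        raise ValueError(f"cell {cell.cell_id} has unset features")
    return vec


# ---------------------------------------------------------------------------
# GraphML I/O
# ---------------------------------------------------------------------------

def write_graphml(graph: ContactGraph, path) -> None:
    G = nx.Graph()
    G.graph["r"] = graph.r
    for node, d in graph.graph.nodes(data=True):
        G.add_node(node, centroid_row=float(d["centroid"][0]),
                   centroid_col=float(d["centroid"][1]),
                   in_roi=bool(d.get("in_roi", False)),
                   n_sides=int(d.get("n_sides", -1)))
    for u, v, d in graph.graph.edges(data=True):
        G.add_edge(u, v, weight=float(d.get("weight", 1.0)))
    nx.write_graphml(G, path)


def read_graphml(path) -> ContactGraph:
    raw = nx.read_graphml(path)
    G = nx.Graph()
    for node, d in raw.nodes(data=True):
        G.add_node(int(node), centroid=(float(d["centroid_row"]), float(d["centroid_col"])),
                   in_roi=bool(d["in_roi"]), n_sides=int(d.get("n_sides", -1)))
    for u, v, d in raw.edges(data=True):
        G.add_edge(int(u), int(v), weight=float(d.get("weight", 1.0)))
    return ContactGraph(graph=G, r=float(raw.graph.get("r", 4.0)))
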