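import numpy as np
import pytest

from epitopo import synthetic
from epitopo.model import extract_image


@pytest.fixture(scope="session")
def honeycomb():
    """Rasterized honeycomb: Voronoi of a regular hexagonal lattice.

    The ROI is restricted to deep-interior cells (all of whose contact
    neighbours are themselves complete, unclipped hexagons), so homogeneity
    assertions are not polluted by frame-clipped boundary cells.
    """
    pts = synthetic.hexagonal_lattice_points((260, 260), 26.0)
    img = synthetic.mosaic_from_points(pts, (260, 260), image_id="honeycomb")
    from epitopo.contacts import build_contact_graph

    g = build_contact_graph(img, r=2)
    roi_ids = set(int(v) for v in img.roi_labels())
    deep = [k for k in roi_ids
            if all(j in roi_ids for j in g.neighbors(k))]
    img.roi_mask = np.isin(img.labels, deep) & (img.labels > 0)
    return img


@pytest.fixture(scope="session")
def small_mosaic():
    spec = synthetic.MosaicSpec(n_cells=120, image_size=(176, 176),
                                lloyd_iterations=2, seed=3)
    return synthetic.generate_mosaic(spec, condition="A", image_id="small")


@pytest.fixture(scope="session")
def small_extracted(small_mosaic):
    """(cells, graph, image vector, polygon distribution) of the small mosaic."""
    return extract_image(small_mosaic, r=4)


@pytest.fixture()
def table_factory():
    """Random two-group feature tables with optional planted group shifts."""

    def make(seed=0, n_a=15, n_b=16, n_features=40, planted=(), delta=3.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_a + n_b, n_features))
        for f in planted:
            X[:n_a, f] += delta
        from epitopo.selection import FeatureTable, normalize

        t = FeatureTable(
            X,
            [f"img{i}" for i in range(n_a + n_b)],
            ["A"] * n_a + ["B"] * n_b,
            feature_names=[f"f{i}" for i in range(n_features)],
        )
        return normalize(t)

    return make
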