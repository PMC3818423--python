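"""End-to-end pipeline: generate/load images -> features -> networks -> statistics.

All stages write plain, re-readable artifacts (CSV, GraphML, JSON) plus a
manifest echoing every parameter and seed, so a run is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import contacts, correlation, geometry, polygons, selection, synthetic
from .model import EpitheliumComparison, extract_image

__all__ = ["RunConfig", "run_pipeline", "read_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``image_prefixes`` (paths to saved label images) or the synthetic
    pair parameters must be given. ``threshold`` or ``component_range`` guides
    the correlation-network stage; ``max_corr_cells`` caps the pairwise assay.
    """

    out_dir: str = "epitopo_out"
    image_prefixes: list[str] = field(default_factory=list)
    n_images_a: int = 15
    n_images_b: int = 16
    n_cells: int = 515
    image_size: tuple[int, int] = (512, 512)
    lloyd_iterations: int = 3
    polygon_shift_a: float = 0.0
    polygon_shift_b: float = 0.15
    r: float = 4.0
    threshold: float | None = None
    component_range: tuple[int, int] | None = None
    max_corr_cells: int = 2000
    n_loops: int = 4000
    seed: int = 0
    write_images: bool = False


def read_config(path) -> RunConfig:
    """Parse a plain ``key = value`` config file (one assignment per line,
    '#' comments); values are JSON-parsed where possible."""
    cfg = RunConfig()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, raw = (t.strip() for t in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            try:
                value = json.loads(raw)
            except json.JSONDecodeError:
                value = raw
            current = getattr(cfg, key)
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(cfg, key, value)
    return cfg


def _load_or_generate(cfg: RunConfig) -> list[synthetic.LabelImage]:
    if cfg.image_prefixes:
        return [synthetic.load_label_image(p) for p in cfg.image_prefixes]
    specA = synthetic.MosaicSpec(
        n_cells=cfg.n_cells, image_size=tuple(cfg.image_size),
        lloyd_iterations=cfg.lloyd_iterations, polygon_shift=cfg.polygon_shift_a)
    specB = dataclasses.replace(specA, polygon_shift=cfg.polygon_shift_b)
    return synthetic.generate_condition_pair(
        specA, specB, cfg.n_images_a, cfg.n_images_b, seed=cfg.seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns a result summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("epitopo")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    images = _load_or_generate(cfg)
    logger.info("analyzing %d images", len(images))

    vectors, dists, all_cells = [], [], []
    for i, img in enumerate(images):
        if not img.image_id:
            img.image_id = f"img{i + 1}"
        cells, graph, vec, dist = extract_image(img, r=cfg.r)
        vectors.append(vec)
        dists.append(dist)
        all_cells.append((img, cells))
        contacts.write_graphml(graph, out / f"{img.image_id}.graphml")
        geometry.write_cell_table(cells, out / f"{img.image_id}_cells.csv")
        if cfg.write_images:
            synthetic.save_label_image(img, out / img.image_id)

    table = selection.FeatureTable.from_images(vectors)
    table.to_csv(out / "features.csv")
    polygons.write_distributions(dists, out / "polygons.csv")

    model = EpitheliumComparison(table, dists)
    results = model.fit(n_random=cfg.n_loops, seed=cfg.seed)
    if results.manova is not None:
        polygons.write_manova_report(results.manova, out / "manova.json")
    results.selection.to_json(out / "selection.json")
    if results.randomization is not None:
        results.randomization.to_dataframe().to_csv(
            out / "randomization.csv", index=False)

    # correlation assay on a capped pool of in-ROI cells
    rng = np.random.default_rng(cfg.seed)
    X_rows, conds, sides = [], [], []
    for img, cells in all_cells:
        for c in cells:
            if c.in_roi:
                X_rows.append(contacts.cell_feature_vector(c))
                conds.append(img.condition)
                sides.append(c.n_sides)
    X = np.vstack(X_rows)
    if len(X) > cfg.max_corr_cells:
        keep = rng.choice(len(X), size=cfg.max_corr_cells, replace=False)
        keep.sort()
        X = X[keep]
        conds = [conds[i] for i in keep]
        sides = [sides[i] for i in keep]
    Xn = correlation.normalize_cell_matrix(X)
    if cfg.threshold is not None:
        cg = correlation.build_correlation_network(
            Xn, cfg.threshold, conditions=conds, n_sides=sides)
        threshold = cfg.threshold
    else:
        lo, hi = cfg.component_range or (max(len(X) // 10, 10), max(len(X) // 2, 20))
        threshold, cg = correlation.threshold_sweep(
            Xn, (lo, hi), conditions=conds, n_sides=sides)
    import networkx as nx
    nx.write_graphml(cg.graph, out / "correlation_network.graphml")
    assort = None
    if cg.graph.number_of_edges() >= 20:
        assort = correlation.polygon_assortment(cg, seed=cfg.seed)

    summary = {
        "n_images": len(images),
        "n_cells_total": int(sum(len(c) for _, c in all_cells)),
        "selected_features": list(results.selected_features),
        "descriptor": results.descriptor,
        "manova": results.manova,
        "correlation_threshold": float(threshold),
        "correlation_largest_component": cg.largest_component_size,
        "polygon_assortment": assort,
    }
    if results.randomization is not None:
        summary["descriptor_percentile"] = results.randomization.descriptor_percentile
    manifest = {"config": dataclasses.asdict(cfg), "summary_file": "summary.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("pipeline complete: %s", summary)
    return summary
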