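"""Model/results interface for two-condition epithelial comparisons.

`EpitheliumComparison` bundles the full analysis of two groups of segmented
images: the 40-characteristic table, the per-image polygon distributions, the
beam-search feature selection with its separation descriptor, the polygon
MANOVA, and (optionally) the group-label randomization null.  `fit()` returns
an `EpitheliumComparisonResults` carrying estimates and diagnostics, with a
statsmodels-flavoured `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import contacts, geometry, polygons, selection
from .synthetic import LabelImage

__all__ = ["EpitheliumComparison", "EpitheliumComparisonResults", "extract_image"]


def extract_image(image: LabelImage, r: float = 4.0):
    """Run the per-image pipeline: cells, contact graph, features, polygons.

    Returns (cells, graph, image_feature_vector, polygon_distribution).
    """
    cells = geometry.extract_cells(image)
    graph = contacts.build_contact_graph(image, r=r)
    contacts.annotate_network_features(cells, graph)
    geometry.fill_neighbor_relations(cells, graph)
    vec = contacts.image_feature_vector(cells, graph, image_id=image.image_id,
                                        condition=image.condition)
    dist = polygons.polygon_distribution(graph, image_id=image.image_id,
                                         condition=image.condition)
    return cells, graph, vec, dist


class EpitheliumComparison:
    """Two-condition comparison of epithelial organization.

    Parameters
    ----------
    table:
        Images x 40 feature table with two condition labels (raw or
        normalized; normalization is applied at fit time if needed).
    distributions:
        Optional per-image polygon distributions aligned with the table rows;
        required for the MANOVA part of the analysis.
    """

    def __init__(self, table: selection.FeatureTable,
                 distributions: list[polygons.PolygonDistribution] | None = None):
        if distributions is not None and len(distributions) != len(table.image_ids):
            raise ValueError("distributions must align with the table rows")
        self.table = table
        self.distributions = distributions

    @classmethod
    def from_images(cls, images: list[LabelImage], r: float = 4.0) -> "EpitheliumComparison":
        """Build the model by extracting features from segmented label images."""
        vectors, dists = [], []
        for img in images:
            _, _, vec, dist = extract_image(img, r=r)
            vectors.append(vec)
            dists.append(dist)
        return cls(selection.FeatureTable.from_images(vectors), dists)

    @classmethod
    def from_dataframe(cls, df, id_col: str = "image_id",
                       condition_col: str = "condition") -> "EpitheliumComparison":
        return cls(selection.FeatureTable.from_dataframe(df, id_col=id_col,
                                                         condition_col=condition_col))

    def fit(self, n_random: int = 0, seed: int = 0) -> "EpitheliumComparisonResults":
        """Run selection, MANOVA and (if n_random > 0) the randomization null."""
        table = self.table if self.table.normalized else selection.normalize(self.table)
        sel = selection.select_features(table)
        scores = selection.pca_project(table, [i - 1 for i in sel.selected])
        maskA, maskB, names = table.group_masks()
        desc = selection.pca_descriptor(scores, np.asarray(table.conditions))
        manova = None
        if self.distributions is not None:
            gA = [d for d, m in zip(self.distributions, maskA) if m]
            gB = [d for d, m in zip(self.distributions, maskB) if m]
            if min(len(gA), len(gB)) >= 6:
                manova = polygons.manova_polygons(gA, gB)
            else:
                import logging
                logging.getLogger(__name__).warning(
                    "groups of %d/%d too small for the 5-variate MANOVA; skipped",
                    len(gA), len(gB))
        randomization = None
        if n_random > 0:
            randomization = selection.randomize_groups(
                table, n_random, seed=seed, distributions=self.distributions)
        return EpitheliumComparisonResults(
            model=self, table=table, selection=sel, descriptor_detail=desc,
            manova=manova, randomization=randomization, group_names=names)


@dataclass
class EpitheliumComparisonResults:
    """Fitted results of an :class:`EpitheliumComparison`."""

    model: EpitheliumComparison
    table: selection.FeatureTable
    selection: selection.SelectionResult
    descriptor_detail: selection.DescriptorResult
    manova: dict | None
    randomization: selection.RandomizationResult | None
    group_names: tuple[str, str]

    @property
    def selected_features(self) -> tuple[int, ...]:
        return self.selection.selected

    @property
    def descriptor(self) -> float:
        return self.selection.descriptor

    @property
    def pc_scores(self) -> np.ndarray:
        return self.descriptor_detail.pc_scores

    def summary(self) -> str:
        lines = []
        a, b = self.group_names
        nA = sum(1 for c in self.table.conditions if c == a)
        nB = len(self.table.conditions) - nA
        lines.append("Epithelium comparison results")
        lines.append("=" * 60)
        lines.append(f"Groups:              {a} (n={nA}) vs {b} (n={nB})")
        lines.append(f"Features available:  {self.table.values.shape[1]}")
        lines.append(f"Selected subset:     {list(self.selected_features)}")
        for i in self.selected_features:
            lines.append(f"    {i:>3}  {self.selection.feature_names[i - 1]}")
        lines.append(f"Separation descriptor (trace B / trace W): {self.descriptor:.4f}")
        if self.manova is not None:
            m = self.manova
            lines.append("Polygon-distribution MANOVA (classes 4-8):")
            lines.append(
                f"    Wilks' lambda = {m['wilks_lambda']:.4f}, "
                f"F({m['df1']:.0f}, {m['df2']:.0f}) = {m['F']:.3f}, p = {m['p']:.4f}"
            )
        if self.randomization is not None:
            r = self.randomization
            lines.append(f"Randomization null ({r.n_loops} loops):")
            lines.append(
                f"    descriptor percentile = {r.descriptor_percentile:.1f}%"
                f" ({int((r.loop_descriptors > r.real_descriptor).sum())} loops higher)"
            )
            if not np.isnan(r.real_manova_p):
                lines.append(f"    MANOVA-p percentile  = {r.manova_percentile:.1f}%")
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of the 2-D PC scores coloured by condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = np.asarray(self.table.conditions)
        for name, color in zip(self.group_names, ("tab:green", "tab:red")):
            pts = self.pc_scores[labels == name]
            ax.scatter(pts[:, 0], pts[:, 1], label=name, color=color)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        ax.set_title(f"descriptor = {self.descriptor:.3f}")
        return ax
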