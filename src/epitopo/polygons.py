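"""Polygon-class distributions and the two-group MANOVA comparison.

The polygon class of a cell is its number of contact-graph neighbours.
Proliferating epithelia show a stereotyped distribution (roughly 3% tetragons,
28% pentagons, 46% hexagons, 20% heptagons); here two groups of images are
compared by a one-way MANOVA on the per-image frequency vectors of classes
4–8.  Classes 3, 9 and 10 are discarded because they are not present in every
image (their zero-inflated columns would degrade the within-group covariance).

Wilks' lambda is used as the test statistic, with Rao's F approximation; for a
two-group design all four classical MANOVA statistics coincide.  Frequencies
enter untransformed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.manova import MANOVA

from .contacts import ContactGraph

__all__ = [
    "PolygonDistribution",
    "polygon_distribution",
    "manova_polygons",
    "distributions_to_dataframe",
    "write_distributions",
    "read_distributions",
    "MANOVA_CLASSES",
]

logger = logging.getLogger(__name__)

#: side classes recorded per image
ALL_CLASSES = tuple(range(3, 11))
#: side classes entering the MANOVA (3, 9, 10 discarded: absent in some images)
MANOVA_CLASSES = (4, 5, 6, 7, 8)


@dataclass
class PolygonDistribution:
    """Per-image polygon-class counts and frequencies over in-ROI cells."""

    counts: dict[int, int]
    frequencies: dict[int, float] = field(default_factory=dict)
    image_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("polygon distribution needs at least one cell")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if not self.frequencies:
            self.frequencies = {k: v / total for k, v in self.counts.items()}
        s = sum(self.frequencies.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {s}, not 1")

    def frequency(self, side_class: int) -> float:
        return self.frequencies.get(side_class, 0.0)


def polygon_distribution(
    graph: ContactGraph, image_id: str = "", condition: str = ""
) -> PolygonDistribution:
    """Polygon-class frequencies of the in-ROI cells of one contact graph.

    Cells with fewer than 3 or more than 10 neighbours (segmentation oddities)
    are excluded, with a logged warning.
    """
    G = graph.graph
    roi_nodes = [n for n, d in G.nodes(data=True) if d.get("in_roi")]
    if not roi_nodes:
        raise ValueError("no in-ROI cells in contact graph")
    degrees = np.array([G.degree(n) for n in roi_nodes])
    out_of_range = (degrees < ALL_CLASSES[0]) | (degrees > ALL_CLASSES[-1])
    if out_of_range.any():
        logger.warning("%d cell(s) with side count outside %s excluded",
                       int(out_of_range.sum()), (ALL_CLASSES[0], ALL_CLASSES[-1]))
        degrees = degrees[~out_of_range]
    if len(degrees) == 0:
        raise ValueError("no in-ROI cells with a valid side count")
    counts = {k: int((degrees == k).sum()) for k in ALL_CLASSES if (degrees == k).any()}
    return PolygonDistribution(counts=counts, image_id=image_id, condition=condition)


def _frequency_matrix(
    dists: list[PolygonDistribution], classes: tuple[int, ...]
) -> np.ndarray:
    return np.array([[d.frequency(k) for k in classes] for d in dists], dtype=float)


def manova_polygons(
    groupA: list[PolygonDistribution],
    groupB: list[PolygonDistribution],
    classes: tuple[int, ...] = MANOVA_CLASSES,
    min_group: int = 6,
) -> dict[str, float]:
    """One-way two-group MANOVA on per-image polygon-class frequencies.

    Returns Wilks' lambda, its Rao F approximation, the numerator/denominator
    degrees of freedom and the p-value; ``different`` is True iff p < 0.05.
    """
    if len(groupA) < min_group or len(groupB) < min_group:
        raise ValueError(
            f"each group needs >= {min_group} images for a {len(classes)}-variate MANOVA"
        )
    Y = np.vstack([_frequency_matrix(groupA, classes),
                   _frequency_matrix(groupB, classes)])
    g = np.concatenate([np.zeros(len(groupA)), np.ones(len(groupB))])
    n, p = Y.shape
    if np.allclose(Y[g == 0].mean(axis=0), Y[g == 1].mean(axis=0),
                   rtol=0, atol=1e-14):
        # exactly coincident group means: no between-group scatter
        return {"wilks_lambda": 1.0, "F": 0.0, "df1": float(p),
                "df2": float(n - p - 1), "p": 1.0, "different": False}
    exog = np.column_stack([np.ones_like(g), g])
    try:
        mv = MANOVA(Y, exog)
        res = mv.mv_test(hypotheses=[("group", np.array([[0.0, 1.0]]), None)])
    except Exception as exc:  # singular within-group covariance
        raise ValueError(
            "MANOVA failed (singular within-group covariance?); consider "
            f"pooling polygon classes: {exc}"
        ) from exc
    stat = res.results["group"]["stat"]
    row = stat.loc["Wilks' lambda"]
    out = {
        "wilks_lambda": float(row["Value"]),
        "F": float(row["F Value"]),
        "df1": float(row["Num DF"]),
        "df2": float(row["Den DF"]),
        "p": float(row["Pr > F"]),
    }
    out["different"] = bool(out["p"] < 0.05)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def distributions_to_dataframe(dists: list[PolygonDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        row = {"image_id": d.image_id, "condition": d.condition}
        for k in ALL_CLASSES:
            row[f"freq_{k}"] = d.frequency(k)
            row[f"count_{k}"] = d.counts.get(k, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_distributions(dists: list[PolygonDistribution], path) -> None:
    distributions_to_dataframe(dists).to_csv(path, index=False)


def read_distributions(path) -> list[PolygonDistribution]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        counts = {k: int(row[f"count_{k}"]) for k in ALL_CLASSES
                  if int(row[f"count_{k}"]) > 0}
        out.append(PolygonDistribution(counts=counts,
                                       image_id=str(row["image_id"]),
                                       condition=str(row["condition"])))
    return out


def write_manova_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
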