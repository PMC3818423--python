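"""Per-cell geometric features and neighbour-relation ratios.

Geometric quantities follow the standard regionprops conventions: axis lengths
are those of the ellipse with the same normalized second central moments as the
region, and the convex-hull ratio is region area divided by convex-hull area
(solidity), equal to 1 for convex cells with smooth, straight sides.

The "relation neighbours" family expresses how a cell compares with its direct
contacts: for a base feature f, rel_neigh_f = f(cell) / mean(f over contact-graph
neighbours). Homogeneous tissue gives ratios of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from skimage import measure

if TYPE_CHECKING:  # pragma: no cover
    from .contacts import ContactGraph
    from .synthetic import LabelImage

__all__ = ["CellRecord", "extract_cells", "fill_neighbor_relations",
           "cells_to_dataframe", "write_cell_table", "read_cell_table"]

_REL_BASES = ("area", "major_axis", "minor_axis", "relation_axis", "convex_hull_ratio")


@dataclass
class CellRecord:
    """Geometric and per-node network features of one cell.

    Fields in the second block (rel_neigh_*) are filled by
    :func:`fill_neighbor_relations`; the network block (n_sides, strength,
    clustering, eccentricity, betweenness) by the contact-network module.
    Unset fields are NaN (or -1 for n_sides).
    """

    cell_id: int
    centroid: tuple[float, float]
    in_roi: bool
    area: float
    major_axis: float
    minor_axis: float
    relation_axis: float
    convex_hull_ratio: float
    rel_neigh_area: float = field(default=np.nan)
    rel_neigh_major: float = field(default=np.nan)
    rel_neigh_minor: float = field(default=np.nan)
    rel_neigh_relation_axis: float = field(default=np.nan)
    rel_neigh_convex_hull: float = field(default=np.nan)
    n_sides: int = -1
    strength: float = field(default=np.nan)
    clustering: float = field(default=np.nan)
    eccentricity: float = field(default=np.nan)
    betweenness: float = field(default=np.nan)

    def _base(self, name: str) -> float:
        return float(getattr(self, name))


def extract_cells(image: "LabelImage") -> list[CellRecord]:
    """Extract geometric features for every labeled cell.

    All cells are measured, including those outside the ROI — out-of-ROI cells
    are needed as neighbours of interior ones. Relation and network fields are
    left unset.
    """
    labels = image.labels
    if labels.max() < 1:
        raise ValueError("no cells: label image is empty")
    records: list[CellRecord] = []
    roi = image.roi_mask
    for rp in measure.regionprops(labels):
        major = float(rp.axis_major_length)
        minor = float(rp.axis_minor_length)
        if minor <= 0:
            raise ValueError(
                f"degenerate region {rp.label}: zero minor axis (line-like cell)"
            )
        r0, c0 = rp.centroid
        # ROI membership is a per-cell property; any pixel suffices since the
        # mask is built from whole cells
        rr, cc = rp.coords[0]
        records.append(
            CellRecord(
                cell_id=int(rp.label),
                centroid=(float(r0), float(c0)),
                in_roi=bool(roi[rr, cc]),
                area=float(rp.area),
                major_axis=major,
                minor_axis=minor,
                relation_axis=major / minor,
                convex_hull_ratio=float(rp.solidity),
            )
        )
    return records


def fill_neighbor_relations(
    cells: list[CellRecord], graph: "ContactGraph"
) -> list[CellRecord]:
    """Fill the rel_neigh_* ratios of every in-ROI cell from its graph neighbours.

    rel_neigh_f = f(cell) / mean(f over neighbours); neighbours may lie outside
    the ROI. Raises if an in-ROI cell has no neighbours (a segmentation fault
    upstream — confluent tissue cannot have isolated interior cells).
    """
    by_id = {c.cell_id: c for c in cells}
    rel_names = {
        "area": "rel_neigh_area",
        "major_axis": "rel_neigh_major",
        "minor_axis": "rel_neigh_minor",
        "relation_axis": "rel_neigh_relation_axis",
        "convex_hull_ratio": "rel_neigh_convex_hull",
    }
    for cell in cells:
        if not cell.in_roi:
            continue
        nbrs = [by_id[j] for j in graph.neighbors(cell.cell_id)]
        if not nbrs:
            raise ValueError(
                f"in-ROI cell {cell.cell_id} has no neighbours; "
                "check the segmentation / contact radius"
            )
        for base, rel in rel_names.items():
            mean_nbr = float(np.mean([n._base(base) for n in nbrs]))
            setattr(cell, rel, cell._base(base) / mean_nbr)
    return cells


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

#: column order of the per-cell feature table
CELL_TABLE_COLUMNS = [
    "cell_id", "centroid_row", "centroid_col", "in_roi",
    "area", "major_axis", "minor_axis", "relation_axis", "convex_hull_ratio",
    "rel_neigh_area", "rel_neigh_major", "rel_neigh_minor",
    "rel_neigh_relation_axis", "rel_neigh_convex_hull",
    "n_sides", "strength", "clustering", "eccentricity", "betweenness",
]


def cells_to_dataframe(cells: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append({
            "cell_id": c.cell_id,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "in_roi": c.in_roi,
            **{k: getattr(c, k) for k in CELL_TABLE_COLUMNS[4:]},
        })
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(cells: list[CellRecord], path) -> None:
    cells_to_dataframe(cells).to_csv(path, index=False)


def read_cell_table(path) -> list[CellRecord]:
    df = pd.read_csv(path)
    cells = []
    for _, row in df.iterrows():
        cells.append(CellRecord(
            cell_id=int(row["cell_id"]),
            centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
            in_roi=bool(row["in_roi"]),
            area=float(row["area"]),
            major_axis=float(row["major_axis"]),
            minor_axis=float(row["minor_axis"]),
            relation_axis=float(row["relation_axis"]),
            convex_hull_ratio=float(row["convex_hull_ratio"]),
            rel_neigh_area=float(row["rel_neigh_area"]),
            rel_neigh_major=float(row["rel_neigh_major"]),
            rel_neigh_minor=float(row["rel_neigh_minor"]),
            rel_neigh_relation_axis=float(row["rel_neigh_relation_axis"]),
            rel_neigh_convex_hull=float(row["rel_neigh_convex_hull"]),
            n_sides=int(row["n_sides"]),
            strength=float(row["strength"]),
            clustering=float(row["clustering"]),
            eccentricity=float(row["eccentricity"]),
            betweenness=float(row["betweenness"]),
        ))
    return cells
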