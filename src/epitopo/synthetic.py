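"""Synthetic epithelial mosaics with controllable polygon-distribution statistics.

The generator rasterizes a Voronoi tessellation of seed points inside the image
frame, optionally applying Lloyd (centroidal) relaxation to tune regularity.
Cells are separated by 1-px background boundaries, emulating segmented membrane
images of a confluent monolayer.  The ``polygon_shift`` knob interpolates the
seed points between their current positions and a strongly relaxed configuration
(positive shift: mass moves from pentagons/heptagons into hexagons, i.e. a more
ordered, prepupa-like packing) or adds positional jitter (negative shift: a less
ordered packing).

Coordinate convention used throughout the package: (row, col), 0-based, origin
at the top-left corner, half-open pixel extents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "MosaicSpec",
    "LabelImage",
    "generate_mosaic",
    "generate_condition_pair",
    "mosaic_from_points",
    "hexagonal_lattice_points",
    "save_label_image",
    "load_label_image",
]

#: pixels a cell needs, at the very least, to survive boundary carving
_MIN_PIXELS_PER_CELL = 16

#: extra Lloyd iterations used to compute the "fully relaxed" target of polygon_shift
_SHIFT_RELAX_ITERATIONS = 30


class OvercrowdedError(ValueError):
    """Raised when n_cells cannot be packed into image_size."""


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of one synthetic mosaic.

    Parameters
    ----------
    n_cells:
        Number of cells (Voronoi seeds). The default, 515, matches the mean
        cells-per-image of the study regime this generator emulates.
    image_size:
        (rows, cols) in pixels; each dimension must be >= 32.
    lloyd_iterations:
        Rounds of centroidal (Lloyd) relaxation applied to random seed points.
        0 gives a Poisson-Voronoi mosaic (broad polygon distribution); a few
        iterations reproduce the hexagon-dominated packing of proliferating
        epithelia.
    polygon_shift:
        Real in [-1, 1]. 0 keeps the relaxed-random baseline; positive values
        interpolate the seeds toward a strongly relaxed configuration (more
        hexagons, fewer pentagons); negative values jitter the seeds (fewer
        hexagons).
    seed:
        RNG seed; the same (spec, seed) is bit-reproducible.
    """

    n_cells: int = 515
    image_size: tuple[int, int] = (512, 512)
    lloyd_iterations: int = 3
    polygon_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.image_size) < 32:
            raise ValueError("image_size dimensions must be >= 32 px")
        if self.lloyd_iterations < 0:
            raise ValueError("lloyd_iterations must be >= 0")
        if not -1.0 <= self.polygon_shift <= 1.0:
            raise ValueError("polygon_shift must lie in [-1, 1]")
        h, w = self.image_size
        if self.n_cells * _MIN_PIXELS_PER_CELL > h * w:
            raise OvercrowdedError(
                f"overcrowded: {self.n_cells} cells do not fit in a "
                f"{h}x{w} px frame (needs >= {_MIN_PIXELS_PER_CELL} px/cell)"
            )


@dataclass
class LabelImage:
    """Integer-labeled segmentation of one epithelial image.

    ``labels`` holds 0 for background/membrane and k >= 1 for cell k.
    ``roi_mask`` marks the pixels of in-ROI cells; cells whose Voronoi domain
    touches the image border are excluded from the ROI (they only provide
    neighbours to interior cells). ``seeds`` retains the generator points
    ((row, col) per cell, ordered by label) for ground-truth tests; it is None
    for images that did not come from the generator.
    """

    labels: np.ndarray
    roi_mask: np.ndarray
    condition: str = ""
    image_id: str = ""
    seeds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels.shape != self.roi_mask.shape:
            raise ValueError("labels and roi_mask must share a shape")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def roi_labels(self) -> np.ndarray:
        """Sorted label ids of in-ROI cells."""
        vals = np.unique(self.labels[self.roi_mask])
        return vals[vals > 0]


def _pixel_grid(image_size: tuple[int, int]) -> np.ndarray:
    h, w = image_size
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _assign_nearest(points: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterized Voronoi assignment: each pixel -> 1-based index of nearest seed."""
    grid = _pixel_grid(image_size)
    _, idx = cKDTree(points).query(grid)
    return (idx + 1).reshape(image_size).astype(np.int32)


def _lloyd_step(points: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    assign = _assign_nearest(points, image_size)
    out = points.copy()
    # centroid of each rasterized Voronoi cell
    flat = assign.ravel()
    grid = _pixel_grid(image_size)
    counts = np.bincount(flat, minlength=len(points) + 1)[1:]
    sums_r = np.bincount(flat, weights=grid[:, 0], minlength=len(points) + 1)[1:]
    sums_c = np.bincount(flat, weights=grid[:, 1], minlength=len(points) + 1)[1:]
    nonzero = counts > 0
    out[nonzero, 0] = sums_r[nonzero] / counts[nonzero]
    out[nonzero, 1] = sums_c[nonzero] / counts[nonzero]
    return out


def _relax(points: np.ndarray, image_size: tuple[int, int], iterations: int) -> np.ndarray:
    for _ in range(iterations):
        points = _lloyd_step(points, image_size)
    return points


def mosaic_from_points(
    points: np.ndarray,
    image_size: tuple[int, int],
    condition: str = "",
    image_id: str = "",
) -> LabelImage:
    """Rasterize the Voronoi tessellation of explicit seed points.

    Regions are separated by 1-px background boundaries; every region is kept
    4-connected (stray rasterization fragments are carved into background).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 1:
        raise ValueError("points must be an (n, 2) array with n >= 1")
    assign = _assign_nearest(points, image_size)

    labels = assign.copy()
    boundary = np.zeros_like(labels, dtype=bool)
    boundary[1:, :] |= labels[1:, :] != labels[:-1, :]
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    labels[boundary] = 0

    # keep each region a single 4-connected component
    for k in range(1, len(points) + 1):
        mask = labels == k
        if not mask.any():
            raise OvercrowdedError(
                f"overcrowded: cell {k} lost all pixels to boundary carving"
            )
        comp = measure.label(mask, connectivity=1)
        if comp.max() > 1:
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            labels[mask & (comp != keep)] = 0

    border_labels = np.unique(
        np.concatenate([assign[0, :], assign[-1, :], assign[:, 0], assign[:, -1]])
    )
    roi_mask = ~np.isin(labels, border_labels) & (labels > 0)
    return LabelImage(
        labels=labels,
        roi_mask=roi_mask,
        condition=condition,
        image_id=image_id,
        seeds=points,
    )


def generate_mosaic(spec: MosaicSpec, condition: str = "", image_id: str = "") -> LabelImage:
    """Generate one labeled mosaic according to ``spec``.

    Deterministic: identical (spec, seed) produce byte-identical label images.
    """
    spec.validate()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    points = np.column_stack(
        [rng.uniform(0, h, spec.n_cells), rng.uniform(0, w, spec.n_cells)]
    )
    points = _relax(points, spec.image_size, spec.lloyd_iterations)

    s = spec.polygon_shift
    if s > 0:
        relaxed = _relax(points, spec.image_size, _SHIFT_RELAX_ITERATIONS)
        points = (1.0 - s) * points + s * relaxed
    elif s < 0:
        spacing = np.sqrt(h * w / spec.n_cells)
        points = points + (-s) * 0.25 * spacing * rng.standard_normal(points.shape)
        points[:, 0] = np.clip(points[:, 0], 0, h - 1)
        points[:, 1] = np.clip(points[:, 1], 0, w - 1)

    return mosaic_from_points(points, spec.image_size, condition=condition, image_id=image_id)


def generate_condition_pair(
    specA: MosaicSpec,
    specB: MosaicSpec,
    n_images_A: int,
    n_images_B: int,
    seed: int = 0,
    condition_names: tuple[str, str] = ("A", "B"),
) -> list[LabelImage]:
    """Generate two tagged groups of mosaics (e.g. 15 larval-like + 16 prepupa-like).

    Per-image seeds are spawned from ``seed``; the images carry their condition
    tag and an id ``"{condition}{index}"``. With identical specs the two groups
    are exchangeable by construction.
    """
    if n_images_A < 2 or n_images_B < 2:
        raise ValueError("need at least 2 images per condition")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images_A + n_images_B)
    images: list[LabelImage] = []
    for i in range(n_images_A):
        s = int(child_seeds[i]) % (2**31)
        images.append(
            generate_mosaic(
                dataclasses.replace(specA, seed=s),
                condition=condition_names[0],
                image_id=f"{condition_names[0]}{i + 1}",
            )
        )
    for i in range(n_images_B):
        s = int(child_seeds[n_images_A + i]) % (2**31)
        images.append(
            generate_mosaic(
                dataclasses.replace(specB, seed=s),
                condition=condition_names[1],
                image_id=f"{condition_names[1]}{i + 1}",
            )
        )
    return images


def hexagonal_lattice_points(
    image_size: tuple[int, int], spacing: float
) -> np.ndarray:
    """Seed points of a regular hexagonal lattice covering the frame.

    The Voronoi diagram of these points is a honeycomb: every interior cell is
    a regular hexagon with exactly six neighbours.
    """
    h, w = image_size
    dy = spacing * np.sqrt(3) / 2
    pts = []
    r = spacing / 2
    row = 0
    while r < h:
        offset = (spacing / 2) if row % 2 else 0.0
        # offset rows get one extra point so the left margin is tiled by a
        # (clipped) border cell instead of inflating its neighbour
        c = spacing / 2 + offset - (spacing if offset else 0.0)
        while c < w:
            pts.append((r, c))
            c += spacing
        r += dy
        row += 1
    return np.array(pts, dtype=float)


# ---------------------------------------------------------------------------
# I/O: 16-bit TIFF labels + 8-bit TIFF ROI + JSON sidecar
# ---------------------------------------------------------------------------

def save_label_image(image: LabelImage, prefix: str | Path, spec: MosaicSpec | None = None) -> None:
    """Write ``{prefix}_labels.tif``, ``{prefix}_roi.tif`` and ``{prefix}.json``."""
    prefix = Path(prefix)
    if image.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(str(prefix) + "_labels.tif", image.labels.astype(np.uint16))
    tifffile.imwrite(str(prefix) + "_roi.tif", image.roi_mask.astype(np.uint8))
    sidecar: dict = {"condition": image.condition, "image_id": image.image_id}
    if spec is not None:
        sidecar["spec"] = dataclasses.asdict(spec)
    if image.seeds is not None:
        sidecar["seeds"] = np.asarray(image.seeds).tolist()
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def default_roi_mask(labels: np.ndarray) -> np.ndarray:
    """ROI fallback: pixels of all cells that do not touch the image border."""
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    return ~np.isin(labels, border_labels) & (labels > 0)


def load_label_image(prefix: str | Path) -> LabelImage:
    prefix = Path(prefix)
    labels = tifffile.imread(str(prefix) + "_labels.tif").astype(np.int32)
    roi_path = Path(str(prefix) + "_roi.tif")
    if roi_path.exists():
        roi = tifffile.imread(roi_path).astype(bool)
    else:
        logging.getLogger(__name__).warning(
            "no ROI mask at %s; defaulting to non-border cells", roi_path)
        roi = default_roi_mask(labels)
    condition, image_id, seeds = "", "", None
    sidecar_path = Path(str(prefix) + ".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        condition = sidecar.get("condition", "")
        image_id = sidecar.get("image_id", "")
        if "seeds" in sidecar:
            seeds = np.asarray(sidecar["seeds"], dtype=float)
    return LabelImage(labels=labels, roi_mask=roi, condition=condition,
                      image_id=image_id, seeds=seeds)
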