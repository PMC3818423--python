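"""Normalization, PCA projection, the cluster-separation descriptor and the
beam-style feature-subset search with its randomization null.

The separation of two groups of images in the plane of the two leading
principal components is scored by a variant of the Calinski–Harabasz index:
with 2x2 between-group and within-group scatter matrices B and W of the PC
scores,

    B = sum_k N_k (c_k - c)(c_k - c)^T,
    W = sum_k sum_i (x_ik - c_k)(x_ik - c_k)^T,
    descriptor = trace(B) / trace(W),

where c_k are group centroids and c the overall centroid. B + W equals the
total scatter of the scores, so compact, well-separated groups give a large
descriptor.  Unlike the classic index, no (N - k)/(k - 1) factor is applied.

The feature search is a beam search over subsets: all feature pairs are
scored and the best 10 kept; each surviving pair is extended by every unused
feature keeping the best 5 (50 trios); then the best 2 per trio (100
quartets); from there one extension per candidate.  A branch stops when its
descriptor drops below its parent's; the search stops at subsets of 7; the
result is the best-scoring subset evaluated anywhere in the search.

The randomization null reshuffles the images into two mixed groups of the
same sizes as the real design (half of each condition into each mixed group),
re-runs the full search and the polygon MANOVA, and locates the real-label
values within the null series.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import FEATURE_NAMES, ImageFeatureVector
from .polygons import PolygonDistribution, manova_polygons

__all__ = [
    "FeatureTable",
    "normalize",
    "pca_project",
    "pca_descriptor",
    "select_features",
    "randomize_groups",
    "independence_report",
    "DescriptorResult",
    "SelectionResult",
    "RandomizationResult",
    "read_two_block_csv",
]

logger = logging.getLogger(__name__)

#: beam widths per iteration: pairs keep 10, each pair keeps 5 extensions,
#: each trio keeps 2, afterwards 1 per candidate
_BEAM_WIDTHS = {1: 10, 2: 5, 3: 2}
_MAX_SUBSET = 7


@dataclass
class FeatureTable:
    """Images x features table of image-level characteristics.

    ``values`` is (n_images, n_features); ``conditions`` carries the two group
    tags. ``normalized`` records whether per-column min-max scaling has been
    applied (required before PCA / selection).
    """

    values: np.ndarray
    image_ids: list[str]
    conditions: list[str]
    normalized: bool = False
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (images x features)")
        n, p = self.values.shape
        if len(self.image_ids) != n or len(self.conditions) != n:
            raise ValueError("image_ids/conditions length mismatch")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")

    @classmethod
    def from_images(cls, vectors: list[ImageFeatureVector]) -> "FeatureTable":
        return cls(values=np.vstack([v.values for v in vectors]),
                   image_ids=[v.image_id for v in vectors],
                   conditions=[v.condition for v in vectors])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_col: str = "image_id",
                       condition_col: str = "condition",
                       normalized: bool = False) -> "FeatureTable":
        feats = [c for c in df.columns if c not in (id_col, condition_col)]
        return cls(values=df[feats].to_numpy(dtype=float),
                   image_ids=[str(v) for v in df[id_col]],
                   conditions=[str(v) for v in df[condition_col]],
                   normalized=normalized, feature_names=feats)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "condition", self.conditions)
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path), normalized=normalized)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
        names = sorted(set(self.conditions))
        if len(names) != 2:
            raise ValueError(f"need exactly 2 conditions, found {names}")
        cond = np.asarray(self.conditions)
        return cond == names[0], cond == names[1], (names[0], names[1])


def read_two_block_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a two-block feature spreadsheet export (real values, then
    normalized values), a common layout for published feature tables.

    The file contains two CSV blocks separated by a blank line, each beginning
    with a marker line (``# real`` / ``# normalized``) followed by a header row
    ``image_id,condition,<feature...>``.
    """
    with open(path) as fh:
        text = fh.read()
    blocks: dict[str, pd.DataFrame] = {}
    for chunk in text.split("\n\n"):
        lines = [ln for ln in chunk.strip().splitlines() if ln]
        if not lines:
            continue
        marker = lines[0].lstrip("# ").strip().lower()
        from io import StringIO
        blocks[marker] = pd.read_csv(StringIO("\n".join(lines[1:])))
    if "real" not in blocks or "normalized" not in blocks:
        raise ValueError("expected '# real' and '# normalized' blocks")
    return blocks["real"], blocks["normalized"]


def normalize(table: FeatureTable) -> FeatureTable:
    """Per-column min-max scaling to [0, 1]; idempotent.

    Constant columns carry no comparative information and are mapped to 0
    (with a warning).
    """
    X = table.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in feature table")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    const = span == 0
    if const.any():
        names = [table.feature_names[i] for i in np.nonzero(const)[0]]
        warnings.warn(f"constant feature column(s) mapped to 0: {names}")
    out = np.zeros_like(X)
    out[:, ~const] = (X[:, ~const] - lo[~const]) / span[~const]
    return FeatureTable(values=out, image_ids=list(table.image_ids),
                        conditions=list(table.conditions), normalized=True,
                        feature_names=list(table.feature_names))


def pca_project(table_or_values, features=None) -> np.ndarray:
    """Project images onto the two leading principal components.

    Accepts a FeatureTable (``features`` as 0-based column indices, or None
    for all) or a raw (n x p) array.  Columns are centered; the covariance
    eigenvectors define the axes; the sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    if isinstance(table_or_values, FeatureTable):
        if not table_or_values.normalized:
            raise ValueError("normalize the table before PCA")
        X = table_or_values.values
    else:
        X = np.asarray(table_or_values, dtype=float)
    if features is not None:
        X = X[:, list(features)]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for a 2-D projection")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / max(len(X) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= max(evals[0], 1.0) * 1e-12:
        raise ValueError("feature submatrix has rank < 2")
    V = evecs[:, :2]
    for k in range(2):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return Xc @ V


@dataclass
class DescriptorResult:
    """Scatter decomposition of 2-D PC scores and the separation descriptor."""

    W: np.ndarray
    B: np.ndarray
    descriptor: float
    pc_scores: np.ndarray


def pca_descriptor(scores: np.ndarray, labels) -> DescriptorResult:
    """Separation descriptor trace(B)/trace(W) of 2-D scores under two groups."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n x 2)")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if min((labels == g).sum() for g in groups) < 2:
        raise ValueError("each group needs at least 2 images")
    c = scores.mean(axis=0)
    B = np.zeros((2, 2))
    W = np.zeros((2, 2))
    for g in groups:
        pts = scores[labels == g]
        ck = pts.mean(axis=0)
        d = (ck - c)[:, None]
        B += len(pts) * (d @ d.T)
        dev = pts - ck
        W += dev.T @ dev
    tw = float(np.trace(W))
    if tw <= 0:
        raise ValueError("within-group scatter has zero trace (coincident points)")
    return DescriptorResult(W=W, B=B, descriptor=float(np.trace(B)) / tw,
                            pc_scores=scores)


def _descriptor_value(X: np.ndarray, subset: tuple[int, ...],
                      mask1: np.ndarray) -> float:
    """Fast trace(B)/trace(W) of the 2-PC scores of X[:, subset].

    Returns -inf for rank-deficient submatrices (such subsets cannot support a
    2-D projection and are excluded from the search).
    """
    Xs = X[:, subset]
    Xc = Xs - Xs.mean(axis=0)
    cov = (Xc.T @ Xc) / max(len(Xs) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] <= max(evals[-1], 1.0) * 1e-12:
        return -np.inf
    V = evecs[:, -2:]
    S = Xc @ V
    m = S.mean(axis=0)
    m1 = S[mask1].mean(axis=0)
    m2 = S[~mask1].mean(axis=0)
    n1 = int(mask1.sum())
    n2 = len(S) - n1
    trB = n1 * float(((m1 - m) ** 2).sum()) + n2 * float(((m2 - m) ** 2).sum())
    trT = float(((S - m) ** 2).sum())
    trW = trT - trB
    if trW <= 1e-300:
        return -np.inf
    return trB / trW


@dataclass
class SelectionResult:
    """Outcome of the beam search.

    ``selected`` holds 1-based feature indices (canonical 40-feature
    numbering) in ascending order; ``trace`` records, per iteration, the
    number of candidates evaluated and the surviving pool with scores.
    """

    selected: tuple[int, ...]
    descriptor: float
    trace: list[dict]
    feature_names: list[str] = field(default_factory=list)

    @property
    def selected_names(self) -> list[str]:
        return [self.feature_names[i - 1] for i in self.selected]

    def to_json(self, path) -> None:
        payload = {
            "selected": list(self.selected),
            "selected_names": self.selected_names,
            "descriptor": self.descriptor,
            "trace": [
                {"size": t["size"], "n_evaluated": t["n_evaluated"],
                 "pool": [[list(s), d] for s, d in t["pool"]]}
                for t in self.trace
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def select_features(table: FeatureTable, labels=None) -> SelectionResult:
    """Beam search for the feature subset that best separates the two groups.

    Iteration 1 scores every feature pair and keeps the top 10; iteration 2
    extends each kept pair with every unused feature, keeping the top 5 per
    pair (50 trios); iteration 3 keeps the top 2 per trio (100 quartets);
    later iterations keep 1 extension per candidate. A candidate whose score
    falls below its parent's is not extended further; no subset exceeds 7
    features. The returned subset is the argmax over everything scored.
    """
    if not table.normalized:
        raise ValueError("normalize the table before feature selection")
    X = table.values
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    if labels is None:
        labels = table.conditions
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    mask1 = labels == groups[0]

    def score(subset: tuple[int, ...]) -> float:
        return _descriptor_value(X, subset, mask1)

    trace: list[dict] = []
    best_subset: tuple[int, ...] | None = None
    best_score = -np.inf

    def consider(subset: tuple[int, ...], value: float) -> None:
        nonlocal best_subset, best_score
        if value > best_score or (value == best_score and
                                  (best_subset is None or subset < best_subset)):
            best_subset, best_score = subset, value

    # iteration 1: all pairs, keep the best 10
    pair_scores = []
    for i in range(p):
        for j in range(i + 1, p):
            s = (i, j)
            v = score(s)
            if np.isfinite(v):
                pair_scores.append((s, v))
    pair_scores.sort(key=lambda t: (-t[1], t[0]))
    # pool entries: (subset, value, live) — a dead branch stays in the books
    # but is not extended further
    pool = [(s, v, True) for s, v in pair_scores[:_BEAM_WIDTHS[1]]]
    for s, v, _ in pool:
        consider(s, v)
    trace.append({"size": 2, "n_evaluated": p * (p - 1) // 2,
                  "pool": [(s, v) for s, v, _ in pool]})

    iteration = 2
    while any(live for _, _, live in pool) and len(pool[0][0]) < _MAX_SUBSET:
        width = _BEAM_WIDTHS.get(iteration, 1)
        next_pool: list[tuple[tuple[int, ...], float, bool]] = []
        n_evaluated = 0
        for subset, parent_score, live in pool:
            if not live:
                continue
            used = set(subset)
            children = []
            for f in range(p):
                if f in used:
                    continue
                child = tuple(sorted(subset + (f,)))
                v = score(child)
                n_evaluated += 1
                if np.isfinite(v):
                    children.append((child, v))
            children.sort(key=lambda t: (-t[1], t[0]))
            for s, v in children[:width]:
                consider(s, v)
                # pair->trio->quartet expansion is unconditional; from the
                # one-extension-per-step phase on, a branch whose descriptor
                # no longer improves stops
                next_pool.append((s, v, width > 1 or v > parent_score))
        if not next_pool:
            break
        next_pool.sort(key=lambda t: (-t[1], t[0]))
        pool = next_pool
        trace.append({"size": iteration + 1, "n_evaluated": n_evaluated,
                      "pool": [(s, v) for s, v, _ in pool]})
        iteration += 1

    assert best_subset is not None, "no scorable feature pair (rank-deficient table)"
    return SelectionResult(
        selected=tuple(i + 1 for i in best_subset),
        descriptor=float(best_score),
        trace=trace,
        feature_names=list(table.feature_names),
    )


@dataclass
class RandomizationResult:
    """Null series from reshuffled group assignments.

    ``loop_descriptors`` / ``loop_manova_p`` hold one value per randomization
    loop; ``real_*`` the values under the true labels.  The percentile is the
    share of loops the real value beats (in percent).
    """

    real_descriptor: float
    real_manova_p: float
    loop_descriptors: np.ndarray
    loop_manova_p: np.ndarray
    n_loops: int
    seed: int

    @property
    def descriptor_percentile(self) -> float:
        if self.n_loops == 0:
            return float("nan")
        return 100.0 * float((self.loop_descriptors < self.real_descriptor).mean())

    @property
    def manova_percentile(self) -> float:
        """Percent of loops with a larger (less significant) p than the real one."""
        if self.n_loops == 0 or np.isnan(self.real_manova_p):
            return float("nan")
        return 100.0 * float((self.loop_manova_p > self.real_manova_p).mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"descriptor": self.loop_descriptors,
                             "manova_p": self.loop_manova_p})


def _mixed_assignment(rng: np.random.Generator, idxA: np.ndarray,
                      idxB: np.ndarray) -> np.ndarray:
    """One reshuffle under the fixed mixed design.

    mixA receives ceil(|A|/2) images of condition A and floor(|B|/2) of
    condition B; mixB the remainder (for the canonical 15+16 design: 8+8
    versus 7+8).  Returns a boolean mask marking mixA membership.
    """
    kA = (len(idxA) + 1) // 2
    kB = len(idxB) // 2
    mask = np.zeros(len(idxA) + len(idxB), dtype=bool)
    mask[rng.choice(idxA, size=kA, replace=False)] = True
    mask[rng.choice(idxB, size=kB, replace=False)] = True
    return mask


def randomize_groups(
    table: FeatureTable,
    n_loops: int,
    seed: int = 0,
    distributions: list[PolygonDistribution] | None = None,
) -> RandomizationResult:
    """Group-label randomization null for the selection descriptor and MANOVA.

    Per loop the images are reshuffled into two mixed groups of the original
    sizes (half of each condition in each), the beam search re-run for the
    descriptor and — when per-image polygon ``distributions`` are supplied
    (aligned with the table rows) — the polygon MANOVA re-run for its p-value.
    """
    if not table.normalized:
        raise ValueError("normalize the table before randomization")
    if n_loops < 0:
        raise ValueError("n_loops must be >= 0")
    maskA, maskB, names = table.group_masks()
    nA, nB = int(maskA.sum()), int(maskB.sum())
    if nA < 2 or nB < 2:
        raise ValueError(
            f"randomization needs >= 2 images per condition, got {nA}+{nB}; "
            "the canonical design is 15+16"
        )
    if distributions is not None and len(distributions) != len(table.image_ids):
        raise ValueError("distributions must align with the table rows")

    def manova_p(mask1: np.ndarray) -> float:
        if distributions is None:
            return float("nan")
        gA = [d for d, m in zip(distributions, mask1) if m]
        gB = [d for d, m in zip(distributions, mask1) if not m]
        if min(len(gA), len(gB)) < 6:
            return float("nan")
        return float(manova_polygons(gA, gB)["p"])

    real_sel = select_features(table)
    real_p = manova_p(maskA)

    rng = np.random.default_rng(seed)
    idxA = np.nonzero(maskA)[0]
    idxB = np.nonzero(maskB)[0]
    descs = np.empty(n_loops)
    ps = np.empty(n_loops)
    for loop in range(n_loops):
        mix_mask = _mixed_assignment(rng, idxA, idxB)
        labels = np.where(mix_mask, "mixA", "mixB")
        descs[loop] = select_features(table, labels=labels).descriptor
        ps[loop] = manova_p(mix_mask)
    return RandomizationResult(
        real_descriptor=float(real_sel.descriptor),
        real_manova_p=real_p,
        loop_descriptors=descs,
        loop_manova_p=ps,
        n_loops=n_loops,
        seed=seed,
    )


def independence_report(result: RandomizationResult) -> dict:
    """Scatter data and summary for the descriptor-vs-MANOVA independence plot.

    Emits the (manova_p, descriptor) pair per loop, the p = 0.05 marker, and
    counts of loops beating the real labels on each axis.
    """
    pairs = [(float(p), float(d))
             for p, d in zip(result.loop_manova_p, result.loop_descriptors)]
    report = {
        "pairs": pairs,
        "real": (float(result.real_manova_p), float(result.real_descriptor)),
        "p_marker": 0.05,
        "n_loops": result.n_loops,
        "loops_above_real_descriptor": int(
            (result.loop_descriptors > result.real_descriptor).sum()),
    }
    if not np.isnan(result.real_manova_p):
        report["loops_below_real_p"] = int(
            np.nansum(result.loop_manova_p < result.real_manova_p))
        report["loops_p_below_marker"] = int(
            np.nansum(result.loop_manova_p < 0.05))
    return report
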