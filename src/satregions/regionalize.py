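"""Grid-bisection regionalization of tract centroids.

The algorithm carves a point-referenced sample into compact regions that
all meet a minimum sampling threshold:

1. tract centroids are allocated to the cells of a very coarse planar
   grid (half-open cells, so a centroid on a shared edge belongs to the
   higher cell);
2. any cell holding more than ``threshold_n`` observations is bisected —
   the cut runs parallel to the cell's shorter side, halving the longer
   one — and the split is undone if both children fall below the
   threshold;
3. when no further split is possible, undersized cells are merged,
   lowest count first, each with the cell whose member centroid is
   nearest, until every region meets the threshold (or one region
   remains).

Regions are therefore approximately contiguous but carry no explicit
contiguity constraint.  All tie-breaks (equal side lengths, equal merge
distances, equal counts) resolve by lexicographic cell id, which makes
the result independent of tract input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted


class EmptyInputError(ValueError):
    """Raised when a stage receives no tracts."""


class UnsplittableCellError(ValueError):
    """Raised when a cell with at most one distinct centroid is split."""


@dataclass
class GridCell:
    """A rectangular cell: half-open bounds and its member tracts.

    ``cell_id`` is a tuple — grid indices for initial cells, extended by
    0/1 for each bisection — ordered lexicographically for tie-breaks.
    """

    cell_id: tuple
    bounds: Tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    members: np.ndarray  # row indices into the tract arrays
    count: int
    depth: int = 0


@dataclass
class Region:
    region_id: str
    tract_ids: List[str]
    count: int
    total_weight: float


@dataclass
class Partition:
    """A threshold-indexed division of all tracts into disjoint regions."""

    threshold_n: int
    grid_offset: Tuple[float, float]
    regions: List[Region]
    labels: pd.Series = field(repr=False)  # tract_id -> region_id

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def init_grid(
    coords: np.ndarray,
    counts: np.ndarray,
    cell_size: float,
    offset: Tuple[float, float] = (0.0, 0.0),
) -> List[GridCell]:
    """Allocate centroids to a coarse grid; only non-empty cells are kept."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("no tracts to grid")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    dx, dy = offset
    ix = np.floor((coords[:, 0] - dx) / cell_size).astype(int)
    iy = np.floor((coords[:, 1] - dy) / cell_size).astype(int)
    cells = []
    keys = np.stack([ix, iy], axis=1)
    order = np.lexsort((iy, ix))
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)) + 1
    for group in np.split(order, boundaries):
        gx, gy = int(ix[group[0]]), int(iy[group[0]])
        cells.append(
            GridCell(
                cell_id=(gx, gy),
                bounds=(
                    dx + gx * cell_size,
                    dx + (gx + 1) * cell_size,
                    dy + gy * cell_size,
                    dy + (gy + 1) * cell_size,
                ),
                members=np.sort(group),
                count=int(counts[group].sum()),
            )
        )
    cells.sort(key=lambda c: c.cell_id)
    return cells


def split_cell(
    cell: GridCell,
    coords: np.ndarray,
    counts: np.ndarray,
    axis_rule: str = "halve-longer",
) -> Tuple[Optional[GridCell], Optional[GridCell]]:
    """Bisect a cell "along its shortest axis" (ties halve the x side).

    The default reading, ``"halve-longer"``, runs the cut parallel to the
    shorter side so the longer side is halved — the compactness-preserving
    interpretation.  ``"halve-shorter"`` implements the opposite reading.
    Members go to the half-open children; an empty child is returned as
    ``None``.  Child counts always sum to the parent count.
    """
    pts = coords[cell.members]
    if len(np.unique(pts, axis=0)) <= 1:
        raise UnsplittableCellError(
            f"cell {cell.cell_id} has at most one distinct centroid position"
        )
    if axis_rule not in ("halve-longer", "halve-shorter"):
        raise ValueError("axis_rule must be 'halve-longer' or 'halve-shorter'")
    x_min, x_max, y_min, y_max = cell.bounds
    x_is_longer = (x_max - x_min) >= (y_max - y_min)
    axis = (0 if x_is_longer else 1) if axis_rule == "halve-longer" else (
        0 if (x_max - x_min) <= (y_max - y_min) else 1
    )
    if axis == 0:
        mid = 0.5 * (x_min + x_max)
        in_low = pts[:, 0] < mid
        lo_bounds = (x_min, mid, y_min, y_max)
        hi_bounds = (mid, x_max, y_min, y_max)
    else:
        mid = 0.5 * (y_min + y_max)
        in_low = pts[:, 1] < mid
        lo_bounds = (x_min, x_max, y_min, mid)
        hi_bounds = (x_min, x_max, mid, y_max)

    children = []
    for tag, mask, bounds in ((0, in_low, lo_bounds), (1, ~in_low, hi_bounds)):
        members = cell.members[mask]
        if len(members) == 0:
            children.append(None)
            continue
        children.append(
            GridCell(
                cell_id=cell.cell_id + (tag,),
                bounds=bounds,
                members=members,
                count=int(counts[members].sum()),
                depth=cell.depth + 1,
            )
        )
    return children[0], children[1]


def refine(
    cells: Sequence[GridCell],
    threshold_n: int,
    coords: np.ndarray,
    counts: np.ndarray,
    axis_rule: str = "halve-longer",
) -> List[GridCell]:
    """Recursively bisect over-threshold cells; undo useless splits.

    A cell is split while its count strictly exceeds ``threshold_n`` and
    it holds at least two distinct centroid positions.  A split is kept
    iff at least one child reaches the threshold; empty children are
    discarded.
    """
    done: List[GridCell] = []
    stack = list(cells)
    while stack:
        cell = stack.pop()
        if cell.count <= threshold_n:
            done.append(cell)
            continue
        pts = coords[cell.members]
        if len(np.unique(pts, axis=0)) <= 1:
            done.append(cell)
            continue
        lo, hi = split_cell(cell, coords, counts, axis_rule)
        kids = [c for c in (lo, hi) if c is not None]
        if max(c.count for c in kids) < threshold_n:
            done.append(cell)  # both children undersized: undo
        else:
            stack.extend(kids)
    done.sort(key=lambda c: c.cell_id)
    return done


def merge_undersized(
    cells: Sequence[GridCell],
    threshold_n: int,
    coords: np.ndarray,
    counts: np.ndarray,
    tract_ids: Sequence[str],
    weights: Optional[np.ndarray] = None,
    offset: Tuple[float, float] = (0.0, 0.0),
) -> Partition:
    """Merge below-threshold cells with their nearest neighbours.

    Repeatedly takes the lowest-count noncompliant proto-region and
    merges it with the proto-region whose member centroid is nearest,
    until all regions meet the threshold or one region remains.
    """
    if not cells:
        raise EmptyInputError("no cells to merge")
    if weights is None:
        weights = np.asarray(counts, dtype=float)
    ids = [c.cell_id for c in cells]
    members = [c.members for c in cells]
    cnts = [c.count for c in cells]
    cents = np.array([coords[c.members].mean(axis=0) for c in cells])
    alive = list(range(len(cells)))

    while len(alive) > 1:
        under = [i for i in alive if cnts[i] < threshold_n]
        if not under:
            break
        src = min(under, key=lambda i: (cnts[i], ids[i]))
        others = [i for i in alive if i != src]
        d = np.hypot(
            cents[others, 0] - cents[src][0], cents[others, 1] - cents[src][1]
        )
        best = min(zip(d, (ids[i] for i in others), others))[2]
        keep, drop = (src, best) if ids[src] < ids[best] else (best, src)
        members[keep] = np.sort(np.concatenate([members[keep], members[drop]]))
        cnts[keep] = cnts[keep] + cnts[drop]
        cents[keep] = coords[members[keep]].mean(axis=0)
        alive.remove(drop)

    alive.sort(key=lambda i: ids[i])
    regions = []
    label_map = {}
    for rank, i in enumerate(alive):
        rid = f"R{rank:05d}"
        tids = [tract_ids[j] for j in members[i]]
        regions.append(
            Region(
                region_id=rid,
                tract_ids=tids,
                count=int(cnts[i]),
                total_weight=float(weights[members[i]].sum()),
            )
        )
        for t in tids:
            label_map[t] = rid
    labels = pd.Series(label_map, name="region_id").sort_index()
    return Partition(
        threshold_n=threshold_n, grid_offset=tuple(offset), regions=regions, labels=labels
    )


def default_cell_size(coords: np.ndarray) -> float:
    """Very coarse starting grid: a quarter of the larger extent."""
    spans = coords.max(axis=0) - coords.min(axis=0)
    return float(max(spans.max() / 4.0, 1e-9))


def regionalize(
    tracts: pd.DataFrame,
    threshold_n: int,
    cell_size: Optional[float] = None,
    offset: Tuple[float, float] = (0.0, 0.0),
    axis_rule: str = "halve-longer",
) -> Partition:
    """Run the full pipeline grid -> refine -> merge on a tract table.

    The tract table needs ``tract_id``, ``x``, ``y``, ``n_k`` and
    (optionally) ``w_k``.  Input row order is irrelevant: tracts are
    sorted by id internally and all tie-breaks are id-based.
    """
    if len(tracts) == 0:
        raise EmptyInputError("no tracts to regionalize")
    t = tracts.sort_values("tract_id").reset_index(drop=True)
    coords = t[["x", "y"]].to_numpy(dtype=float)
    counts = t["n_k"].to_numpy()
    weights = t["w_k"].to_numpy(dtype=float) if "w_k" in t else None
    if cell_size is None:
        cell_size = default_cell_size(coords)
    cells = init_grid(coords, counts, cell_size, offset)
    cells = refine(cells, threshold_n, coords, counts, axis_rule)
    return merge_undersized(
        cells, threshold_n, coords, counts, t["tract_id"].tolist(), weights, offset
    )


class GridRegionalizer(ClusterMixin, BaseEstimator):
    """Scikit-learn style clusterer wrapping the grid-bisection algorithm.

    Parameters
    ----------
    threshold_n : int, default=400
        Minimum sample observations per region.
    cell_size : float or None, default=None
        Side of the starting grid cells; ``None`` uses a quarter of the
        larger coordinate extent.
    offset : tuple of float, default=(0.0, 0.0)
        Origin offset of the starting grid.
    axis_rule : {"halve-longer", "halve-shorter"}, default="halve-longer"
        Which reading of "bisect along the shortest axis" to use.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Integer region label per input point.
    n_regions_ : int
        Number of regions formed.
    region_counts_ : ndarray
        Total sample observations per region.
    """

    def __init__(self, threshold_n: int = 400, cell_size: Optional[float] = None,
                 offset: Tuple[float, float] = (0.0, 0.0),
                 axis_rule: str = "halve-longer"):
        self.threshold_n = threshold_n
        self.cell_size = cell_size
        self.offset = offset
        self.axis_rule = axis_rule

    def fit(self, X, y=None, sample_weight=None):
        """Partition points ``X`` (n_samples, 2) carrying ``sample_weight`` counts."""
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("GridRegionalizer expects planar coordinates (n, 2)")
        counts = (
            np.ones(len(X), dtype=int)
            if sample_weight is None
            else np.asarray(sample_weight)
        )
        tracts = pd.DataFrame(
            {
                "tract_id": [f"P{i:07d}" for i in range(len(X))],
                "x": X[:, 0],
                "y": X[:, 1],
                "n_k": counts,
                "w_k": counts.astype(float),
            }
        )
        part = regionalize(
            tracts, self.threshold_n, self.cell_size, self.offset, self.axis_rule
        )
        rid_to_int = {r.region_id: i for i, r in enumerate(part.regions)}
        self.labels_ = np.array(
            [rid_to_int[part.labels[t]] for t in tracts["tract_id"]]
        )
        self.n_regions_ = part.n_regions
        self.region_counts_ = np.array([r.count for r in part.regions])
        self.partition_ = part
        return self

    def fit_predict(self, X, y=None, sample_weight=None):
        return self.fit(X, sample_weight=sample_weight).labels_

    def predict(self, X):  # pragma: no cover - convenience passthrough
        check_is_fitted(self)
        raise NotImplementedError(
            "GridRegionalizer assigns labels only to the points it was fit on"
        )
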