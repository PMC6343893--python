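"""Grid-bisection regionalizer: hand-traced oracles and partition laws."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from satregions import (
    GridRegionalizer,
    init_grid,
    merge_undersized,
    refine,
    regionalize,
    split_cell,
)
from satregions.regionalize import EmptyInputError, GridCell, UnsplittableCellError

from conftest import random_tracts


def make_cells(coords, counts, cell_size=1.0, offset=(0.0, 0.0)):
    coords = np.asarray(coords, dtype=float)
    counts = np.asarray(counts)
    return init_grid(coords, counts, cell_size, offset), coords, counts


# ---------------------------------------------------------------- init_grid

def test_single_tract_single_cell():
    cells, *_ = make_cells([(3.7, 9.1)], [5], cell_size=10.0)
    assert len(cells) == 1 and cells[0].count == 5


def test_two_tracts_two_cells():
    cells, *_ = make_cells([(0.5, 0.5), (1.5, 0.5)], [1, 1], cell_size=1.0)
    assert len(cells) == 2


def test_edge_centroid_belongs_to_higher_cell():
    cells, *_ = make_cells([(1.0, 0.5)], [1], cell_size=1.0)
    assert cells[0].cell_id == (1, 0)


def test_grid_conserves_counts():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 10, size=(100, 2))
    counts = rng.integers(1, 50, size=100)
    cells, *_ = make_cells(coords, counts, cell_size=2.5)
    assert sum(c.count for c in cells) == counts.sum()
    assert sorted(np.concatenate([c.members for c in cells])) == list(range(100))


def test_empty_input_rejected():
    with pytest.raises(EmptyInputError):
        init_grid(np.empty((0, 2)), np.empty(0), 1.0)


# --------------------------------------------------------------- split_cell

def test_square_tie_halves_x_axis():
    cells, coords, counts = make_cells([(0.2, 0.2), (0.8, 0.8)], [1, 1], cell_size=1.0)
    lo, hi = split_cell(cells[0], coords, counts)
    assert lo.bounds == (0.0, 0.5, 0.0, 1.0)
    assert hi.bounds == (0.5, 1.0, 0.0, 1.0)


def test_long_cell_halved_at_midpoint():
    cell = GridCell(cell_id=(0, 0), bounds=(0.0, 4.0, 0.0, 1.0),
                    members=np.array([0, 1]), count=2)
    coords = np.array([[1.0, 0.5], [3.0, 0.5]])
    lo, hi = split_cell(cell, coords, np.array([1, 1]))
    assert lo.bounds == (0.0, 2.0, 0.0, 1.0) and len(lo.members) == 1
    assert hi.bounds == (2.0, 4.0, 0.0, 1.0) and len(hi.members) == 1


def test_halve_shorter_reading_cuts_other_axis():
    cell = GridCell(cell_id=(0, 0), bounds=(0.0, 4.0, 0.0, 1.0),
                    members=np.array([0, 1]), count=2)
    coords = np.array([[1.0, 0.2], [3.0, 0.8]])
    lo, hi = split_cell(cell, coords, np.array([1, 1]), axis_rule="halve-shorter")
    assert lo.bounds == (0.0, 4.0, 0.0, 0.5)
    assert hi.bounds == (0.0, 4.0, 0.5, 1.0)


def test_split_conserves_counts():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 1, size=(30, 2))
    counts = rng.integers(1, 9, size=30)
    cells, *_ = make_cells(coords, counts, cell_size=1.0)
    lo, hi = split_cell(cells[0], coords, counts)
    assert lo.count + hi.count == cells[0].count


def test_degenerate_cell_unsplittable():
    cells, coords, counts = make_cells([(0.5, 0.5), (0.5, 0.5)], [1, 1], cell_size=1.0)
    with pytest.raises(UnsplittableCellError):
        split_cell(cells[0], coords, counts)


# ------------------------------------------------------------------- refine

def test_count_at_threshold_not_split():
    cells, coords, counts = make_cells([(0.2, 0.5), (0.8, 0.5)], [75, 75], cell_size=1.0)
    out = refine(cells, 150, coords, counts)
    assert len(out) == 1  # split condition is strictly greater-than


def test_four_collinear_tracts_split_once():
    coords = [(0.5, 0.5), (1.5, 0.5), (2.5, 0.5), (3.5, 0.5)]
    cells, coords, counts = make_cells(coords, [100] * 4, cell_size=4.0)
    out = refine(cells, 150, coords, counts)
    assert sorted(c.count for c in out) == [200, 200]


def test_threshold_one_isolates_each_tract():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 8, size=(20, 2))
    cells, coords, counts = make_cells(coords, np.ones(20, dtype=int), cell_size=8.0)
    out = refine(cells, 1, coords, counts)
    assert len(out) == 20 and all(len(c.members) == 1 for c in out)


# ------------------------------------------------------------------- merge

def _merge(cells, threshold, coords, counts):
    ids = [f"T{i:05d}" for i in range(len(coords))]
    return merge_undersized(cells, threshold, coords, counts, ids)


def test_compliant_cells_untouched():
    cells, coords, counts = make_cells(
        [(0.5, 0.5), (3.5, 0.5)], [300, 280], cell_size=1.0
    )
    part = _merge(cells, 250, coords, counts)
    assert part.n_regions == 2


def test_forced_merge_of_two_cells():
    cells, coords, counts = make_cells(
        [(0.5, 0.5), (3.5, 0.5)], [100, 300], cell_size=1.0
    )
    part = _merge(cells, 250, coords, counts)
    assert part.n_regions == 1 and part.regions[0].count == 400


def test_ascending_count_merge_order_conserves_and_complies():
    cells, coords, counts = make_cells(
        [(0.5, 0.5), (2.5, 0.5), (5.5, 0.5)], [100, 120, 300], cell_size=1.0
    )
    part = _merge(cells, 250, coords, counts)
    assert sum(r.count for r in part.regions) == 520
    assert all(r.count >= 250 for r in part.regions)


# -------------------------------------------------------------- regionalize

def test_total_below_threshold_single_region():
    rng = np.random.default_rng(3)
    tracts = random_tracts(rng, 10)
    part = regionalize(tracts, threshold_n=10**9)
    assert part.n_regions == 1


def test_regionalize_deterministic_and_order_invariant():
    rng = np.random.default_rng(4)
    tracts = random_tracts(rng, 80)
    p1 = regionalize(tracts, 500)
    p2 = regionalize(tracts.sample(frac=1.0, random_state=1), 500)
    pd.testing.assert_series_equal(p1.labels, p2.labels)


def test_partition_laws_fuzzed():
    rng = np.random.default_rng(5)
    for trial in range(60):
        n = int(rng.integers(2, 120))
        tracts = random_tracts(rng, n)
        threshold = int(rng.integers(1, 2000))
        part = regionalize(tracts, threshold)
        assigned = sorted(t for r in part.regions for t in r.tract_ids)
        assert assigned == sorted(tracts["tract_id"])  # coverage + disjointness
        total = tracts["n_k"].sum()
        assert sum(r.count for r in part.regions) == total  # conservation
        if total >= threshold:
            assert all(r.count >= threshold for r in part.regions)
        else:
            assert part.n_regions == 1


def test_average_region_size_monotone_in_threshold():
    rng = np.random.default_rng(6)
    tracts = random_tracts(rng, 150)
    sizes = []
    for threshold in (50, 200, 800, 3200):
        part = regionalize(tracts, threshold)
        sizes.append(tracts["n_k"].sum() / part.n_regions)
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))


# ---------------------------------------------------------------- estimator

def test_grid_regionalizer_sklearn_contract():
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 10, size=(200, 2))
    w = rng.integers(1, 100, size=200)
    est = GridRegionalizer(threshold_n=300)
    cloned = clone(est)
    assert cloned.get_params()["threshold_n"] == 300
    labels = est.fit_predict(X, sample_weight=w)
    assert labels.shape == (200,)
    assert est.n_regions_ == len(np.unique(labels))
    assert est.region_counts_.sum() == w.sum()
    est.set_params(threshold_n=50)
    assert est.threshold_n == 50
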