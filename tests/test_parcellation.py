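import numpy as np
import pandas as pd
import pytest

from cctopo.parcellation import (DEFAULT_BILATERAL_THRESHOLD, combine_bilateral,
                                 field_mean_density, field_size,
                                 per_scan_densities, per_scan_fields,
                                 trace_boundaries)
from cctopo.popmap import population_average

from conftest import (counts_from_array, flat_grid, flood_fill_8,
                      nm_from_values, outer_boundary_oracle)


def _pop_pair(grid, left_vals, right_vals):
    pl = population_average([nm_from_values(grid, np.zeros_like(left_vals))])
    pl.values = np.asarray(left_vals, dtype=float)
    pr = population_average([nm_from_values(grid, np.zeros_like(right_vals),
                                            side="right")])
    pr.values = np.asarray(right_vals, dtype=float)
    pr.side = "right"
    return pl, pr


# --------------------------------------------------------------------- #
# combine_bilateral


def test_product_threshold_printed_value():
    assert DEFAULT_BILATERAL_THRESHOLD == pytest.approx(0.0025)
    grid = flat_grid(4)
    left = np.array([[0.06], [0.0], [0.05], [0.05]])
    right = np.array([[0.05], [0.9], [0.05], [0.051]])
    pl, pr = _pop_pair(grid, left, right)
    fld = combine_bilateral(pl, pr, "a0")
    got = {tuple(v) for v in np.argwhere(fld.mask)}
    # 0.06*0.05 = 0.003 > 0.0025 -> in; 0*0.9 -> out;
    # 0.05*0.05 = 0.0025 exactly -> out (strict); 0.05*0.051 -> in
    expect = {tuple(grid.voxels[0]), tuple(grid.voxels[3])}
    assert got == expect


def test_product_annihilation():
    grid = flat_grid(4)
    pl, pr = _pop_pair(grid, np.zeros((4, 1)), np.ones((4, 1)))
    fld = combine_bilateral(pl, pr, "a0")
    assert fld.size == 0 and not fld.mask.any()
    assert fld.boundaries == []


def test_bilateral_mask_matches_bruteforce(rng):
    grid = flat_grid(40)
    lv, rv = rng.random((40, 3)) * 0.2, rng.random((40, 3)) * 0.2
    pl, pr = _pop_pair(grid, lv, rv)
    for j, area in enumerate(("a0", "a1", "a2")):
        fld = combine_bilateral(pl, pr, area)
        for i, (x, y) in enumerate(grid.voxels):
            assert fld.mask[x, y] == (lv[i, j] * rv[i, j] > 0.0025)


def test_missing_area_rejected(rng):
    grid = flat_grid(4)
    pl, pr = _pop_pair(grid, rng.random((4, 1)), rng.random((4, 1)))
    with pytest.raises(KeyError):
        combine_bilateral(pl, pr, "nope")


def test_product_bound_and_monotonicity(rng):
    grid = flat_grid(40)
    lv, rv = rng.random((40, 1)), rng.random((40, 1))
    pl, pr = _pop_pair(grid, lv, rv)
    fld = combine_bilateral(pl, pr, "a0", 0.04)
    # product > thr and values <= 1 force each side above thr on its own
    in_field = fld.mask[grid.voxels[:, 0], grid.voxels[:, 1]]
    assert np.all(lv[in_field, 0] > 0.04)
    assert np.all(rv[in_field, 0] > 0.04)
    loose = combine_bilateral(pl, pr, "a0", 0.01)
    tight = combine_bilateral(pl, pr, "a0", 0.3)
    assert not (tight.mask & ~loose.mask).any()


# --------------------------------------------------------------------- #
# boundary tracing


def test_boundary_single_voxel():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 3] = True
    paths = trace_boundaries(mask)
    assert len(paths) == 1
    assert paths[0].tolist() == [[2, 3]]


def test_boundary_solid_block():
    mask = np.zeros((7, 7), dtype=bool)
    mask[2:5, 2:5] = True
    paths = trace_boundaries(mask)
    assert len(paths) == 1
    visited = {tuple(p) for p in paths[0]}
    perimeter = {(x, y) for x in range(2, 5) for y in range(2, 5)
                 if not (x == 3 and y == 3)}
    assert visited == perimeter  # 8 perimeter voxels, centre untouched


def test_boundary_ring_hole_suppressed():
    mask = np.zeros((7, 7), dtype=bool)
    mask[1:6, 1:6] = True
    mask[3, 3] = False  # 1-voxel hole
    paths = trace_boundaries(mask)
    assert len(paths) == 1  # only the outer contour
    visited = {tuple(p) for p in paths[0]}
    assert visited == outer_boundary_oracle(mask)
    assert (3, 3) not in visited


def test_boundary_empty_mask():
    assert trace_boundaries(np.zeros((4, 4), dtype=bool)) == []


def test_boundary_paths_closed_and_inside_mask(rng):
    mask = rng.random((12, 12)) < 0.4
    for path in trace_boundaries(mask):
        assert mask[path[:, 0], path[:, 1]].all()
        if len(path) > 1:
            assert tuple(path[0]) == tuple(path[-1])


@pytest.mark.parametrize("trial", range(5))
def test_boundary_soundness_random(trial, rng):
    rng = np.random.default_rng(trial)
    for _ in range(100):
        shape = (int(rng.integers(2, 30)), int(rng.integers(2, 30)))
        mask = rng.random(shape) < rng.uniform(0.2, 0.8)
        union = set()
        for path in trace_boundaries(mask):
            union |= {tuple(p) for p in path}
        assert union == outer_boundary_oracle(mask)


# --------------------------------------------------------------------- #
# field size


def test_field_size_trivial(rng):
    grid = flat_grid(40)
    pl, pr = _pop_pair(grid, np.zeros((40, 1)), np.zeros((40, 1)))
    assert field_size(combine_bilateral(pl, pr, "a0")) == 0
    lv = np.zeros((40, 1)); lv[:9] = 1.0
    pl, pr = _pop_pair(grid, lv, lv)
    assert field_size(combine_bilateral(pl, pr, "a0")) == 9


def test_field_size_matches_component_labeling_oracle(rng):
    grid = flat_grid(60)
    lv, rv = rng.random((60, 1)), rng.random((60, 1))
    pl, pr = _pop_pair(grid, lv, rv)
    fld = combine_bilateral(pl, pr, "a0", 0.25)
    # independent component labeling via flood fill
    remaining = {tuple(v) for v in np.argwhere(fld.mask)}
    total = 0
    while remaining:
        comp = flood_fill_8(fld.mask, next(iter(remaining)))
        comp &= remaining
        total += len(comp)
        remaining -= comp
    assert field_size(fld) == total == sum(fld.component_sizes)


# --------------------------------------------------------------------- #
# per-scan tables


def _two_sided_scan(grid, counts, subject="s1", age=6.0):
    return [counts_from_array(grid, counts, side="left", subject=subject, age=age),
            counts_from_array(grid, counts, side="right", subject=subject, age=age)]


def _meta(*subjects):
    return pd.DataFrame([{"subject_id": s, "sex": "male", "cohort": "X",
                          "scan_age_months": 6.0} for s in subjects])


def test_per_scan_field_size_constructed():
    grid = flat_grid(60)
    counts = np.zeros((60, 2), dtype=int)
    counts[:40, 0] = 5          # P(a0) = 1 on exactly 40 voxels
    counts[40:, 1] = 5          # elsewhere all mass on a1
    scans = _two_sided_scan(grid, counts)
    out = per_scan_fields(scans, _meta("s1"), "a0")
    assert len(out) == 1
    assert out.loc[0, "size_voxels"] == 40


def test_per_scan_field_size_zero_counts():
    grid = flat_grid(20)
    scans = _two_sided_scan(grid, np.zeros((20, 2), dtype=int))
    out = per_scan_fields(scans, _meta("s1"), "a0")
    assert out.loc[0, "size_voxels"] == 0


def test_per_scan_independence_duplicate_scan():
    grid = flat_grid(60)
    counts = np.zeros((60, 2), dtype=int)
    counts[:25, 0] = 5
    counts[25:, 1] = 5
    scans = (_two_sided_scan(grid, counts, subject="s1")
             + _two_sided_scan(grid, counts, subject="s2"))
    out = per_scan_fields(scans, _meta("s1", "s2"), "a0")
    assert len(out) == 2
    assert out["size_voxels"].tolist() == [25, 25]


def test_missing_hemisphere_skipped_with_warning(caplog):
    grid = flat_grid(20)
    counts = np.zeros((20, 1), dtype=int)
    counts[:, 0] = 5
    scans = [counts_from_array(grid, counts, side="left", subject="s1")]
    with caplog.at_level("WARNING"):
        out = per_scan_fields(scans, _meta("s1"), "a0")
    assert out.empty
    assert "missing one hemisphere" in caplog.text


def test_per_age_mode():
    grid = flat_grid(60)
    counts = np.zeros((60, 2), dtype=int)
    counts[:30, 0] = 5
    counts[30:, 1] = 5
    scans = (_two_sided_scan(grid, counts, subject="s1", age=6.0)
             + _two_sided_scan(grid, counts, subject="s2", age=6.0))
    out = per_scan_fields(scans, _meta("s1", "s2"), "a0", mode="per_age")
    assert len(out) == 1
    assert out.loc[0, "n_scans"] == 2
    assert out.loc[0, "size_voxels"] == 30


def test_per_scan_densities_and_field_mean():
    grid = flat_grid(20)
    counts = np.zeros((20, 2), dtype=int)
    counts[:10, 0] = 5          # P = 1 -> per-scan value 1 on 10 voxels
    counts[10:, 1] = 5
    scans = _two_sided_scan(grid, counts)
    mask = np.zeros(grid.shape, dtype=bool)
    vox = grid.voxels[:10]
    mask[vox[:, 0], vox[:, 1]] = True
    dens = per_scan_densities(scans, _meta("s1"), "a0", mask)
    assert len(dens) == 10
    assert np.allclose(dens["density"], 1.0)
    mean = field_mean_density(dens)
    assert len(mean) == 1 and mean.loc[0, "mean_density"] == pytest.approx(1.0)
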