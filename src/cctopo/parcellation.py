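"""Bilateral passage-field parcellation, boundary tracing and field sizes."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import EIGHT_CONN, VoxelGrid
from .popmap import (NormalizedMap, PopulationMap, StreamlineCounts,
                     ThresholdScheme, normalize_streamlines,
                     population_average)

__all__ = [
    "PassageField",
    "combine_bilateral",
    "trace_boundaries",
    "field_size",
    "per_scan_fields",
    "per_scan_densities",
    "field_mean_density",
    "DEFAULT_BILATERAL_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: 0.05 squared — the left*right product cut-off for bilateral fields.
DEFAULT_BILATERAL_THRESHOLD = 0.05 ** 2


@dataclass
class PassageField:
    """Binary bilateral passage field for one area with traced boundaries."""

    area_id: str
    mask: np.ndarray                 # (n_x, n_y) boolean over the full grid
    boundaries: list[np.ndarray]     # closed voxel paths, one per component
    size: int
    threshold: float
    grid: VoxelGrid

    @property
    def component_sizes(self) -> list[int]:
        lab, n = ndimage.label(self.mask, structure=EIGHT_CONN)
        return [int((lab == i).sum()) for i in range(1, n + 1)]


def combine_bilateral(left: PopulationMap, right: PopulationMap,
                      area_id: str,
                      thr_sq: float = DEFAULT_BILATERAL_THRESHOLD,
                      ) -> PassageField:
    """Threshold the voxelwise left*right product to get a bilateral field.

    A voxel is in the field iff the product of the two hemispheres'
    population values strictly exceeds ``thr_sq`` (default ``0.05**2``).
    """
    if not left.grid.same_geometry(right.grid):
        raise ValueError("left/right maps have mismatched grids")
    vl = left.area_values(area_id)   # raises KeyError if absent
    vr = right.area_values(area_id)
    masked = (vl * vr) > thr_sq
    mask2d = np.zeros(left.grid.shape, dtype=bool)
    vox = left.grid.voxels[masked]
    mask2d[vox[:, 0], vox[:, 1]] = True
    return PassageField(area_id=area_id, mask=mask2d,
                        boundaries=trace_boundaries(mask2d),
                        size=int(mask2d.sum()), threshold=thr_sq,
                        grid=left.grid)


# clockwise Moore neighbourhood offsets (dx, dy)
_CW = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _trace_component(comp: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of one 8-connected component's outer boundary.

    Returns a closed path (first voxel repeated at the end for components of
    more than one voxel).  Interior holes are never entered, so hole
    contours are suppressed by construction.
    """
    pts = np.argwhere(comp)
    if len(pts) == 1:
        return pts.copy()
    n_x, n_y = comp.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < n_x and 0 <= y < n_y and comp[x, y]

    start = (int(pts[0, 0]), int(pts[0, 1]))
    # the voxel scanned just before the start in row-major order is background
    state0 = (start, (start[0], start[1] - 1))
    cur, prev = state0
    path = [start]
    max_steps = 4 * len(pts) + 8
    for _ in range(max_steps):
        d = (prev[0] - cur[0], prev[1] - cur[1])
        i = _CW.index(d)
        nxt = None
        for k in range(1, 9):
            dx, dy = _CW[(i + k) % 8]
            cand = (cur[0] + dx, cur[1] + dy)
            if fg(*cand):
                nxt = cand
                bx, by = _CW[(i + k - 1) % 8]
                new_prev = (cur[0] + bx, cur[1] + by)
                break
        if nxt is None:  # pragma: no cover - single voxel handled above
            break
        if (nxt, new_prev) == state0:
            break
        path.append(nxt)
        cur, prev = nxt, new_prev
    path.append(start)  # close the loop
    return np.array(path, dtype=int)


def trace_boundaries(mask: np.ndarray) -> list[np.ndarray]:
    """Trace the outer boundary of every 8-connected component of a mask.

    Returns one closed path per component reachable from the outside;
    interior holes contribute no path, and components nested entirely
    inside another component's hole are suppressed with them (hole-free
    convention).  An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=EIGHT_CONN)
    # outer background: 4-connected background region touching the border
    padded = np.pad(mask, 1)
    bg_lab, _ = ndimage.label(~padded)  # default structure is 4-connectivity
    outer = bg_lab == bg_lab[0, 0]
    # components 4-adjacent to the outer background (or the grid edge)
    reach = np.zeros_like(padded)
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        reach |= np.roll(outer, (dx, dy), axis=(0, 1))
    reachable = reach[1:-1, 1:-1] & mask
    paths = []
    for i in range(1, n + 1):
        comp = lab == i
        if not (comp & reachable).any():
            continue  # nested inside a hole: not an outer contour
        paths.append(_trace_component(comp))
    return paths


def field_size(fieldobj: PassageField) -> int:
    """Number of voxels inside the field mask."""
    return int(fieldobj.mask.sum())


def _pair_scans(scans: list[StreamlineCounts]) -> dict:
    """Group scans by (subject, age) into {'left': ..., 'right': ...} dicts."""
    pairs: dict[tuple[str, float], dict[str, StreamlineCounts]] = {}
    for sc in scans:
        pairs.setdefault((sc.subject_id, sc.scan_age), {})[sc.side] = sc
    return pairs


def _metadata_lookup(metadata: pd.DataFrame) -> dict:
    info = {}
    for _, row in metadata.drop_duplicates("subject_id").iterrows():
        info[row["subject_id"]] = (row["sex"], row.get("cohort", ""))
    return info


def _single_scan_map(sc: StreamlineCounts,
                     scheme: ThresholdScheme) -> PopulationMap:
    return population_average([normalize_streamlines(sc)], scheme)


def per_scan_fields(scans: list[StreamlineCounts], metadata: pd.DataFrame,
                    area_id: str, scheme: ThresholdScheme | None = None,
                    thr_sq: float = DEFAULT_BILATERAL_THRESHOLD,
                    mode: str = "per_scan") -> pd.DataFrame:
    """Field size per scan (or per age group) for one area.

    ``mode="per_scan"`` runs the normalization/threshold-average pipeline on
    each scan alone (a single-sample population map) and sizes the bilateral
    field; rows are keyed by subject and age for the stats stage.
    ``mode="per_age"`` pools all scans at each age into one population map
    before sizing.  Scans missing one hemisphere are skipped with a warning.
    """
    if scheme is None:
        scheme = ThresholdScheme()
    if mode not in ("per_scan", "per_age"):
        raise ValueError(f"unknown mode {mode!r}")
    info = _metadata_lookup(metadata)
    pairs = _pair_scans(scans)

    if mode == "per_scan":
        rows = []
        for (sid, age), sides in sorted(pairs.items()):
            if "left" not in sides or "right" not in sides:
                logger.warning("scan (%s, %s) is missing one hemisphere; skipped",
                               sid, age)
                continue
            pop_l = _single_scan_map(sides["left"], scheme)
            pop_r = _single_scan_map(sides["right"], scheme)
            fld = combine_bilateral(pop_l, pop_r, area_id, thr_sq)
            sex, cohort = info.get(sid, ("", ""))
            rows.append({"subject_id": sid, "scan_age_months": age,
                         "sex": sex, "cohort": cohort, "area_id": area_id,
                         "size_voxels": fld.size})
        return pd.DataFrame(rows)

    by_age: dict[float, dict[str, list[NormalizedMap]]] = {}
    for (sid, age), sides in sorted(pairs.items()):
        if "left" not in sides or "right" not in sides:
            logger.warning("scan (%s, %s) is missing one hemisphere; skipped",
                           sid, age)
            continue
        slot = by_age.setdefault(age, {"left": [], "right": []})
        slot["left"].append(normalize_streamlines(sides["left"]))
        slot["right"].append(normalize_streamlines(sides["right"]))
    rows = []
    for age in sorted(by_age):
        pop_l = population_average(by_age[age]["left"], scheme)
        pop_r = population_average(by_age[age]["right"], scheme)
        fld = combine_bilateral(pop_l, pop_r, area_id, thr_sq)
        rows.append({"scan_age_months": age, "n_scans": pop_l.n_samples,
                     "area_id": area_id, "size_voxels": fld.size})
    return pd.DataFrame(rows)


def per_scan_densities(scans: list[StreamlineCounts], metadata: pd.DataFrame,
                       area_id: str, field_mask: np.ndarray,
                       scheme: ThresholdScheme | None = None) -> pd.DataFrame:
    """Per-scan voxelwise densities within a field, long format.

    The density at a voxel is the mean of the scan's left and right
    single-sample population values for the area.  One row per complete
    scan per field voxel; suitable input for the voxelwise mixed models.
    """
    if scheme is None:
        scheme = ThresholdScheme()
    field_mask = np.asarray(field_mask, dtype=bool)
    info = _metadata_lookup(metadata)
    pairs = _pair_scans(scans)
    rows = []
    for (sid, age), sides in sorted(pairs.items()):
        if "left" not in sides or "right" not in sides:
            logger.warning("scan (%s, %s) is missing one hemisphere; skipped",
                           sid, age)
            continue
        grid = sides["left"].grid
        in_field = field_mask[grid.voxels[:, 0], grid.voxels[:, 1]]
        pop_l = _single_scan_map(sides["left"], scheme)
        pop_r = _single_scan_map(sides["right"], scheme)
        dens = 0.5 * (pop_l.area_values(area_id) + pop_r.area_values(area_id))
        sex, cohort = info.get(sid, ("", ""))
        for vox, d in zip(grid.voxels[in_field], dens[in_field]):
            rows.append({"subject_id": sid, "scan_age_months": age,
                         "sex": sex, "cohort": cohort, "area_id": area_id,
                         "voxel_x": int(vox[0]), "voxel_y": int(vox[1]),
                         "density": float(d)})
    columns = ["subject_id", "scan_age_months", "sex", "cohort", "area_id",
               "voxel_x", "voxel_y", "density"]
    return pd.DataFrame(rows, columns=columns)


def field_mean_density(densities: pd.DataFrame) -> pd.DataFrame:
    """Collapse voxelwise densities to one mean-density row per scan."""
    keys = ["subject_id", "scan_age_months", "sex", "cohort", "area_id"]
    out = (densities.groupby(keys, as_index=False)["density"].mean()
           .rename(columns={"density": "mean_density"}))
    return out
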