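"""Readers and writers for the pipeline's plain-text and NIfTI formats.

Datasets are directories holding ``counts.tsv`` (long format), ``metadata.tsv``
and ``grid.json``.  All writers round-trip exactly through the matching
readers.  NIfTI export embeds the 2-D grid as a single-slice 3-D volume with
the voxel size in the affine and the anterior-commissure origin as the
affine translation.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .popmap import PopulationMap, StreamlineCounts, ThresholdScheme

__all__ = [
    "write_dataset", "read_dataset",
    "write_counts", "read_counts",
    "write_metadata", "read_metadata",
    "write_grid", "read_grid",
    "write_pop_map", "read_pop_map",
    "write_nifti_map", "read_nifti_map",
    "write_boundaries",
]

COUNT_COLUMNS = ["subject_id", "scan_age_months", "side", "voxel_x",
                 "voxel_y", "area_id", "count"]
METADATA_COLUMNS = ["subject_id", "sex", "cohort", "scan_age_months"]


# --------------------------------------------------------------------------- #
# grid


def write_grid(path: Path | str, grid: VoxelGrid, areas: tuple[str, ...]) -> None:
    payload = {
        "shape": list(grid.shape),
        "voxel_size": grid.voxel_size,
        "origin": list(grid.origin),
        "mask_voxels": grid.voxels.tolist(),
        "areas": list(areas),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_grid(path: Path | str) -> tuple[VoxelGrid, tuple[str, ...]]:
    payload = json.loads(Path(path).read_text())
    mask = np.zeros(tuple(payload["shape"]), dtype=bool)
    vox = np.asarray(payload["mask_voxels"], dtype=int)
    mask[vox[:, 0], vox[:, 1]] = True
    grid = VoxelGrid(shape=tuple(payload["shape"]),
                     voxel_size=payload["voxel_size"],
                     origin=tuple(payload["origin"]), mask=mask)
    return grid, tuple(payload["areas"])


# --------------------------------------------------------------------------- #
# counts


def write_counts(path: Path | str, scans: list[StreamlineCounts]) -> None:
    """Long-format TSV, zero counts omitted (the grid defines the voxel set)."""
    frames = []
    for sc in scans:
        vi, ai = np.nonzero(sc.counts)
        vox = sc.grid.voxels[vi]
        frames.append(pd.DataFrame({
            "subject_id": sc.subject_id,
            "scan_age_months": sc.scan_age,
            "side": sc.side,
            "voxel_x": vox[:, 0],
            "voxel_y": vox[:, 1],
            "area_id": np.asarray(sc.areas)[ai],
            "count": sc.counts[vi, ai],
        }))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=COUNT_COLUMNS))
    table.to_csv(path, sep="\t", index=False)


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} has unknown columns (ignored): {extra}")


def read_counts(path: Path | str, grid: VoxelGrid,
                areas: tuple[str, ...]) -> list[StreamlineCounts]:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, COUNT_COLUMNS, "counts table")
    if len(df) and (df["count"] < 0).any():
        raise ValueError("counts table contains negative counts")
    unknown = set(df["area_id"].unique()) - set(areas) if len(df) else set()
    if unknown:
        raise ValueError(f"counts table references unknown areas: {sorted(unknown)}")
    # map voxel indices to masked-vector positions
    index_of = {}
    for i, (x, y) in enumerate(grid.voxels):
        index_of[(int(x), int(y))] = i
    area_index = {a: j for j, a in enumerate(areas)}
    scans = []
    for (sid, age, side), sub in df.groupby(
            ["subject_id", "scan_age_months", "side"], sort=True):
        counts = np.zeros((grid.n_voxels, len(areas)), dtype=np.int64)
        for vx, vy, aid, c in zip(sub["voxel_x"], sub["voxel_y"],
                                  sub["area_id"], sub["count"]):
            key = (int(vx), int(vy))
            if key not in index_of:
                raise ValueError(f"voxel {key} lies outside the grid mask")
            counts[index_of[key], area_index[aid]] = int(c)
        scans.append(StreamlineCounts(str(sid), float(age), str(side),
                                      areas, counts, grid))
    return scans


# --------------------------------------------------------------------------- #
# metadata


def write_metadata(path: Path | str, metadata: pd.DataFrame) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, METADATA_COLUMNS, "metadata table")
    bad_sex = set(df["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"metadata has invalid sex values: {sorted(bad_sex)}")
    return df


# --------------------------------------------------------------------------- #
# dataset bundles


def write_dataset(directory: Path | str, scans: list[StreamlineCounts],
                  metadata: pd.DataFrame, grid: VoxelGrid) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    areas = scans[0].areas
    write_grid(directory / "grid.json", grid, areas)
    write_counts(directory / "counts.tsv", scans)
    write_metadata(directory / "metadata.tsv", metadata)
    return directory


def read_dataset(directory: Path | str
                 ) -> tuple[list[StreamlineCounts], pd.DataFrame, VoxelGrid]:
    directory = Path(directory)
    grid, areas = read_grid(directory / "grid.json")
    scans = read_counts(directory / "counts.tsv", grid, areas)
    metadata = read_metadata(directory / "metadata.tsv")
    return scans, metadata, grid


# --------------------------------------------------------------------------- #
# population maps


def write_pop_map(path: Path | str, pop: PopulationMap) -> None:
    vox = pop.grid.voxels
    rows = []
    for j, area in enumerate(pop.areas):
        rows.append(pd.DataFrame({
            "voxel_x": vox[:, 0], "voxel_y": vox[:, 1],
            "area_id": area, "p_hat": pop.values[:, j],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_pop_map(path: Path | str, grid: VoxelGrid, side: str,
                 scheme: ThresholdScheme, n_samples: int,
                 sample_unit: str = "scan") -> PopulationMap:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["voxel_x", "voxel_y", "area_id", "p_hat"],
                   "population map")
    areas = tuple(dict.fromkeys(df["area_id"]))
    index_of = {(int(x), int(y)): i for i, (x, y) in enumerate(grid.voxels)}
    values = np.zeros((grid.n_voxels, len(areas)))
    area_index = {a: j for j, a in enumerate(areas)}
    for vx, vy, aid, p in zip(df["voxel_x"], df["voxel_y"],
                              df["area_id"], df["p_hat"]):
        values[index_of[(int(vx), int(vy))], area_index[aid]] = p
    return PopulationMap(side=side, areas=areas, values=values,
                         n_samples=n_samples, scheme=scheme, grid=grid,
                         sample_unit=sample_unit)


# --------------------------------------------------------------------------- #
# NIfTI


def write_nifti_map(path: Path | str, values2d: np.ndarray,
                    grid: VoxelGrid) -> None:
    """Embed a full-grid 2-D map as a single-slice NIfTI-1 volume."""
    data = np.asarray(values2d, dtype=np.float32)[:, :, None]
    vs = grid.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    affine[0, 3] = -grid.origin[0] * vs
    affine[1, 3] = -grid.origin[1] * vs
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti_map(path: Path | str) -> tuple[np.ndarray, float,
                                              tuple[float, float]]:
    """Return (2-D values, voxel size, origin in grid units)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)[:, :, 0]
    affine = img.affine
    vs = float(affine[0, 0])
    origin = (float(-affine[0, 3] / vs), float(-affine[1, 3] / vs))
    return data, vs, origin


# --------------------------------------------------------------------------- #
# boundaries


def write_boundaries(path: Path | str, fields: dict) -> None:
    """JSON export of field boundaries: voxel paths plus mm coordinates."""
    payload = []
    for area_id, fld in fields.items():
        paths_index = [p.tolist() for p in fld.boundaries]
        paths_mm = [fld.grid.to_mm(p).tolist() for p in fld.boundaries]
        payload.append({"area_id": area_id, "threshold": fld.threshold,
                        "size_voxels": fld.size,
                        "paths_index": paths_index, "paths_mm": paths_mm})
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
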