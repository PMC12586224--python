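"""Left-right symmetry of passage fields via voxelwise linear regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popmap import PopulationMap

__all__ = [
    "SymmetryFit",
    "paired_voxel_values",
    "fit_symmetry",
    "classify_symmetric",
    "symmetry_table",
    "DEFAULT_SLOPE_BAND",
    "DEFAULT_R2_MIN",
]

DEFAULT_SLOPE_BAND = (0.5, 1.5)
DEFAULT_R2_MIN = 0.7


@dataclass
class SymmetryFit:
    """OLS fit of right-side on left-side population values for one area."""

    area_id: str
    n_voxels: int
    slope: float
    intercept: float
    r2_adjusted: float
    symmetric_flag: bool


def paired_voxel_values(left: PopulationMap, right: PopulationMap,
                        area_id: str,
                        inclusion: str = "nonzero_union") -> np.ndarray:
    """Collect per-voxel (left, right) value pairs for one area.

    ``inclusion="nonzero_union"`` (default) keeps voxels where either side
    is nonzero; ``"all"`` keeps every masked voxel.
    """
    if not left.grid.same_geometry(right.grid):
        raise ValueError("left/right maps have mismatched grids")
    vl = left.area_values(area_id)
    vr = right.area_values(area_id)
    if inclusion == "nonzero_union":
        keep = np.maximum(vl, vr) > 0
    elif inclusion == "all":
        keep = np.ones_like(vl, dtype=bool)
    else:
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    return np.column_stack([vl[keep], vr[keep]])


def fit_symmetry(pairs: np.ndarray, area_id: str = "") -> SymmetryFit:
    """Ordinary least squares of right on left with intercept.

    Refuses fits with fewer than 3 pairs or a degenerate (constant)
    predictor.  The adjusted R-squared uses the single-predictor formula
    ``1 - (1 - R2) * (n - 1) / (n - 2)``.
    """
    pairs = np.asarray(pairs, dtype=float)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"symmetry fit requires >= 3 voxel pairs, got {n}")
    x, y = pairs[:, 0], pairs[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate fit: left-side values are constant")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r2 = 1.0 if np.allclose(resid, 0) else 0.0
    else:
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    fit = SymmetryFit(area_id=area_id, n_voxels=n, slope=slope,
                      intercept=intercept, r2_adjusted=r2_adj,
                      symmetric_flag=False)
    fit.symmetric_flag = classify_symmetric(fit)
    return fit


def classify_symmetric(fit: SymmetryFit,
                       band: tuple[float, float] = DEFAULT_SLOPE_BAND,
                       r2_min: float = DEFAULT_R2_MIN) -> bool:
    """True iff the slope falls inside the closed band and R2 clears the floor."""
    return bool(band[0] <= fit.slope <= band[1] and fit.r2_adjusted > r2_min)


def symmetry_table(left: PopulationMap, right: PopulationMap,
                   areas: list[str] | None = None,
                   inclusion: str = "nonzero_union",
                   band: tuple[float, float] = DEFAULT_SLOPE_BAND,
                   r2_min: float = DEFAULT_R2_MIN) -> pd.DataFrame:
    """Fit all (or the given) areas, reporting unfittable ones as such."""
    if areas is None:
        areas = list(left.areas)
    rows = []
    for area in areas:
        pairs = paired_voxel_values(left, right, area, inclusion)
        try:
            fit = fit_symmetry(pairs, area)
        except ValueError:
            rows.append({"area_id": area, "n_voxels": len(pairs),
                         "slope": np.nan, "intercept": np.nan,
                         "r2_adjusted": np.nan, "symmetric_flag": False,
                         "fit_ok": False})
            continue
        fit.symmetric_flag = classify_symmetric(fit, band, r2_min)
        rows.append({"area_id": area, "n_voxels": fit.n_voxels,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "r2_adjusted": fit.r2_adjusted,
                     "symmetric_flag": fit.symmetric_flag, "fit_ok": True})
    return pd.DataFrame(rows)
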