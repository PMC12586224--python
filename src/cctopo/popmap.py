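"""Per-scan connectivity normalization and population-averaged maps.

The pipeline here is: raw streamline counts -> per-voxel normalized
connection probabilities -> binarization at a multi-threshold scheme ->
population average over sample units.  Detectability classification and
ROI mean profiles operate on the averaged maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import VoxelGrid

__all__ = [
    "StreamlineCounts",
    "NormalizedMap",
    "ThresholdScheme",
    "PopulationMap",
    "DetectabilityCriteria",
    "normalize_streamlines",
    "binarize_at_threshold",
    "population_average",
    "roi_mean_profile",
    "roi_mean_sem",
    "classify_detectability",
]

_SIDES = ("left", "right")


@dataclass
class StreamlineCounts:
    """Streamline counts from one scan, one hemisphere.

    ``counts[i, j]`` is the nonnegative integer number of streamlines from
    masked voxel ``i`` (in ``grid.voxels`` order) to cortical target ``j``.
    """

    subject_id: str
    scan_age: float
    side: str
    areas: tuple[str, ...]
    counts: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        self.areas = tuple(self.areas)
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area ids")
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind not in "iu":
            if not np.all(self.counts == np.rint(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (self.grid.n_voxels, len(self.areas)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({self.grid.n_voxels} masked voxels, {len(self.areas)} areas)")
        if (self.counts < 0).any():
            raise ValueError("negative streamline counts are invalid")


@dataclass
class NormalizedMap:
    """Row-normalized connection probabilities for one scan/side."""

    subject_id: str
    scan_age: float
    side: str
    areas: tuple[str, ...]
    values: np.ndarray          # (V, A) floats in [0, 1]
    zero_total_flags: np.ndarray  # (V,) True where the count row summed to 0
    grid: VoxelGrid


def normalize_streamlines(counts: StreamlineCounts) -> NormalizedMap:
    """Divide each voxel's counts by its row total.

    Voxels whose total count is zero are left as all-zero rows and flagged
    (the ratio is undefined there); every other row sums to 1.
    """
    c = counts.counts.astype(float)
    totals = c.sum(axis=1)
    zero = totals == 0
    values = np.zeros_like(c)
    np.divide(c, totals[:, None], out=values, where=~zero[:, None])
    return NormalizedMap(
        subject_id=counts.subject_id,
        scan_age=counts.scan_age,
        side=counts.side,
        areas=counts.areas,
        values=values,
        zero_total_flags=zero,
        grid=counts.grid,
    )


@dataclass(frozen=True)
class ThresholdScheme:
    """Strictly increasing exact-decimal thresholds, stored as thousandths.

    The default is the five-level scheme 0.100, 0.125, 0.150, 0.175, 0.200.
    Storing scaled integers keeps threshold values exact decimals so the
    strict-inequality convention at equality is unambiguous.
    """

    milli: tuple[int, ...] = (100, 125, 150, 175, 200)

    def __post_init__(self) -> None:
        milli = tuple(int(m) for m in self.milli)
        object.__setattr__(self, "milli", milli)
        if len(milli) == 0:
            raise ValueError("threshold scheme must contain at least one threshold")
        if any(not (0 < m < 1000) for m in milli):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(milli, milli[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "ThresholdScheme":
        milli = []
        for v in values:
            m = round(float(v) * 1000)
            if abs(float(v) * 1000 - m) > 1e-6:
                raise ValueError(
                    f"threshold {v} is not an exact multiple of 0.001")
            milli.append(m)
        return cls(tuple(milli))

    @property
    def values(self) -> np.ndarray:
        return np.array(self.milli, dtype=float) / 1000.0

    def __len__(self) -> int:
        return len(self.milli)


def binarize_at_threshold(normalized: NormalizedMap | np.ndarray,
                          thr: float) -> np.ndarray:
    """Strictly threshold a probability map: 1 where ``P > thr`` else 0.

    Values exactly equal to the threshold map to 0 (the defining inequality
    is strict).
    """
    if not (0 < thr < 1):
        raise ValueError(f"threshold must lie in (0, 1), got {thr}")
    values = normalized.values if isinstance(normalized, NormalizedMap) else np.asarray(normalized)
    return (values > thr).astype(np.uint8)


@dataclass
class PopulationMap:
    """Population-averaged exceedance map for one hemisphere.

    ``values[i, j]`` is the fraction of (sample unit, threshold) pairs whose
    normalized probability exceeded the threshold, so every entry is an
    integer multiple of ``1 / (n_samples * len(scheme))`` in per-scan mode.
    """

    side: str
    areas: tuple[str, ...]
    values: np.ndarray
    n_samples: int
    scheme: ThresholdScheme
    grid: VoxelGrid
    sample_unit: str = "scan"

    def area_index(self, area_id: str) -> int:
        try:
            return self.areas.index(area_id)
        except ValueError:
            raise KeyError(f"area {area_id!r} not present in map") from None

    def area_values(self, area_id: str) -> np.ndarray:
        return self.values[:, self.area_index(area_id)]


def population_average(samples: Sequence[NormalizedMap],
                       scheme: ThresholdScheme | None = None,
                       sample_unit: str = "scan") -> PopulationMap:
    """Average binarized maps over all thresholds and sample units.

    With ``sample_unit="scan"`` every map in ``samples`` is one unit; with
    ``"subject"`` maps are first averaged within ``subject_id`` and then
    across subjects.  The result is invariant to the ordering of
    ``samples`` (exceedances are accumulated as exact integers, and
    subjects are processed in sorted order).
    """
    if scheme is None:
        scheme = ThresholdScheme()
    if len(samples) == 0:
        raise ValueError("population_average requires at least one sample")
    if sample_unit not in ("scan", "subject"):
        raise ValueError(f"unknown sample_unit {sample_unit!r}")
    ref = samples[0]
    for s in samples[1:]:
        if s.areas != ref.areas:
            raise ValueError("samples have mismatched area sets")
        if s.side != ref.side:
            raise ValueError("samples mix hemispheres")
        if not s.grid.same_geometry(ref.grid):
            raise ValueError("samples have mismatched grids")

    thr = scheme.values
    m = len(scheme)

    def exceed_count(nm: NormalizedMap) -> np.ndarray:
        # (V, A) integer count of thresholds strictly exceeded
        return (nm.values[:, :, None] > thr[None, None, :]).sum(axis=2)

    if sample_unit == "scan":
        acc = np.zeros((ref.grid.n_voxels, len(ref.areas)), dtype=np.int64)
        for nm in samples:
            acc += exceed_count(nm)
        values = acc / (len(samples) * m)
        n_units = len(samples)
    else:
        by_subject: dict[str, list[NormalizedMap]] = {}
        for nm in samples:
            by_subject.setdefault(nm.subject_id, []).append(nm)
        subject_means = []
        for sid in sorted(by_subject):
            group = by_subject[sid]
            acc = np.zeros((ref.grid.n_voxels, len(ref.areas)), dtype=np.int64)
            for nm in group:
                acc += exceed_count(nm)
            subject_means.append(acc / (len(group) * m))
        values = np.mean(subject_means, axis=0)
        n_units = len(subject_means)

    return PopulationMap(side=ref.side, areas=ref.areas, values=values,
                         n_samples=n_units, scheme=scheme, grid=ref.grid,
                         sample_unit=sample_unit)


def roi_mean_profile(pop: PopulationMap,
                     area_sizes: Mapping[str, float]) -> pd.DataFrame:
    """Per-area mean over CC voxels, raw and divided by the cortical ROI size."""
    rows = []
    for j, area in enumerate(pop.areas):
        if area not in area_sizes:
            raise ValueError(f"missing ROI size for area {area!r}")
        size = float(area_sizes[area])
        if not size > 0:
            raise ValueError(f"ROI size for {area!r} must be positive, got {size}")
        mean = float(pop.values[:, j].mean())
        rows.append({"area_id": area, "mean_p": mean,
                     "size_normalized_mean": mean / size})
    return pd.DataFrame(rows)


def roi_mean_sem(samples: Sequence[NormalizedMap],
                 scheme: ThresholdScheme | None = None) -> pd.DataFrame:
    """Per-area mean of single-scan averaged maps with two SEM variants.

    Whether error bars should be computed across scans or across subjects is
    ambiguous for unbalanced designs, so both are reported: ``sem_scans``
    treats every scan as independent; ``sem_subjects`` first averages scans
    within subject.
    """
    if scheme is None:
        scheme = ThresholdScheme()
    per_scan = []   # scan-level mean over CC voxels, per area
    subjects = []
    for nm in samples:
        pop = population_average([nm], scheme)
        per_scan.append(pop.values.mean(axis=0))
        subjects.append(nm.subject_id)
    per_scan = np.asarray(per_scan)
    subjects = np.asarray(subjects)
    subj_means = np.asarray([per_scan[subjects == s].mean(axis=0)
                             for s in sorted(set(subjects))])
    n_scans, n_subj = len(per_scan), len(subj_means)
    rows = []
    for j, area in enumerate(samples[0].areas):
        rows.append({
            "area_id": area,
            "mean_p": float(per_scan[:, j].mean()),
            "sem_scans": float(per_scan[:, j].std(ddof=1) / np.sqrt(n_scans))
            if n_scans > 1 else np.nan,
            "sem_subjects": float(subj_means[:, j].std(ddof=1) / np.sqrt(n_subj))
            if n_subj > 1 else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DetectabilityCriteria:
    """Cut-offs separating passage-field, widespread-weak and undetectable areas.

    ``peak_high``: peak value above which an area has a concentrated passage
    field.  ``peak_low``: peak value below which streamlines count as weak.
    ``mean_min``: CC-mean floor distinguishing widespread-weak from
    undetectable.
    """

    peak_high: float = 0.15
    peak_low: float = 0.08
    mean_min: float = 0.01

    def __post_init__(self) -> None:
        if self.peak_low >= self.peak_high:
            raise ValueError(
                f"peak_low ({self.peak_low}) must be < peak_high ({self.peak_high})")
        if self.mean_min <= 0:
            raise ValueError("mean_min must be positive")


PASSAGE_FIELD = "passage_field"
WIDESPREAD_WEAK = "widespread_weak"
UNDETECTABLE = "undetectable"


def classify_detectability(left: PopulationMap,
                           right: PopulationMap | None = None,
                           criteria: DetectabilityCriteria | None = None,
                           ) -> pd.DataFrame:
    """Classify each area by its pooled left/right population map statistics.

    ``passage_field``: max voxel value > ``peak_high``.
    ``widespread_weak``: mean > ``mean_min`` while max < ``peak_low``.
    ``undetectable``: everything else.
    """
    if criteria is None:
        criteria = DetectabilityCriteria()
    if right is not None:
        if right.areas != left.areas:
            raise ValueError("left/right maps have mismatched area sets")
        pooled = np.concatenate([left.values, right.values], axis=0)
    else:
        pooled = left.values
    rows = []
    for j, area in enumerate(left.areas):
        col = pooled[:, j]
        vmax = float(col.max())
        vmean = float(col.mean())
        if vmax > criteria.peak_high:
            klass = PASSAGE_FIELD
        elif vmean > criteria.mean_min and vmax < criteria.peak_low:
            klass = WIDESPREAD_WEAK
        else:
            klass = UNDETECTABLE
        rows.append({"area_id": area, "max_p": vmax, "mean_p": vmean,
                     "class": klass,
                     "peak_high": criteria.peak_high,
                     "peak_low": criteria.peak_low,
                     "mean_min": criteria.mean_min})
    return pd.DataFrame(rows)
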