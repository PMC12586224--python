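"""Synthetic longitudinal streamline-count cohorts with known structure.

Generates unbalanced multi-cohort designs of per-scan, per-hemisphere
streamline-count matrices on a corpus-callosum-shaped grid.  The generative
model is log-linear in age and sex with subject-specific random intercepts,
so downstream recovery targets (symmetry slopes, mixed-model effects) have
closed-form ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .popmap import StreamlineCounts

__all__ = [
    "VoxelGrid",
    "AreaTemplate",
    "AreaEffect",
    "CohortSpec",
    "CohortDesign",
    "SubjectRecord",
    "make_cc_grid",
    "make_area_templates",
    "simulate_cohort",
    "mirror_counts",
    "asymmetry_field",
    "metadata_frame",
    "default_design",
    "small_design",
]

VALID_SCAN_AGES = (6.0, 12.0, 18.0, 24.0)


def make_cc_grid(n_x: int, n_y: int, voxel_size: float) -> VoxelGrid:
    """Build an elongated arc-shaped grid mimicking a midsagittal CC slice.

    Requires ``n_x >= 4 * n_y`` and ``n_y >= 2`` (the CC is much longer
    anterior-posterior than it is thick).  The anterior-commissure origin is
    placed at the grid's AP midpoint on the ventral edge.
    """
    if n_x <= 0 or n_y <= 0:
        raise ValueError(f"grid dimensions must be positive, got ({n_x}, {n_y})")
    if n_y < 2 or n_x < 4 * n_y:
        raise ValueError(
            f"grid must be elongated: need n_x >= 4*n_y and n_y >= 2, got ({n_x}, {n_y})")
    t = np.linspace(0.0, 1.0, n_x)
    # gently arched midline, thicker than half the grid height
    mid = (n_y - 1) * (0.45 + 0.25 * np.sin(np.pi * t))
    half = max(0.75, 0.35 * (n_y - 1))
    y = np.arange(n_y)
    mask = np.abs(y[None, :] - mid[:, None]) <= half
    origin = ((n_x - 1) / 2.0, 0.0)
    return VoxelGrid(shape=(n_x, n_y), voxel_size=voxel_size,
                     origin=origin, mask=mask)


@dataclass
class AreaTemplate:
    """Expected streamline rate per masked voxel for one cortical area/side."""

    area_id: str
    side: str
    intensity: np.ndarray  # (V,) nonnegative rates in grid.voxels order
    ap_center: float       # intensity-weighted AP centroid, mm
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if (self.intensity < 0).any():
            raise ValueError("template intensity must be nonnegative")
        if self.intensity.shape != (self.grid.n_voxels,):
            raise ValueError("intensity must be a masked-voxel vector")


def make_area_templates(grid: VoxelGrid,
                        area_specs: list[tuple[str, float, float, float]],
                        ) -> list[tuple[AreaTemplate, AreaTemplate]]:
    """Create (left, right) template pairs from ordered area specifications.

    ``area_specs`` is an anterior-to-posterior ordered list of
    ``(area_id, ap_position_mm, spread_mm, peak_rate)``.  Each template is a
    Gaussian bump along the AP axis restricted to the mask; left and right
    are identical (asymmetry is applied later at sampling time).
    """
    ids = [s[0] for s in area_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping (duplicate) area ids")
    ap_positions = [float(s[1]) for s in area_specs]
    if any(b <= a for a, b in zip(ap_positions, ap_positions[1:])):
        raise ValueError("area specs must be ordered with strictly increasing AP position")
    x = grid.x_mm
    lo, hi = x.min(), x.max()
    pairs = []
    for area_id, ap, spread, peak in area_specs:
        if not (lo <= ap <= hi):
            raise ValueError(
                f"AP position {ap} for {area_id!r} outside mask extent [{lo:.3f}, {hi:.3f}]")
        if not spread > 0:
            raise ValueError(f"spread for {area_id!r} must be positive")
        if not peak > 0:
            raise ValueError(f"peak_rate for {area_id!r} must be positive")
        intensity = peak * np.exp(-0.5 * ((x - ap) / spread) ** 2)
        centroid = float(np.average(x, weights=intensity))
        left = AreaTemplate(area_id, "left", intensity, centroid, grid)
        right = AreaTemplate(area_id, "right", intensity.copy(), centroid, grid)
        pairs.append((left, right))
    return pairs


@dataclass(frozen=True)
class AreaEffect:
    """Per-area generative effects on the log expected rate."""

    age_slope: float = 0.0   # per month
    sex_effect: float = 0.0  # added for females (males are the reference)


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_subjects: int
    n_females: int
    scan_ages: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError(f"cohort {self.name!r} has no subjects")
        if not 0 <= self.n_females <= self.n_subjects:
            raise ValueError(f"cohort {self.name!r}: invalid female count")
        ages = tuple(float(a) for a in self.scan_ages)
        object.__setattr__(self, "scan_ages", ages)
        if len(ages) == 0:
            raise ValueError(f"cohort {self.name!r} has no scheduled scans")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("scheduled scan ages must be strictly increasing")
        if any(a not in VALID_SCAN_AGES for a in ages):
            raise ValueError(f"scan ages must be drawn from {VALID_SCAN_AGES}")


@dataclass(frozen=True)
class CohortDesign:
    """Full generative design for a longitudinal cohort simulation."""

    cohorts: tuple[CohortSpec, ...]
    effects: dict = field(default_factory=dict)  # area_id -> AreaEffect
    dropout: float = 0.0          # per-interval Bernoulli probability
    subject_sd: float = 0.0       # SD of the subject random intercept (log scale)
    asymmetry: float = 0.0        # bound on the left/right rate perturbation
    dispersion: float = 0.0       # NB dispersion; 0 -> Poisson
    noise_free: bool = False      # deterministic rounded rates, no sampling
    reference_age: float = 6.0    # months; age effects are relative to this
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        if len(self.cohorts) == 0:
            raise ValueError("design contains no cohorts")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout probability must lie in [0, 1]")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory (reproducibility contract)")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: str
    cohort: str
    scan_ages: tuple[float, ...]


def metadata_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format subject metadata: one row per realized scan."""
    rows = []
    for r in records:
        for age in r.scan_ages:
            rows.append({"subject_id": r.subject_id, "sex": r.sex,
                         "cohort": r.cohort, "scan_age_months": age})
    return pd.DataFrame(rows)


def asymmetry_field(grid: VoxelGrid, asymmetry: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative left/right perturbation bounded by the asymmetry.

    Returns per-voxel multipliers in ``[1/(1+a), 1+a]``; ``a == 0`` gives the
    all-ones field.
    """
    if asymmetry < 0:
        raise ValueError("asymmetry must be >= 0")
    if asymmetry == 0:
        return np.ones(grid.n_voxels)
    x = grid.x_mm
    y = grid.y_mm
    span_x = max(x.max() - x.min(), grid.voxel_size)
    span_y = max(y.max() - y.min(), grid.voxel_size)
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=2)
    s = np.sin(2 * np.pi * x / span_x + phase_x) * np.cos(np.pi * y / span_y + phase_y)
    return (1.0 + asymmetry) ** s


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float, noise_free: bool) -> np.ndarray:
    """Nonnegative integer counts with mean ``mu``.

    Negative binomial with Var = mu + dispersion * mu**2; Poisson at
    dispersion 0; deterministic rounding when noise-free.
    """
    if noise_free:
        return np.rint(mu).astype(np.int64)
    if dispersion <= 0:
        return rng.poisson(mu).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_cohort(design: CohortDesign, grid: VoxelGrid,
                    templates: list[tuple[AreaTemplate, AreaTemplate]],
                    ) -> tuple[list[StreamlineCounts], list[SubjectRecord]]:
    """Simulate streamline counts for every realized scan of every subject.

    The expected left-hemisphere count for voxel ``v``, area ``b`` at age
    ``a`` is ``rate_b(v) * exp(slope_b * (a - ref) + sex_b * female + u_k)``
    with ``u_k ~ N(0, subject_sd**2)``.  The right hemisphere applies the
    smooth asymmetry perturbation to the expected rates before sampling;
    with asymmetry 0 the right matrix is an exact copy of the left.
    Identical designs (including the seed) produce bit-identical output.
    """
    for left, right in templates:
        if not left.grid.same_geometry(grid) or not right.grid.same_geometry(grid):
            raise ValueError("templates are not defined on the given grid")
    rng = np.random.default_rng(design.seed)
    areas = tuple(pair[0].area_id for pair in templates)
    base = np.column_stack([pair[0].intensity for pair in templates])  # (V, A)
    slopes = np.array([design.effects.get(a, AreaEffect()).age_slope for a in areas])
    sex_effects = np.array([design.effects.get(a, AreaEffect()).sex_effect for a in areas])

    scans: list[StreamlineCounts] = []
    records: list[SubjectRecord] = []
    counter = 0
    for cohort in design.cohorts:
        for i in range(cohort.n_subjects):
            counter += 1
            sid = f"{cohort.name}{counter:03d}"
            sex = "female" if i < cohort.n_females else "male"
            u = rng.normal(0.0, design.subject_sd) if design.subject_sd > 0 else 0.0
            realized = [cohort.scan_ages[0]]
            for age in cohort.scan_ages[1:]:
                if design.dropout > 0 and rng.random() < design.dropout:
                    break  # monotone dropout: no re-entry
                realized.append(age)
            records.append(SubjectRecord(sid, sex, cohort.name, tuple(realized)))
            for age in realized:
                logmult = (slopes * (age - design.reference_age)
                           + sex_effects * (sex == "female") + u)
                rate_l = base * np.exp(logmult)[None, :]
                counts_l = _draw_counts(rng, rate_l, design.dispersion,
                                        design.noise_free)
                scans.append(StreamlineCounts(sid, age, "left", areas,
                                              counts_l, grid))
                if design.asymmetry > 0:
                    m = asymmetry_field(grid, design.asymmetry, rng)
                    rate_r = rate_l * m[:, None]
                    counts_r = _draw_counts(rng, rate_r, design.dispersion,
                                            design.noise_free)
                else:
                    counts_r = counts_l.copy()
                scans.append(StreamlineCounts(sid, age, "right", areas,
                                              counts_r, grid))
    if not scans:
        raise ValueError("design produced no scans")
    return scans, records


def mirror_counts(left: StreamlineCounts, asymmetry: float,
                  rng: np.random.Generator | None = None) -> StreamlineCounts:
    """Produce a right-hemisphere matrix from a left one.

    With asymmetry 0 the counts are an exact copy.  Otherwise the left
    counts (taken as expected rates) are multiplied by a smooth perturbation
    bounded by the asymmetry factor and re-sampled from a Poisson.
    """
    if asymmetry < 0:
        raise ValueError("asymmetry must be >= 0")
    if asymmetry == 0:
        return replace(left, side="right", counts=left.counts.copy())
    if rng is None:
        raise ValueError("an rng is required when asymmetry > 0")
    m = asymmetry_field(left.grid, asymmetry, rng)
    mu = left.counts * m[:, None]
    return replace(left, side="right",
                   counts=rng.poisson(mu).astype(np.int64))


# --------------------------------------------------------------------------- #
# Bundled designs


def default_area_specs() -> list[tuple[str, float, float, float]]:
    """Area templates for the bundled default design (60 x 12 grid).

    Eight concentrated areas ordered anterior to posterior, three weak
    widespread areas, and two near-silent areas.  Peak rates put the busiest
    voxels near a total budget of ~5000 streamlines.
    """
    return [
        ("ILA", -4.6, 1.0, 2800.0),
        ("ORB", -3.4, 0.8, 2800.0),
        ("AI", -2.6, 4.5, 150.0),
        ("MO", -2.0, 1.2, 3200.0),
        ("ACA", -1.0, 1.1, 3000.0),
        ("GU", -0.5, 5.0, 140.0),
        ("SSp_m", -0.2, 0.9, 3200.0),
        ("TEa", 0.4, 3.0, 30.0),
        ("SSp_bfd", 1.0, 0.9, 3200.0),
        ("AUD", 1.5, 4.5, 150.0),
        ("VISC", 2.0, 3.0, 25.0),
        ("RSP", 2.4, 1.0, 3000.0),
        ("VIS", 4.2, 1.0, 2800.0),
    ]


def default_design(seed: int) -> CohortDesign:
    """Three-cohort, 66-subject design emulating the studied population."""
    effects = {
        "ORB": AreaEffect(age_slope=-0.010, sex_effect=0.35),
        "ACA": AreaEffect(age_slope=-0.025),
        "MO": AreaEffect(age_slope=-0.020),
        "RSP": AreaEffect(age_slope=-0.020),
        "SSp_m": AreaEffect(age_slope=0.012),
        "SSp_bfd": AreaEffect(age_slope=0.020),
    }
    return CohortDesign(
        cohorts=(
            CohortSpec("A", 22, 6, (12.0, 18.0, 24.0)),
            CohortSpec("B", 12, 4, (6.0, 12.0, 18.0, 24.0)),
            CohortSpec("C", 32, 10, (6.0, 12.0, 18.0, 24.0)),
        ),
        effects=effects,
        dropout=0.12,
        subject_sd=0.12,
        asymmetry=0.08,
        dispersion=0.08,
        seed=seed,
    )


def small_area_specs() -> list[tuple[str, float, float, float]]:
    """Compact five-area layout for the small (smoke/test) design."""
    return [
        ("ORB", -1.8, 0.5, 2600.0),
        ("MO", -0.8, 0.6, 3000.0),
        ("ACA", 0.2, 0.6, 3000.0),
        ("RSP", 1.2, 0.6, 3000.0),
        ("VIS", 2.2, 0.5, 2600.0),
    ]


def small_design(seed: int) -> CohortDesign:
    """Single-cohort 12-subject design for fast end-to-end runs."""
    effects = {
        "ORB": AreaEffect(sex_effect=0.3),
        "ACA": AreaEffect(age_slope=-0.02),
        "RSP": AreaEffect(age_slope=0.015),
    }
    return CohortDesign(
        cohorts=(CohortSpec("S", 12, 4, (6.0, 12.0, 18.0, 24.0)),),
        effects=effects,
        dropout=0.1,
        subject_sd=0.1,
        asymmetry=0.0,
        dispersion=0.05,
        seed=seed,
    )
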