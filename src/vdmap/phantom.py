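"""Synthetic hemisphere phantoms with analytic ground-truth territories.

Real vessel delineations are manual voxel labels on in-vivo MRI and cannot
be shipped; the phantom module replaces them with a fully parametric scene
whose correct answer is known in closed form:

* the cortical ROI is a section of a cylindrical shell — a gyrus-like
  curved gray-matter sheet of configurable radius, thickness and angular
  extent;
* each artery is a parametric curve (ordered 3D control points in mm,
  interpreted as a polyline) running a few mm outside the sheet, mimicking
  pial arteries; it is rasterized onto the grid by marking every voxel
  whose center lies within a fixed radius of the curve;
* the ground-truth supply territory of each ROI voxel is its nearest
  *continuous* curve (exact point-to-polyline distance), independent of the
  voxel-based distance transform used downstream — so discretization error
  of the pipeline is measurable, not baked into the reference.

Cohorts pair a list of phantoms with a covariate table (age, sex, mean
cortical thickness) generated from a linear model with Gaussian noise, so
the regression machinery can be validated against known effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .volumes import (
    CANONICAL_VESSELS,
    HEMISPHERE_COLUMNS,
    LabeledVolume,
    VESSEL_IDS,
    VoxelGrid,
)

__all__ = [
    "CortexSpec",
    "VesselSpec",
    "PhantomConfig",
    "PhantomTruth",
    "Phantom",
    "CohortConfig",
    "polyline_distance",
    "default_phantom_config",
    "mirrored_phantom_config",
    "generate_phantom",
    "generate_cohort",
    "CANONICAL_COMPOSITIONS",
]

#: Default composition for each pattern size, following the dominant
#: anatomical variants: three-vessel supply is always the MCA precentral and
#: central groups plus one ACA branch; four-vessel supply most often adds
#: the second ACA branch; five-vessel supply involves all arteries.
CANONICAL_COMPOSITIONS: dict[int, tuple[int, ...]] = {
    1: (1,),
    2: (1, 4),
    3: (1, 3, 4),
    4: (1, 2, 3, 4),
    5: (1, 2, 3, 4, 5),
}


@dataclass(frozen=True)
class CortexSpec:
    """Cylindrical-shell section standing in for a curved cortical sheet.

    The cylinder axis is parallel to the third grid axis and passes through
    ``center`` (x, y in mm). The sheet occupies radii within
    ``thickness / 2`` of ``radius`` and polar angles within
    ``angle_extent_deg / 2`` of ``angle_center_deg``.
    """

    center: tuple[float, float]
    radius: float
    thickness: float = 2.5
    angle_center_deg: float = 90.0
    angle_extent_deg: float = 120.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("cortex thickness must be > 0")
        if self.radius <= self.thickness / 2:
            raise ValueError("cortex radius must exceed half its thickness")


@dataclass(frozen=True)
class VesselSpec:
    """One artery: a label id, an ordered polyline (mm), and a presence flag."""

    vessel_id: int
    points: np.ndarray
    present: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("vessel curve needs >= 2 control points of 3 coordinates")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class PhantomConfig:
    grid: VoxelGrid
    cortex: CortexSpec
    vessels: tuple[VesselSpec, ...]
    raster_radius_mm: float | None = None  # None -> one voxel (mean spacing)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessels", tuple(self.vessels))
        if not any(v.present for v in self.vessels):
            raise ValueError("at least one vessel must be present")


@dataclass
class PhantomTruth:
    """Analytic nearest-curve territories and the fractions they imply."""

    territories: LabeledVolume
    fractions: dict[int, float]


class Phantom(NamedTuple):
    volume: LabeledVolume
    roi_mask: np.ndarray
    truth: PhantomTruth
    composition: tuple[int, ...]


def polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each query point to a polyline (mm).

    ``points`` is (n, 3); ``polyline`` is (k, 3) ordered control points.
    """
    points = np.asarray(points, dtype=float)
    polyline = np.asarray(polyline, dtype=float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = (ab**2).sum(axis=-1)
    denom_safe = np.where(denom == 0.0, 1.0, denom)
    best = np.full(points.shape[0], np.inf)
    # chunk the query points to bound the (n, m, 3) temporaries
    for start in range(0, points.shape[0], 65536):
        p = points[start : start + 65536, None, :]
        t = ((p - a[None]) * ab[None]).sum(axis=-1) / denom_safe
        np.clip(t, 0.0, 1.0, out=t)
        proj = a[None] + t[..., None] * ab[None]
        d = np.sqrt(((p - proj) ** 2).sum(axis=-1)).min(axis=1)
        best[start : start + 65536] = d
    return best


def _arc_points(
    center: tuple[float, float],
    radius: float,
    theta_start_deg: float,
    theta_end_deg: float,
    z: float,
    n_points: int = 9,
) -> np.ndarray:
    theta = np.radians(np.linspace(theta_start_deg, theta_end_deg, n_points))
    return np.column_stack(
        [
            center[0] + radius * np.cos(theta),
            center[1] + radius * np.sin(theta),
            np.full(n_points, z),
        ]
    )


def default_phantom_config(
    present: Iterable[int | str] | int = 5,
    grid: VoxelGrid | None = None,
    vessel_offset_mm: float = 2.8,
    seed: int = 0,
) -> PhantomConfig:
    """Canonical phantom: a 120° shell with up to five pial arcs outside it.

    ``present`` is a pattern size (uses :data:`CANONICAL_COMPOSITIONS`) or an
    explicit composition of vessel ids/names. All five arteries keep fixed
    angular sectors; absent ones are simply not rasterized, so their sector
    is absorbed by the neighbors — the same mechanism by which a missing ACA
    branch hands its territory to the remaining one in vivo.
    """
    if grid is None:
        grid = VoxelGrid((64, 64, 64))
    present_ids = _parse_composition(present)

    extent = tuple((grid.shape[a] - 1) * grid.spacing[a] for a in range(3))
    center = (
        grid.origin[0] + extent[0] / 2.0,
        grid.origin[1] + extent[1] / 2.0,
    )
    radius = 0.31 * min(extent[0], extent[1])
    cortex = CortexSpec(center=center, radius=radius)
    # keep arcs inside the grid even on coarse/small test grids
    vessel_radius = min(
        radius + cortex.thickness / 2.0 + vessel_offset_mm,
        0.47 * min(extent[0], extent[1]),
    )
    z_mid = grid.origin[2] + extent[2] / 2.0

    theta_lo = cortex.angle_center_deg - cortex.angle_extent_deg / 2.0
    sector = cortex.angle_extent_deg / 5.0
    margin = 0.15 * sector
    vessels = []
    for k, vid in enumerate(sorted(CANONICAL_VESSELS)):
        start = theta_lo + k * sector + margin
        end = theta_lo + (k + 1) * sector - margin
        vessels.append(
            VesselSpec(
                vessel_id=vid,
                points=_arc_points(center, vessel_radius, start, end, z_mid),
                present=vid in present_ids,
            )
        )
    return PhantomConfig(grid=grid, cortex=cortex, vessels=tuple(vessels), seed=seed)


def mirrored_phantom_config(
    pairs: Sequence[tuple[int, int]] = ((1, 2),),
    grid: VoxelGrid | None = None,
    vessel_offset_mm: float = 2.8,
    seed: int = 0,
) -> PhantomConfig:
    """Phantom whose vessel pairs are exact mirror images about the sheet's
    mid-angle plane.

    Each ``(a, b)`` pair places one arc on the high-angle side of the cortex
    section and its point-wise mirrored copy on the low-angle side, so both
    vessels see geometrically identical ROI halves and must split the ROI
    50/50 within rasterization error — the canonical symmetry check for the
    winner-takes-all parcellation.
    """
    if grid is None:
        grid = VoxelGrid((64, 64, 64))
    extent = tuple((grid.shape[a] - 1) * grid.spacing[a] for a in range(3))
    center = (
        grid.origin[0] + extent[0] / 2.0,
        grid.origin[1] + extent[1] / 2.0,
    )
    radius = 0.31 * min(extent[0], extent[1])
    cortex = CortexSpec(center=center, radius=radius)
    vessel_radius = min(
        radius + cortex.thickness / 2.0 + vessel_offset_mm,
        0.47 * min(extent[0], extent[1]),
    )
    z_mid = grid.origin[2] + extent[2] / 2.0

    half = cortex.angle_extent_deg / 2.0
    sector = half / len(pairs)
    vessels = []
    for k, (a, b) in enumerate(pairs):
        margin = 0.15 * sector
        start = cortex.angle_center_deg + k * sector + margin
        end = cortex.angle_center_deg + (k + 1) * sector - margin
        arc_hi = _arc_points(center, vessel_radius, start, end, z_mid)
        arc_lo = arc_hi[::-1].copy()
        arc_lo[:, 0] = 2.0 * center[0] - arc_lo[:, 0]  # mirror across mid-plane
        vessels.append(VesselSpec(vessel_id=int(a), points=arc_hi))
        vessels.append(VesselSpec(vessel_id=int(b), points=arc_lo))
    vessels.sort(key=lambda v: v.vessel_id)
    return PhantomConfig(grid=grid, cortex=cortex, vessels=tuple(vessels), seed=seed)


def _parse_composition(present: Iterable[int | str] | int) -> tuple[int, ...]:
    if isinstance(present, (int, np.integer)):
        if int(present) not in CANONICAL_COMPOSITIONS:
            raise ValueError(f"no canonical composition with {present} vessels")
        return CANONICAL_COMPOSITIONS[int(present)]
    ids = []
    for item in present:
        if isinstance(item, str):
            if item not in VESSEL_IDS:
                raise ValueError(f"unknown vessel name {item!r}")
            ids.append(VESSEL_IDS[item])
        else:
            if int(item) not in CANONICAL_VESSELS:
                raise ValueError(f"unknown vessel id {item}")
            ids.append(int(item))
    if not ids:
        raise ValueError("composition must name at least one vessel")
    if len(set(ids)) != len(ids):
        raise ValueError("composition lists a vessel twice")
    return tuple(sorted(ids))


def generate_phantom(
    config: PhantomConfig,
) -> tuple[LabeledVolume, np.ndarray, PhantomTruth]:
    """Rasterize a phantom scene and compute its analytic territory truth."""
    grid = config.grid
    centers = grid.voxel_centers().reshape(-1, 3)

    cx, cy = config.cortex.center
    dx = centers[:, 0] - cx
    dy = centers[:, 1] - cy
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))
    dtheta = (theta - config.cortex.angle_center_deg + 180.0) % 360.0 - 180.0
    roi_flat = (np.abs(r - config.cortex.radius) <= config.cortex.thickness / 2.0) & (
        np.abs(dtheta) <= config.cortex.angle_extent_deg / 2.0
    )
    if not roi_flat.any():
        raise ValueError("cortex sheet does not intersect the grid")

    radius_mm = (
        config.raster_radius_mm
        if config.raster_radius_mm is not None
        else float(np.mean(grid.spacing))
    )

    present = [v for v in config.vessels if v.present]
    voxels = np.zeros(centers.shape[0], dtype=np.int32)
    dists = {}
    for spec in sorted(present, key=lambda v: v.vessel_id):
        d = polyline_distance(centers, spec.points)
        dists[spec.vessel_id] = d
        hit = (d <= radius_mm) & (voxels == 0)  # overlaps keep the smaller id
        if not (d <= radius_mm).any():
            warnings.warn(
                f"vessel {spec.vessel_id} rasterizes to no voxel (curve outside grid?)",
                stacklevel=2,
            )
        voxels[hit] = spec.vessel_id

    ids = np.asarray(sorted(dists), dtype=np.int32)
    stack = np.stack([dists[v] for v in ids], axis=0)
    winner = ids[np.argmin(stack, axis=0)]  # ties -> smallest id
    truth_flat = np.where(roi_flat, winner, 0).astype(np.int32)

    n_roi = int(roi_flat.sum())
    fractions = {
        int(v): float(np.count_nonzero(truth_flat == v)) / n_roi for v in ids
    }
    shape = grid.shape
    volume = LabeledVolume(grid, voxels.reshape(shape), dict(CANONICAL_VESSELS))
    territories = LabeledVolume(
        grid, truth_flat.reshape(shape), dict(CANONICAL_VESSELS)
    )
    return volume, roi_flat.reshape(shape), PhantomTruth(territories, fractions)


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort: pattern mix plus a linear thickness model.

    Thickness (mm) per hemisphere is
    ``intercept + sex_effect * 1[male] + age_slope * age + N(0, noise_sd)``.
    Defaults emulate a healthy young-adult cohort of 38 hemispheres with a
    4-vessel pattern about twice as frequent as the 3- and 5-vessel ones,
    ages around 31 ± 6 years, mean thickness near 2.53 mm and a sex effect
    large relative to the residual scatter.
    """

    n_hemispheres: int = 38
    pattern_mix: Mapping[int | tuple, int] = field(
        default_factory=lambda: {3: 10, 4: 19, 5: 9}
    )
    grid: VoxelGrid | None = None
    thickness_intercept_mm: float = 2.70
    sex_effect_mm: float = -0.11
    age_slope_mm_per_year: float = -0.0045
    noise_sd_mm: float = 0.05
    age_range_years: tuple[float, float] = (22.0, 42.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise ValueError("noise sd must be >= 0")
        if sum(self.pattern_mix.values()) != self.n_hemispheres:
            raise ValueError(
                f"pattern counts sum to {sum(self.pattern_mix.values())}, "
                f"expected n_hemispheres = {self.n_hemispheres}"
            )


def generate_cohort(config: CohortConfig) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate phantoms with the requested pattern mix plus a covariate table."""
    rng = np.random.default_rng(config.seed)

    compositions: list[tuple[int, ...]] = []
    for key in sorted(config.pattern_mix, key=str):
        comp = _parse_composition(key)
        compositions.extend([comp] * config.pattern_mix[key])
    order = rng.permutation(len(compositions))
    compositions = [compositions[i] for i in order]

    phantoms: list[Phantom] = []
    rows = []
    for i, comp in enumerate(compositions):
        cfg = default_phantom_config(
            present=comp, grid=config.grid, seed=int(rng.integers(2**31))
        )
        volume, roi, truth = generate_phantom(cfg)
        phantoms.append(Phantom(volume, roi, truth, comp))

        age = float(rng.uniform(*config.age_range_years))
        sex = "male" if rng.random() < 0.5 else "female"
        thickness = (
            config.thickness_intercept_mm
            + config.sex_effect_mm * (sex == "male")
            + config.age_slope_mm_per_year * age
            + (rng.normal(0.0, config.noise_sd_mm) if config.noise_sd_mm > 0 else 0.0)
        )
        rows.append(
            {
                "subject": f"S{i // 2 + 1:02d}",
                "hemisphere": "left" if i % 2 == 0 else "right",
                "age": age,
                "sex": sex,
                "region": "motor",
                "thickness_mm": thickness,
                "n_vessels": len(comp),
            }
        )
    table = pd.DataFrame(rows, columns=HEMISPHERE_COLUMNS + ["n_vessels"])
    return phantoms, table
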