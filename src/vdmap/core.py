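"""Per-artery distance maps and winner-takes-all supply territories.

For every voxel center ``x`` and artery ``v`` the vessel distance map (VDM)
holds

.. math:: d_v(x) = \\min_{y \\in S_v} \\lVert x - y \\rVert_2

where ``S_v`` is the set of voxel centers carrying the label of ``v`` and
the norm is Euclidean in physical mm (anisotropic spacing honored). The
cortical ROI is then parcellated by assigning each ROI voxel the label of
its closest artery — a winner-takes-all rule: only the nearest vessel
counts, relative closeness of the runners-up does not. The relative size of
each territory within the ROI is the vessel's supply volume fraction, the
quantity every downstream pattern/dominance analysis consumes.

Arteries that are absent (no labeled voxel) are skipped and receive supply
fraction exactly 0. Distance ties are broken toward the smallest vessel id
so that parcellations are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volumes import CANONICAL_VESSELS, LabeledVolume, VoxelGrid

__all__ = [
    "DistanceMap",
    "TerritoryParcellation",
    "SupplyFractionRecord",
    "compute_distance_map",
    "combined_vdm",
    "parcellate",
    "supply_fractions",
]


@dataclass
class DistanceMap:
    """Shortest physical distance (mm) from every voxel center to one artery."""

    grid: VoxelGrid
    values: np.ndarray
    vessel_id: int
    empty: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("distance array shape does not match grid")


@dataclass
class TerritoryParcellation:
    """Winner-takes-all territory labels, nonzero only inside the ROI."""

    grid: VoxelGrid
    labels: np.ndarray
    vessel_ids: tuple[int, ...]


@dataclass
class SupplyFractionRecord:
    """Per-vessel fraction of ROI voxels assigned to each supply territory.

    Fractions are voxel-count ratios; absent vessels carry exactly 0 and the
    nonzero fractions sum to 1 (up to floating round-off).
    """

    key: str
    fractions: dict[int, float]
    roi_voxel_count: int
    roi_volume_mm3: float
    labels: dict[int, str] = field(default_factory=lambda: dict(CANONICAL_VESSELS))

    def fraction(self, vessel_id: int) -> float:
        return self.fractions.get(vessel_id, 0.0)

    def present_ids(self) -> list[int]:
        return [vid for vid, f in sorted(self.fractions.items()) if f > 0]


def compute_distance_map(volume: LabeledVolume, vessel_id: int) -> DistanceMap:
    """Exact Euclidean distance transform to one artery's voxels.

    Returns a map flagged ``empty`` (all +inf) when the artery has no voxel;
    an absent vessel is a normal anatomical situation, not an error.
    """
    vessel_id = int(vessel_id)
    if vessel_id not in volume.labels:
        raise KeyError(f"vessel id {vessel_id} not in label map {sorted(volume.labels)}")
    source = volume.mask(vessel_id)
    if not source.any():
        values = np.full(volume.grid.shape, np.inf)
        return DistanceMap(volume.grid, values, vessel_id, empty=True)
    values = ndimage.distance_transform_edt(~source, sampling=volume.grid.spacing)
    return DistanceMap(volume.grid, np.asarray(values, dtype=float), vessel_id)


def combined_vdm(volume: LabeledVolume) -> DistanceMap:
    """Distance to the pooled vasculature: voxel-wise min over all vessels."""
    source = volume.voxels != 0
    if not source.any():
        raise ValueError("volume contains no vessel voxels")
    values = ndimage.distance_transform_edt(~source, sampling=volume.grid.spacing)
    return DistanceMap(volume.grid, np.asarray(values, dtype=float), vessel_id=0)


def parcellate(
    volume: LabeledVolume,
    roi_mask: np.ndarray,
    vessel_ids: Sequence[int] | None = None,
) -> TerritoryParcellation:
    """Assign each ROI voxel the label of its nearest artery.

    Empty vessels are skipped. Equidistant voxels go to the smallest vessel
    id: the id list is scanned in increasing order and ``argmin`` keeps the
    first minimum.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if tuple(roi_mask.shape) != volume.grid.shape:
        raise ValueError("ROI mask shape does not match volume grid")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if vessel_ids is None:
        vessel_ids = sorted(volume.labels)
    vessel_ids = sorted(int(v) for v in vessel_ids)

    maps = [compute_distance_map(volume, vid) for vid in vessel_ids]
    nonempty = [(vid, m) for vid, m in zip(vessel_ids, maps) if not m.empty]
    if not nonempty:
        raise ValueError("all requested vessels are empty")

    stack = np.stack([m.values for _, m in nonempty], axis=0)
    # argmin returns the first (= smallest-id) minimizer at exact ties
    winner = np.argmin(stack, axis=0)
    ids = np.asarray([vid for vid, _ in nonempty], dtype=np.int32)
    labels = np.zeros(volume.grid.shape, dtype=np.int32)
    labels[roi_mask] = ids[winner[roi_mask]]
    return TerritoryParcellation(volume.grid, labels, tuple(vessel_ids))


def supply_fractions(
    parcellation: TerritoryParcellation,
    roi_mask: np.ndarray,
    key: str = "",
    labels: dict[int, str] | None = None,
) -> SupplyFractionRecord:
    """Supply volume fraction per vessel: ROI voxel-count share of each territory."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("ROI mask is empty")
    inside = parcellation.labels[roi_mask]
    fractions = {
        int(vid): float(np.count_nonzero(inside == vid)) / n_roi
        for vid in parcellation.vessel_ids
    }
    return SupplyFractionRecord(
        key=key,
        fractions=fractions,
        roi_voxel_count=n_roi,
        roi_volume_mm3=n_roi * parcellation.grid.voxel_volume_mm3,
        labels=dict(labels) if labels is not None else dict(CANONICAL_VESSELS),
    )
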