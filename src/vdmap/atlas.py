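"""Fusing pre-aligned hemisphere parcellations into territory atlases.

Inputs are label volumes already resampled onto one common grid (nonlinear
template registration is an external preprocessing step and out of scope;
phantom cohorts are generated pre-aligned). This module implements the
fusion arithmetic itself: the left-right flip that mirrors right
hemispheres onto a left-hemisphere convention, per-voxel majority vote over
territory labels, voxel-wise averaging of distance maps, and a simple
majority fusion of ROI masks.

Background (label 0) never competes in the vote: a voxel labeled by any
hemisphere receives the most frequent *nonzero* label, with ties resolved
to the smallest vessel id as everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DistanceMap
from .volumes import LabeledVolume

__all__ = [
    "FusedAtlas",
    "flip_lr",
    "align_stack",
    "majority_vote",
    "mean_distance_atlas",
    "fuse_roi_masks",
]


@dataclass
class FusedAtlas:
    """Majority-vote label volume with its per-label vote counts."""

    volume: LabeledVolume
    vote_counts: dict[int, np.ndarray]
    support: np.ndarray  # voxels with at least one nonzero vote


def flip_lr(volume: LabeledVolume) -> LabeledVolume:
    """Mirror along the left-right axis (first array axis). Involutive."""
    return LabeledVolume(volume.grid, volume.voxels[::-1].copy(), dict(volume.labels))


def align_stack(
    volumes: Sequence[LabeledVolume],
    lateralities: Sequence[str] | None = None,
) -> list[LabeledVolume]:
    """Flip every right hemisphere so the whole stack shares the left convention."""
    if lateralities is None:
        return list(volumes)
    if len(lateralities) != len(volumes):
        raise ValueError("one laterality flag required per volume")
    out = []
    for vol, side in zip(volumes, lateralities):
        if side not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {side!r}")
        out.append(flip_lr(vol) if side == "right" else vol)
    return out


def _check_shared_grid(volumes: Sequence[LabeledVolume]) -> None:
    if not volumes:
        raise ValueError("empty stack")
    grid = volumes[0].grid
    for vol in volumes[1:]:
        if vol.grid != grid:
            raise ValueError("stack volumes must share one grid")


def majority_vote(stack: Sequence[LabeledVolume]) -> FusedAtlas:
    """Per-voxel mode of nonzero labels across a pre-aligned stack.

    Voxels never labeled by any volume stay background; ties between labels
    go to the smallest id.
    """
    _check_shared_grid(stack)
    grid = stack[0].grid
    label_ids = sorted({vid for vol in stack for vid in vol.present_ids()})
    labels = {}
    for vol in stack:
        labels.update(vol.labels)

    counts = {
        vid: np.sum([vol.voxels == vid for vol in stack], axis=0).astype(np.int32)
        for vid in label_ids
    }
    fused = np.zeros(grid.shape, dtype=np.int32)
    best = np.zeros(grid.shape, dtype=np.int32)
    for vid in label_ids:  # increasing id: strict > keeps the smaller id at ties
        wins = counts[vid] > best
        fused[wins] = vid
        best[wins] = counts[vid][wins]
    support = best > 0
    return FusedAtlas(
        volume=LabeledVolume(grid, fused, labels),
        vote_counts=counts,
        support=support,
    )


def mean_distance_atlas(maps: Sequence[DistanceMap]) -> DistanceMap:
    """Voxel-wise arithmetic mean of distance maps on one common grid.

    Maps flagged empty (absent vessel, all +inf) are excluded; the per-voxel
    divisor is the number of contributing maps.
    """
    if not maps:
        raise ValueError("no distance maps to average")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("distance maps must share one grid")
    valid = [m for m in maps if not m.empty]
    if not valid:
        raise ValueError("all distance maps are empty")
    finite = np.stack([np.isfinite(m.values) for m in valid], axis=0)
    values = np.stack([np.where(np.isfinite(m.values), m.values, 0.0) for m in valid])
    n = finite.sum(axis=0)
    mean = np.divide(values.sum(axis=0), n, out=np.full(grid.shape, np.inf), where=n > 0)
    return DistanceMap(grid, mean, vessel_id=valid[0].vessel_id)


def fuse_roi_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Fused ROI: voxels present in at least half of the input masks."""
    if not masks:
        raise ValueError("no masks to fuse")
    shape = np.asarray(masks[0]).shape
    for m in masks[1:]:
        if np.asarray(m).shape != shape:
            raise ValueError("ROI masks must share one grid")
    votes = np.sum([np.asarray(m, dtype=bool) for m in masks], axis=0)
    return votes * 2 >= len(masks)
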