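"""Labeled-volume containers and NIfTI-1 input/output.

Conventions shared by every downstream module:

* voxel indices are 0-based; physical positions refer to voxel *centers*;
  all distances are reported in millimeters derived from the grid spacing;
* the left-right axis is the first array axis (mirroring for atlas fusion
  flips axis 0);
* label id 0 is background; artery labels use the canonical ids in
  :data:`CANONICAL_VESSELS`;
* the cortical region of interest (ROI) travels as a separate binary mask,
  never as a sixth label inside the vessel volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_VESSELS",
    "VESSEL_IDS",
    "ACA_IDS",
    "MCA_IDS",
    "VoxelGrid",
    "LabeledVolume",
    "read_labeled_volume",
    "write_labeled_volume",
    "read_mask",
    "write_mask",
    "read_hemisphere_table",
    "write_hemisphere_table",
    "LabelMapError",
    "VolumeFormatError",
]

#: Canonical artery ids. The motor cortex is supplied by up to two anterior
#: cerebral artery (ACA) branches and three middle cerebral artery (MCA)
#: groups; fixing the id order makes distance ties reproducible.
CANONICAL_VESSELS: dict[int, str] = {
    1: "pericallosa",
    2: "callosomarginalis",
    3: "precentral",
    4: "central",
    5: "postcentral",
}

#: Reverse lookup, vessel name -> id.
VESSEL_IDS: dict[str, int] = {name: vid for vid, name in CANONICAL_VESSELS.items()}

ACA_IDS: tuple[int, int] = (1, 2)
MCA_IDS: tuple[int, int, int] = (3, 4, 5)


class VolumeFormatError(ValueError):
    """Raised when a file on disk is not an integer label volume."""


class LabelMapError(ValueError):
    """Raised when voxel values and the label map disagree."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis, all >= 1.
    spacing
        Physical size of one voxel along each axis in mm, all > 0.
        Defaults to 0.45 mm isotropic, a typical high-resolution
        ultra-high-field protocol.
    origin
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.45, 0.45, 0.45)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scaling plus origin shift)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape ``(*shape, 3)`` in mm."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


@dataclass
class LabeledVolume:
    """Integer label volume on a :class:`VoxelGrid`.

    Every nonzero voxel value must appear in ``labels``; 0 is background.
    """

    grid: VoxelGrid
    voxels: np.ndarray
    labels: dict[int, str] = field(default_factory=lambda: dict(CANONICAL_VESSELS))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeFormatError(
                f"label volume must hold integers, got dtype {self.voxels.dtype}"
            )
        if tuple(self.voxels.shape) != self.grid.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        self.labels = {int(k): str(v) for k, v in self.labels.items()}
        if 0 in self.labels:
            raise LabelMapError("label id 0 is reserved for background")
        present = self.present_ids()
        unknown = sorted(set(present) - set(self.labels))
        if unknown:
            raise LabelMapError(
                f"voxel values {unknown} missing from label map {sorted(self.labels)}"
            )

    def present_ids(self) -> list[int]:
        """Sorted label ids with at least one voxel."""
        vals = np.unique(self.voxels)
        return [int(v) for v in vals if v != 0]

    def mask(self, label_id: int) -> np.ndarray:
        return self.voxels == label_id


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_labeled_volume(volume: LabeledVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI-1 plus a JSON label-map sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.int16), affine=volume.grid.affine
    )
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({str(k): v for k, v in sorted(volume.labels.items())}, indent=1)
    )


def read_labeled_volume(
    path: str | Path, labels: Mapping[int, str] | None = None
) -> LabeledVolume:
    """Read a NIfTI-1 integer label volume.

    The label map is taken from ``labels`` if given, otherwise from the
    ``*.labels.json`` sidecar written by :func:`write_labeled_volume`.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise VolumeFormatError(f"{path} holds non-integer data")
        data = np.round(data).astype(np.int32)
    if labels is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise LabelMapError(f"no label map supplied and no sidecar at {sidecar}")
        raw = json.loads(sidecar.read_text())
        label_map = {int(k): str(v) for k, v in raw.items()}
        if len(label_map) != len(raw):
            raise LabelMapError(f"duplicate label ids in {sidecar}")
    else:
        label_map = {int(k): str(v) for k, v in labels.items()}
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    grid = VoxelGrid(tuple(data.shape), spacing, origin)
    return LabeledVolume(grid, data.astype(np.int32), label_map)


def write_mask(mask: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a binary ROI mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=grid.affine)
    nib.save(img, str(Path(path)))


def read_mask(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(Path(path)))
    data = np.asanyarray(img.dataobj)
    aff = img.affine
    grid = VoxelGrid(
        tuple(data.shape),
        tuple(float(s) for s in np.abs(np.diag(aff)[:3])),
        tuple(float(o) for o in aff[:3, 3]),
    )
    return data != 0, grid


HEMISPHERE_COLUMNS = ["subject", "hemisphere", "age", "sex", "region", "thickness_mm"]


def write_hemisphere_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write per-hemisphere covariate records (age, sex, thickness) as CSV."""
    missing = [c for c in HEMISPHERE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"hemisphere table missing columns {missing}")
    table.to_csv(path, index=False)


def read_hemisphere_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in HEMISPHERE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"hemisphere table missing columns {missing}")
    if (table["age"] <= 0).any() or (table["thickness_mm"] <= 0).any():
        raise ValueError("age and thickness_mm must be positive")
    return table
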