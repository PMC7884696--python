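"""Volumetric raster containers shared by the atlas, masks and FA maps.

A :class:`VolumeGrid` is a 3-D array plus a 4x4 voxel-to-world affine in
millimetres, mirroring the NIfTI convention (voxel index ``(i, j, k)`` maps
to the *centre* of that voxel in world space). A :class:`LabelAtlas` pairs an
integer-labelled grid with a lookup table describing each structure
(name, region group, hemisphere, bilateral partner, ventricle/cerebellum
flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VolumeGrid", "LabelAtlas", "LOOKUP_COLUMNS"]

LOOKUP_COLUMNS = [
    "label_id",
    "name",
    "region_group",
    "hemisphere",
    "partner_id",
    "is_ventricle",
    "is_cerebellum",
]


@dataclass
class VolumeGrid:
    """A 3-D scalar or integer raster with world-space geometry.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``.
    affine
        4x4 voxel-to-world matrix in mm. Voxel ``(i, j, k)`` maps to the
        world coordinate of its centre.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the spatial block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.atleast_2d(ijk)
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out if out.shape[0] > 1 else out[0]

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_binary(self, what: str = "mask") -> np.ndarray:
        """Return the data as boolean, rejecting non-binary values."""
        d = self.data
        if d.dtype == bool:
            return d
        vals = np.unique(d)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{what} is not binary (values {vals[:5]} ...)")
        return d.astype(bool)

    # -- NIfTI I/O -------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))


@dataclass
class LabelAtlas:
    """Integer parcellation volume plus a per-structure lookup table.

    ``lookup`` has one row per label with columns ``label_id, name,
    region_group, hemisphere, partner_id, is_ventricle, is_cerebellum``.
    ``partner_id`` is the mirrored bilateral partner, or -1 for unpaired
    (midline / cerebellar) structures. Background is label 0 and carries no
    lookup row.
    """

    grid: VolumeGrid
    lookup: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(LOOKUP_COLUMNS) - set(self.lookup.columns)
        if missing:
            raise ValueError(f"lookup table missing columns: {sorted(missing)}")
        if not np.issubdtype(self.grid.data.dtype, np.integer):
            raise ValueError("atlas grid must hold integer labels")

    @property
    def labels(self) -> np.ndarray:
        return self.lookup["label_id"].to_numpy()

    def name_of(self, label_id: int) -> str:
        row = self.lookup.loc[self.lookup["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"unknown label {label_id}")
        return str(row["name"].iloc[0])

    def id_of(self, name: str) -> int:
        row = self.lookup.loc[self.lookup["name"] == name]
        if row.empty:
            raise KeyError(f"unknown structure name {name!r}")
        return int(row["label_id"].iloc[0])

    def mask_of(self, label_id: int) -> np.ndarray:
        return self.grid.data == label_id

    def tissue_labels(self) -> pd.DataFrame:
        """Lookup rows for parenchymal structures (no ventricles/cerebellum)."""
        lk = self.lookup
        return lk.loc[~(lk["is_ventricle"] | lk["is_cerebellum"])]

    def save(self, volume_path: str | Path, lookup_path: str | Path) -> None:
        self.grid.save(volume_path)
        self.lookup.to_csv(lookup_path, index=False)

    @classmethod
    def load(cls, volume_path: str | Path, lookup_path: str | Path) -> "LabelAtlas":
        grid = VolumeGrid.load(volume_path)
        grid.data = np.rint(np.asarray(grid.data)).astype(np.int32)
        lookup = pd.read_csv(lookup_path)
        lookup["is_ventricle"] = lookup["is_ventricle"].astype(bool)
        lookup["is_cerebellum"] = lookup["is_cerebellum"].astype(bool)
        return cls(grid, lookup)
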