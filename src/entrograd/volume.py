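"""Lightweight 3-D/4-D scalar-field container shared across pipeline stages.

A :class:`VolumeMap` couples a numpy array with an affine so that beta maps,
Z maps, masks and BOLD runs all move through the pipeline with their spatial
metadata attached.  NIfTI round-trips go through nibabel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeMap", "default_affine"]


def default_affine(voxel_size: float = 3.0, shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Diagonal affine with isotropic voxels, origin at the grid centre."""
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if shape is not None:
        aff[:3, 3] = -voxel_size * (np.asarray(shape[:3]) - 1) / 2.0
    return aff


@dataclass
class VolumeMap:
    """Scalar field (3-D) or time series of fields (4-D, time last) plus affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"VolumeMap expects 3-D or 4-D data, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three spatial axes."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "VolumeMap") -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(self.affine, other.affine)

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        homog = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ homog.T).T[:, :3].squeeze()

    def like(self, data: np.ndarray) -> "VolumeMap":
        """New map on this grid carrying ``data``."""
        return VolumeMap(np.asarray(data), self.affine.copy())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumeMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine)
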