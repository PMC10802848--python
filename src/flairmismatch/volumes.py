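"""Core image containers, NIfTI I/O and affine-based mask resampling.

All volumes are kept in a canonical RAS+ orientation: after loading, axis 0
runs left-to-right, axis 1 posterior-to-anterior and axis 2
inferior-to-superior in world coordinates.  Mirroring across the hemispheric
midplane (see :mod:`flairmismatch.mirroring`) is then a flip of axis 0.
Voxel indices are 0-based and voxel *centers* map through the affine,
following the NIfTI convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised when an image or mask violates its contract."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise np.linalg.LinAlgError("affine is singular")
    return affine


@dataclass
class ImageVolume:
    """A 3D scalar image with a voxel-index-to-world-mm affine.

    Parameters
    ----------
    data:
        3D array of intensities in arbitrary units.
    affine:
        4x4 matrix mapping homogeneous 0-based voxel indices to world mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3D image, got {self.data.ndim} dims")
        if min(self.data.shape) < 1:
            raise VolumeError("every axis must have length >= 1")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of a voxel in mm, per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_center(self) -> np.ndarray:
        """World coordinate of the geometric center of the voxel grid."""
        center_idx = (np.array(self.shape, dtype=float) - 1.0) / 2.0
        return self.affine[:3, :3] @ center_idx + self.affine[:3, 3]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid_as(self, other: "ImageVolume | BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class BinaryMask:
    """A boolean voxel mask aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3D mask, got {self.data.ndim} dims")
        self.affine = _check_affine(self.affine)

    @classmethod
    def like(cls, data: np.ndarray, grid: "ImageVolume | BinaryMask") -> "BinaryMask":
        data = np.asarray(data)
        if data.shape != grid.shape:
            raise VolumeError(
                f"mask shape {data.shape} does not match grid {grid.shape}"
            )
        return cls(data, grid.affine.copy())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3


def _canonicalize(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def load_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI-1 file as a canonically oriented :class:`ImageVolume`.

    A 4D image with a singleton last axis is squeezed; any other
    dimensionality raises :class:`VolumeError`.
    """
    img = nib.load(str(path))
    img = _canonicalize(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D image, got shape {data.shape}")
    return ImageVolume(data.astype(float), np.asarray(img.affine, dtype=float))


def load_mask(path: str | Path) -> BinaryMask:
    """Load a NIfTI-1 file as a canonically oriented binary mask."""
    vol = load_volume(path)
    return BinaryMask(vol.data > 0.5, vol.affine)


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as unsigned 8-bit 0/1 NIfTI; round-trips bit-exactly."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def index_map(source_affine: np.ndarray, target_affine: np.ndarray) -> np.ndarray:
    """Homogeneous matrix mapping target voxel indices to source voxel indices.

    Composes target-index -> world -> source-index.
    """
    source_affine = _check_affine(source_affine)
    target_affine = _check_affine(target_affine)
    return np.linalg.inv(source_affine) @ target_affine


def resample_mask_to(mask: BinaryMask, target: ImageVolume | BinaryMask) -> BinaryMask:
    """Resample ``mask`` onto the grid of ``target`` by nearest neighbor.

    Every target voxel center is mapped through the target affine and the
    inverse source affine; samples falling outside the source field of view
    are false.  On identical grids this is the identity.
    """
    if mask.shape == target.shape and np.allclose(mask.affine, target.affine, atol=1e-6):
        return BinaryMask(mask.data.copy(), np.asarray(target.affine, dtype=float).copy())
    m = index_map(mask.affine, target.affine)
    out = ndimage.affine_transform(
        mask.data.astype(np.uint8),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(out > 0, np.asarray(target.affine, dtype=float).copy())
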