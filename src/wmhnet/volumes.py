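"""Voxel volume carrier shared by masks and atlases."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabeledVolume", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class LabeledVolume:
    """A 3D integer (or binary) voxel array with an affine mapping indices to mm.

    Parameters
    ----------
    data
        3D array of integer labels; binary volumes contain only {0, 1}.
    affine
        4x4 voxel-index -> mm affine. Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def require_binary(self, name: str = "mask") -> None:
        if not self.is_binary():
            raise ValueError(f"{name} is not binary (values outside {{0,1}} present)")

    def same_grid(self, other: "LabeledVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def require_same_grid(self, other: "LabeledVolume", names: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(f"{names} do not share shape/affine")

    # -- coordinate transforms ------------------------------------------
    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map Nx3 mm coordinates to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_mm(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_centers_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """mm coordinates of voxel centers; restricted to ``mask`` if given."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        idx = np.argwhere(mask)
        return self.voxel_to_mm(idx)

    # -- I/O -------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "LabeledVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: volume does not contain integer labels")
        return cls(data=np.round(data).astype(np.int32), affine=np.asarray(img.affine))
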