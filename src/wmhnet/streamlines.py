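"""Streamline sets: polylines in mm space with endpoint-region assignments.

Supports TCK (via nibabel) and a line-oriented plain-text dialect: one
streamline per block, one "x y z" triplet per line, blocks separated by a
blank line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines.tractogram import Tractogram

from .volumes import LabeledVolume

__all__ = ["StreamlineSet", "resample_polyline", "assign_endpoint_regions"]


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps of ``step`` mm.

    The first and last vertices are always included. A polyline of zero total
    length collapses to its first point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("polyline must be an Nx3 array with N >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return pts[:1]
    s = np.arange(0.0, total, step)
    s = np.concatenate([s, [total]])
    out = np.empty((s.size, 3))
    for k in range(3):
        out[:, k] = np.interp(s, cum, pts[:, k])
    return out


def assign_endpoint_regions(
    streamlines: list[np.ndarray], atlas: LabeledVolume
) -> np.ndarray:
    """Atlas label at each streamline's two endpoints (0 = unassigned).

    Endpoint mm coordinates are mapped through the inverse affine and rounded
    to the nearest voxel index; points outside the grid get label 0.
    """
    n = len(streamlines)
    out = np.zeros((n, 2), dtype=np.int32)
    if n == 0:
        return out
    ends = np.array([[sl[0], sl[-1]] for sl in streamlines])  # (n, 2, 3)
    idx = np.rint(atlas.mm_to_voxel(ends.reshape(-1, 3))).astype(int)
    shape = np.asarray(atlas.shape)
    ok = ((idx >= 0) & (idx < shape)).all(axis=1)
    labels = np.zeros(idx.shape[0], dtype=np.int32)
    labels[ok] = atlas.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return labels.reshape(n, 2)


@dataclass
class StreamlineSet:
    """Ordered 3D polylines (mm) plus per-streamline endpoint region ids."""

    streamlines: list[np.ndarray]
    endpoint_regions: np.ndarray  # (n, 2) int, 0 = unassigned
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    _voxel_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(sl, dtype=float) for sl in self.streamlines]
        for i, sl in enumerate(self.streamlines):
            if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 2:
                raise ValueError(f"streamline {i} is not an Nx3 polyline with N >= 2")
        self.endpoint_regions = np.asarray(self.endpoint_regions, dtype=np.int32)
        if self.endpoint_regions.shape != (len(self.streamlines), 2):
            raise ValueError("endpoint_regions must have shape (n_streamlines, 2)")
        self.affine = np.asarray(self.affine, dtype=float)

    def __len__(self) -> int:
        return len(self.streamlines)

    # -- voxelization ----------------------------------------------------
    def voxelized(self, grid: LabeledVolume, step: float):
        """Per-point flat voxel indices on ``grid`` for all streamlines.

        Returns ``(flat_idx, owner)`` where ``flat_idx`` are raveled voxel
        indices of every resampled in-grid point and ``owner`` maps each point
        to its streamline. Cached per (shape, affine, step).
        """
        key = (grid.shape, grid.affine.tobytes(), float(step))
        hit = self._voxel_cache.get(key)
        if hit is not None:
            return hit
        pts = [resample_polyline(sl, step) for sl in self.streamlines]
        counts = np.array([p.shape[0] for p in pts])
        allpts = np.concatenate(pts) if pts else np.empty((0, 3))
        owner = np.repeat(np.arange(len(pts)), counts)
        idx = np.rint(grid.mm_to_voxel(allpts)).astype(np.int64)
        shape = np.asarray(grid.shape)
        ok = ((idx >= 0) & (idx < shape)).all(axis=1)
        flat = np.ravel_multi_index(
            (idx[ok, 0], idx[ok, 1], idx[ok, 2]), grid.shape
        )
        result = (flat, owner[ok])
        self._voxel_cache[key] = result
        return result

    # -- I/O -------------------------------------------------------------
    def save_tck(self, path) -> None:
        tg = Tractogram(self.streamlines, affine_to_rasmm=np.eye(4))
        nib.streamlines.save(tg, str(path))

    def save_text(self, path) -> None:
        with open(path, "w") as fh:
            for i, sl in enumerate(self.streamlines):
                if i:
                    fh.write("\n")
                for x, y, z in sl:
                    fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")

    @classmethod
    def _from_polylines(
        cls, polylines: list[np.ndarray], atlas: LabeledVolume | None
    ) -> "StreamlineSet":
        if atlas is not None:
            regions = assign_endpoint_regions(polylines, atlas)
            affine = atlas.affine.copy()
        else:
            regions = np.zeros((len(polylines), 2), dtype=np.int32)
            affine = np.eye(4)
        return cls(streamlines=polylines, endpoint_regions=regions, affine=affine)

    @classmethod
    def load_tck(cls, path, atlas: LabeledVolume | None = None) -> "StreamlineSet":
        tractogram = nib.streamlines.load(str(path)).tractogram
        polylines = [np.asarray(sl, dtype=float) for sl in tractogram.streamlines]
        return cls._from_polylines(polylines, atlas)

    @classmethod
    def load_text(cls, path, atlas: LabeledVolume | None = None) -> "StreamlineSet":
        polylines: list[np.ndarray] = []
        block: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    if block:
                        polylines.append(np.array(block))
                        block = []
                    continue
                vals = line.split()
                if len(vals) != 3:
                    raise ValueError(f"malformed streamline line: {line!r}")
                block.append([float(v) for v in vals])
        if block:
            polylines.append(np.array(block))
        return cls._from_polylines(polylines, atlas)

    @classmethod
    def load(cls, path, atlas: LabeledVolume | None = None) -> "StreamlineSet":
        path = str(path)
        if path.endswith(".tck"):
            return cls.load_tck(path, atlas)
        return cls.load_text(path, atlas)
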