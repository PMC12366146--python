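"""Regional disconnectivity (ChaCo) of a binary mask against a reference
streamline set.

For each region r, the raw score is the fraction of streamlines with at
least one endpoint assigned to r that intersect the mask. A streamline
intersects the mask iff any point of the polyline, resampled at half the
minimum voxel edge, falls in a voxel where the mask is 1. Point-in-voxel
uses the inverse affine with rounding to the nearest voxel index; points
outside the grid never intersect.

Regions with zero connected streamlines yield missing (NaN), not 0 --
"no information" is distinct from "no damage".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .streamlines import StreamlineSet, resample_polyline
from .volumes import LabeledVolume

__all__ = [
    "ChaCoVector",
    "streamline_intersects_mask",
    "streamline_intersections",
    "compute_chaco",
    "clean_chaco",
    "global_chaco",
    "chaco_long_frame",
    "chaco_matrix_from_long",
]

DEFAULT_FLOOR = 0.02


@dataclass
class ChaCoVector:
    """Per-region disconnectivity values in [0,1]; NaN = no information."""

    values: np.ndarray  # length n_regions, index i -> region id i+1
    mask_type: str = "wmh"
    patient_id: str | None = None
    region_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.region_ids is None:
            self.region_ids = np.arange(1, self.values.size + 1)
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.size != self.values.size:
            raise ValueError("region_ids and values disagree in length")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.region_ids, name="chaco")


def _intersection_step(mask: LabeledVolume) -> float:
    return 0.5 * float(mask.voxel_sizes.min())


def streamline_intersects_mask(streamline: np.ndarray, mask: LabeledVolume) -> bool:
    """True iff any resampled point of the polyline lies in a masked voxel."""
    mask.require_binary()
    pts = resample_polyline(np.asarray(streamline, dtype=float), _intersection_step(mask))
    idx = np.rint(mask.mm_to_voxel(pts)).astype(int)
    shape = np.asarray(mask.shape)
    ok = ((idx >= 0) & (idx < shape)).all(axis=1)
    if not ok.any():
        return False
    return bool(mask.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]].any())


def streamline_intersections(mask: LabeledVolume, connectome: StreamlineSet) -> np.ndarray:
    """Boolean per-streamline intersection with ``mask`` (vectorized)."""
    mask.require_binary()
    flat, owner = connectome.voxelized(mask, _intersection_step(mask))
    hits = np.asarray(mask.data).ravel()[flat].astype(bool)
    out = np.zeros(len(connectome), dtype=bool)
    if hits.any():
        np.logical_or.at(out, owner[hits], True)
    return out


def compute_chaco(
    mask: LabeledVolume,
    connectome: StreamlineSet,
    n_regions: int,
    mask_type: str = "wmh",
    patient_id: str | None = None,
) -> ChaCoVector:
    """Raw per-region disconnectivity of ``mask`` against ``connectome``.

    ChaCo(r) = (# streamlines with >= 1 endpoint in r intersecting the mask)
             / (# streamlines with >= 1 endpoint in r).
    A streamline with both endpoints in r is counted once. Regions with no
    connected streamlines are NaN.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask.require_binary()
    hit = streamline_intersections(mask, connectome)
    ep = connectome.endpoint_regions
    values = np.full(n_regions, np.nan)
    for r in range(1, n_regions + 1):
        member = (ep[:, 0] == r) | (ep[:, 1] == r)
        denom = int(member.sum())
        if denom:
            values[r - 1] = hit[member].sum() / denom
    return ChaCoVector(values=values, mask_type=mask_type, patient_id=patient_id)


def clean_chaco(raw: ChaCoVector | np.ndarray, floor: float = DEFAULT_FLOOR):
    """Apply the value-cleaning rule: values strictly below ``floor`` -> 0,
    values above 1 -> 1; missing preserved. Idempotent."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if isinstance(raw, ChaCoVector):
        return ChaCoVector(
            values=clean_chaco(raw.values, floor),
            mask_type=raw.mask_type,
            patient_id=raw.patient_id,
            region_ids=raw.region_ids.copy(),
        )
    v = np.asarray(raw, dtype=float).copy()
    present = ~np.isnan(v)
    v[present & (v < floor)] = 0.0
    v[present & (v > 1.0)] = 1.0
    return v


def global_chaco(vector: ChaCoVector) -> float:
    """Arithmetic mean over non-missing regions."""
    present = ~np.isnan(vector.values)
    if not present.any():
        raise ValueError("all regions are missing; global score undefined")
    return float(vector.values[present].mean())


def chaco_long_frame(vectors: list[ChaCoVector]) -> pd.DataFrame:
    """Stack vectors into a long table (patient_id, mask_type, region_id, chaco)."""
    rows = []
    for v in vectors:
        for rid, val in zip(v.region_ids, v.values):
            rows.append((v.patient_id, v.mask_type, int(rid), val))
    return pd.DataFrame(rows, columns=["patient_id", "mask_type", "region_id", "chaco"])


def chaco_matrix_from_long(frame: pd.DataFrame, mask_type: str) -> pd.DataFrame:
    """Patients x regions matrix for one mask type (NaN = missing)."""
    sub = frame[frame["mask_type"] == mask_type]
    return sub.pivot(index="patient_id", columns="region_id", values="chaco")
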