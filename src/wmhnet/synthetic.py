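"""Seeded synthetic cohorts: toy atlas, ventricles, streamline connectome,
per-patient WMH/stroke masks, and ordinal outcomes from a proportional-odds
generator with known effects.

All randomness derives from ``SimulationConfig.seed``; per-patient streams
are seeded by (seed, patient index) so cohorts are extensible without
reshuffling earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectome import ChaCoVector, clean_chaco, compute_chaco
from .streamlines import StreamlineSet, assign_endpoint_regions, resample_polyline
from .topology import mask_volume_ml, split_wmh, ventricle_distance_mm
from .volumes import LabeledVolume

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "AtlasBundle",
    "SizingError",
    "GenerationError",
    "make_atlas",
    "make_streamlines",
    "make_patient_masks",
    "make_outcomes",
    "simulate_cohort",
]

MASK_TYPES = ("wmh", "pwmh", "dwmh")


class SizingError(ValueError):
    """The grid cannot accommodate the requested structures."""


class GenerationError(RuntimeError):
    """A stochastic construction failed within its attempt budget."""


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float | tuple[float, float, float] = 1.0
    n_regions: int = 8
    n_streamlines: int = 400
    n_patients: int = 40
    pwmh_volume_ml: float = 2.0
    dwmh_volume_ml: float = 1.0
    stroke_volume_ml: float = 2.0
    pv_threshold_mm: float = 10.0
    causal_region_ids: tuple[int, ...] = ()
    beta_disconnect: float = 0.0
    beta_age: float = 0.5
    beta_nihss: float = 0.5
    beta_logvol: float = 0.5
    n_outcome_levels: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_outcome_levels < 2:
            raise ValueError("n_outcome_levels must be >= 2")
        if self.pwmh_volume_ml < 0 or self.dwmh_volume_ml < 0:
            raise ValueError("WMH component volumes must be >= 0")
        if self.pwmh_volume_ml + self.dwmh_volume_ml <= 0:
            raise ValueError("total WMH volume must be > 0")
        if self.stroke_volume_ml <= 0:
            raise ValueError("stroke volume must be > 0")
        bad = set(self.causal_region_ids) - set(range(1, self.n_regions + 1))
        if bad:
            raise ValueError(f"causal_region_ids outside 1..n_regions: {sorted(bad)}")

    @property
    def voxel_sizes(self) -> np.ndarray:
        v = self.voxel_size_mm
        if np.isscalar(v):
            return np.full(3, float(v))
        return np.asarray(v, dtype=float)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_sizes)
        return aff

    def rng(self, *stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), *stage)))


@dataclass
class AtlasBundle:
    atlas: LabeledVolume
    region_meta: pd.DataFrame  # region_id, name, hemisphere, cortical
    ventricles: LabeledVolume


def _voxel_center_grid_mm(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def make_atlas(config: SimulationConfig) -> AtlasBundle:
    """Place ``n_regions`` non-overlapping spherical regions plus a central
    ventricle ellipsoid on the configured grid.

    Labels run 1..n_regions (0 = background). Regions whose center lies in
    the outer shell of the grid are flagged cortical; left/right hemisphere
    is split at the first-axis midplane.
    """
    shape = tuple(int(s) for s in config.grid_shape)
    affine = config.affine()
    extent = np.asarray(shape) * config.voxel_sizes  # mm
    center = (np.asarray(shape) - 1) / 2.0 * config.voxel_sizes

    # ventricles: central ellipsoid, semi-axes 12% of grid extent (>= 1 voxel)
    semi = np.maximum(0.12 * extent, config.voxel_sizes)
    coords = _voxel_center_grid_mm(shape, affine)
    vent_flat = (((coords - center) / semi) ** 2).sum(axis=1) <= 1.0
    ventricles = LabeledVolume(vent_flat.reshape(shape).astype(np.int16), affine.copy())
    if ventricles.data.sum() == 0:
        raise SizingError("grid too small to contain the ventricle ellipsoid")

    radius = max(0.08 * extent.min(), 1.2 * config.voxel_sizes.max())
    margin = radius
    lo, hi = margin, extent - margin
    if np.any(lo >= hi):
        raise SizingError(
            f"grid extent {extent} mm too small for region radius {radius:.1f} mm"
        )

    rng = config.rng(1)
    centers: list[np.ndarray] = []
    attempts = 0
    budget = 2000 * config.n_regions
    vent_clearance = semi.max() + radius
    while len(centers) < config.n_regions:
        if attempts >= budget:
            raise SizingError(
                f"could not place {config.n_regions} non-overlapping regions of "
                f"radius {radius:.1f} mm on a {shape} grid after {budget} attempts"
            )
        attempts += 1
        c = rng.uniform(lo, hi)
        if np.linalg.norm(c - center) < vent_clearance:
            continue
        if any(np.linalg.norm(c - o) < 2 * radius + 0.5 for o in centers):
            continue
        centers.append(c)

    data = np.zeros(shape, dtype=np.int16)
    flat = data.reshape(-1)
    for label, c in enumerate(centers, start=1):
        inside = np.linalg.norm(coords - c, axis=1) <= radius
        flat[inside & (flat.reshape(-1) == 0) & ~vent_flat] = label
    atlas = LabeledVolume(data, affine.copy())

    rows = []
    for label, c in enumerate(centers, start=1):
        if np.sum(data == label) == 0:
            raise SizingError(f"region {label} collapsed to zero voxels")
        boundary_dist = np.minimum(c, extent - c).min()
        rows.append({
            "region_id": label,
            "name": f"region_{label:03d}",
            "hemisphere": "left" if c[0] < extent[0] / 2 else "right",
            "cortical": bool(boundary_dist < 0.3 * extent.min()),
        })
    meta = pd.DataFrame(rows)
    return AtlasBundle(atlas=atlas, region_meta=meta, ventricles=ventricles)


def make_streamlines(atlas: LabeledVolume, config: SimulationConfig) -> StreamlineSet:
    """Noisy polylines between random voxels of random region pairs.

    Interior points follow the straight line between the endpoints, resampled
    at half-voxel steps with Gaussian jitter; endpoints stay exactly on
    region voxel centers. The first ``n_regions`` streamlines are anchored to
    regions 1..n_regions so every region is an endpoint of at least one
    streamline (requires n_streamlines >= n_regions).
    """
    labels = np.unique(atlas.data)
    labels = labels[labels > 0]
    if labels.size < 2:
        raise ValueError("atlas must contain >= 2 regions")
    region_voxels = {int(r): np.argwhere(atlas.data == r) for r in labels}
    rng = config.rng(2)
    step = 0.5 * float(atlas.voxel_sizes.min())
    jitter = 0.35 * float(atlas.voxel_sizes.min())

    if config.n_streamlines < labels.size:
        raise GenerationError(
            f"region {int(labels[config.n_streamlines])} cannot be covered: "
            f"only {config.n_streamlines} streamlines for {labels.size} regions"
        )

    polylines = []
    for i in range(config.n_streamlines):
        if i < labels.size:
            ra = int(labels[i])
        else:
            ra = int(rng.choice(labels))
        rb = int(rng.choice(labels))
        va = region_voxels[ra][rng.integers(len(region_voxels[ra]))]
        vb = region_voxels[rb][rng.integers(len(region_voxels[rb]))]
        a = atlas.voxel_to_mm(va)[0]
        b = atlas.voxel_to_mm(vb)[0]
        if np.array_equal(a, b):
            b = b + atlas.voxel_sizes * 0.25  # avoid degenerate polyline
        line = resample_polyline(np.vstack([a, b]), step)
        if line.shape[0] > 2:
            line[1:-1] += rng.normal(0.0, jitter, size=(line.shape[0] - 2, 3))
        polylines.append(line)

    regions = assign_endpoint_regions(polylines, atlas)
    covered = set(regions.reshape(-1).tolist())
    for r in labels:
        if int(r) not in covered:
            raise GenerationError(f"region {int(r)} has no streamline endpoint")
    return StreamlineSet(streamlines=polylines, endpoint_regions=regions,
                         affine=atlas.affine.copy())


def _select_clustered(candidates: np.ndarray, coords: np.ndarray, n_target: int,
                      n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """Pick ~n_target candidate voxels clustered around random seed points.

    Returns a boolean selection over ``candidates`` rows.
    """
    n_cand = candidates.shape[0]
    if n_cand == 0 or n_target <= 0:
        return np.zeros(n_cand, dtype=bool)
    n_target = min(n_target, n_cand)
    seeds = coords[candidates][rng.integers(n_cand, size=max(1, n_seeds))]
    pts = coords[candidates]
    d = np.min(
        np.linalg.norm(pts[:, None, :] - seeds[None, :, :], axis=2), axis=1
    )
    d = d + rng.normal(0.0, 0.25, size=d.shape)  # roughen the blob boundary
    chosen = np.argsort(d, kind="stable")[:n_target]
    sel = np.zeros(n_cand, dtype=bool)
    sel[chosen] = True
    return sel


def make_patient_masks(
    atlas: LabeledVolume,
    ventricles: LabeledVolume,
    config: SimulationConfig,
    patient_seed,
) -> tuple[LabeledVolume, LabeledVolume]:
    """One patient's (WMH, stroke) binary masks on the atlas grid.

    The WMH mask is the union of a rim component inside the periventricular
    band (distance <= pv_threshold_mm, excluding the ventricles) and isolated
    spots beyond the band; expected component volumes follow the config
    targets. The stroke mask is a single blob.
    """
    rng = np.random.default_rng(patient_seed)
    if ventricles.data.sum() == 0:
        raise ValueError("ventricle mask is empty")
    shape = atlas.shape
    dist = ventricle_distance_mm(ventricles)
    voxel_vol = atlas.voxel_volume_mm3
    coords = _voxel_center_grid_mm(shape, atlas.affine)

    margin_ok = np.ones(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = slice(0, 1)
        margin_ok[tuple(sl)] = False
        sl[ax] = slice(-1, None)
        margin_ok[tuple(sl)] = False

    flat_dist = dist.reshape(-1)
    flat_margin = margin_ok.reshape(-1)
    band = (flat_dist > 0) & (flat_dist <= config.pv_threshold_mm) & flat_margin
    deep = (flat_dist > config.pv_threshold_mm) & flat_margin

    def target_voxels(ml: float) -> int:
        # per-patient volumes scatter lognormally around the config target
        # so the expectations match the config while volumes vary
        if ml <= 0:
            return 0
        realized = ml * rng.lognormal(mean=-0.3**2 / 2, sigma=0.3)
        return int(round(realized * 1000.0 / voxel_vol))

    band_idx = np.flatnonzero(band)
    deep_idx = np.flatnonzero(deep)
    n_pv = target_voxels(config.pwmh_volume_ml)
    n_dp = target_voxels(config.dwmh_volume_ml)
    if config.pwmh_volume_ml > 0:
        n_pv = max(n_pv, 1)
    if config.dwmh_volume_ml > 0:
        n_dp = max(n_dp, 1)

    wmh_flat = np.zeros(np.prod(shape), dtype=np.int16)
    sel_pv = _select_clustered(band_idx, coords, n_pv, n_seeds=3, rng=rng)
    wmh_flat[band_idx[sel_pv]] = 1
    sel_dp = _select_clustered(deep_idx, coords, n_dp, n_seeds=3, rng=rng)
    wmh_flat[deep_idx[sel_dp]] = 1
    if wmh_flat.sum() == 0:
        raise GenerationError("WMH mask came out empty; grid too small for targets")

    stroke_flat = np.zeros_like(wmh_flat)
    stroke_idx = np.flatnonzero(flat_margin)
    n_stroke = max(target_voxels(config.stroke_volume_ml), 1)
    sel_st = _select_clustered(stroke_idx, coords, n_stroke, n_seeds=1, rng=rng)
    stroke_flat[stroke_idx[sel_st]] = 1

    return (
        LabeledVolume(wmh_flat.reshape(shape), atlas.affine.copy()),
        LabeledVolume(stroke_flat.reshape(shape), atlas.affine.copy()),
    )


def make_outcomes(
    chaco_truth: np.ndarray,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Ordinal grades from a proportional-odds generator.

    latent = beta_disconnect * 1[chaco above sample median]
           + beta_age * (age - 70)/10 + beta_nihss * (nihss - 8)/4
           + beta_logvol * (log10(wmh_volume_ml) - mean) + logistic noise,
    cut at fixed equally spaced thresholds into ``n_outcome_levels`` grades
    (0 .. K-1). Returns (grades, truth record incl. cutpoints).
    """
    chaco = np.asarray(chaco_truth, dtype=float)
    n = chaco.size
    if np.unique(chaco).size >= 2:
        high = (chaco > np.median(chaco)).astype(int)
    else:
        high = np.zeros(n, dtype=int)

    age = covariates["age"].to_numpy(dtype=float)
    nihss = covariates["nihss"].to_numpy(dtype=float)
    vol = covariates["wmh_volume_ml"].to_numpy(dtype=float)
    if np.any(vol <= 0):
        raise ValueError("wmh_volume_ml must be > 0 for the log term")
    logvol = np.log10(vol)
    systematic = (
        config.beta_disconnect * high
        + config.beta_age * (age - 70.0) / 10.0
        + config.beta_nihss * (nihss - 8.0) / 4.0
        + config.beta_logvol * (logvol - logvol.mean())
    )
    if not np.all(np.isfinite(systematic)):
        raise ValueError("non-finite latent score")

    K = config.n_outcome_levels
    cutpoints = float(np.mean(systematic)) + np.linspace(-2.2, 2.2, K - 1)
    latent = systematic + rng.logistic(size=n)
    grades = (latent[:, None] > cutpoints[None, :]).sum(axis=1)
    truth = {
        "cutpoints": cutpoints.tolist(),
        "beta_disconnect": config.beta_disconnect,
        "beta_age": config.beta_age,
        "beta_nihss": config.beta_nihss,
        "beta_logvol": config.beta_logvol,
        "high_indicator": high.tolist(),
        "covariate_coding": {
            "age": "(age - 70)/10",
            "nihss": "(nihss - 8)/4",
            "logvol": "log10(wmh_volume_ml) - sample mean",
        },
    }
    return grades.astype(int), truth


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    atlas: LabeledVolume
    region_meta: pd.DataFrame
    ventricles: LabeledVolume
    streamlines: StreamlineSet
    wmh_masks: list[LabeledVolume]
    stroke_masks: list[LabeledVolume]
    cohort: pd.DataFrame
    chaco: dict[str, pd.DataFrame]  # mask_type -> patients x regions (cleaned)
    truth: dict = field(default_factory=dict)

    def save(self, out_dir) -> list[str]:
        """Write NIfTI volumes, TCK + text streamlines, cohort CSV, truth JSON.

        Returns the list of written file names (relative to ``out_dir``).
        """
        import os

        os.makedirs(out_dir, exist_ok=True)
        written = []

        def path(name):
            written.append(name)
            return os.path.join(out_dir, name)

        self.atlas.save(path("atlas.nii"))
        self.ventricles.save(path("ventricles.nii"))
        self.region_meta.to_csv(path("region_meta.csv"), index=False)
        self.streamlines.save_tck(path("connectome.tck"))
        self.streamlines.save_text(path("connectome.txt"))
        for pid, wmh, stroke in zip(self.cohort["patient_id"],
                                    self.wmh_masks, self.stroke_masks):
            wmh.save(path(f"{pid}_wmh.nii"))
            stroke.save(path(f"{pid}_stroke.nii"))
        self.cohort.to_csv(path("cohort.csv"), index=False)
        for mask_type, mat in self.chaco.items():
            mat.to_csv(path(f"chaco_{mask_type}.csv"))
        with open(path("truth.json"), "w") as fh:
            json.dump({"config": asdict(self.config), **self.truth}, fh, indent=2,
                      default=float)
        return written


def patient_seed(config: SimulationConfig, index: int) -> np.random.SeedSequence:
    """Seed for patient ``index`` derived from (global seed, index)."""
    return np.random.SeedSequence((int(config.seed), 3, int(index)))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full synthetic cohort: atlas, connectome, masks, disconnectivity,
    covariates and proportional-odds outcomes."""
    bundle = make_atlas(config)
    streams = make_streamlines(bundle.atlas, config)

    wmh_masks, stroke_masks, rows = [], [], []
    chaco_rows: dict[str, list[np.ndarray]] = {t: [] for t in MASK_TYPES}
    for i in range(config.n_patients):
        prng = np.random.default_rng(patient_seed(config, i))
        wmh, stroke = make_patient_masks(bundle.atlas, bundle.ventricles, config,
                                         patient_seed(config, i))
        pwmh, dwmh = split_wmh(wmh, bundle.ventricles, config.pv_threshold_mm)
        masks = {"wmh": wmh, "pwmh": pwmh, "dwmh": dwmh}
        for t in MASK_TYPES:
            raw = compute_chaco(masks[t], streams, config.n_regions, mask_type=t)
            chaco_rows[t].append(clean_chaco(raw).values)
        age = float(np.clip(prng.normal(70.7, 12.2), 35.0, 95.0))
        nihss = int(np.clip(np.round(prng.normal(7.8, 3.6)), 1, 20))
        rows.append({
            "patient_id": f"p{i:03d}",
            "age": age,
            "nihss": nihss,
            "lesion_volume_ml": mask_volume_ml(stroke),
            "wmh_volume_ml": mask_volume_ml(wmh),
            "pwmh_volume_ml": mask_volume_ml(pwmh),
            "dwmh_volume_ml": mask_volume_ml(dwmh),
        })
        wmh_masks.append(wmh)
        stroke_masks.append(stroke)

    cohort = pd.DataFrame(rows)
    region_ids = list(range(1, config.n_regions + 1))
    chaco = {
        t: pd.DataFrame(np.vstack(chaco_rows[t]), index=cohort["patient_id"],
                        columns=region_ids)
        for t in MASK_TYPES
    }

    if config.causal_region_ids:
        causal = list(config.causal_region_ids)
        chaco_truth = chaco["pwmh"][causal].mean(axis=1).to_numpy()
    else:
        chaco_truth = np.zeros(config.n_patients)
    grades, outcome_truth = make_outcomes(chaco_truth, cohort, config, config.rng(4))
    cohort["mrs"] = grades
    # keep the canonical column order
    cohort = cohort[["patient_id", "age", "nihss", "mrs", "lesion_volume_ml",
                     "wmh_volume_ml", "pwmh_volume_ml", "dwmh_volume_ml"]]

    truth = {
        "causal_region_ids": list(config.causal_region_ids),
        "causal_chaco_mean": chaco_truth.tolist(),
        "outcome": outcome_truth,
        "pv_threshold_mm": config.pv_threshold_mm,
    }
    return SyntheticCohort(
        config=config,
        atlas=bundle.atlas,
        region_meta=bundle.region_meta,
        ventricles=bundle.ventricles,
        streamlines=streams,
        wmh_masks=wmh_masks,
        stroke_masks=stroke_masks,
        cohort=cohort,
        chaco=chaco,
        truth=truth,
    )
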