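"""End-to-end orchestration: simulate/load -> split -> disconnectivity ->
group stats -> outcome models, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (
    DEFAULT_FLOOR,
    chaco_long_frame,
    clean_chaco,
    compute_chaco,
)
from .group_stats import SKEW_LIMIT, filter_regions, region_disconnection_test
from .outcome import ModelConfig, run_region_models
from .streamlines import StreamlineSet
from .synthetic import MASK_TYPES, SimulationConfig, simulate_cohort
from .topology import split_wmh
from .volumes import LabeledVolume

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    simulation: dict | None = None
    inputs: dict | None = None
    floor: float = DEFAULT_FLOOR
    threshold_mm: float = 10.0
    skew_limit: float = SKEW_LIMIT
    r2_kind: str = "nagelkerke"
    ci_method: str = "wald"
    fdr_alpha: float = 0.05
    base_adjust: str = "wmh_volume"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be supplied"
            )
        if not (0 <= self.fdr_alpha <= 1):
            raise ValueError("fdr_alpha must be in [0, 1]")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.threshold_mm < 0:
            raise ValueError("threshold_mm must be >= 0")


def load_run_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    options = raw.pop("options", {})
    return RunConfig(**{**raw, **options})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(inputs: dict):
    atlas = LabeledVolume.load(inputs["atlas"])
    ventricles = LabeledVolume.load(inputs["ventricles"])
    streams = StreamlineSet.load(inputs["connectome"], atlas=atlas)
    cohort = pd.read_csv(inputs["cohort"])
    patients = inputs["patients"]
    wmh_masks = [LabeledVolume.load(p["wmh"]) for p in patients]
    stroke_masks = [LabeledVolume.load(p["stroke"]) for p in patients]
    meta = pd.read_csv(inputs["region_meta"]) if "region_meta" in inputs else None
    return atlas, ventricles, streams, cohort, wmh_masks, stroke_masks, meta


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages for each mask type; returns the run directory.

    The run directory receives per-stage CSV outputs and ``manifest.json``
    recording the seed, options, package version and a SHA-256 per output
    file. Reruns with the same config and seed reproduce identical outputs.
    """
    out_dir = config.out_dir
    if out_dir is None:
        out_dir = os.path.join("runs", f"run_seed{config.seed}")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def path(name: str) -> str:
        written.append(name)
        return os.path.join(out_dir, name)

    threshold_mm = config.threshold_mm
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        # the band threshold that generated the masks is authoritative for
        # the split so a simulated run is internally consistent
        threshold_mm = sim.pv_threshold_mm
        log.info("simulating cohort (n=%d patients)", sim.n_patients)
        cohort_obj = simulate_cohort(sim)
        data_dir = os.path.join(out_dir, "data")
        for name in cohort_obj.save(data_dir):
            written.append(os.path.join("data", name))
        atlas = cohort_obj.atlas
        ventricles = cohort_obj.ventricles
        streams = cohort_obj.streamlines
        cohort = cohort_obj.cohort
        wmh_masks = cohort_obj.wmh_masks
        n_regions = sim.n_regions
        region_meta = cohort_obj.region_meta
    else:
        atlas, ventricles, streams, cohort, wmh_masks, _, region_meta = _load_inputs(
            config.inputs
        )
        n_regions = int(atlas.data.max())

    patient_ids = list(cohort["patient_id"])
    if len(patient_ids) != len(wmh_masks):
        raise ValueError("cohort rows and mask count disagree")

    # stage: partition + disconnectivity for every mask type
    log.info("computing disconnectivity for %d patients", len(patient_ids))
    vectors = []
    matrices: dict[str, pd.DataFrame] = {}
    rows: dict[str, list[np.ndarray]] = {t: [] for t in MASK_TYPES}
    for pid, wmh in zip(patient_ids, wmh_masks):
        pwmh, dwmh = split_wmh(wmh, ventricles, threshold_mm)
        for mask_type, mask in (("wmh", wmh), ("pwmh", pwmh), ("dwmh", dwmh)):
            vec = clean_chaco(
                compute_chaco(mask, streams, n_regions, mask_type=mask_type,
                              patient_id=pid),
                floor=config.floor,
            )
            vectors.append(vec)
            rows[mask_type].append(vec.values)
    for t in MASK_TYPES:
        matrices[t] = pd.DataFrame(np.vstack(rows[t]), index=patient_ids,
                                   columns=range(1, n_regions + 1))
    chaco_long_frame(vectors).to_csv(path("chaco.csv"), index=False)

    model_cfg = ModelConfig(
        ci_method=config.ci_method,
        r2_kind=config.r2_kind,
        fdr_alpha=config.fdr_alpha,
        base_adjust=config.base_adjust,
    )

    for t in MASK_TYPES:
        mat = matrices[t]
        region_disconnection_test(mat).to_csv(path(f"disconnection_{t}.csv"),
                                              index=False)
        report = filter_regions(mat, skew_limit=config.skew_limit)
        report.to_csv(path(f"region_filter_{t}.csv"), index=False)
        kept = [int(r) for r in report.loc[report["kept"], "region_id"]]

        cohort_t = cohort.copy()
        if config.base_adjust == "global_chaco":
            cohort_t["global_chaco"] = mat.mean(axis=1, skipna=True).to_numpy()
        if kept:
            results = run_region_models(mat, cohort_t, kept_regions=kept,
                                        config=model_cfg)
        else:
            results = pd.DataFrame()
            log.warning("no regions kept for mask type %s", t)
        results.to_csv(path(f"outcome_{t}.csv"), index=False)

    if region_meta is not None:
        region_meta.to_csv(path("region_meta.csv"), index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "options": {
            k: v for k, v in asdict(config).items() if k not in ("out_dir",)
        },
        "files": {
            name: _sha256(os.path.join(out_dir, name)) for name in sorted(written)
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return out_dir
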