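"""Region-wise ordinal outcome modeling.

Per region: the cohort is split at the sample median of the region's
disconnectivity (ties at the median go to the low group); the high/low
indicator enters a proportional-odds model for the ordinal outcome alongside
covariates, with age and total WMH volume residualized against the region's
continuous disconnectivity; effects are summarized as OR / 95% CI / Wald p,
a pseudo-R^2 gain over a base model without the indicator, and
Benjamini-Hochberg adjustment across the region family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ordinal import (
    ConvergenceError,
    PropOddsFit,
    SeparationError,
    extract_effect,
    fit_proportional_odds,
    pseudo_r2,
)

__all__ = [
    "ModelConfig",
    "RegionModelResult",
    "dichotomize",
    "residualize",
    "fdr_adjust",
    "run_region_models",
]


def dichotomize(values: np.ndarray) -> np.ndarray:
    """Split values at the sample median into {0: low, 1: high}.

    Values strictly above the median are high; values equal to the median go
    to the low group (with odd n the median observation itself is low).
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("all values identical; cannot dichotomize")
    return (v > np.median(v)).astype(int)


def residualize(covariate: np.ndarray, against: np.ndarray) -> np.ndarray:
    """OLS residuals of ``covariate`` on (intercept + ``against``).

    The residuals have zero mean and exactly zero sample covariance with
    ``against``.
    """
    cov = np.asarray(covariate, dtype=float)
    ag = np.asarray(against, dtype=float)
    if cov.shape != ag.shape:
        raise ValueError("covariate and against must have equal length")
    if np.var(ag) == 0:
        raise ValueError("zero-variance regressor; cannot residualize")
    X = np.column_stack([np.ones_like(ag), ag])
    coef, *_ = np.linalg.lstsq(X, cov, rcond=None)
    return cov - X @ coef


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Adjusted p_(i) = min over j >= i of (m * p_(j) / j), capped at 1;
    always >= the raw value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass
class ModelConfig:
    """Options for the region-model sweep."""

    ci_method: str = "wald"            # or "profile"
    r2_kind: str = "nagelkerke"        # or "mcfadden"
    fdr_alpha: float = 0.05
    base_adjust: str = "wmh_volume"    # or "global_chaco"
    residualize_target: str = "continuous"  # or "indicator"


@dataclass
class RegionModelResult:
    region_id: int
    or_estimate: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_raw: float = np.nan
    p_fdr: float = np.nan
    r2_base: float = np.nan
    r2_full: float = np.nan
    r2_gain: float = np.nan
    n_low: int = 0
    n_high: int = 0
    status: str = "ok"


_COVARIATE_NAMES = ["age_resid", "nihss", "log10_lesion_vol", "log10_wmh_vol_resid"]


def _design_for_region(
    chaco: np.ndarray,
    cohort: pd.DataFrame,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray, list[str], int, int]:
    """Build (full design, base design, names, n_low, n_high) for one region."""
    indicator = dichotomize(chaco)
    target = chaco if config.residualize_target == "continuous" else indicator.astype(float)

    age = cohort["age"].to_numpy(dtype=float)
    nihss = cohort["nihss"].to_numpy(dtype=float)
    lesion = cohort["lesion_volume_ml"].to_numpy(dtype=float)
    if np.any(lesion <= 0):
        raise ValueError("lesion volumes must be > 0 before log transform")
    log_lesion = np.log10(lesion)

    if config.base_adjust == "wmh_volume":
        wmh_vol = cohort["wmh_volume_ml"].to_numpy(dtype=float)
        if np.any(wmh_vol <= 0):
            raise ValueError("WMH volumes must be > 0 before log transform")
        burden = np.log10(wmh_vol)
        burden_name = "log10_wmh_vol_resid"
    elif config.base_adjust == "global_chaco":
        burden = cohort["global_chaco"].to_numpy(dtype=float)
        burden_name = "global_chaco_resid"
    else:
        raise ValueError(f"unknown base_adjust {config.base_adjust!r}")

    age_r = residualize(age, target)
    burden_r = residualize(burden, target)

    base = np.column_stack([age_r, nihss, log_lesion, burden_r])
    full = np.column_stack([indicator.astype(float), base])
    names = ["high_disconnectivity", "age_resid", "nihss", "log10_lesion_vol", burden_name]
    return full, base, names, int((indicator == 0).sum()), int((indicator == 1).sum())


def run_region_models(
    chaco_matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    kept_regions: list[int] | None = None,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Fit the per-region outcome models and FDR-adjust across the family.

    Parameters
    ----------
    chaco_matrix
        Patients x regions cleaned disconnectivity (columns = region ids),
        indexed compatibly with ``cohort['patient_id']``.
    cohort
        Must contain patient_id, age, nihss, mrs, lesion_volume_ml and
        wmh_volume_ml (or global_chaco when ``base_adjust='global_chaco'``).
    kept_regions
        Region ids entering the sweep (the FDR family). Defaults to all
        columns with no missing values.

    Per-region fit failures are recorded in the ``status`` column and do not
    abort the run.
    """
    config = config or ModelConfig()
    cohort = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    chaco_matrix = chaco_matrix.loc[cohort.index]
    y = cohort["mrs"].to_numpy()

    if kept_regions is None:
        kept_regions = [int(c) for c in chaco_matrix.columns
                        if not chaco_matrix[c].isna().any()]

    results: list[RegionModelResult] = []
    for rid in kept_regions:
        res = RegionModelResult(region_id=int(rid))
        try:
            chaco = chaco_matrix[rid].to_numpy(dtype=float)
            if np.isnan(chaco).any():
                raise ValueError("missing disconnectivity values for kept region")
            full_X, base_X, names, n_low, n_high = _design_for_region(
                chaco, cohort, config
            )
            res.n_low, res.n_high = n_low, n_high
            full_fit = fit_proportional_odds(y, full_X, beta_names=names)
            full_fit._data = (y, full_X)  # retained for profile CIs
            base_fit = fit_proportional_odds(y, base_X, beta_names=names[1:])
            null_fit = _intercept_only_fit(y)
            eff = extract_effect(full_fit, "high_disconnectivity",
                                 ci_method=config.ci_method)
            res.or_estimate = eff.or_estimate
            res.ci_low, res.ci_high = eff.ci_low, eff.ci_high
            res.p_raw = eff.p_value
            res.r2_full = pseudo_r2(full_fit, null_fit, config.r2_kind)
            res.r2_base = pseudo_r2(base_fit, null_fit, config.r2_kind)
            res.r2_gain = res.r2_full - res.r2_base
        except (SeparationError, ConvergenceError, ValueError, KeyError) as exc:
            res.status = f"failed: {exc}"
        results.append(res)

    frame = pd.DataFrame([vars(r) for r in results])
    ok = frame["status"] == "ok"
    frame["p_fdr"] = np.nan
    if ok.any():
        frame.loc[ok, "p_fdr"] = fdr_adjust(frame.loc[ok, "p_raw"].to_numpy())
    return frame


def _intercept_only_fit(y: np.ndarray) -> PropOddsFit:
    return fit_proportional_odds(y, np.empty((len(y), 0)), beta_names=[])
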