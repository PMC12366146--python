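"""Group-level disconnection tests and the region-exclusion filter.

The disconnection test is a one-sample, one-sided (greater-than-zero) t-test
per region on the non-missing values. Regions whose value distribution shows
(almost) complete connection or disconnection -- sample skewness beyond
+/- ``skew_limit`` or a column median of exactly 0 or 1 -- are excluded from
outcome modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "region_disconnection_test",
    "filter_regions",
    "compare_mask_types",
    "sample_skewness",
]

SKEW_LIMIT = 1.3


def sample_skewness(x: np.ndarray, bias_corrected: bool = True) -> float:
    """Sample skewness; bias-corrected (adjusted Fisher-Pearson) by default.

    Zero-variance input yields 0.0 (no asymmetry to measure).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires >= 3 values")
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=not bias_corrected))


def region_disconnection_test(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-region mean, t statistic, and one-sided p against 0.

    Columns with < 2 non-missing values are skipped; zero-variance columns
    are flagged degenerate with p = 0 if the mean is positive else 1.
    """
    rows = []
    for rid in matrix.columns:
        x = matrix[rid].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        row = {"region_id": rid, "n": x.size, "mean": np.nan, "t": np.nan,
               "p": np.nan, "status": "ok"}
        if x.size < 2:
            row["status"] = "skipped: <2 non-missing values"
        elif np.ptp(x) == 0:
            row["mean"] = float(x.mean())
            row["p"] = 0.0 if x.mean() > 0 else 1.0
            row["status"] = "degenerate: zero variance"
        else:
            t, p = stats.ttest_1samp(x, 0.0, alternative="greater")
            row.update(mean=float(x.mean()), t=float(t), p=float(p))
        rows.append(row)
    return pd.DataFrame(rows)


def filter_regions(matrix: pd.DataFrame, skew_limit: float = SKEW_LIMIT,
                   bias_corrected: bool = True) -> pd.DataFrame:
    """Region-exclusion report: kept flag, skewness, median, reason.

    A region is excluded iff its skewness exceeds +/- ``skew_limit``, its
    median is exactly 0 or exactly 1, it is entirely missing, or it has too
    few values for a skewness estimate.
    """
    rows = []
    for rid in matrix.columns:
        x = matrix[rid].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        row = {"region_id": rid, "kept": False, "skewness": np.nan,
               "median": np.nan, "reason": "none"}
        if x.size == 0:
            row["reason"] = "missing"
        elif x.size < 3:
            row["reason"] = "degenerate"
        else:
            g1 = sample_skewness(x, bias_corrected=bias_corrected)
            med = float(np.median(x))
            row["skewness"], row["median"] = g1, med
            if med == 0.0 or med == 1.0:
                row["reason"] = "median"
            elif abs(g1) > skew_limit:
                row["reason"] = "skewness"
            else:
                row["kept"] = True
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MaskTypeComparison:
    mask_a: str
    mask_b: str
    stratum: str
    pairing: str
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    n_pairs: int


def compare_mask_types(
    matrices: dict[str, pd.DataFrame],
    region_meta: pd.DataFrame,
    stratum: str,
    pairing: str,
    restrict_significant: bool = True,
    alpha: float = 0.05,
) -> list[MaskTypeComparison]:
    """Paired two-tailed t-tests of mean disconnectivity between mask types.

    Parameters
    ----------
    matrices
        mask_type -> patients x regions matrix (shared patients and regions).
    region_meta
        Table with columns region_id and cortical (bool).
    stratum
        'cortical' or 'subcortical'.
    pairing
        'region' pairs the per-region means (df = n_regions - 1);
        'patient' pairs the per-patient stratum means (df = n_patients - 1).
        The pairing unit must be chosen explicitly.
    restrict_significant
        With region pairing, keep only regions significantly disconnected
        (one-sided p < alpha) in both members of each pair.
    """
    if pairing not in ("region", "patient"):
        raise ValueError("pairing must be 'region' or 'patient'")
    if stratum not in ("cortical", "subcortical"):
        raise ValueError("stratum must be 'cortical' or 'subcortical'")
    want_cortical = stratum == "cortical"
    stratum_ids = set(
        region_meta.loc[region_meta["cortical"] == want_cortical, "region_id"]
    )

    out = []
    for name_a, name_b in combinations(matrices, 2):
        ma, mb = matrices[name_a], matrices[name_b]
        cols = [c for c in ma.columns if c in stratum_ids and c in mb.columns]
        if pairing == "region":
            if restrict_significant:
                sig_a = _significant_regions(ma[cols], alpha)
                sig_b = _significant_regions(mb[cols], alpha)
                cols = [c for c in cols if c in sig_a and c in sig_b]
            a = ma[cols].mean(axis=0, skipna=True).to_numpy()
            b = mb[cols].mean(axis=0, skipna=True).to_numpy()
        else:
            a = ma[cols].mean(axis=1, skipna=True).to_numpy()
            b = mb[cols].mean(axis=1, skipna=True).to_numpy()
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        if a.size < 2:
            raise ValueError(
                f"fewer than 2 pairs for {name_a} vs {name_b} ({stratum}, {pairing})"
            )
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        out.append(MaskTypeComparison(
            mask_a=name_a, mask_b=name_b, stratum=stratum, pairing=pairing,
            t=float(t), df=a.size - 1, p=float(p),
            mean_a=float(a.mean()), mean_b=float(b.mean()), n_pairs=a.size,
        ))
    return out


def _significant_regions(matrix: pd.DataFrame, alpha: float) -> set:
    rep = region_disconnection_test(matrix)
    return set(rep.loc[rep["p"] < alpha, "region_id"])
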