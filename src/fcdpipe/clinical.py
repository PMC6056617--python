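"""Clinical association: partial correlation of cluster-mean FCD with
clinical variables, controlling for age, gender and TIV (optionally mFD),
Bonferroni-corrected over all (cluster, variable) tests.

The disease progression rate is (48 - ALSFRS-R) / disease duration, with
duration in months; ALSFRS-R is the revised ALS Functional Rating Scale
(0-48, lower = more impairment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "progression_rate",
    "cluster_mean_fcd",
    "partial_correlation",
    "bonferroni_flag",
    "associate_clusters",
]

ALSFRS_MAX = 48


def progression_rate(alsfrs_r, duration_months):
    """Disease progression rate: (48 - ALSFRS-R) / duration (per month)."""
    alsfrs_r = np.asarray(alsfrs_r, dtype=float)
    duration = np.asarray(duration_months, dtype=float)
    if np.any(duration <= 0):
        raise ValueError("disease duration must be positive")
    if np.any((alsfrs_r < 0) | (alsfrs_r > ALSFRS_MAX)):
        raise ValueError("ALSFRS-R scores must lie in [0, 48]")
    return (ALSFRS_MAX - alsfrs_r) / duration


def cluster_mean_fcd(fcd_map: np.ndarray, cluster_mask: np.ndarray) -> float:
    """Unweighted mean of the map over the cluster voxels."""
    m = np.asarray(cluster_mask, dtype=bool)
    if not m.any():
        raise ValueError("cluster mask is empty")
    return float(np.asarray(fcd_map, dtype=float)[m].mean())


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus an intercept);
    r is the Pearson correlation of the residuals and p comes from
    t = r * sqrt((n - k - 2) / (1 - r^2)) with df = n - k - 2, two-sided.
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        k = covariates.shape[1]
        Z = np.column_stack([covariates, np.ones(n)])
    if y.size != n or Z.shape[0] != n:
        raise ValueError("x, y and covariates must have the same length")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    # residuals that vanish up to float error count as zero variance
    if sx <= 1e-10 * max(1.0, np.linalg.norm(x)) or sy <= 1e-10 * max(1.0, np.linalg.norm(y)):
        raise ValueError("degenerate: zero residual variance after removing covariates")
    r = float(np.dot(rx, ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bonferroni_flag(p_values, alpha: float = 0.05) -> np.ndarray:
    """Significance flags under Bonferroni: p_i < alpha / m, m = len(p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p values to correct")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return p < alpha / p.size


def associate_clusters(
    cluster_means: pd.DataFrame,
    clinical: pd.DataFrame,
    variables: tuple[str, ...] = ("progression_rate", "duration_months", "alsfrs_r"),
    controls: tuple[str, ...] = ("age", "gender", "tiv"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial correlation of every cluster-mean column against every
    clinical variable, Bonferroni-corrected across all tests.

    ``cluster_means``: one row per patient, one column per cluster (indexed
    like ``clinical``).  Returns a tidy frame with r, p, the adjusted alpha
    (alpha / m, m = clusters x variables, recorded so the correction is
    auditable) and the significance flag.
    """
    if len(cluster_means) != len(clinical):
        raise ValueError("cluster means and clinical table must align by patient")
    cov_cols = []
    for c in controls:
        v = clinical[c]
        if c == "gender" and v.dtype == object:
            cov_cols.append(v.map({"M": 0.0, "F": 1.0}).to_numpy())
        else:
            cov_cols.append(v.to_numpy(dtype=float))
    Z = np.column_stack(cov_cols) if cov_cols else None
    rows = []
    for cluster in cluster_means.columns:
        for var in variables:
            r, p = partial_correlation(
                cluster_means[cluster].to_numpy(dtype=float),
                clinical[var].to_numpy(dtype=float),
                Z,
            )
            rows.append(
                {"cluster": cluster, "variable": var, "n": len(clinical), "r": r, "p": p}
            )
    out = pd.DataFrame(rows)
    m = len(out)
    out["n_tests"] = m
    out["adjusted_alpha"] = alpha / m
    out["significant"] = bonferroni_flag(out["p"].to_numpy(), alpha)
    out["controls"] = ",".join(controls)
    return out
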