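"""Per-probe age-association testing with FDR control.

For every probe a univariate ordinary-least-squares regression of beta on
chronological age is fitted; the overall F-test of that regression (which
for a single regressor equals the squared t-statistic of the slope) gives
a p-value from the F(1, n-2) upper tail, and Benjamini-Hochberg adjustment
over the whole probe family yields q-values. Probes with q below the FDR
threshold (0.05 by default) are the age-associated candidates passed to
stability selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tissueclock.containers import BetaMatrix, ValidationError, ages_for


class AssociationError(ValueError):
    pass


def fit_probe_regression(betas: np.ndarray, ages: np.ndarray) -> dict:
    """OLS of one probe's beta values on age with the overall F-test.

    Returns a dict with slope, intercept, f_statistic, p_value. Requires
    n >= 3 observations and non-constant ages. A probe with zero residual
    structure (constant betas) gets slope 0, F = 0, p = 1.
    """
    betas = np.asarray(betas, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if betas.shape != ages.shape:
        raise AssociationError("betas and ages must have equal length")
    n = betas.size
    if n < 3:
        raise AssociationError(f"need at least 3 samples for the F(1, n-2) test, got {n}")
    res = _vectorized_ols(betas[None, :], ages)
    return {k: float(v[0]) for k, v in res.items()}


def _vectorized_ols(Y: np.ndarray, x: np.ndarray) -> dict[str, np.ndarray]:
    """Row-wise simple OLS of Y (p x n) on x (n,), with F(1, n-2) p-values."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise AssociationError("ages have zero variance; slope is unidentifiable")
    ym = Y.mean(axis=1)
    sxy = Y @ xc
    slope = sxy / sxx
    intercept = ym - slope * x.mean()
    yc = Y - ym[:, None]
    sst = np.einsum("ij,ij->i", yc, yc)
    ssr = slope**2 * sxx  # regression sum of squares
    sse = np.maximum(sst - ssr, 0.0)
    df2 = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sse > 0, ssr / (sse / df2), np.where(ssr > 0, np.inf, 0.0))
    p = stats.f.sf(f, 1, df2)
    p = np.where(f == 0.0, 1.0, p)
    return {"slope": slope, "intercept": intercept, "f_statistic": f, "p_value": p}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, returned in input order.

    On the sorted scale q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise AssociationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def associate_all(mat: BetaMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Fit every probe's regression and BH-adjust over the whole family.

    The matrix must be harmonized (no missing values). Returns a DataFrame
    indexed like the matrix with columns slope, intercept, f_statistic,
    p_value, q_value.
    """
    if mat.values.isna().any().any():
        raise ValidationError("association requires an imputed (no-missing) matrix")
    ages = ages_for(mat, samples)
    n = ages.size
    if n < 3:
        raise AssociationError(f"need at least 3 samples, got {n}")
    res = _vectorized_ols(mat.values.to_numpy(), ages)
    out = pd.DataFrame(res, index=mat.probe_ids)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def select_age_probes(
    mat: BetaMatrix, samples: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Probes with q strictly below the FDR threshold, sorted by (q, probe)."""
    if not 0.0 <= fdr_threshold < 1.0:
        raise AssociationError(f"fdr_threshold must lie in [0, 1), got {fdr_threshold}")
    results = associate_all(mat, samples)
    selected = results[results["q_value"] < fdr_threshold]
    # stable sort on q after an index sort -> ties broken by probe ID
    return selected.sort_index(kind="mergesort").sort_values("q_value", kind="mergesort")
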