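"""Shared masked/vectorized statistical primitives.

All matrices carry missing entries as NaN; every routine here treats NaN as
"not observed" and never as a value.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "masked_pearson",
    "masked_corr_matrix",
    "corr_pvalues",
    "two_sample_t_rows",
]


def masked_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r over jointly observed entries of two vectors.

    Returns ``(r, n_used)``; ``r`` is NaN when fewer than 3 entries are
    jointly observed or either side has zero variance on the overlap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    joint = np.isfinite(x) & np.isfinite(y)
    n = int(joint.sum())
    if n < 3:
        return float("nan"), n
    xv = x[joint]
    yv = y[joint]
    xv = xv - xv.mean()
    yv = yv - yv.mean()
    denom = np.sqrt((xv * xv).sum() * (yv * yv).sum())
    if denom <= 0.0:
        return float("nan"), n
    r = float((xv * yv).sum() / denom)
    return max(-1.0, min(1.0, r)), n


def masked_corr_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs masked Pearson correlation between rows of X and rows of Y.

    Parameters
    ----------
    X : (G, C) array with NaN for missing.
    Y : (K, C) array with NaN for missing.

    Returns
    -------
    R : (G, K) correlation matrix, NaN where fewer than 3 joint observations
        or zero variance on the overlap.
    N : (G, K) integer count of jointly observed entries per pair.

    Implemented with dense matrix products over zero-filled values and
    boolean masks, so the cost is a handful of GEMMs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Mx = np.isfinite(X)
    My = np.isfinite(Y)
    X0 = np.where(Mx, X, 0.0)
    Y0 = np.where(My, Y, 0.0)
    MxF = Mx.astype(float)
    MyF = My.astype(float)

    n = MxF @ MyF.T
    Sx = X0 @ MyF.T
    Sy = MxF @ Y0.T
    Sxy = X0 @ Y0.T
    Sxx = (X0 * X0) @ MyF.T
    Syy = MxF @ (Y0 * Y0).T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sy / n
        vx = Sxx - Sx * Sx / n
        vy = Syy - Sy * Sy / n
        R = cov / np.sqrt(vx * vy)
    bad = (n < 3) | (vx <= 0) | (vy <= 0)
    R = np.where(bad, np.nan, np.clip(R, -1.0, 1.0))
    return R, n.astype(int)


def corr_pvalues(R: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Two-sided p-values for Pearson correlations via the t transform.

    t = r * sqrt((n - 2) / (1 - r^2)), referred to Student's t with n-2 df.
    |r| = 1 maps to p = 0; undefined correlations map to p = NaN.
    """
    R = np.asarray(R, dtype=float)
    N = np.asarray(N, dtype=float)
    p = np.full(R.shape, np.nan)
    ok = np.isfinite(R) & (N >= 3)
    r = R[ok]
    n = N[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    pv = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p[ok] = pv
    return p


def two_sample_t_rows(
    A: np.ndarray, B: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test between column groups A and B.

    A and B are (rows, nA) and (rows, nB) slices of the same matrix; NaNs are
    ignored per row. Returns (t, p) arrays; degenerate rows (fewer than 2
    observed values in either group) get p = NaN. Rows where both groups have
    zero variance get p = 1 when the means agree, p = 0 otherwise.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    nA = np.isfinite(A).sum(axis=1).astype(float)
    nB = np.isfinite(B).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mA = np.nanmean(A, axis=1) if A.shape[1] else np.full(A.shape[0], np.nan)
        mB = np.nanmean(B, axis=1) if B.shape[1] else np.full(B.shape[0], np.nan)
        vA = np.nanvar(A, axis=1, ddof=1) if A.shape[1] > 1 else np.full(A.shape[0], np.nan)
        vB = np.nanvar(B, axis=1, ddof=1) if B.shape[1] > 1 else np.full(B.shape[0], np.nan)

    t = np.full(A.shape[0], np.nan)
    p = np.full(A.shape[0], np.nan)
    ok = (nA >= 2) & (nB >= 2)
    if not np.any(ok):
        return t, p

    mA, mB, vA, vB, na, nb = (arr[ok] for arr in (mA, mB, vA, vB, nA, nB))
    diff = mA - mB
    if equal_var:
        pooled = ((na - 1) * vA + (nb - 1) * vB) / (na + nb - 2)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(vA / na + vB / nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (vA / na + vB / nb) ** 2 / (
                (vA / na) ** 2 / (na - 1) + (vB / nb) ** 2 / (nb - 1)
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        tv = diff / se
    pv = 2.0 * stats.t.sf(np.abs(tv), df)
    # both groups constant: exact tie -> p=1, any difference -> p=0
    degenerate = se == 0.0
    pv = np.where(degenerate, np.where(diff == 0.0, 1.0, 0.0), pv)
    tv = np.where(degenerate, np.where(diff == 0.0, 0.0, np.inf * np.sign(diff)), tv)
    t[ok] = tv
    p[ok] = pv
    return t, p
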