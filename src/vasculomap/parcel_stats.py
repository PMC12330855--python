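"""Parcel-level aggregation and the statistical battery: per-area medians,
Pearson correlations with two-tailed bootstrap tests, correlation-difference
tests, paired t-test, variance-ratio comparison and Bonferroni correction.

Bootstrap tests resample observation pairs with replacement; the two-tailed
p-value is the percentile form 2·min(P(r* ≤ 0), P(r* ≥ 0)), clipped to
[2/n_boot, 1].  All bootstrap draws are reproducible bit-for-bit given
(seed, n_boot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "parcel_median",
    "pearson_bootstrap",
    "compare_correlations",
    "paired_t_and_variance",
    "bonferroni",
]


@dataclass
class CorrelationResult:
    r: float
    p_boot: float
    n: int
    n_boot: int
    p_bonferroni: float | None = None
    defined: bool = True


def parcel_median(metric: np.ndarray, labels: np.ndarray,
                  exclude: tuple = ()) -> pd.Series:
    """Per-area median of a per-vertex (or per-voxel) metric.

    ``labels`` assigns an area id to each entry of ``metric``; areas listed
    in ``exclude`` are dropped.  Empty areas come back as NaN with their id
    retained, so callers can flag them.  When several subjects are pooled,
    compute per-subject medians first and average the resulting Series.
    """
    metric = np.asarray(metric, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if metric.shape != labels.shape:
        raise ValueError("metric and labels must align")
    out = {}
    for area in pd.unique(labels):
        if area in exclude:
            continue
        vals = metric[labels == area]
        vals = vals[np.isfinite(vals)]
        out[area] = float(np.median(vals)) if vals.size else np.nan
    return pd.Series(out, name="median")


def _clean_pairs(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def _bootstrap_r(x: np.ndarray, y: np.ndarray, n_boot: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized bootstrap distribution of Pearson r over pair resamples."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    xb = xb - xb.mean(axis=1, keepdims=True)
    yb = yb - yb.mean(axis=1, keepdims=True)
    num = (xb * yb).sum(axis=1)
    den = np.sqrt((xb**2).sum(axis=1) * (yb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def _two_tailed_p(r_boot: np.ndarray, n_boot: int) -> float:
    r_boot = r_boot[np.isfinite(r_boot)]
    lo = float(np.mean(r_boot <= 0))
    hi = float(np.mean(r_boot >= 0))
    p = 2.0 * min(lo, hi)
    return float(np.clip(p, 2.0 / n_boot, 1.0))


def pearson_bootstrap(x, y, n_boot: int = 10000, seed: int = 0) -> CorrelationResult:
    """Pearson r with a two-tailed bootstrap significance test."""
    x, y = _clean_pairs(x, y, min_n=5)
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, x.size, n_boot, defined=False)
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    r_boot = _bootstrap_r(x, y, n_boot, rng)
    return CorrelationResult(r, _two_tailed_p(r_boot, n_boot), x.size, n_boot)


def compare_correlations(x_a, y_a, x_b, y_b, n_boot: int = 10000,
                         seed: int = 0) -> dict:
    """Two-tailed bootstrap test for a difference between two correlations.

    The two tables are resampled independently; the bootstrap distribution
    of Δr = r_A* − r_B* is centred on its point estimate, and the p-value
    tests Δr = 0.
    """
    x_a, y_a = _clean_pairs(x_a, y_a, min_n=5)
    x_b, y_b = _clean_pairs(x_b, y_b, min_n=5)
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    ra = float(stats.pearsonr(x_a, y_a)[0])
    rb = float(stats.pearsonr(x_b, y_b)[0])
    da = _bootstrap_r(x_a, y_a, n_boot, rng)
    db = _bootstrap_r(x_b, y_b, n_boot, rng)
    delta = da - db
    p = _two_tailed_p(delta, n_boot)
    return {"r_a": ra, "r_b": rb, "delta_r": ra - rb, "p_boot": p,
            "n_a": x_a.size, "n_b": x_b.size, "n_boot": n_boot}


def paired_t_and_variance(gm, swm) -> dict:
    """Paired two-tailed t-test plus a variance-ratio comparison.

    Returns the paired t statistic with df = n − 1, the variance ratio
    F = s²_gm / s²_swm with a two-tailed p, and descriptive SD/IQR per
    group.
    """
    gm = np.asarray(gm, dtype=float).ravel()
    swm = np.asarray(swm, dtype=float).ravel()
    if gm.shape != swm.shape:
        raise ValueError("paired vectors must have equal length")
    if gm.size < 2:
        raise ValueError("need at least 2 pairs")
    n = gm.size
    diff = gm - swm
    sd_diff = diff.std(ddof=1)
    if sd_diff == 0:
        t, p_t = 0.0, 1.0
    else:
        t = float(diff.mean() / (sd_diff / np.sqrt(n)))
        p_t = float(2 * stats.t.sf(abs(t), df=n - 1))
    var_g = gm.var(ddof=1)
    var_s = swm.var(ddof=1)
    if var_s == 0:
        f, p_f = np.nan, np.nan
    else:
        f = float(var_g / var_s)
        cdf = stats.f.cdf(f, n - 1, n - 1)
        p_f = float(2 * min(cdf, 1 - cdf))
    return {
        "t": t, "df": n - 1, "p_t": p_t,
        "F": f, "df1": n - 1, "df2": n - 1, "p_F": p_f,
        "sd_gm": float(gm.std(ddof=1)), "sd_swm": float(swm.std(ddof=1)),
        "iqr_gm": float(np.subtract(*np.percentile(gm, [75, 25]))),
        "iqr_swm": float(np.subtract(*np.percentile(swm, [75, 25]))),
    }


def bonferroni(p_values, m: int | None = None):
    """Bonferroni correction: min(1, m·p) per value."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
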