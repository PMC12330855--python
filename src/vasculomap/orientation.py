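"""Orientation bias of ΔR2* with respect to the main magnetic field.

Vessel-induced gradient-echo relaxation depends on the angle between the
tubular structure and B0; empirically this is modelled as a linear term in
cos²θ.  The same relation is used two ways: estimating vessel alignment from
the sign of the ΔR2* ~ cos²θ_normal,B0 correlation, and regressing the
cos²θ component out of per-vertex maps.  A negative slope is read as vessels
predominantly perpendicular to the cortical surface, a positive slope as
parallel; this sign convention is a documented reading, not asserted physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BiasFit", "cos2_angle", "fit_orientation_bias", "correct_orientation_bias"]


@dataclass
class BiasFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    defined: bool = True


def cos2_angle(v: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """cos²θ between vector(s) ``v`` and the unit field direction ``b0``.

    ``v`` may be a single 3-vector or an (n, 3) stack; vectors are
    renormalized defensively.  Zero vectors are rejected.
    """
    v = np.asarray(v, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    nb = np.linalg.norm(b0)
    if nb == 0:
        raise ValueError("b0 must be nonzero")
    b0 = b0 / nb
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    nv = np.linalg.norm(v2, axis=1)
    if np.any(nv == 0):
        raise ValueError("zero orientation vector")
    c2 = (v2 @ b0 / nv) ** 2
    c2 = np.clip(c2, 0.0, 1.0)
    return float(c2[0]) if single else c2


def fit_orientation_bias(delta: np.ndarray, cos2: np.ndarray) -> BiasFit:
    """OLS fit of ΔR2* = intercept + slope * cos²θ with Pearson r.

    Requires at least 10 paired finite samples.  Zero variance in cos²θ
    yields a flagged, undefined fit rather than an exception.
    """
    delta = np.asarray(delta, dtype=float).ravel()
    cos2 = np.asarray(cos2, dtype=float).ravel()
    if delta.shape != cos2.shape:
        raise ValueError("delta and cos2 must have equal length")
    keep = np.isfinite(delta) & np.isfinite(cos2)
    d, c = delta[keep], cos2[keep]
    if d.size < 10:
        raise ValueError("need at least 10 paired samples")
    if np.ptp(c) == 0 or np.allclose(np.var(c), 0.0):
        return BiasFit(np.nan, float(d.mean()), np.nan, np.nan, d.size, defined=False)
    slope, intercept = np.polyfit(c, d, 1)
    if np.ptp(d) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(c, d)
    return BiasFit(float(slope), float(intercept), float(r), float(p), d.size)


def correct_orientation_bias(
    metric: np.ndarray, cos2: np.ndarray, fit: BiasFit | None = None
) -> np.ndarray:
    """Remove the fitted cos²θ component, preserving the mean exactly.

    corrected = metric - slope * (cos²θ - mean(cos²θ)).  If the fit is
    undefined (zero cos²θ variance) the input is returned unchanged.
    """
    metric = np.asarray(metric, dtype=float)
    cos2 = np.asarray(cos2, dtype=float)
    if metric.shape != cos2.shape:
        raise ValueError("metric and cos2 must share shape")
    if fit is None:
        fit = fit_orientation_bias(metric, cos2)
    if not fit.defined:
        return metric.copy()
    keep = np.isfinite(metric) & np.isfinite(cos2)
    cbar = cos2[keep].mean()
    out = metric - fit.slope * (cos2 - cbar)
    return out
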