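"""Voxel-wise R2* fitting from multi-echo magnitude data and ΔR2* maps.

The mono-exponential model is S(TE) = S0 * exp(-R2* * TE).  Echo times are
stored in milliseconds at the interface (matching acquisition protocol
tables) and converted to seconds internally, so R2* and ΔR2* are always in
1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_TE_MS",
    "MultiEchoSeries",
    "R2StarMap",
    "DeltaR2StarMap",
    "fit_r2star",
    "delta_r2star",
    "loglinear_r2star_sd",
]

#: Default echo-time grid, ms (10 equidistant echoes, 3.4-25.0 ms, step 2.4).
DEFAULT_TE_MS = tuple(np.arange(3.4, 25.0 + 1e-9, 2.4).round(6))


@dataclass
class MultiEchoSeries:
    """Stack of echo volumes with strictly increasing echo times (ms)."""

    echoes: list[np.ndarray]
    te_ms: np.ndarray

    def __post_init__(self) -> None:
        self.echoes = [np.asarray(e, dtype=float) for e in self.echoes]
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if len(self.echoes) < 3:
            raise ValueError("need at least 3 echoes")
        if len(self.echoes) != len(self.te_ms):
            raise ValueError("echo count and TE count differ")
        if np.any(np.diff(self.te_ms) <= 0) or np.any(self.te_ms <= 0):
            raise ValueError("te_ms must be positive and strictly increasing")
        shape = self.echoes[0].shape
        if any(e.shape != shape for e in self.echoes):
            raise ValueError("all echo volumes must share a shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.echoes[0].shape

    def stacked(self) -> np.ndarray:
        """(n_echoes, *shape) array."""
        return np.stack(self.echoes, axis=0)

    def scaled(self, k: float) -> "MultiEchoSeries":
        return MultiEchoSeries([e * k for e in self.echoes], self.te_ms)


@dataclass
class R2StarMap:
    """Voxel-wise mono-exponential fit: rate (1/s), S0, and log-domain R²."""

    r2star: np.ndarray
    s0: np.ndarray
    fit_quality: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.r2star)


@dataclass
class DeltaR2StarMap:
    """Post-minus-pre R2* (1/s); NaN where either input is invalid."""

    delta: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.delta)


def _loglinear_fit(signal: np.ndarray, te_s: np.ndarray, valid_e: np.ndarray):
    """OLS of log-signal on TE per voxel, using only valid echoes.

    signal: (n_echoes, n_vox); valid_e: same-shape bool.  Returns
    (r2star, s0, r_squared, valid) over voxels.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(valid_e, np.log(np.where(valid_e, signal, 1.0)), 0.0)
    w = valid_e.astype(float)
    n = w.sum(axis=0)
    te = te_s[:, None]
    sw_t = (w * te).sum(axis=0)
    sw_y = (w * logs).sum(axis=0)
    sw_tt = (w * te * te).sum(axis=0)
    sw_ty = (w * te * logs).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sw_tt - sw_t**2
        slope = (n * sw_ty - sw_t * sw_y) / denom
        intercept = (sw_y - slope * sw_t) / n
        # R^2 of the log-linear fit
        ss_tot = (w * logs**2).sum(axis=0) - sw_y**2 / n
        resid = np.where(valid_e, logs - (intercept[None] + slope[None] * te), 0.0)
        ss_res = (resid**2).sum(axis=0)
        r2q = np.where(ss_tot > 0, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), 1.0)
    ok = (n >= 3) & np.isfinite(slope)
    return -slope, np.exp(intercept), r2q, ok


def _nls_refine(signal, te_s, valid_e, r2_0, s0_0, ok, n_iter: int = 30):
    """Vectorized Gauss-Newton refinement of (S0, R2*) per voxel.

    Minimizes sum over echoes of (S0*exp(-R2* TE) - y)^2 with damping;
    starts from the log-linear solution.
    """
    s0 = s0_0.copy()
    r2 = r2_0.copy()
    w = valid_e.astype(float)
    te = te_s[:, None]
    lam = np.full(r2.shape, 1e-6)
    y = np.where(valid_e, signal, 0.0)

    def cost(s0_, r2_):
        m = s0_[None] * np.exp(-r2_[None] * te)
        return (w * (m - y) ** 2).sum(axis=0)

    c = cost(s0, r2)
    for _ in range(n_iter):
        e = np.exp(-r2[None] * te)
        model = s0[None] * e
        r = model - y
        j_s0 = e
        j_r2 = -te * model
        a11 = (w * j_s0 * j_s0).sum(axis=0)
        a12 = (w * j_s0 * j_r2).sum(axis=0)
        a22 = (w * j_r2 * j_r2).sum(axis=0)
        g1 = (w * j_s0 * r).sum(axis=0)
        g2 = (w * j_r2 * r).sum(axis=0)
        d11 = a11 * (1 + lam)
        d22 = a22 * (1 + lam)
        det = d11 * d22 - a12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            ds0 = -(d22 * g1 - a12 * g2) / det
            dr2 = -(d11 * g2 - a12 * g1) / det
        bad = ~np.isfinite(ds0) | ~np.isfinite(dr2)
        ds0 = np.where(bad, 0.0, ds0)
        dr2 = np.where(bad, 0.0, dr2)
        s0_new = s0 + ds0
        r2_new = r2 + dr2
        c_new = cost(s0_new, r2_new)
        improved = c_new < c
        s0 = np.where(improved, s0_new, s0)
        r2 = np.where(improved, r2_new, r2)
        c = np.where(improved, c_new, c)
        lam = np.where(improved, lam * 0.5, lam * 4.0)
    return r2, s0


def fit_r2star(
    series: MultiEchoSeries,
    method: str = "loglinear",
    mask: np.ndarray | None = None,
) -> R2StarMap:
    """Fit S(TE) = S0 exp(-R2* TE) per voxel.

    Parameters
    ----------
    method : {"loglinear", "nls"}
        ``loglinear`` is OLS on log-signal; ``nls`` is nonlinear least
        squares initialized from the log-linear solution.
    mask : bool array, optional
        Voxels to fit; everything else is NaN in the output.

    Voxels with non-positive signal at an echo simply drop that echo; voxels
    with fewer than 3 valid echoes are flagged invalid (NaN), never raised.
    """
    if method not in ("loglinear", "nls"):
        raise ValueError(f"unknown method {method!r}")
    shape = series.shape
    sig = series.stacked().reshape(len(series.te_ms), -1)
    te_s = series.te_ms / 1000.0

    if mask is None:
        mvox = np.ones(sig.shape[1], dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape mismatch")
        mvox = mask.reshape(-1)

    valid_e = (sig > 0) & mvox[None, :]
    r2, s0, r2q, ok = _loglinear_fit(sig, te_s, valid_e)
    if method == "nls":
        r2, s0 = _nls_refine(sig, te_s, valid_e, np.where(ok, r2, 0.0),
                             np.where(ok, s0, 1.0), ok)
    ok = ok & mvox
    nan = np.where(ok, 0.0, np.nan)
    out = R2StarMap(
        r2star=(r2 + nan).reshape(shape),
        s0=(s0 + nan).reshape(shape),
        fit_quality=(r2q + nan).reshape(shape),
        valid=ok.reshape(shape),
    )
    return out


def delta_r2star(post: R2StarMap, pre: R2StarMap) -> DeltaR2StarMap:
    """Post-contrast minus pre-contrast R2*, voxel-wise."""
    if post.r2star.shape != pre.r2star.shape:
        raise ValueError("R2* map geometries differ")
    delta = post.r2star - pre.r2star
    valid = post.valid & pre.valid
    delta = np.where(valid, delta, np.nan)
    return DeltaR2StarMap(delta=delta, valid=valid)


def loglinear_r2star_sd(
    s0: float, r2star: float, te_ms: np.ndarray, noise_sd: float
) -> float:
    """First-order propagated SD of the log-linear R2* estimate.

    Additive Gaussian noise of ``noise_sd`` on each echo maps to noise of
    sd/S(TE) on log-signal; the OLS slope then has variance
    sum(c_i^2 sd_i^2) with c the slope contrast of the TE design.  Used as
    an independent error bound for phantom round-trip checks.
    """
    te_s = np.asarray(te_ms, dtype=float) / 1000.0
    s = s0 * np.exp(-r2star * te_s)
    sd_log = noise_sd / s
    tbar = te_s.mean()
    c = (te_s - tbar) / ((te_s - tbar) ** 2).sum()
    return float(np.sqrt(((c * sd_log) ** 2).sum()))
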