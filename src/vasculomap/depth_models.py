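"""Exponential depth models for along-tract metric profiles, plus
linear/quadratic/logistic alternatives and AICc/BIC comparison.

The exponential family is y = -a * exp(-b * d) + c with d the relative
distance in percent (0 at the white-matter surface, 100 at the midline).
Group-level results are conventionally displayed with a positive amplitude,
``A * exp(-b d) + c`` with A = -a; :attr:`DepthModelFit.display_params`
exposes that form so reported curves read like published ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = [
    "DepthModelFit",
    "ModelComparison",
    "fit_exponential",
    "fit_linear",
    "fit_quadratic",
    "fit_logistic",
    "fit_alternatives",
    "compare_models",
    "exponential_curve",
    "logistic_curve",
]

_K_FREE = {"exponential": 3, "linear": 2, "quadratic": 3, "logistic": 3}

#: Multi-start grid on the exponential rate (per percent distance).
_B_STARTS = (0.005, 0.01, 0.02, 0.05, 0.1)


def exponential_curve(d: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """y = -a exp(-b d) + c (internal sign convention)."""
    return -a * np.exp(-b * np.asarray(d, dtype=float)) + c


def logistic_curve(d: np.ndarray, amplitude: float, midpoint: float, rate: float) -> np.ndarray:
    """y = amplitude / (1 + exp(-rate (d - midpoint))); no separate offset."""
    z = np.clip(rate * (np.asarray(d, dtype=float) - midpoint), -500, 500)
    return amplitude / (1.0 + np.exp(-z))


@dataclass
class DepthModelFit:
    """One fitted depth-model family with information criteria.

    ``params`` holds the family-specific parameters; ``k`` counts the free
    mean-model parameters (the noise variance is added as one more when
    computing the criteria).
    """

    family: str
    params: dict[str, float]
    rss: float
    n: int
    k: int
    r_squared: float
    aic: float = np.nan
    aicc: float = np.nan
    bic: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def display_params(self) -> dict[str, float]:
        """Positive-amplitude display form for the exponential family."""
        if self.family != "exponential":
            return dict(self.params)
        return {
            "amplitude": -self.params["a"],
            "rate": self.params["b"],
            "offset": self.params["c"],
        }

    def predict(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        p = self.params
        if self.family == "exponential":
            return exponential_curve(d, p["a"], p["b"], p["c"])
        if self.family == "linear":
            return p["slope"] * d + p["intercept"]
        if self.family == "quadratic":
            return p["c2"] * d**2 + p["c1"] * d + p["c0"]
        if self.family == "logistic":
            return logistic_curve(d, p["amplitude"], p["midpoint"], p["rate"])
        raise ValueError(self.family)


@dataclass
class ModelComparison:
    fits: dict[str, DepthModelFit]
    winner_aicc: str
    winner_bic: str
    delta_aicc: dict[str, float]
    delta_bic: dict[str, float]
    ties_aicc: list[str] = field(default_factory=list)
    ties_bic: list[str] = field(default_factory=list)


def _check_inputs(d: np.ndarray, y: np.ndarray, min_n: int = 4):
    d = np.asarray(d, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if d.shape != y.shape:
        raise ValueError("d and y must have equal length")
    keep = np.isfinite(d) & np.isfinite(y)
    d, y = d[keep], y[keep]
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} finite points")
    return d, y


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    rss = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    return rss, r2


def _exp_linear_solve(d: np.ndarray, y: np.ndarray, b: float):
    """Given the rate, solve the conditionally-linear (a, c) by OLS."""
    basis = np.stack([-np.exp(-b * d), np.ones_like(d)], axis=1)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return coef[0], coef[1], float((resid**2).sum())


def fit_exponential(d: np.ndarray, y: np.ndarray) -> DepthModelFit:
    """Nonlinear least squares for (a, b, c) of y = -a exp(-b d) + c.

    Variable projection over a multi-start rate grid (the amplitude and
    offset are conditionally linear), followed by a full 3-parameter polish.
    The sign of ``a`` is free, so both decay and growth profiles fit.
    """
    d, y = _check_inputs(d, y)
    flags: list[str] = []

    if np.ptp(y) == 0:
        # constant data: amplitude 0, rate unidentifiable
        c = float(y[0])
        return DepthModelFit(
            "exponential", {"a": 0.0, "b": np.nan, "c": c}, 0.0, d.size, 3, 1.0,
            flags=["rate_unidentifiable"],
        )

    span = max(np.ptp(d), 1e-12)
    grid = np.unique(np.concatenate([
        np.asarray(_B_STARTS, dtype=float),
        np.geomspace(0.05 / span, 50.0 / span, 40),
    ]))
    best = None
    for b in grid:
        a, c, rss = _exp_linear_solve(d, y, b)
        if best is None or rss < best[3]:
            best = (a, b, c, rss)
    a0, b0, c0, _ = best

    def resid(p):
        return exponential_curve(d, *p) - y

    sol = optimize.least_squares(resid, [a0, b0, c0], method="lm", xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14, max_nfev=2000)
    a, b, c = sol.x
    rss, r2 = _metrics(y, exponential_curve(d, a, b, c))
    if rss > best[3]:  # polish made things worse: keep grid solution
        a, b, c = a0, b0, c0
        rss, r2 = _metrics(y, exponential_curve(d, a, b, c))
        flags.append("polish_failed")
    return DepthModelFit("exponential", {"a": float(a), "b": float(b), "c": float(c)},
                         rss, d.size, 3, r2, flags=flags)


def fit_linear(d: np.ndarray, y: np.ndarray) -> DepthModelFit:
    d, y = _check_inputs(d, y, min_n=3)
    slope, intercept = np.polyfit(d, y, 1)
    rss, r2 = _metrics(y, slope * d + intercept)
    return DepthModelFit("linear", {"slope": float(slope), "intercept": float(intercept)},
                         rss, d.size, 2, r2)


def fit_quadratic(d: np.ndarray, y: np.ndarray) -> DepthModelFit:
    d, y = _check_inputs(d, y)
    c2, c1, c0 = np.polyfit(d, y, 2)
    rss, r2 = _metrics(y, c2 * d**2 + c1 * d + c0)
    return DepthModelFit("quadratic", {"c2": float(c2), "c1": float(c1), "c0": float(c0)},
                         rss, d.size, 3, r2)


def fit_logistic(d: np.ndarray, y: np.ndarray) -> DepthModelFit:
    """3-parameter logistic (amplitude, midpoint, rate) by multi-start NLS."""
    d, y = _check_inputs(d, y)
    flags: list[str] = []
    span = max(np.ptp(d), 1e-12)
    # variable projection: the amplitude is conditionally linear given
    # (midpoint, rate), so scan a coarse grid and polish the best start
    rates = np.concatenate([np.geomspace(0.3 / span, 30.0 / span, 8),
                            -np.geomspace(0.3 / span, 30.0 / span, 8)])
    mids = d.min() + span * np.linspace(0.1, 0.9, 7)
    rr, mm = np.meshgrid(rates, mids, indexing="ij")
    z = np.clip(rr.ravel()[:, None] * (d[None, :] - mm.ravel()[:, None]), -500, 500)
    sig = 1.0 / (1.0 + np.exp(-z))  # (n_grid, n_points)
    denom = (sig * sig).sum(axis=1)
    amp = (sig * y[None, :]).sum(axis=1) / np.maximum(denom, 1e-300)
    rss_grid = ((amp[:, None] * sig - y[None, :]) ** 2).sum(axis=1)
    i0 = int(np.argmin(rss_grid))
    p0 = (float(amp[i0]), float(mm.ravel()[i0]), float(rr.ravel()[i0]))

    def resid(p):
        return logistic_curve(d, *p) - y

    best = (np.asarray(p0), float(rss_grid[i0]))
    try:
        sol = optimize.least_squares(resid, p0, max_nfev=100)
        rss = float((sol.fun**2).sum())
        if rss < best[1]:
            best = (sol.x, rss)
        if rss <= 1e-10 * max(float((y**2).sum()), 1.0):
            # near-exact data: polish to machine precision
            sol = optimize.least_squares(resid, best[0], xtol=1e-15, ftol=1e-15,
                                         gtol=1e-15, max_nfev=300)
            rss = float((sol.fun**2).sum())
            if rss < best[1]:
                best = (sol.x, rss)
    except Exception:
        flags.append("nonconvergent")
        best = None
    if best is None:
        flags.append("nonconvergent")
        lin = fit_linear(d, y)
        lin.flags = flags + ["fallback_linear"]
        return lin
    p, rss = best
    _, r2 = _metrics(y, logistic_curve(d, *p))
    return DepthModelFit(
        "logistic",
        {"amplitude": float(p[0]), "midpoint": float(p[1]), "rate": float(p[2])},
        rss, d.size, 3, r2, flags=flags,
    )


_FITTERS: dict[str, Callable] = {
    "exponential": fit_exponential,
    "linear": fit_linear,
    "quadratic": fit_quadratic,
    "logistic": fit_logistic,
}


def fit_alternatives(d: np.ndarray, y: np.ndarray,
                     families: tuple[str, ...] = ("exponential", "linear", "quadratic", "logistic"),
                     ) -> dict[str, DepthModelFit]:
    """Fit each requested family to the same (d, y)."""
    return {fam: _FITTERS[fam](d, y) for fam in families}


def information_criteria(rss: float, n: int, k_free: int) -> tuple[float, float, float]:
    """(AIC, AICc, BIC) under a Gaussian likelihood with RSS.

    k' = k_free + 1 counts the noise variance as a free parameter:
    AIC = n ln(RSS/n) + 2k', BIC = n ln(RSS/n) + k' ln n,
    AICc = AIC + 2k'(k'+1)/(n-k'-1).
    """
    kp = k_free + 1
    base = n * np.log(max(rss, 1e-300) / n)
    aic = base + 2 * kp
    bic = base + kp * np.log(n)
    aicc = aic + 2 * kp * (kp + 1) / (n - kp - 1) if n > kp + 1 else np.nan
    return float(aic), float(aicc), float(bic)


def compare_models(fits: dict[str, DepthModelFit], tie_tol: float = 1e-9) -> ModelComparison:
    """Rank fitted families by AICc and BIC (all on identical data)."""
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValueError("all fits must be computed on the same data")
    for fam, f in fits.items():
        f.aic, f.aicc, f.bic = information_criteria(f.rss, f.n, f.k)
        if not np.isfinite(f.aicc):
            f.flags.append("aicc_undefined")

    def rank(attr):
        vals = {fam: getattr(f, attr) for fam, f in fits.items()}
        finite = {fam: v for fam, v in vals.items() if np.isfinite(v)}
        if not finite:  # criterion undefined for every family (tiny n)
            return None, [], {fam: np.nan for fam in vals}
        winner = min(finite, key=finite.get)
        ties = [fam for fam, v in finite.items()
                if fam != winner and abs(v - finite[winner]) <= tie_tol]
        deltas = {fam: v - finite[winner] for fam, v in vals.items()}
        return winner, ties, deltas

    w_aicc, ties_aicc, d_aicc = rank("aicc")
    w_bic, ties_bic, d_bic = rank("bic")
    return ModelComparison(fits, w_aicc, w_bic, d_aicc, d_bic, ties_aicc, ties_bic)
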