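"""Forward stepwise nonlinear regression of node-wise ΔR2* on tract
microstructure and depth, with leave-one-bundle-out cross-validation.

Candidate terms: NDI and ODI enter linearly; relative distance enters as a
nonlinear term A·exp(-rate·d) with no separate offset (the model intercept
plays that role).  Selection greedily adds the term with the largest BIC
decrease and stops when no candidate helps; BIC uses the Gaussian RSS form
with every free parameter (including the exponential rate and the noise
variance) counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["PredictorSet", "StepwiseResult", "CVResult", "forward_stepwise", "loobcv"]

log = logging.getLogger(__name__)

CANDIDATE_ORDER = ("ndi", "odi", "exp_distance")

_RATE_GRID = np.concatenate([[0.005, 0.01, 0.02, 0.05, 0.1],
                             np.geomspace(1e-3, 1.0, 25)])


@dataclass
class PredictorSet:
    """Complete-case per-(bundle, node) observations."""

    table: pd.DataFrame  # columns: bundle, ndi, odi, relative_distance, delta_r2star

    def __post_init__(self) -> None:
        required = {"bundle", "ndi", "odi", "relative_distance", "delta_r2star"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.table = self.table.dropna(subset=sorted(required)).reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def bundles(self) -> list[str]:
        return sorted(self.table["bundle"].unique())


@dataclass
class TermFit:
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    rss: float
    n: int
    k_free: int  # mean-model free parameters (intercept + linear + 2 per exp)
    converged: bool = True

    @property
    def bic(self) -> float:
        kp = self.k_free + 1  # + noise variance
        return self.n * float(np.log(max(self.rss, 1e-300) / self.n)) + kp * np.log(self.n)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        c = self.coefficients
        yhat = np.full(len(table), c["intercept"])
        if "ndi" in self.terms:
            yhat = yhat + c["ndi"] * table["ndi"].to_numpy()
        if "odi" in self.terms:
            yhat = yhat + c["odi"] * table["odi"].to_numpy()
        if "exp_distance" in self.terms:
            yhat = yhat + c["exp_amplitude"] * np.exp(
                -c["exp_rate"] * table["relative_distance"].to_numpy())
        return yhat


@dataclass
class StepwiseResult:
    selected_terms: tuple[str, ...]
    coefficients: dict[str, float]
    bic_path: list[float]
    step_log: list[dict]
    r: float
    r_squared: float
    final: TermFit = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class CVResult:
    pooled_r: float
    per_bundle_r: dict[str, float]
    predictions: pd.DataFrame
    dropped_folds: list[str] = field(default_factory=list)


def _design(table: pd.DataFrame, terms: tuple[str, ...], rate: float | None):
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for t in terms:
        if t == "ndi" or t == "odi":
            cols.append(table[t].to_numpy())
            names.append(t)
        elif t == "exp_distance":
            cols.append(np.exp(-rate * table["relative_distance"].to_numpy()))
            names.append("exp_amplitude")
    return np.stack(cols, axis=1), names


def _fit_terms(table: pd.DataFrame, terms: tuple[str, ...]) -> TermFit:
    """Least-squares fit of intercept + selected terms.

    With the exponential term present, the rate is profiled over a grid
    (the remaining coefficients are conditionally linear) and polished by
    full nonlinear least squares.
    """
    y = table["delta_r2star"].to_numpy()
    n = len(y)
    has_exp = "exp_distance" in terms
    if not has_exp:
        x, names = _design(table, terms, None)
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ coef) ** 2).sum())
        return TermFit(terms, dict(zip(names, coef)), rss, n, x.shape[1])

    best = None
    for rate in _RATE_GRID:
        x, names = _design(table, terms, rate)
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ coef) ** 2).sum())
        if best is None or rss < best[2]:
            best = (rate, coef, rss, names)
    rate0, coef0, rss0, names = best

    d = table["relative_distance"].to_numpy()
    x_lin, _ = _design(table, tuple(t for t in terms if t != "exp_distance"), None)

    def resid(p):
        lin = x_lin @ p[:x_lin.shape[1]]
        return lin + p[-2] * np.exp(-np.clip(p[-1], -10, 10) * d) - y

    # parameter vector: [linear coefs..., exp_amplitude, exp_rate]
    amp_idx = names.index("exp_amplitude")
    lin_coefs = [c for i, c in enumerate(coef0) if i != amp_idx]
    p0 = np.array(lin_coefs + [coef0[amp_idx], rate0])
    converged = True
    try:
        sol = optimize.least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                     max_nfev=2000)
        rss = float((sol.fun**2).sum())
        if rss <= rss0:
            p = sol.x
        else:
            p, rss = p0, rss0
    except Exception:  # pragma: no cover - defensive
        p, rss = p0, rss0
        converged = False
    lin_names = [nm for nm in names if nm != "exp_amplitude"]
    coefs = dict(zip(lin_names, p[:len(lin_names)]))
    coefs["exp_amplitude"] = float(p[-2])
    coefs["exp_rate"] = float(p[-1])
    k_free = len(lin_names) + 2
    return TermFit(terms, coefs, rss, n, k_free, converged)


def forward_stepwise(data: PredictorSet, criterion: str = "bic") -> StepwiseResult:
    """Greedy forward selection over {ndi, odi, exp_distance} by BIC."""
    if criterion.lower() != "bic":
        raise ValueError("only BIC selection is supported")
    if data.n < 20:
        raise ValueError("need at least 20 observations")
    table = data.table
    y_all = table["delta_r2star"].to_numpy()
    ss_tot0 = float(((y_all - y_all.mean()) ** 2).sum())
    current = _fit_terms(table, ())
    path = [current.bic]
    step_log: list[dict] = []
    remaining = list(CANDIDATE_ORDER)
    while remaining:
        if current.rss <= 1e-20 * max(ss_tot0, 1.0):
            break  # already a numerically perfect fit
        trials = []
        for cand in remaining:
            try:
                fit = _fit_terms(table, current.terms + (cand,))
            except Exception as exc:  # candidate fit failed: skip this step
                log.warning("candidate %s failed: %s", cand, exc)
                continue
            trials.append((cand, fit))
        if not trials:
            break
        # largest BIC decrease; ties broken by candidate order (list order)
        best_cand, best_fit = min(trials, key=lambda t: t[1].bic)
        step_log.append({
            "candidates": {c: f.bic for c, f in trials},
            "chosen": best_cand if best_fit.bic < path[-1] else None,
        })
        if best_fit.bic >= path[-1] - 1e-12:
            break
        current = best_fit
        path.append(current.bic)
        remaining.remove(best_cand)
    y = table["delta_r2star"].to_numpy()
    yhat = current.predict(table)
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(y, yhat)[0])
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - current.rss / ss_tot if ss_tot > 0 else 1.0
    return StepwiseResult(
        selected_terms=current.terms,
        coefficients=current.coefficients,
        bic_path=path,
        step_log=step_log,
        r=r,
        r_squared=r2,
        final=current,
    )


def loobcv(data: PredictorSet, model: StepwiseResult) -> CVResult:
    """Leave-one-bundle-out CV of the selected model form."""
    bundles = data.bundles
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles for cross-validation")
    frames = []
    per_bundle_r = {}
    dropped = []
    for b in bundles:
        train = data.table[data.table["bundle"] != b]
        test = data.table[data.table["bundle"] == b]
        try:
            fit = _fit_terms(train, model.selected_terms)
        except Exception as exc:
            log.warning("fold %s failed to converge: %s", b, exc)
            dropped.append(b)
            continue
        pred = fit.predict(test)
        obs = test["delta_r2star"].to_numpy()
        frames.append(pd.DataFrame({"bundle": b, "node": test.get("node", np.arange(len(test))),
                                    "observed": obs, "predicted": pred}))
        if len(obs) > 2 and np.ptp(obs) > 0 and np.ptp(pred) > 0:
            per_bundle_r[b] = float(stats.pearsonr(obs, pred)[0])
        else:
            per_bundle_r[b] = np.nan
    preds = pd.concat(frames, ignore_index=True)
    o = preds["observed"].to_numpy()
    p = preds["predicted"].to_numpy()
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        pooled = 0.0
    else:
        pooled = float(stats.pearsonr(o, p)[0])
    return CVResult(pooled_r=pooled, per_bundle_r=per_bundle_r,
                    predictions=preds, dropped_folds=dropped)
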