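"""Degree-distribution model fitting and AIC selection.

Three candidate laws are fit to the *cumulative* (survival) degree
distribution by least squares on its logarithm, matching the log-log
presentation convention of the cumulative-fit toolchain this mirrors:

* power law:            log P(k) = c - alpha * log k
* exponential:          log P(k) = c - rate * k
* truncated power law:  log P(k) = c + (alpha - 1) * log k - k / kc

The truncated family nests both others (kc -> inf recovers the power
law up to reparameterization; alpha -> 1 recovers the exponential).
Model choice is by minimum AIC = n * ln(RSS/n) + 2 * n_params, with
ties broken toward fewer parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ModelFit",
    "cumulative_distribution",
    "fit_model",
    "fit_all_models",
    "select_model",
    "MODELS",
]

MODELS = ("power_law", "exponential", "truncated_power_law")
_N_PARAMS = {"power_law": 2, "exponential": 2, "truncated_power_law": 3}


@dataclass
class ModelFit:
    model: str
    parameters: dict[str, float] = field(default_factory=dict)
    rss: float = np.inf
    aic: float = np.inf
    n_points: int = 0
    converged: bool = True


def cumulative_distribution(degrees) -> tuple[np.ndarray, np.ndarray]:
    """Survival function P(K >= k) over the observed positive degrees.

    Zero-degree nodes are excluded.  Returns (k, P) with P strictly
    decreasing and P = 1 at the smallest observed degree.
    """
    d = np.asarray(degrees, dtype=np.int64)
    d = d[d >= 1]
    if d.size == 0:
        raise ValueError("no positive degrees")
    ks, counts = np.unique(d, return_counts=True)
    # P(K >= k): reverse cumulative counts
    surv = counts[::-1].cumsum()[::-1] / d.size
    return ks.astype(float), surv


def _aic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)  # guard: exact fits would give -inf
    return n * float(np.log(rss / n)) + 2 * n_params


def fit_model(cdd: tuple[np.ndarray, np.ndarray], model: str) -> ModelFit:
    """Least-squares fit of one model to the log survival function."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    k, p = cdd
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    n = k.size
    n_params = _N_PARAMS[model]
    if n < n_params + 2:
        raise ValueError(f"need at least {n_params + 2} distinct degrees, got {n}")
    logp = np.log(p)
    logk = np.log(k)

    if model == "power_law":
        # linear in (c, alpha)
        slope, intercept = np.polyfit(logk, logp, 1)
        resid = logp - (intercept + slope * logk)
        params = {"alpha": -slope, "c": intercept}
        rss = float(resid @ resid)
        return ModelFit(model, params, rss, _aic(rss, n, n_params), n)

    if model == "exponential":
        slope, intercept = np.polyfit(k, logp, 1)
        resid = logp - (intercept + slope * k)
        params = {"rate": -slope, "c": intercept}
        rss = float(resid @ resid)
        return ModelFit(model, params, rss, _aic(rss, n, n_params), n)

    # truncated power law: nonlinear in (c, alpha, kc)
    def f(kv, c, alpha, inv_kc):
        return c + (alpha - 1.0) * np.log(kv) - kv * inv_kc

    # warm starts from the two nested linear fits
    pl_slope, pl_int = np.polyfit(logk, logp, 1)
    ex_slope, ex_int = np.polyfit(k, logp, 1)
    starts = [
        (pl_int, pl_slope + 1.0, 1e-6),
        (ex_int, 1.0, max(-ex_slope, 1e-6)),
        (logp[0], 0.0, 1.0 / max(k.mean(), 1.0)),
    ]
    best: ModelFit | None = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    f, k, logp, p0=p0,
                    bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = logp - f(k, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best.rss:
            kc = 1.0 / popt[2] if popt[2] > 0 else np.inf
            best = ModelFit(
                "truncated_power_law",
                {"c": float(popt[0]), "alpha": float(popt[1]), "kc": float(kc)},
                rss,
                _aic(rss, n, n_params),
                n,
            )
    if best is None:
        warnings.warn("truncated power-law fit failed to converge", stacklevel=2)
        return ModelFit("truncated_power_law", {}, np.inf, np.inf, n, converged=False)
    return best


def fit_all_models(degrees) -> list[ModelFit]:
    """Fit all three candidate laws to one degree sequence."""
    cdd = cumulative_distribution(degrees)
    return [fit_model(cdd, m) for m in MODELS]


def select_model(fits: list[ModelFit]) -> ModelFit:
    """Minimum-AIC model among converged fits; ties favor fewer parameters."""
    valid = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid fits to select a model")
    return min(valid, key=lambda f: (f.aic, _N_PARAMS[f.model]))
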