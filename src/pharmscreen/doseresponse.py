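"""Four-parameter log-logistic (4PL) dose-response fitting and ICx inversion.

The model is

    y(d) = lower + (upper - lower) / (1 + (d / ec50)^(-hill))

with ``hill > 0`` giving a response that increases with dose and
``hill < 0`` a response that decreases with dose.  ``ec50`` is the dose of
half-maximal effect on the fitted scale.  Fitting is ordinary least squares
on the response scale with the dose handled on a log axis internally;
``d = 0`` points are supported and evaluate to the appropriate asymptote.

ICx values ("the concentration producing an absolute response level x") are
obtained by closed-form inversion of the fitted curve, and confidence
intervals by a case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FourPLFit",
    "fit_4pl",
    "inverse_concentration",
    "bootstrap_ci",
    "ic50_from_viability",
]

_SSE_RTOL = 1e-10
_MAX_NFEV = 10_000


@dataclass(frozen=True)
class FourPLFit:
    """A fitted four-parameter log-logistic curve.

    After fitting, parameters are canonicalized so ``lower <= upper``; the
    direction of the curve is carried entirely by the sign of ``hill``.
    """

    lower: float
    upper: float
    hill: float
    ec50: float
    sse: float = float("nan")
    converged: bool = True

    def predict(self, dose) -> np.ndarray | float:
        return predict_4pl(dose, self.lower, self.upper, self.hill, self.ec50)


def predict_4pl(dose, lower, upper, hill, ec50):
    """Evaluate the 4PL model; dose 0 maps to the limiting asymptote."""
    d = np.asarray(dose, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d < 0):
        raise ValueError("invalid concentration: doses must be >= 0")
    y = np.empty_like(d)
    pos = d > 0
    with np.errstate(over="ignore"):
        t = np.exp(-hill * (np.log(d[pos]) - np.log(ec50)))
    y[pos] = lower + (upper - lower) / (1.0 + t)
    # d -> 0 limit: hill > 0 => lower asymptote, hill < 0 => upper asymptote
    y[~pos] = lower if hill > 0 else upper
    return float(y[0]) if scalar else y


def _canonicalize(lower, upper, hill):
    if lower > upper:
        lower, upper, hill = upper, lower, -hill
    return lower, upper, hill


def _initial_log_ec50(doses, responses):
    """Dose (log) bracketing the half-range crossing of the responses."""
    order = np.argsort(doses)
    d, y = doses[order], responses[order]
    half = 0.5 * (y.min() + y.max())
    crossings = np.nonzero(np.diff(np.sign(y - half)) != 0)[0]
    pos = d[d > 0]
    if crossings.size:
        i = crossings[0]
        lo = d[i] if d[i] > 0 else pos.min()
        hi = d[i + 1]
        return 0.5 * (np.log(lo) + np.log(hi))
    return float(np.mean(np.log(pos)))


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    direction: str = "decreasing",
    fix_lower: float | None = None,
    fix_upper: float | None = None,
    x0: Sequence[float] | None = None,
) -> FourPLFit:
    """Least-squares 4PL fit with multi-start hill initialization.

    Parameters
    ----------
    doses, responses
        Paired observations; replicate points simply repeat a dose.
    direction
        ``"increasing"`` or ``"decreasing"`` response with dose; constrains
        the sign of the fitted hill slope.
    fix_lower, fix_upper
        Pin an asymptote instead of fitting it (used for conditional fits
        in the synergy surface).
    x0
        Optional warm-start ``(lower, upper, hill, log_ec50)`` (entries for
        pinned asymptotes are ignored); replaces the multi-start grid.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(d < 0):
        raise ValueError("invalid concentration: doses must be >= 0")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.unique(d[d > 0]).size < 4:
        raise ValueError("insufficient design: need >= 4 distinct nonzero doses")
    span = y.max() - y.min()
    if span <= 1e-9 * max(1.0, abs(y.max())):
        raise ValueError("degenerate: no dose dependence")

    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    hill_sign = 1.0 if direction == "increasing" else -1.0

    free_lower = fix_lower is None
    free_upper = fix_upper is None

    def unpack(theta):
        i = 0
        if free_lower:
            lower = theta[i]; i += 1
        else:
            lower = fix_lower
        if free_upper:
            upper = theta[i]; i += 1
        else:
            upper = fix_upper
        hill = theta[i]
        log_ec50 = theta[i + 1]
        return lower, upper, hill, log_ec50

    pos = d > 0
    logd = np.zeros_like(d)
    logd[pos] = np.log(d[pos])

    def residuals(theta):
        lower, upper, hill, log_ec50 = unpack(theta)
        with np.errstate(over="ignore"):
            t = np.exp(-hill * (logd[pos] - log_ec50))
        pred = np.empty_like(y)
        pred[pos] = lower + (upper - lower) / (1.0 + t)
        pred[~pos] = lower if hill > 0 else upper
        return pred - y

    lo_init = y.min() if free_lower else fix_lower
    hi_init = y.max() if free_upper else fix_upper
    log_e0 = _initial_log_ec50(d, y)

    if x0 is not None:
        l0, u0, h0, le0 = x0
        starts = [(l0 if free_lower else None, u0 if free_upper else None, h0, le0)]
    else:
        starts = [
            (lo_init if free_lower else None, hi_init if free_upper else None,
             hill_sign * h, log_e0)
            for h in (1.0, 2.0)
        ]

    # hill sign constrained by direction; asymptotes unbounded
    n_asym = int(free_lower) + int(free_upper)
    lb = [-np.inf] * n_asym
    ub = [np.inf] * n_asym
    if hill_sign > 0:
        lb += [1e-6, -np.inf]
        ub += [np.inf, np.inf]
    else:
        lb += [-np.inf, -np.inf]
        ub += [-1e-6, np.inf]

    best = None
    for start in starts:
        theta0 = [v for v in start if v is not None]
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lb, ub),
                ftol=_SSE_RTOL, xtol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        hill = unpack(sol.x)[2]
        key = (sse, abs(hill))  # tie-break: smallest |hill|
        if best is None or key < best[0]:
            best = (key, sol, sse)

    if best is None:
        raise ValueError("degenerate: optimizer failed from all starts")

    _, sol, sse = best
    lower, upper, hill, log_ec50 = unpack(sol.x)
    lower, upper, hill = _canonicalize(lower, upper, hill)
    converged = bool(sol.status > 0)
    return FourPLFit(
        lower=float(lower), upper=float(upper), hill=float(hill),
        ec50=float(np.exp(log_ec50)), sse=sse, converged=converged,
    )


def inverse_concentration(fit: FourPLFit, effect_level: float) -> float:
    """Dose at which the fitted curve attains ``effect_level`` (absolute scale).

    Closed form: with ``f = (effect - lower)/(upper - lower)``,
    ``d = ec50 * (f/(1-f))^(1/hill)``.
    """
    lo, hi = fit.lower, fit.upper
    if not (lo < effect_level < hi):
        raise ValueError(
            f"unreachable effect level: {effect_level} not in ({lo}, {hi})"
        )
    f = (effect_level - lo) / (hi - lo)
    return float(fit.ec50 * (f / (1.0 - f)) ** (1.0 / fit.hill))


def bootstrap_ci(
    doses: Sequence[float],
    responses: Sequence[float],
    statistic: Callable[[FourPLFit], float],
    n_boot: int = 1000,
    seed: int | None = None,
    direction: str = "decreasing",
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a statistic of the refitted curve.

    Cases (dose, response points) are resampled with replacement; each
    resample is refit warm-started at the full-data solution.  Raises if
    more than half of the bootstrap refits fail.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    full = fit_4pl(d, y, direction=direction)
    warm = (full.lower, full.upper, full.hill, np.log(full.ec50))
    rng = np.random.default_rng(seed)
    n = d.size
    stats, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_4pl(d[idx], y[idx], direction=direction, x0=warm)
            stats.append(statistic(fit))
        except Exception:
            failures += 1
    if failures > n_boot / 2:
        raise ValueError("unstable fit: majority of bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ic50_from_viability(
    raw_signal: Sequence[float],
    vehicle_controls: Sequence[float],
    doses: Sequence[float],
) -> tuple[FourPLFit, float]:
    """Normalize raw viability signal to vehicle and extract an absolute IC50.

    Responses become fractions of the mean vehicle signal; a decreasing 4PL
    is fit and inverted at the 0.5 absolute level (half of the untreated
    signal), the convention of plate-reader IC50 rescreens.
    """
    vehicle = np.asarray(vehicle_controls, dtype=float)
    mean_vehicle = vehicle.mean()
    if mean_vehicle <= 0:
        raise ValueError("invalid control: mean vehicle signal <= 0")
    frac = np.asarray(raw_signal, dtype=float) / mean_vehicle
    fit = fit_4pl(doses, frac, direction="decreasing")
    ic50 = inverse_concentration(fit, 0.5)
    return fit, ic50
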