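"""Non-compartmental pharmacokinetic summaries.

AUC by the trapezoidal rule (linear by default, linear-up/log-down by
flag), terminal half-life from a log-linear regression on the last
``n_terminal`` samples, and the time-averaged concentration
``Cavg = AUC / interval`` with a threshold check used for exposure-matched
dosing design (e.g. keeping Cavg above 100 ug/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NCAResult",
    "auc_trapezoid",
    "terminal_half_life",
    "cavg_check",
    "nca_summary",
]


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    auc_0_t: float
    lambda_z: float
    t_half: float
    c_avg: float
    meets_target: bool
    n_terminal_points: int


def _validate(times, concentrations):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concentrations must align")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return t, c


def auc_trapezoid(times, concentrations, method: str = "linear") -> float:
    """AUC from 0-ordered samples; ``method`` is 'linear' or 'linear-log'.

    'linear-log' applies the log-trapezoid on strictly declining positive
    segments and the linear rule elsewhere.
    """
    t, c = _validate(times, concentrations)
    if t.size < 2:
        raise ValueError("insufficient samples: need >= 2")
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linear-log":
        raise ValueError("method must be 'linear' or 'linear-log'")
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c0 > c1 > 0:
            auc += dt * (c0 - c1) / np.log(c0 / c1)
        else:
            auc += dt * (c0 + c1) / 2.0
    return float(auc)


def terminal_half_life(times, concentrations, n_terminal: int = 3) -> tuple[float, float]:
    """(lambda_z, t_half) from log-linear regression on the final points."""
    t, c = _validate(times, concentrations)
    if t.size < n_terminal:
        raise ValueError(f"insufficient samples: need >= {n_terminal}")
    tt, cc = t[-n_terminal:], c[-n_terminal:]
    if np.any(cc <= 0):
        raise ValueError("log-undefined sample: zero concentration in terminal window")
    slope = stats.linregress(tt, np.log(cc)).slope
    if slope >= 0:
        raise ValueError("no terminal decline")
    lambda_z = -float(slope)
    return lambda_z, float(np.log(2.0) / lambda_z)


def cavg_check(auc: float, interval_h: float, threshold: float = 100.0) -> tuple[float, bool]:
    """Time-averaged concentration and whether it meets the exposure target."""
    if interval_h <= 0:
        raise ValueError("interval must be positive")
    c_avg = auc / interval_h
    return float(c_avg), bool(c_avg >= threshold)


def nca_summary(
    profiles: pd.DataFrame,
    interval_h: float | None = None,
    threshold: float = 100.0,
    n_terminal: int = 3,
    method: str = "linear",
) -> list[NCAResult]:
    """Per-subject NCA from a long table (subject, time_h, conc_ugL)."""
    results = []
    for subject, sub in profiles.groupby("subject", sort=False):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(dtype=float)
        c = sub["conc_ugL"].to_numpy(dtype=float)
        auc = auc_trapezoid(t, c, method=method)
        lam, t_half = terminal_half_life(t, c, n_terminal=n_terminal)
        span = interval_h if interval_h is not None else (t[-1] - t[0])
        c_avg, meets = cavg_check(auc, span, threshold)
        results.append(NCAResult(
            subject_id=str(subject), auc_0_t=auc, lambda_z=lam,
            t_half=t_half, c_avg=c_avg, meets_target=meets,
            n_terminal_points=n_terminal,
        ))
    return results
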