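"""ZIP (zero interaction potency) synergy analysis of combination plates.

A checkerboard plate crosses two dose ladders (12 points each, 1:2
dilutions).  Raw signal is normalized to percent cell death against
inter-plate controls (vehicle = 0% death, maximum-kill combination = 100%
death); normalized values are deliberately *not* clipped to [0, 100] so
replicate noise stays honest for the downstream t-tests.

The ZIP independence expectation for two single-agent percent-death values
is ``E = y1 + y2 - y1*y2/100``.  The delta surface compares a curve-fitted
combination response against that expectation: monotherapies are fit with
4PL curves, then each grid row (and, symmetrically, each column) is refit
conditionally with its lower asymptote pinned to the other drug's fitted
single-agent effect, and the two conditional predictions are averaged.

Synergy/antagonism calls extract the extreme delta dose pairs and test the
per-replicate log2 fold change of observed death over the ZIP expectation
with a one-sample t-test; default thresholds are |log2 FC| >= 1.5 and
P <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .doseresponse import FourPLFit, fit_4pl

__all__ = [
    "CombinationPlate",
    "DeathMatrix",
    "SynergySurface",
    "CombinationCall",
    "normalize_plate",
    "zip_expectation",
    "zip_delta_surface",
    "call_combination",
]


@dataclass
class CombinationPlate:
    """Raw combination plate: replicate 12x12 signal grids plus controls.

    ``raw[r, i, j]`` is the signal with drug1 at ``doses1[i]`` and drug2 at
    ``doses2[j]``.  ``raw_mono1``/``raw_mono2`` are dedicated single-agent
    wells (replicates x 12); when absent, monotherapy is taken from the
    stored grids' single-agent rows if the caller provides them that way.
    """

    drug1_id: str
    drug2_id: str
    doses1: np.ndarray
    doses2: np.ndarray
    raw: np.ndarray
    vehicle_signals: np.ndarray
    maxkill_signals: np.ndarray
    raw_mono1: np.ndarray | None = None
    raw_mono2: np.ndarray | None = None
    cell_line_id: str = ""

    def __post_init__(self):
        self.doses1 = np.asarray(self.doses1, dtype=float)
        self.doses2 = np.asarray(self.doses2, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 3:
            raise ValueError("raw must be (replicates, n1, n2)")
        for d in (self.doses1, self.doses2):
            if np.any(d <= 0) or np.any(np.diff(d) >= 0):
                raise ValueError("dose ladders must be positive and strictly decreasing")
        if len(self.vehicle_signals) < 2 or len(self.maxkill_signals) < 2:
            raise ValueError("need >= 2 control wells of each kind")


@dataclass
class DeathMatrix:
    """Percent-cell-death grids per replicate, plus monotherapy vectors."""

    percent_death: np.ndarray  # (replicates, n1, n2)
    doses1: np.ndarray
    doses2: np.ndarray
    mono1: np.ndarray | None = None  # (replicates, n1)
    mono2: np.ndarray | None = None  # (replicates, n2)


@dataclass
class SynergySurface:
    delta: np.ndarray  # (n1, n2)
    delta_max: float
    delta_min: float
    argmax_pair: tuple[float, float]
    argmin_pair: tuple[float, float]
    fit1: FourPLFit | None = None
    fit2: FourPLFit | None = None
    fitted_combination: np.ndarray | None = None
    fallback_rows: list = field(default_factory=list)
    fallback_cols: list = field(default_factory=list)


@dataclass
class CombinationCall:
    log2_fc_at_max: float
    log2_fc_at_min: float
    p_max: float
    p_min: float
    classification: str  # synergy | antagonism | none
    max_pair: tuple[float, float] = (float("nan"), float("nan"))
    min_pair: tuple[float, float] = (float("nan"), float("nan"))
    skipped_pairs: int = 0


def normalize_plate(plate: CombinationPlate) -> DeathMatrix:
    """Map raw signal to percent cell death using inter-plate controls.

    ``percent_death = 100 * (mean_vehicle - x) / (mean_vehicle - mean_maxkill)``
    applied per well per replicate, without clipping.
    """
    v = float(np.mean(plate.vehicle_signals))
    m = float(np.mean(plate.maxkill_signals))
    if v <= m:
        raise ValueError("invalid controls: vehicle mean must exceed max-kill mean")
    to_death = lambda x: 100.0 * (v - x) / (v - m)
    return DeathMatrix(
        percent_death=to_death(plate.raw),
        doses1=plate.doses1,
        doses2=plate.doses2,
        mono1=None if plate.raw_mono1 is None else to_death(np.asarray(plate.raw_mono1, float)),
        mono2=None if plate.raw_mono2 is None else to_death(np.asarray(plate.raw_mono2, float)),
    )


def zip_expectation(y1, y2):
    """ZIP independence expectation for percent-death inputs.

    Inputs are clamped to [0, 100] internally; stored matrices are never
    modified.
    """
    a = np.clip(np.asarray(y1, dtype=float), 0.0, 100.0)
    b = np.clip(np.asarray(y2, dtype=float), 0.0, 100.0)
    out = a + b - a * b / 100.0
    return float(out) if out.ndim == 0 else out


def _fit_mono(doses, response):
    return fit_4pl(doses, response, direction="increasing")


def zip_delta_surface(death: DeathMatrix, mode: str = "zip") -> SynergySurface:
    """Delta-ZIP surface from replicate-averaged percent-death grids.

    ``mode="zip"`` uses the two-directional conditional-fit scheme
    (reference behavior); ``mode="naive"`` scores observed minus
    expectation directly without conditional smoothing.
    """
    if death.mono1 is None or death.mono2 is None:
        raise ValueError("monotherapy responses required for both drugs")
    grid = death.percent_death.mean(axis=0)  # (n1, n2)
    mono1 = np.asarray(death.mono1, float).mean(axis=0)
    mono2 = np.asarray(death.mono2, float).mean(axis=0)
    d1, d2 = death.doses1, death.doses2
    n1, n2 = grid.shape

    try:
        fit1 = _fit_mono(d1, mono1)
    except ValueError:
        fit1 = None
    try:
        fit2 = _fit_mono(d2, mono2)
    except ValueError:
        fit2 = None
    if fit1 is None and fit2 is None:
        raise ValueError("no monotherapy signal: both monotherapy fits degenerate")

    y1 = fit1.predict(d1) if fit1 is not None else mono1
    y2 = fit2.predict(d2) if fit2 is not None else mono2
    expect = zip_expectation(y1[:, None], y2[None, :])

    fallback_rows, fallback_cols = [], []
    if mode == "naive":
        fitted = grid.copy()
    elif mode == "zip":
        # conditional fits: response in drug1 dose at each fixed drug2 dose,
        # lower asymptote pinned to drug2's fitted single-agent effect
        row_pred = np.empty((n1, n2))
        for j in range(n2):
            base = float(np.clip(y2[j], 0.0, 100.0))
            try:
                cfit = fit_4pl(d1, grid[:, j], direction="increasing",
                               fix_lower=base)
                row_pred[:, j] = cfit.predict(d1)
            except ValueError:
                row_pred[:, j] = grid[:, j]
                fallback_cols.append(j)
        col_pred = np.empty((n1, n2))
        for i in range(n1):
            base = float(np.clip(y1[i], 0.0, 100.0))
            try:
                cfit = fit_4pl(d2, grid[i, :], direction="increasing",
                               fix_lower=base)
                col_pred[i, :] = cfit.predict(d2)
            except ValueError:
                col_pred[i, :] = grid[i, :]
                fallback_rows.append(i)
        fitted = 0.5 * (row_pred + col_pred)
    else:
        raise ValueError("mode must be 'zip' or 'naive'")

    delta = fitted - expect
    imax = np.unravel_index(int(np.argmax(delta)), delta.shape)
    imin = np.unravel_index(int(np.argmin(delta)), delta.shape)
    return SynergySurface(
        delta=delta,
        delta_max=float(delta[imax]),
        delta_min=float(delta[imin]),
        argmax_pair=(float(d1[imax[0]]), float(d2[imax[1]])),
        argmin_pair=(float(d1[imin[0]]), float(d2[imin[1]])),
        fit1=fit1,
        fit2=fit2,
        fitted_combination=fitted,
        fallback_rows=fallback_rows,
        fallback_cols=fallback_cols,
    )


def _extremum_fc(death: DeathMatrix, surface: SynergySurface, order):
    """Per-replicate log2 FC and p at the first usable extremum pair.

    ``order`` ranks candidate grid cells (best extremum first); a pair is
    skipped when its ZIP expectation or any replicate's observed death is
    non-positive (log2 undefined there).
    """
    d1, d2 = death.doses1, death.doses2
    y1 = surface.fit1.predict(d1) if surface.fit1 is not None else np.asarray(death.mono1, float).mean(axis=0)
    y2 = surface.fit2.predict(d2) if surface.fit2 is not None else np.asarray(death.mono2, float).mean(axis=0)
    skipped = 0
    for flat in order:
        i, j = np.unravel_index(int(flat), surface.delta.shape)
        expectation = zip_expectation(float(y1[i]), float(y2[j]))
        obs = death.percent_death[:, i, j]
        if expectation <= 0 or np.any(obs <= 0):
            skipped += 1
            continue
        log2_fc = np.log2(obs / expectation)
        if np.allclose(log2_fc, log2_fc[0]):
            p = 1.0 if abs(log2_fc.mean()) < 1e-12 else 0.0
        else:
            _, p = stats.ttest_1samp(log2_fc, 0.0)
        return float(log2_fc.mean()), float(p), (float(d1[i]), float(d2[j])), skipped
    return float("nan"), float("nan"), (float("nan"), float("nan")), skipped


def call_combination(
    death: DeathMatrix,
    surface: SynergySurface,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    fc_scale: str = "log2",
) -> CombinationCall:
    """Classify a combination at its extreme-delta dose pairs.

    One-sample two-sided t-test of per-replicate log2(observed/expected)
    against zero at the max- and min-delta pairs; classification requires
    both the fold-change and p-value thresholds.  ``fc_scale="linear"``
    interprets ``fc_threshold`` as a plain fold change instead of a log2
    one.
    """
    if death.percent_death.shape[0] < 2:
        raise ValueError("need >= 2 replicates for the one-sample t-test")
    flat = surface.delta.ravel()
    fc_max, p_max, max_pair, skip1 = _extremum_fc(death, surface, np.argsort(-flat))
    fc_min, p_min, min_pair, skip2 = _extremum_fc(death, surface, np.argsort(flat))

    thr = fc_threshold if fc_scale == "log2" else np.log2(fc_threshold)
    classification = "none"
    if np.isfinite(fc_max) and fc_max >= thr and p_max <= p_threshold:
        classification = "synergy"
    elif np.isfinite(fc_min) and fc_min <= -thr and p_min <= p_threshold:
        classification = "antagonism"
    return CombinationCall(
        log2_fc_at_max=fc_max,
        log2_fc_at_min=fc_min,
        p_max=p_max,
        p_min=p_min,
        classification=classification,
        max_pair=max_pair,
        min_pair=min_pair,
        skipped_pairs=skip1 + skip2,
    )
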