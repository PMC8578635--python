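"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the study's data modalities — GDSC/PRISM
style IC50 screening tables, 12x12 checkerboard combination plates,
expression/genotype cohorts with a mediation chain, replicated
decatenation assays, and one-compartment PK profiles — with configurable
effect sizes, noise, missingness and seeds.  Defaults are anchored to the
study conditions: a 1,001-line x 265-drug screen with a 31/1001 target
lineage fraction, genotype effects of x17.45 (TP53 mutant, resistance) and
x10.9 (MYCN amplified, sensitization) on IC50, plate ladders topping out
at the printed concentrations, decatenation doses spanning 1.734-400 uM
over 5 runs, and a mouse-like terminal half-life of 3.7 h.

Every generator returns its ground truth next to the data, and identical
seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import predict_4pl
from .synergy import CombinationPlate, zip_expectation

__all__ = [
    "ScreenSimConfig",
    "PlateSimConfig",
    "ChainSimConfig",
    "DecatSimConfig",
    "PKSimConfig",
    "simulate_screen",
    "simulate_combination_plate",
    "simulate_expression_chain",
    "simulate_decatenation",
    "simulate_pk",
]

TARGET_LINEAGE = "neuroblastoma"


# ---------------------------------------------------------------------------
# drug screen


@dataclass
class ScreenSimConfig:
    n_lines: int = 1001
    n_drugs: int = 265
    target_fraction: float = 31 / 1001
    base_mu: float = 0.5          # log10 IC50 (uM)
    base_sigma: float = 0.6
    selective_shift: dict = field(default_factory=dict)  # drug -> log10 shift in target lineage
    tp53_effect: float = float(np.log10(17.45))   # resistance in mutants
    mycn_effect: float = -float(np.log10(10.9))   # sensitization when amplified
    p_mycn_amp: float = 0.4       # within target lineage
    p_tp53_mut: float = 0.3
    genotype_effects_target_only: bool = True
    missingness: float = 0.0
    seed: int = 0


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Long-format screen table + annotations + ground truth."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_lines, config.n_drugs
    lines = [f"CL{i:04d}" for i in range(n)]
    drugs = [f"drug{j:03d}" for j in range(m)]
    for _ in range(100):
        is_target = rng.random(n) < config.target_fraction
        if is_target.sum() >= 1:
            break
    else:
        raise RuntimeError("could not sample a non-empty target lineage")
    lineages = np.where(is_target, TARGET_LINEAGE, "other")
    mycn = np.where(is_target, rng.random(n) < config.p_mycn_amp, rng.random(n) < 0.05)
    tp53 = np.where(is_target, rng.random(n) < config.p_tp53_mut,
                    rng.random(n) < 0.5)

    base = rng.normal(config.base_mu, config.base_sigma, size=(n, m))
    log10_ic50 = base.copy()
    geno_mask = is_target if config.genotype_effects_target_only else np.ones(n, bool)
    log10_ic50[mycn & geno_mask] += config.mycn_effect
    log10_ic50[tp53 & geno_mask] += config.tp53_effect
    for j, drug in enumerate(drugs):
        shift = config.selective_shift.get(drug, 0.0)
        if shift:
            log10_ic50[is_target, j] += shift

    keep = rng.random((n, m)) >= config.missingness
    rows = np.repeat(np.arange(n), m)[keep.ravel()]
    cols = np.tile(np.arange(m), n)[keep.ravel()]
    table = pd.DataFrame({
        "cell_line": np.asarray(lines)[rows],
        "drug": np.asarray(drugs)[cols],
        "ic50_uM": 10.0 ** log10_ic50[rows, cols],
    })
    annotations = pd.DataFrame({
        "cell_line": lines,
        "lineage": lineages,
        "mycn_amplified": mycn,
        "tp53_mutant": tp53,
    })
    truth = {
        "selective_shift": dict(config.selective_shift),
        "tp53_effect_log10": config.tp53_effect,
        "mycn_effect_log10": config.mycn_effect,
        "n_target": int(is_target.sum()),
        "seed": config.seed,
    }
    return table, annotations, truth


# ---------------------------------------------------------------------------
# combination plates

# printed top concentrations (uM) of the study's four compounds
TOP_CONCENTRATIONS = {
    "SN-38": 0.3114,
    "CX-5461": 1.89,
    "AZD6738": 19.93,
    "AZD1390": 87.19,
}


def _ladder(top: float, n: int = 12) -> np.ndarray:
    return top / 2.0 ** np.arange(n)


@dataclass
class PlateSimConfig:
    drug1_id: str = "CX-5461"
    drug2_id: str = "AZD6738"
    top1: float | None = None      # default: printed top concentration
    top2: float | None = None
    n_doses: int = 12
    # monotherapy truth: (lower, upper, hill, ec50); ec50 None -> ladder midpoint
    mono1: tuple = (0.0, 95.0, 1.2, None)
    mono2: tuple = (0.0, 90.0, 1.0, None)
    delta_spec: tuple = ("zero",)  # ("zero",) | ("block", rows, cols, eps) | ("bump", i0, j0, width, eps)
    noise_sd: float = 2.0          # percent-death points
    replicates: int = 4
    vehicle_mean: float = 10_000.0
    maxkill_mean: float = 500.0
    control_wells: int = 8
    control_noise_sd: float = 50.0
    cell_line_id: str = "CHP-134"
    seed: int = 0


def _true_delta(spec, n1, n2):
    delta = np.zeros((n1, n2))
    kind = spec[0]
    if kind == "zero":
        pass
    elif kind == "block":
        rows, cols, eps = spec[1], spec[2], spec[3]
        delta[np.ix_(list(rows), list(cols))] = eps
    elif kind == "bump":
        i0, j0, width, eps = spec[1], spec[2], spec[3], spec[4]
        ii, jj = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
        delta = eps * np.exp(-((ii - i0) ** 2 + (jj - j0) ** 2) / (2.0 * width**2))
    else:
        raise ValueError(f"unknown delta_spec kind: {kind}")
    return delta


def simulate_combination_plate(config: PlateSimConfig) -> tuple[CombinationPlate, dict]:
    """Raw-signal checkerboard plate with a known interaction surface.

    True combined death is the ZIP expectation of the two monotherapy
    truths plus the configured delta; raw signal inverts the control
    normalization and adds Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    top1 = config.top1 if config.top1 is not None else TOP_CONCENTRATIONS[config.drug1_id]
    top2 = config.top2 if config.top2 is not None else TOP_CONCENTRATIONS[config.drug2_id]
    d1 = _ladder(top1, config.n_doses)
    d2 = _ladder(top2, config.n_doses)

    def mono_curve(params, doses, top):
        lo, hi, hill, ec50 = params
        ec50 = ec50 if ec50 is not None else top / 16.0
        return predict_4pl(doses, lo, hi, hill, ec50), (lo, hi, hill, ec50)

    y1, p1 = mono_curve(config.mono1, d1, top1)
    y2, p2 = mono_curve(config.mono2, d2, top2)
    delta = _true_delta(config.delta_spec, config.n_doses, config.n_doses)
    true_death = zip_expectation(y1[:, None], y2[None, :]) + delta

    v, m = config.vehicle_mean, config.maxkill_mean
    death_to_signal = lambda death: v - death / 100.0 * (v - m)
    sig_sd = config.noise_sd / 100.0 * (v - m)

    raw = death_to_signal(true_death)[None, :, :] + rng.normal(
        0.0, sig_sd, size=(config.replicates, config.n_doses, config.n_doses))
    raw_mono1 = death_to_signal(y1)[None, :] + rng.normal(
        0.0, sig_sd, size=(config.replicates, config.n_doses))
    raw_mono2 = death_to_signal(y2)[None, :] + rng.normal(
        0.0, sig_sd, size=(config.replicates, config.n_doses))
    vehicle = rng.normal(v, config.control_noise_sd, size=config.control_wells)
    maxkill = rng.normal(m, config.control_noise_sd, size=config.control_wells)

    plate = CombinationPlate(
        drug1_id=config.drug1_id, drug2_id=config.drug2_id,
        doses1=d1, doses2=d2, raw=raw,
        vehicle_signals=vehicle, maxkill_signals=maxkill,
        raw_mono1=raw_mono1, raw_mono2=raw_mono2,
        cell_line_id=config.cell_line_id,
    )
    truth = {
        "mono1": p1, "mono2": p2, "delta": delta,
        "true_death": true_death, "seed": config.seed,
    }
    return plate, truth


# ---------------------------------------------------------------------------
# expression / mediation / feature chain


@dataclass
class ChainSimConfig:
    n_samples: int = 29            # cell-line mode; 88 for tumor mode
    a: float = 0.8                 # exposure -> mediator
    b: float = -0.7                # mediator -> outcome (sensitization)
    c: float = 0.0                 # direct exposure -> outcome (0 = full mediation)
    mediator_noise_sd: float = 0.6
    outcome_noise_sd: float = 0.5
    exposure_gene: str = "MYCN"
    mediator_gene: str = "TOP2B"
    housekeeping_tpm: tuple = (1000.0, 1000.0)
    mediator_base_log2: float = 7.0
    exposure_base_log2: float = 8.0
    n_features: int = 38
    n_true_features: int = 3
    feature_effect: float = 0.5    # standardized effect of each true feature on the mediator
    feature_corr: float = 0.3      # pairwise correlation among noise features
    n_noise_genes: int = 50
    seed: int = 0


def simulate_expression_chain(
    config: ChainSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Expression table, sensitivity vector, feature matrix and truth.

    The mediation chain is ``exposure -> mediator -> outcome`` on latent
    log2 scales; the feature matrix plants ``n_true_features`` genuine
    predictors of mediator expression among correlated noise features.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(n)]

    # correlated feature block (equicorrelated via a shared latent factor)
    shared = rng.normal(size=(n, 1))
    rho = config.feature_corr
    features = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(
        size=(n, config.n_features))
    true_idx = np.arange(config.n_true_features)
    feature_names = [f"feat{j:02d}" for j in range(config.n_features)]

    exposure = rng.normal(size=n)
    mediator = (
        config.a * exposure
        + features[:, true_idx] @ np.full(config.n_true_features, config.feature_effect)
        + rng.normal(0.0, config.mediator_noise_sd, size=n)
    )
    outcome = (
        config.b * mediator + config.c * exposure
        + rng.normal(0.0, config.outcome_noise_sd, size=n)
    )

    expr_log2 = {
        config.exposure_gene: config.exposure_base_log2 + exposure,
        config.mediator_gene: config.mediator_base_log2 + mediator,
    }
    for g in range(config.n_noise_genes):
        expr_log2[f"gene{g:03d}"] = rng.normal(5.0, 1.0, size=n)
    expr = pd.DataFrame(
        {k: 2.0**v - 1.0 for k, v in expr_log2.items()}, index=samples
    ).T.clip(lower=0.0)
    for hk, level in zip(("ACTB", "GAPDH"), config.housekeeping_tpm):
        expr.loc[hk] = level

    sensitivity = pd.Series(outcome, index=samples, name="log10_ic50")
    feature_df = pd.DataFrame(features, index=samples, columns=feature_names)
    truth = {
        "a": config.a, "b": config.b, "c": config.c,
        "true_features": [feature_names[j] for j in true_idx],
        "feature_effect": config.feature_effect,
        "seed": config.seed,
    }
    return expr, sensitivity, feature_df, truth


# ---------------------------------------------------------------------------
# decatenation assays


@dataclass
class DecatSimConfig:
    ic25_a: float = 30.0           # uM, TOP2A
    ic25_b: float = 10.0           # uM, TOP2B (3-fold preference default)
    hill: float = 1.0
    noise_sd: float = 5.0          # percent-decatenation points
    n_runs: int = 5
    dose_min: float = 1.734
    dose_max: float = 400.0
    n_doses: int = 9
    seed: int = 0


def simulate_decatenation(config: DecatSimConfig):
    """Replicated two-enzyme decatenation runs from decreasing 4PL truths.

    The true curve has asymptotes 100 -> 0 with the configured hill; the
    true IC25 fixes the EC50 through the closed-form inversion.
    """
    from .paralog import DecatenationRun

    rng = np.random.default_rng(config.seed)
    doses = np.geomspace(config.dose_min, config.dose_max, config.n_doses)
    runs = []
    ec50 = {
        "TOP2A": config.ic25_a * 3.0 ** (1.0 / config.hill),
        "TOP2B": config.ic25_b * 3.0 ** (1.0 / config.hill),
    }
    for r in range(config.n_runs):
        percent = {}
        for enzyme in ("TOP2A", "TOP2B"):
            mu = predict_4pl(doses, 0.0, 100.0, -config.hill, ec50[enzyme])
            percent[enzyme] = mu + rng.normal(0.0, config.noise_sd, size=doses.size)
        runs.append(DecatenationRun(run_id=r + 1, doses=doses, percent=percent))
    truth = {
        "ic25_a": config.ic25_a, "ic25_b": config.ic25_b,
        "fold_preference": config.ic25_a / config.ic25_b,
        "ec50": ec50, "seed": config.seed,
    }
    return runs, truth


# ---------------------------------------------------------------------------
# pharmacokinetics


@dataclass
class PKSimConfig:
    dose_mgkg: float = 5.0
    volume_L_per_kg: float = 2.0
    k_elim: float = float(np.log(2.0) / 3.7)   # 1/h; mouse-like t1/2 3.7 h
    times_h: tuple = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
    noise_cv: float = 0.1
    n_subjects: int = 3
    route: str = "IV"
    seed: int = 0


def simulate_pk(config: PKSimConfig) -> tuple[pd.DataFrame, dict]:
    """One-compartment profiles with multiplicative lognormal noise (ug/L)."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times_h, dtype=float)
    c0 = config.dose_mgkg / config.volume_L_per_kg * 1000.0  # mg/L -> ug/L
    rows = []
    for s in range(config.n_subjects):
        mu = c0 * np.exp(-config.k_elim * t)
        if config.noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + config.noise_cv**2))
            conc = mu * rng.lognormal(-sigma**2 / 2.0, sigma, size=t.size)
        else:
            conc = mu
        for ti, ci in zip(t, conc):
            rows.append({
                "subject": f"M{s + 1}", "time_h": ti, "conc_ugL": ci,
                "dose_mgkg": config.dose_mgkg, "route": config.route,
            })
    profiles = pd.DataFrame(rows)
    truth = {
        "k_elim": config.k_elim,
        "t_half": float(np.log(2.0) / config.k_elim),
        "c0_ugL": c0, "seed": config.seed,
    }
    return profiles, truth
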