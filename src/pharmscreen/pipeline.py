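"""End-to-end orchestration: run configured stages, collect a RunReport.

The configuration is a plain YAML mapping with one optional section per
stage; each section names its input files (the CSV schemas of ``io``) and
stage parameters.  Stages run in dependency order; a failed stage is
recorded and does not abort the remaining independent stages, but the
process exit code reflects any failure.  All randomness comes from the
per-stage seeds in the config, so an identical config reproduces an
identical report (timestamps excluded by design: none are recorded).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__, genomics, io, pk, selectivity
from .doseresponse import bootstrap_ci, fit_4pl, inverse_concentration
from .paralog import simulation_test
from .synergy import call_combination, normalize_plate, zip_delta_surface

STAGE_ORDER = ["selectivity", "dose_response", "synergy", "assoc", "mediation",
               "enet", "paralog", "pk"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def _require_files(section: dict, keys) -> None:
    for key in keys:
        p = section.get(key)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing input path for '{key}': {p}")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute configured stages; return the RunReport dict."""
    report = {"version": __version__, "config": config, "stages": {}, "warnings": []}
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # validate all referenced inputs before computing anything
    validators = {
        "selectivity": ("screen", "annotations"),
        "dose_response": ("in",),
        "synergy": ("controls",),
        "assoc": ("expression", "sensitivity"),
        "mediation": ("expression", "sensitivity"),
        "enet": ("features", "expression"),
        "paralog": ("in",),
        "pk": ("in",),
    }
    for stage in STAGE_ORDER:
        if stage in config:
            _require_files(config[stage], validators[stage])
            if stage == "synergy":
                for p in config[stage].get("plates", []):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"missing plate CSV: {p}")

    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        section = config[stage]
        entry = {"status": "ok"}
        try:
            entry["outputs"] = _RUNNERS[stage](section, report["warnings"])
        except Exception as exc:  # recorded, not raised
            entry = {"status": "failed", "error": str(exc)}
        report["stages"][stage] = entry

    report["ok"] = all(s["status"] == "ok" for s in report["stages"].values())
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        with open(out_dir / "report.txt", "w") as fh:
            for stage, entry in report["stages"].items():
                fh.write(f"{stage}: {entry['status']}\n")
            for w in report["warnings"]:
                fh.write(f"warning: {w}\n")
    return _jsonable(report)


def _run_selectivity(section, warnings):
    table = selectivity.read_screen_csv(section["screen"])
    ann = selectivity.read_annotations_csv(section["annotations"])
    subgroup = None
    if section.get("subgroup") == "mycn_amp_tp53_wt":
        subgroup = lambda row: bool(row["mycn_amplified"]) and not bool(row["tp53_mutant"])
    results, skipped = selectivity.rank_drugs(
        table, ann, section.get("target_lineage", "neuroblastoma"),
        subgroup_filter=subgroup, min_target=section.get("min_target", 3),
    )
    if skipped:
        warnings.append(f"selectivity: skipped {len(skipped)} drugs below min_target")
    return {"n_ranked": len(results), "skipped": skipped,
            "top": [dataclasses.asdict(r) for r in results[:10]]}


def _run_dose_response(section, warnings):
    df = io.read_dr_csv(section["in"])
    direction = {"dec": "decreasing", "inc": "increasing"}.get(
        section.get("direction", "dec"), section.get("direction", "decreasing"))
    fit = fit_4pl(df["dose_uM"], df["response"], direction=direction)
    out = {"fit": dataclasses.asdict(fit), "icx": {}}
    for level in section.get("icx", [50]):
        eff = fit.lower + float(level) / 100.0 * (fit.upper - fit.lower)
        conc = inverse_concentration(fit, eff)
        ci = bootstrap_ci(
            df["dose_uM"], df["response"],
            statistic=lambda f, e=eff: inverse_concentration(f, e),
            n_boot=section.get("boot", 1000), seed=section.get("seed", 0),
            direction=direction,
        )
        out["icx"][str(level)] = {"concentration": conc, "ci": ci}
    if not fit.converged:
        warnings.append("dose_response: fit did not converge")
    return out


def _run_synergy(section, warnings):
    plate = io.read_plate_csvs(
        section["plates"], section["controls"],
        mono1_path=section.get("mono1"), mono2_path=section.get("mono2"),
    )
    death = normalize_plate(plate)
    surface = zip_delta_surface(death, mode=section.get("mode", "zip"))
    call = call_combination(
        death, surface,
        fc_threshold=section.get("fc_threshold", 1.5),
        p_threshold=section.get("p_threshold", 0.01),
    )
    if surface.fallback_rows or surface.fallback_cols:
        warnings.append("synergy: conditional fit fell back to observed values")
    return {"delta_max": surface.delta_max, "delta_min": surface.delta_min,
            "argmax_pair": surface.argmax_pair, "argmin_pair": surface.argmin_pair,
            "call": dataclasses.asdict(call), "delta": surface.delta}


def _run_assoc(section, warnings):
    expr = io.read_expression_csv(section["expression"])
    sens = io.read_expression_csv(section["sensitivity"]).iloc[:, 0]
    scan = genomics.expression_sensitivity_scan(expr, 1.0 / sens if section.get(
        "reciprocal", True) else sens)
    return {"n_genes": int(scan.shape[0]),
            "top": scan.sort_values("p_value").head(10).to_dict("index")}


def _run_mediation(section, warnings):
    expr = io.read_expression_csv(section["expression"])
    sens = io.read_expression_csv(section["sensitivity"]).iloc[:, 0]
    exposure = np.log2(expr.loc[section.get("exposure", "MYCN")] + 1.0)
    mediator = np.log2(expr.loc[section.get("mediator", "TOP2B")] + 1.0)
    res = genomics.mediation(sens, exposure, mediator)
    return dataclasses.asdict(res)


def _run_enet(section, warnings):
    features = io.read_expression_csv(section["features"])
    expr = io.read_expression_csv(section["expression"])
    y = np.log2(expr.loc[section.get("gene", "TOP2B")] + 1.0)
    res = genomics.elasticnet_cv(
        features, y.loc[features.index],
        alpha=section.get("alpha", 0.5), k=section.get("folds", 10),
        seed=section.get("seed", 0),
    )
    if res.dropped:
        warnings.append(f"enet: dropped zero-variance features {res.dropped}")
    return {"selected": res.selected, "lambda": res.lambda_,
            "coefficients": res.coefficients[res.coefficients != 0].to_dict()}


def _run_paralog(section, warnings):
    runs = io.read_decat_csv(section["in"])
    est = simulation_test(
        runs, n_sim=section.get("nsim", 10_000), seed=section.get("seed", 0))
    if est.dropped_runs:
        warnings.append(f"paralog: dropped runs {est.dropped_runs}")
    return {"fold_preference": est.fold_preference, "ci": est.ci,
            "p_value": est.p_value, "n_sim": est.n_sim}


def _run_pk(section, warnings):
    profiles = io.read_pk_csv(section["in"])
    results = pk.nca_summary(
        profiles, interval_h=section.get("interval"),
        threshold=section.get("threshold", 100.0),
        n_terminal=section.get("n_terminal", 3),
    )
    return {"subjects": [dataclasses.asdict(r) for r in results],
            "mean_t_half": float(np.mean([r.t_half for r in results])),
            "mean_c_avg": float(np.mean([r.c_avg for r in results]))}


_RUNNERS = {
    "selectivity": _run_selectivity,
    "dose_response": _run_dose_response,
    "synergy": _run_synergy,
    "assoc": _run_assoc,
    "mediation": _run_mediation,
    "enet": _run_enet,
    "paralog": _run_paralog,
    "pk": _run_pk,
}
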