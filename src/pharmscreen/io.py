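"""CSV readers/writers for the pipeline's external interfaces.

All formats are plain UTF-8 comma-separated text with dot decimals:

- ``screen.csv``: ``cell_line,drug,ic50_uM``
- ``annotations.csv``: ``cell_line,lineage,mycn_amplified,tp53_mutant``
- ``dr.csv``: ``dose_uM,response,replicate``
- combination plates: one 13x13 CSV per replicate (first row/column are the
  dose ladders, top-left cell blank), ``controls.csv`` with
  ``kind,signal`` (kind in vehicle|maxkill), and single-agent wells in
  ``mono1.csv``/``mono2.csv`` with ``dose_uM,rep,signal``
- ``decat.csv``: ``run,enzyme,dose_uM,percent_decatenation``
- ``pk.csv``: ``subject,time_h,conc_ugL,dose_mgkg,route``
- ``expression.csv``: genes x samples, first column the gene id
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .paralog import DecatenationRun
from .synergy import CombinationPlate


def read_dr_csv(path):
    df = pd.read_csv(path)
    need = {"dose_uM", "response"}
    if not need.issubset(df.columns):
        raise ValueError("dr CSV must have columns dose_uM,response[,replicate]")
    return df


def write_plate_csvs(plate: CombinationPlate, out_dir) -> list[Path]:
    """Write one 13x13 grid CSV per replicate plus controls and mono wells."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(plate.raw.shape[0]):
        p = out_dir / f"rep{r + 1}.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + [f"{d:.10g}" for d in plate.doses2])
            for i, d1 in enumerate(plate.doses1):
                w.writerow([f"{d1:.10g}"] + [f"{v:.10g}" for v in plate.raw[r, i, :]])
        paths.append(p)
    with open(out_dir / "controls.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "signal"])
        for v in plate.vehicle_signals:
            w.writerow(["vehicle", f"{v:.10g}"])
        for v in plate.maxkill_signals:
            w.writerow(["maxkill", f"{v:.10g}"])
    for name, doses, mono in (
        ("mono1.csv", plate.doses1, plate.raw_mono1),
        ("mono2.csv", plate.doses2, plate.raw_mono2),
    ):
        if mono is None:
            continue
        with open(out_dir / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["dose_uM", "rep", "signal"])
            for r in range(mono.shape[0]):
                for d, v in zip(doses, mono[r]):
                    w.writerow([f"{d:.10g}", r + 1, f"{v:.10g}"])
    return paths


def _read_mono_csv(path, doses) -> np.ndarray:
    df = pd.read_csv(path)
    reps = sorted(df["rep"].unique())
    out = np.empty((len(reps), len(doses)))
    for k, r in enumerate(reps):
        sub = df[df["rep"] == r].set_index("dose_uM")["signal"]
        out[k] = [sub.loc[d] for d in doses]
    return out


def read_plate_csvs(
    replicate_paths, controls_path, mono1_path=None, mono2_path=None,
    drug1_id="drug1", drug2_id="drug2", cell_line_id="",
) -> CombinationPlate:
    grids, doses1, doses2 = [], None, None
    for p in replicate_paths:
        raw = pd.read_csv(p, header=None).to_numpy()
        d2 = raw[0, 1:].astype(float)
        d1 = raw[1:, 0].astype(float)
        grid = raw[1:, 1:].astype(float)
        if doses1 is None:
            doses1, doses2 = d1, d2
        elif not (np.allclose(d1, doses1) and np.allclose(d2, doses2)):
            raise ValueError("replicate plates disagree on dose ladders")
        grids.append(grid)
    controls = pd.read_csv(controls_path)
    vehicle = controls.loc[controls["kind"] == "vehicle", "signal"].to_numpy(float)
    maxkill = controls.loc[controls["kind"] == "maxkill", "signal"].to_numpy(float)
    mono1 = _read_mono_csv(mono1_path, doses1) if mono1_path else None
    mono2 = _read_mono_csv(mono2_path, doses2) if mono2_path else None
    return CombinationPlate(
        drug1_id=drug1_id, drug2_id=drug2_id,
        doses1=doses1, doses2=doses2, raw=np.stack(grids),
        vehicle_signals=vehicle, maxkill_signals=maxkill,
        raw_mono1=mono1, raw_mono2=mono2, cell_line_id=cell_line_id,
    )


def write_decat_csv(runs, path) -> None:
    rows = []
    for run in runs:
        for enzyme, values in run.percent.items():
            for d, v in zip(run.doses, values):
                rows.append({
                    "run": run.run_id, "enzyme": enzyme,
                    "dose_uM": d, "percent_decatenation": v,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decat_csv(path) -> list[DecatenationRun]:
    df = pd.read_csv(path)
    runs = []
    for run_id, sub in df.groupby("run", sort=True):
        percent, doses = {}, None
        for enzyme, esub in sub.groupby("enzyme", sort=True):
            esub = esub.sort_values("dose_uM")
            d = esub["dose_uM"].to_numpy(float)
            if doses is None:
                doses = d
            elif not np.allclose(d, doses):
                raise ValueError(f"run {run_id}: enzymes measured on different doses")
            percent[enzyme] = esub["percent_decatenation"].to_numpy(float)
        runs.append(DecatenationRun(run_id=int(run_id), doses=doses, percent=percent))
    return runs


def read_pk_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"subject", "time_h", "conc_ugL"}
    if not need.issubset(df.columns):
        raise ValueError("pk CSV must have columns subject,time_h,conc_ugL")
    return df


def read_expression_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
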