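"""Lineage Selectivity Scores for large cell-line drug screens.

For one drug, all screened cell lines are ranked ascending by IC50
(rank 1 = most sensitive; ties get mean ranks).  The Selectivity Score is
the median rank of the target-lineage lines divided by the number of lines
screened against that drug, giving a value in (0, 1] where *lower* means
more selective for the target lineage.  The score depends on the IC50s only
through their ranks, so it is invariant under any strictly increasing
transform of the concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectivityResult",
    "selectivity_score",
    "rank_drugs",
    "lineage_t_test",
    "rescreen_concordance",
    "read_screen_csv",
    "read_annotations_csv",
]


@dataclass(frozen=True)
class SelectivityResult:
    drug_id: str
    score: float
    n_screened: int
    n_target: int
    median_target_rank: float
    t_statistic: float = float("nan")
    p_value: float = float("nan")


def selectivity_score(
    ic50_by_line: Mapping[str, float],
    annotations: pd.DataFrame,
    target_lineage: str,
    drug_id: str = "",
    target_filter: Callable[[pd.Series], bool] | None = None,
) -> SelectivityResult:
    """Selectivity Score of one drug for a target lineage.

    ``annotations`` must have columns ``cell_line``, ``lineage`` (and
    optionally genotype flags); ``target_filter`` further restricts which
    target-lineage lines define the median rank, while ``n_screened``
    always counts every screened line.
    """
    lines = list(ic50_by_line)
    ic50 = np.array([ic50_by_line[c] for c in lines], dtype=float)
    if np.any(ic50 <= 0) or not np.all(np.isfinite(ic50)):
        raise ValueError("invalid concentration: IC50 must be positive and finite")

    ann = annotations.set_index("cell_line") if "cell_line" in annotations.columns else annotations
    lineage = ann["lineage"]
    is_target = np.array([
        c in lineage.index and lineage.loc[c] == target_lineage for c in lines
    ])
    if target_filter is not None:
        keep = np.array([
            bool(target_filter(ann.loc[c])) if c in ann.index else False
            for c in lines
        ])
        is_target &= keep
    n_target = int(is_target.sum())
    if n_target == 0:
        raise ValueError("empty target group")

    ranks = stats.rankdata(ic50, method="average")
    median_rank = float(np.median(ranks[is_target]))
    n = len(lines)

    targ = np.log10(ic50[is_target])
    other = np.log10(ic50[~is_target])
    if targ.size >= 2 and other.size >= 2 and (targ.std() > 0 or other.std() > 0):
        t, p = lineage_t_test(targ, other)
    else:
        t, p = float("nan"), float("nan")

    return SelectivityResult(
        drug_id=drug_id,
        score=median_rank / n,
        n_screened=n,
        n_target=n_target,
        median_target_rank=median_rank,
        t_statistic=t,
        p_value=p,
    )


def rank_drugs(
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    target_lineage: str,
    subgroup_filter: Callable[[pd.Series], bool] | None = None,
    min_target: int = 3,
) -> tuple[list[SelectivityResult], list[str]]:
    """Selectivity Scores for every drug in a long-format screen table.

    ``table`` columns: ``cell_line``, ``drug``, ``ic50_uM``.  Drugs with
    fewer than ``min_target`` (filtered) target-lineage lines are skipped
    and reported in the second return value.  Results are sorted ascending
    by score (most selective first).
    """
    if table.empty:
        raise ValueError("empty screen table")
    if table.duplicated(["cell_line", "drug"]).any():
        raise ValueError("duplicate (cell_line, drug) record")
    results, skipped = [], []
    for drug, sub in table.groupby("drug", sort=False):
        ic50_by_line = dict(zip(sub["cell_line"], sub["ic50_uM"]))
        try:
            res = selectivity_score(
                ic50_by_line, annotations, target_lineage,
                drug_id=str(drug), target_filter=subgroup_filter,
            )
        except ValueError:
            skipped.append(str(drug))
            continue
        if res.n_target < min_target:
            skipped.append(str(drug))
            continue
        results.append(res)
    results.sort(key=lambda r: r.score)
    return results, skipped


def lineage_t_test(log10_ic50_target, log10_ic50_other) -> tuple[float, float]:
    """Welch two-sample two-sided t-test on log10 IC50 vectors."""
    a = np.asarray(log10_ic50_target, dtype=float)
    b = np.asarray(log10_ic50_other, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("insufficient observations: both groups need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # equal constants: no evidence of difference
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("insufficient observations: zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def rescreen_concordance(log10_ic50_a, log10_ic50_b) -> tuple[float, float]:
    """Pearson correlation between paired original and rescreen log10 IC50s."""
    a = np.asarray(log10_ic50_a, dtype=float)
    b = np.asarray(log10_ic50_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length paired vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate correlation: zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def read_screen_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"cell_line", "drug", "ic50_uM"}
    if not expected.issubset(df.columns):
        raise ValueError(f"screen CSV must have columns {sorted(expected)}")
    return df


def read_annotations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"cell_line", "lineage"}
    if not expected.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(expected)}")
    for col in ("mycn_amplified", "tp53_mutant"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
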