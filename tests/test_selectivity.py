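"""Selectivity Score ranking, lineage t-test, and rescreen concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pharmscreen.selectivity import (
    lineage_t_test,
    rank_drugs,
    rescreen_concordance,
    selectivity_score,
)


def brute_force_score(ic50_by_line, target_lines):
    """Independent oracle: enumerate the ranking by exhaustive sort."""
    items = sorted(ic50_by_line.items(), key=lambda kv: kv[1])
    ranks = {}
    i = 0
    while i < len(items):
        j = i
        while j < len(items) and items[j][1] == items[i][1]:
            j += 1
        mean_rank = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[items[k][0]] = mean_rank
        i = j
    target_ranks = sorted(ranks[c] for c in target_lines if c in ranks)
    n = len(target_ranks)
    median = (target_ranks[(n - 1) // 2] + target_ranks[n // 2]) / 2.0
    return median / len(items)


def make_annotations(lines, target_lines):
    return pd.DataFrame({
        "cell_line": lines,
        "lineage": ["neuroblastoma" if c in target_lines else "other" for c in lines],
    })


class TestSelectivityScore:
    def test_extreme_sensitivity(self):
        # 100 lines, 5 target lines occupying ranks 1-5
        ic50 = {f"c{i}": float(i + 1) for i in range(100)}
        targets = [f"c{i}" for i in range(5)]
        res = selectivity_score(ic50, make_annotations(list(ic50), targets),
                                "neuroblastoma")
        assert res.median_target_rank == 3
        assert res.score == pytest.approx(0.03)

    def test_least_sensitive_boundary(self):
        ic50 = {f"c{i}": float(i + 1) for i in range(10)}
        res = selectivity_score(ic50, make_annotations(list(ic50), ["c9"]),
                                "neuroblastoma")
        assert res.score == 1.0

    def test_three_targets_known_ranks(self):
        # 12 lines; targets at ranks 2, 5, 9 -> median rank 5, score 5/12
        ic50 = {f"c{i}": float(i + 1) for i in range(12)}
        targets = ["c1", "c4", "c8"]
        res = selectivity_score(ic50, make_annotations(list(ic50), targets),
                                "neuroblastoma")
        assert res.score == pytest.approx(5 / 12)
        assert res.score == pytest.approx(
            brute_force_score(ic50, targets))

    def test_total_tie(self):
        n = 7
        ic50 = {f"c{i}": 1.0 for i in range(n)}
        res = selectivity_score(ic50, make_annotations(list(ic50), ["c3"]),
                                "neuroblastoma")
        assert res.score == pytest.approx((n + 1) / (2 * n))

    def test_empty_target_group(self):
        ic50 = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError, match="empty target group"):
            selectivity_score(ic50, make_annotations(["a", "b"], []), "neuroblastoma")

    def test_invalid_concentration(self):
        ic50 = {"a": -1.0, "b": 2.0}
        with pytest.raises(ValueError, match="invalid concentration"):
            selectivity_score(ic50, make_annotations(["a", "b"], ["a"]),
                              "neuroblastoma")

    def test_matches_oracle_on_random_tables(self):
        # random tables with ties and missing records
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(3, 21)
            lines = [f"c{i}" for i in range(n)]
            # quantized IC50s force ties
            ic50 = {c: float(rng.integers(1, 6)) for c in lines}
            n_target = rng.integers(1, max(2, n // 2))
            targets = list(rng.choice(lines, size=n_target, replace=False))
            res = selectivity_score(ic50, make_annotations(lines, targets),
                                    "neuroblastoma")
            assert res.score == pytest.approx(brute_force_score(ic50, targets))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        lines = [f"c{i}" for i in range(n)]
        vals = rng.lognormal(0, 1, n)
        targets = lines[: max(1, n // 3)]
        ann = make_annotations(lines, targets)
        s1 = selectivity_score(dict(zip(lines, vals)), ann, "neuroblastoma").score
        s2 = selectivity_score(dict(zip(lines, np.exp(vals))), ann,
                               "neuroblastoma").score
        assert s1 == pytest.approx(s2)

    def test_lower_target_ic50_never_increases_score(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = 12
            lines = [f"c{i}" for i in range(n)]
            vals = np.sort(rng.uniform(1, 10, n))
            targets = ["c3", "c7"]
            ann = make_annotations(lines, targets)
            base = selectivity_score(dict(zip(lines, vals)), ann,
                                     "neuroblastoma").score
            moved = vals.copy()
            moved[3] = vals[3] * 0.01  # strictly more sensitive, no tie
            after = selectivity_score(dict(zip(lines, moved)), ann,
                                      "neuroblastoma").score
            assert after <= base + 1e-12


class TestRankDrugs:
    def test_subgroup_filter_restricts_median_not_n(self):
        lines = [f"c{i}" for i in range(10)]
        ann = pd.DataFrame({
            "cell_line": lines,
            "lineage": ["neuroblastoma"] * 4 + ["other"] * 6,
            "mycn_amplified": [True, True, True, False] + [False] * 6,
            "tp53_mutant": [False] * 10,
        })
        table = pd.DataFrame({
            "cell_line": lines, "drug": "d",
            "ic50_uM": np.arange(1.0, 11.0),
        })
        pred = lambda row: bool(row["mycn_amplified"]) and not bool(row["tp53_mutant"])
        results, _ = rank_drugs(table, ann, "neuroblastoma", subgroup_filter=pred)
        assert results[0].n_screened == 10
        assert results[0].n_target == 3
        assert results[0].median_target_rank == 2.0  # ranks {1,2,3}

    def test_min_target_skips(self):
        lines = ["a", "b", "c"]
        ann = make_annotations(lines, ["a"])
        table = pd.DataFrame({"cell_line": lines, "drug": "d",
                              "ic50_uM": [1.0, 2.0, 3.0]})
        results, skipped = rank_drugs(table, ann, "neuroblastoma", min_target=3)
        assert results == [] and skipped == ["d"]

    def test_duplicate_record_rejected(self):
        table = pd.DataFrame({"cell_line": ["a", "a"], "drug": ["d", "d"],
                              "ic50_uM": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            rank_drugs(table, make_annotations(["a"], ["a"]), "neuroblastoma")


class TestLineageTTest:
    def test_equal_means(self):
        t, p = lineage_t_test([1.0, 2.0, 3.0], [0.0, 2.0, 4.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_welch(self):
        a = np.array([-2.0, -2.1, -1.9])
        b = np.array([0.0, 0.1, -0.1])
        t, p = lineage_t_test(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert t == pytest.approx((a.mean() - b.mean()) / se)
        assert p < 0.01

    def test_sign_antisymmetry(self):
        a, b = [1.0, 1.5, 0.5], [2.0, 2.5, 3.0]
        t1, p1 = lineage_t_test(a, b)
        t2, p2 = lineage_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_small_group(self):
        with pytest.raises(ValueError, match="insufficient observations"):
            lineage_t_test([1.0], [1.0, 2.0])


class TestRescreenConcordance:
    def test_identity_and_reversal(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert rescreen_concordance(a, a)[0] == pytest.approx(1.0)
        assert rescreen_concordance(a, a[::-1])[0] == pytest.approx(-1.0)

    def test_closed_form_covariance(self):
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([0.0, 1.0, 4.0])
        r, _ = rescreen_concordance(a, b)
        expected = np.cov(a, b)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        assert r == pytest.approx(expected)

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="degenerate correlation"):
            rescreen_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
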