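import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osteomap.stats import (
    ContingencyTable2x2, contingency_from_cohort, describe, fisher_exact_2x2,
    kruskal_wallis, log1_volume, logistic_fit, odds_ratio_woolf,
    univariable_or_report,
)

# per-class counts of brain edema (yes / no) for POM, SOM-I, SOM-IIA, SOM-IIB
EDEMA_YES = {"POM": 0, "SOM-I": 2, "SOM-IIA": 14, "SOM-IIB": 49}
EDEMA_NO = {"POM": 6, "SOM-I": 35, "SOM-IIA": 43, "SOM-IIB": 19}


def expand_cohort(yes: dict, no: dict) -> tuple[list, list]:
    subtypes, flags = [], []
    for st_ in yes:
        subtypes += [st_] * yes[st_] + [st_] * no[st_]
        flags += [1] * yes[st_] + [0] * no[st_]
    return subtypes, flags


class TestContingency:
    def test_collapse_target_vs_others(self):
        subtypes, flags = expand_cohort(EDEMA_YES, EDEMA_NO)
        t = contingency_from_cohort(subtypes, flags, "SOM-IIB")
        assert (t.a, t.b, t.c, t.d) == (49, 19, 16, 84)

    def test_all_flags_zero(self):
        t = contingency_from_cohort(["SOM-IIB", "POM"], [0, 0], "SOM-IIB")
        assert t.a == t.c == 0 and t.b == t.d == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            contingency_from_cohort([], [], "POM")

    def test_missing_flags_dropped_complete_case(self):
        t = contingency_from_cohort(
            ["SOM-IIB", "SOM-IIB", "POM"], [1, float("nan"), None], "SOM-IIB")
        assert t.total == 1 and t.a == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency_from_cohort(["POM"], [1, 0], "POM")


class TestWoolfOddsRatio:
    def test_symmetric_table_or_one(self):
        assert odds_ratio_woolf(ContingencyTable2x2(1, 1, 1, 1)).or_point == 1.0

    def test_icp_table_or_seven(self):
        r = odds_ratio_woolf(ContingencyTable2x2(21, 47, 6, 94))
        assert r.or_point == pytest.approx(7.00, abs=5e-3)

    def test_zero_cell_haldane_correction_flagged(self):
        r = odds_ratio_woolf(ContingencyTable2x2(5, 0, 3, 7))
        assert r.correction_applied
        assert r.or_point == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_woolf(ContingencyTable2x2(0, 0, 0, 0))

    def test_point_inside_interval(self):
        r = odds_ratio_woolf(ContingencyTable2x2(14, 23, 16, 115))
        assert r.ci_low <= r.or_point <= r.ci_high

    @settings(derandomize=True, max_examples=100)
    @given(*(st.integers(1, 200) for _ in range(4)))
    def test_exposure_relabeling_reciprocity(self, a, b, c, d):
        r1 = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        r2 = odds_ratio_woolf(ContingencyTable2x2(b, a, d, c))
        assert r1.or_point == pytest.approx(1 / r2.or_point)
        assert r1.ci_low == pytest.approx(1 / r2.ci_high)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration over all tables with the
    observed margins; two-sided p sums point probabilities <= observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_hand_enumerated_example(self):
        # [[3,1],[1,3]]: 5 feasible tables, p = 34/70
        assert fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3)) == \
            pytest.approx(34 / 70)

    def test_extreme_diagonal_table(self):
        p = fisher_exact_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10))

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 7)) == 1.0

    @settings(derandomize=True, max_examples=60)
    @given(*(st.integers(0, 12) for _ in range(4)))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        margins = (a + b, c + d, a + c, b + d)
        if 0 in margins:
            assert fisher_exact_2x2(t) == 1.0
        else:
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7)

    @settings(derandomize=True, max_examples=60)
    @given(*(st.integers(1, 15) for _ in range(4)))
    def test_transposition_invariance(self, a, b, c, d):
        p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        p2 = fisher_exact_2x2(ContingencyTable2x2(a, c, b, d))  # transpose
        p3 = fisher_exact_2x2(ContingencyTable2x2(c, d, a, b))  # swap rows
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert p1 == pytest.approx(p3, rel=1e-9)


def kw_oracle(groups):
    """Independent rank-formula implementation with mid-rank ties and the
    standard tie correction."""
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(flat)
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    srt = flat[order]
    while i < n:
        j = i
        while j + 1 < n and srt[j + 1] == srt[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        rbar = ranks[start:start + ni].mean()
        h += ni * (rbar - (n + 1) / 2) ** 2
        start += ni
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(flat, return_counts=True)
    denom = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / denom


class TestKruskalWallis:
    def test_two_pair_hand_value(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_identical_values_h_zero(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(12)
        groups = [list(rng.integers(0, 20, size=n)) for n in (8, 11, 9)]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestLogVolumeAndDescribe:
    def test_log1_volume_anchors(self):
        assert log1_volume(0.0) == 0.0
        assert log1_volume(math.e - 1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            log1_volume(-0.1)

    def test_log1_volume_monotone(self):
        vols = [0.0, 0.5, 1.0, 7.3, 100.0]
        out = [log1_volume(v) for v in vols]
        assert out == sorted(out) and len(set(out)) == len(out)

    def test_describe_hand_computation(self):
        s = describe([2, 4, 4, 4, 5, 5, 7, 9])
        assert s.mean == pytest.approx(5.0)
        assert s.sd == pytest.approx(2.138, abs=1e-3)

    def test_describe_single_value_flagged(self):
        s = describe([3.0])
        assert s.sd == 0.0 and s.sd_degenerate

    def test_describe_constant_list(self):
        s = describe([4.0, 4.0, 4.0])
        assert s.sd == 0.0 and s.iqr == (4.0, 4.0)

    def test_describe_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestLogisticFit:
    def test_single_binary_predictor_reproduces_table_or(self):
        t = ContingencyTable2x2(49, 19, 16, 84)
        x = [1] * (t.a + t.b) + [0] * (t.c + t.d)
        y = [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
        fit = logistic_fit(y, pd.DataFrame({"exposed": x}))
        table_or = (t.a * t.d) / (t.b * t.c)
        assert fit.term("exposed").aor == pytest.approx(table_or, abs=1e-8)

    def test_separation_flag_on_perfect_predictor(self):
        y = [0] * 20 + [1] * 20
        x = pd.DataFrame({"sep": y, "noise": np.random.default_rng(3).normal(size=40)})
        fit = logistic_fit(y, x)
        assert fit.term("sep").separation_flag

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(21)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, size=n).astype(float)
        eta = -0.5 + 0.8 * x1 + 1.2 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(y, pd.DataFrame({"x1": x1, "x2": x2}))
        for name, truth in (("const", -0.5), ("x1", 0.8), ("x2", 1.2)):
            term = fit.term(name)
            assert abs(term.coef - truth) < 3 * term.se

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit([1, 1, 1], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))

    def test_rank_deficiency_names_column(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="rank deficient"):
            logistic_fit([0, 1, 0, 1], x)

    def test_wald_interval_is_exp_of_coef_pm_z_se(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(int)
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        t = fit.term("x")
        assert t.ci_low == pytest.approx(math.exp(t.coef - 1.959964 * t.se))
        assert t.ci_high == pytest.approx(math.exp(t.coef + 1.959964 * t.se))


def test_univariable_report_on_reconstructed_cohort():
    """The predefined pair report reproduces the four published associations
    from a cohort table expanded out of the per-class counts."""
    rows = []
    per_class = {
        # subtype: (n, edema, seizure, icp, exophthalmos)
        "POM": (6, 0, 0, 1, 0),
        "SOM-I": (37, 2, 0, 1, 14),
        "SOM-IIA": (57, 14, 6, 4, 11),
        "SOM-IIB": (68, 49, 15, 21, 5),
    }
    for st_, (n, ed, sz, icp, ex) in per_class.items():
        for i in range(n):
            rows.append({"subtype": st_, "edema": int(i < ed),
                         "seizure": int(i < sz), "icp": int(i < icp),
                         "exophthalmos": int(i < ex)})
    report = univariable_or_report(pd.DataFrame(rows))
    by = report.set_index("symptom")
    assert by.loc["edema", "odds_ratio"] == pytest.approx(13.54, abs=5e-3)
    assert by.loc["icp", "odds_ratio"] == pytest.approx(7.00, abs=5e-3)
    assert by.loc["exophthalmos", "target"] == "SOM-I"
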