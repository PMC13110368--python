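"""ΔΔCt, Mann–Whitney (exact vs enumeration oracle), labels, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pllpquant.exceptions import UndefinedStatisticError
from pllpquant.stats import (compare_cohorts, delta_delta_ct, mann_whitney_u,
                             percent_change, proportion_with_ci,
                             significance_label, summarize_groups, welch_t)
from pllpquant.synthetic import make_qpcr_plate


class TestDeltaDeltaCt:
    def test_identical_groups_fold_one(self):
        plate = make_qpcr_plate(1.0, 0.0, n_biological=4, seed=0)
        folds = delta_delta_ct(plate, "target", "rpl13", "control")
        assert folds["mutant"] == pytest.approx(1.0)

    def test_one_cycle_up_halves_expression(self):
        plate = make_qpcr_plate(1.0, 0.0, n_biological=3, seed=0)
        plate.loc[(plate.group == "mutant") & (plate.gene == "target"),
                  "ct"] += 1.0
        folds = delta_delta_ct(plate, "target", "rpl13", "control")
        assert folds["mutant"] == pytest.approx(0.5)

    def test_simulation_recovery_fold_035(self):
        folds = [delta_delta_ct(make_qpcr_plate(0.35, 0.15, 6, seed=s),
                                "target", "rpl13", "control")["mutant"]
                 for s in range(50)]
        assert float(np.mean(folds)) == pytest.approx(0.35, abs=0.03)

    def test_ct_shift_invariance(self):
        plate = make_qpcr_plate(0.4, 0.2, n_biological=5, seed=3)
        f1 = delta_delta_ct(plate, "target", "rpl13", "control")
        shifted = plate.copy()
        shifted["ct"] += 7.3
        f2 = delta_delta_ct(shifted, "target", "rpl13", "control")
        assert f2["mutant"] == pytest.approx(f1["mutant"], rel=1e-12)

    def test_missing_reference_named_in_error(self):
        plate = make_qpcr_plate(1.0, 0.0, n_biological=2, seed=0)
        broken = plate[~((plate["sample"] == "mutant_01")
                         & (plate.gene == "rpl13"))]
        with pytest.raises(ValueError, match="mutant_01"):
            delta_delta_ct(broken, "target", "rpl13", "control")

    def test_technical_replicates_averaged_first(self):
        # unbalanced technical replicates must not weight samples unequally
        plate = make_qpcr_plate(1.0, 0.0, n_biological=2, n_technical=3, seed=0)
        extra = plate[(plate["sample"] == "mutant_00")
                      & (plate.gene == "target")].copy()
        extra["ct"] += 3.0  # outlier wells on one sample
        stacked = pd.concat([plate, extra], ignore_index=True)
        folds = delta_delta_ct(stacked, "target", "rpl13", "control")
        # sample mean moves by +1.5 cycles on one of two samples -> ΔΔCt +0.75
        assert folds["mutant"] == pytest.approx(2 ** -0.75, rel=1e-9)


def enumeration_p(x, y):
    """Brute-force two-tailed Mann–Whitney p by enumerating all labelings."""
    pooled = np.concatenate([x, y])
    n_x = len(x)
    n = len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    def u_of(idx):
        return ranks[list(idx)].sum() - n_x * (n_x + 1) / 2
    u_obs = u_of(range(n_x))
    u_lo = min(u_obs, n_x * (n - n_x) - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(n), n_x):
        total += 1
        u = u_of(combo)
        if min(u, n_x * (n - n_x) - u) <= u_lo + 1e-9:
            count += 1
    # two-tailed by symmetry: P(U <= u_lo) + P(U >= nm - u_lo)
    return min(1.0, count / total)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_tailed == 1.0

    def test_complete_separation_n3(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic_U == 0.0
        assert res.method == "exact"
        assert res.p_two_tailed == pytest.approx(0.1)

    @pytest.mark.parametrize("n_x,n_y", [(n, m) for n in range(1, 7)
                                         for m in range(n, 7)])
    def test_exact_matches_enumeration_oracle(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        x = rng.normal(0, 1, n_x)
        y = rng.normal(0.5, 1, n_y)
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.p_two_tailed == pytest.approx(enumeration_p(x, y),
                                                 abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        p1 = mann_whitney_u(x, y).p_two_tailed
        p2 = mann_whitney_u(np.exp(x), np.exp(y)).p_two_tailed
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_type_one_error_calibrated_at_5pct(self):
        # null: both samples are rounded-normal cell counts from the same
        # genotype distribution (mean 120, cv 0.08), n = 20 per arm
        rng = np.random.default_rng(2024)
        n_sims = 10000
        rejections = 0
        for _ in range(n_sims):
            x = np.round(rng.normal(120, 9.6, 20))
            y = np.round(rng.normal(120, 9.6, 20))
            if mann_whitney_u(x, y).p_two_tailed <= 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_ties_fall_back_to_normal_approx(self):
        res = mann_whitney_u([1, 2, 2, 3], [2, 3, 4, 5])
        assert res.method == "normal_approx_tie_corrected"
        assert 0 <= res.p_two_tailed <= 1

    def test_u_statistic_range(self):
        res = mann_whitney_u([5, 6], [1, 2, 3])
        assert res.statistic_U == 6.0  # x above all of y: U_x = n_x * n_y


class TestSignificanceLabel:
    @pytest.mark.parametrize("p,label", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.02, "*"),
        (0.01, "**"), (0.001, "***"), (1e-6, "****"), (0.0001, "****"),
    ])
    def test_brackets(self, p, label):
        assert significance_label(p) == label

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_monotone(self, p1, p2):
        order = ["****", "***", "**", "*", "ns"]
        lo, hi = min(p1, p2), max(p1, p2)
        assert order.index(significance_label(lo)) \
            <= order.index(significance_label(hi))


class TestPercentChange:
    @pytest.mark.parametrize("ref,test,expected", [
        (120, 96, -20.0), (120, 120, 0.0), (120, 180, 50.0),
    ])
    def test_arithmetic(self, ref, test, expected):
        assert percent_change(ref, test) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            percent_change(0.0, 5.0)


class TestGroupSummaries:
    def test_closed_form(self):
        table = pd.DataFrame({"group": "a", "v": [2.0, 4.0, 6.0]})
        s = summarize_groups(table, "v")[0]
        assert (s.n, s.mean, s.sd) == (3, 4.0, 2.0)
        assert s.sem == pytest.approx(2.0 / math.sqrt(3))

    def test_duplication_shrinks_sem_by_sqrt2(self):
        t1 = pd.DataFrame({"group": "a", "v": [1.0, 3.0, 5.0, 7.0]})
        t2 = pd.concat([t1, t1], ignore_index=True)
        s1 = summarize_groups(t1, "v")[0]
        s2 = summarize_groups(t2, "v")[0]
        assert s2.n == 2 * s1.n
        assert s2.mean == s1.mean
        # duplicating rows changes ddof slightly; population SD is identical
        assert s2.sem == pytest.approx(s1.sem / math.sqrt(2), rel=0.1)

    def test_single_value_group_flagged(self):
        table = pd.DataFrame({"group": "a", "v": [5.0]})
        s = summarize_groups(table, "v")[0]
        assert math.isnan(s.sd)


class TestProportionCI:
    def test_extremes(self):
        p0, (lo0, _) = proportion_with_ci(0, 20)
        p1, (_, hi1) = proportion_with_ci(20, 20)
        assert (p0, lo0) == (0.0, 0.0)
        assert (p1, hi1) == (1.0, 1.0)

    def test_wilson_brackets_estimate(self):
        p, (lo, hi) = proportion_with_ci(16, 100)
        assert p == pytest.approx(0.16)
        assert lo < 0.16 < hi
        # Wilson closed form at z = 1.96
        z = 1.959963984540054
        centre = (16 / 100 + z * z / 200) / (1 + z * z / 100)
        half = (z / (1 + z * z / 100)
                * math.sqrt(0.16 * 0.84 / 100 + z * z / 40000))
        assert lo == pytest.approx(centre - half, abs=1e-6)
        assert hi == pytest.approx(centre + half, abs=1e-6)


class TestCompareCohorts:
    def test_tidy_table_against_reference(self):
        rng = np.random.default_rng(8)
        cohort = pd.DataFrame({
            "genotype": ["wt"] * 10 + ["mut"] * 10,
            "cell_count": np.concatenate([rng.normal(120, 8, 10),
                                          rng.normal(90, 8, 10)]),
        })
        table = compare_cohorts(cohort, "cell_count")
        row = table.iloc[0]
        assert row["reference"] == "wt" and row["group"] == "mut"
        assert row["effect_percent"] < -15
        assert row["label"] in {"*", "**", "***", "****"}

    def test_welch_available_as_sensitivity_check(self):
        t, p = welch_t([1, 2, 3, 4], [5, 6, 7, 8])
        assert p < 0.01
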