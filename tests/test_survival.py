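"""Extinction-time extraction, Kaplan-Meier, and log-rank tests."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hoiscan import (
    Species,
    SurvivalDatum,
    extract_survival,
    km_estimate,
    logrank_test,
    pairwise_logrank,
)

from conftest import series_table


def datum(uid, t, event, group="CD"):
    return SurvivalDatum(uid, group, Species.C, float(t), bool(event))


class TestExtraction:
    def test_positive_to_the_end_is_censored(self):
        table = series_table([100.0] * 27)
        (d,) = extract_survival(table, "C")
        assert d.time == 53.0 and d.event is False

    def test_terminal_zero_run_start_is_event_time(self):
        series = [100.0] * 11 + [0.0] * 16  # zeros from day 22 onward
        (d,) = extract_survival(series_table(series), "C")
        assert d.time == 22.0 and d.event is True

    def test_rebound_after_zero_is_censored(self):
        series = [100.0] * 5 + [0.0] + [50.0] * 21
        (d,) = extract_survival(series_table(series), "C")
        assert d.event is False and d.time == 53.0

    def test_rule_matches_brute_force_scan(self):
        """Randomized series: event iff a suffix of zeros exists, timed at
        its first day."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            series = [float(v) for v in rng.integers(0, 3, size=12) * 10]
            if series[0] == 0:
                series[0] = 10.0  # species must establish
            (d,) = extract_survival(series_table(series), "C")
            # brute force: scan every index, check all-zero suffix
            expected_event, expected_time = False, 53.0
            for i in range(1, len(series)):
                if all(v == 0 for v in series[i:]):
                    expected_event, expected_time = True, i * 2.0
                    break
            assert (d.event, d.time) == (expected_event, expected_time)

    def test_absent_species_gives_empty(self):
        table = series_table([100.0, 100.0])
        assert extract_survival(table, "S") == []


class TestKaplanMeier:
    def test_single_event_among_four(self):
        data = [datum("a", 2, True)] + [datum(u, 53, False) for u in "bcd"]
        km = km_estimate(data)
        assert km.survival_at(2.0) == pytest.approx(0.75)
        assert km.survival_at(1.9) == 1.0

    def test_no_events_flat_at_one(self):
        data = [datum(u, 53, False) for u in "abcd"]
        km = km_estimate(data)
        assert np.allclose(km.survival, 1.0)

    def test_hand_computed_product_limit(self):
        """Eight units, mixed events and censoring, against a hand-built
        product-limit table:

        t=5:  8 at risk, 2 events  -> S = 6/8 = 0.75
        t=10: 5 at risk (1 censored at 7), 1 event -> S = 0.75 * 4/5 = 0.60
        t=20: 3 at risk (1 censored at 15), 2 events -> S = 0.60 * 1/3 = 0.20
        """
        data = [
            datum("u1", 5, True), datum("u2", 5, True),
            datum("u3", 7, False),
            datum("u4", 10, True),
            datum("u5", 15, False),
            datum("u6", 20, True), datum("u7", 20, True),
            datum("u8", 53, False),
        ]
        km = km_estimate(data)
        assert km.survival_at(5) == pytest.approx(0.75)
        assert km.survival_at(10) == pytest.approx(0.60)
        assert km.survival_at(20) == pytest.approx(0.20)
        assert km.survival_at(53) == pytest.approx(0.20)

    def test_bands_contain_estimate(self):
        data = [datum("u1", 5, True), datum("u2", 10, True),
                datum("u3", 53, False), datum("u4", 53, False)]
        km = km_estimate(data)
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.survival <= km.ci_upper + 1e-12).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(1, 53), st.booleans()),
                    min_size=1, max_size=12))
    def test_survival_is_nonincreasing_step_function(self, records):
        data = [datum(f"u{i}", t, e) for i, (t, e) in enumerate(records)]
        km = km_estimate(data)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((0 <= km.survival) & (km.survival <= 1)).all()


def _two_groups(times_a, times_b):
    return {
        "A": [datum(f"a{i}", t, True, "A") for i, t in enumerate(times_a)],
        "B": [datum(f"b{i}", t, True, "B") for i, t in enumerate(times_b)],
    }


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = [datum(f"u{i}", t, e) for i, (t, e) in
             enumerate([(5, True), (10, True), (53, False)])]
        h = [datum(f"v{i}", d.time, d.event, "CDP") for i, d in enumerate(g)]
        res = logrank_test({"CD": g, "CDP": h})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_df_is_groups_minus_one(self):
        groups = {f"g{k}": [datum(f"u{k}{i}", 5 + k + i, True, f"g{k}")
                            for i in range(3)] for k in range(4)}
        assert logrank_test(groups).df == 3

    def test_textbook_two_group_observed_vs_expected(self):
        """{1,2,3} vs {4,5,6}, all events: the statistic equals the manual
        O-E / hypergeometric-variance computation."""
        groups = _two_groups([1, 2, 3], [4, 5, 6])
        res = logrank_test(groups)

        # manual O/E table over event times 1..6
        at_risk_a, at_risk_b = 3, 3
        o_minus_e, var = 0.0, 0.0
        for t in [1, 2, 3, 4, 5, 6]:
            n = at_risk_a + at_risk_b
            event_in_a = t <= 3
            e_a = at_risk_a / n  # one event at each time
            o_minus_e += (1.0 if event_in_a else 0.0) - e_a
            var += at_risk_a * at_risk_b * (n - 1) / (n ** 2 * (n - 1)) if n > 1 else 0
            if event_in_a:
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        expected_stat = o_minus_e ** 2 / var
        assert res.statistic == pytest.approx(expected_stat, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no data"):
            logrank_test({"A": [datum("a", 5, True, "A")], "B": []})

    def test_relabeling_invariance(self):
        g = _two_groups([1, 3, 6], [2, 5, 9])
        swapped = {"A": g["B"], "B": g["A"]}
        assert logrank_test(g).statistic == \
            pytest.approx(logrank_test(swapped).statistic)

    @pytest.mark.parametrize("times_a,times_b,tol", [
        ([1, 2, 3], [4, 5, 6], 0.1),
        ([1, 3, 5, 7], [2, 4, 6, 8], 0.1),
        ([1, 2, 5, 6], [3, 4, 7, 8], 0.1),
    ])
    def test_asymptotic_p_tracks_exact_permutation_p(self, times_a, times_b, tol):
        """All-events two-group case: the chi-square p-value approximates the
        exact permutation p (every group assignment enumerated) at n <= 8."""
        res = logrank_test(_two_groups(times_a, times_b))
        allt = list(times_a) + list(times_b)
        k = len(times_a)
        stats = []
        for idx in combinations(range(len(allt)), k):
            ta = [allt[i] for i in idx]
            tb = [allt[i] for i in range(len(allt)) if i not in idx]
            stats.append(logrank_test(_two_groups(ta, tb)).statistic)
        perm_p = np.mean(np.array(stats) >= res.statistic - 1e-12)
        assert abs(res.p_value - perm_p) <= tol


class TestPairwise:
    def test_three_identical_groups_all_p_one(self):
        base = [(5, True), (10, True), (53, False)]
        groups = {g: [datum(f"{g}{i}", t, e, g) for i, (t, e) in enumerate(base)]
                  for g in ("CD", "CDP", "CDS")}
        out = pairwise_logrank(groups)
        assert len(out) == 3
        assert np.allclose(out["p_adjusted"], 1.0)

    def test_unadjusted_matches_two_group_tests(self):
        groups = {"CD": _two_groups([1, 2, 4], [3, 5, 6])["A"],
                  "CDP": _two_groups([1, 2, 4], [3, 5, 6])["B"],
                  "CDS": [datum(f"s{i}", t, True, "CDS") for i, t in
                          enumerate([2, 4, 8])]}
        out = pairwise_logrank(groups, adjust="none")
        for _, row in out.iterrows():
            direct = logrank_test({row["group1"]: groups[row["group1"]],
                                   row["group2"]: groups[row["group2"]]})
            assert row["p_raw"] == pytest.approx(direct.p_value, rel=1e-6)
            assert row["p_adjusted"] == row["p_raw"]

    def test_bh_adjustment_matches_direct_formula(self):
        groups = {"CD": _two_groups([1, 2, 3], [10, 20, 30])["A"],
                  "CDP": _two_groups([1, 2, 3], [10, 20, 30])["B"],
                  "CDS": [datum(f"s{i}", t, True, "CDS") for i, t in
                          enumerate([2, 15, 25])]}
        out = pairwise_logrank(groups, adjust="BH")
        raw = out["p_raw"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        manual = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            prev = min(prev, raw[i] * m / (rank_from_top + 1))
            manual[i] = prev
        assert np.allclose(out["p_adjusted"], manual)
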