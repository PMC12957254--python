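import math

import numpy as np
import pandas as pd
import pytest

from faersig.disproportionality import (
    ContingencyTable,
    SignalCriteria,
    SignalStats,
    build_contingency,
    disproportionality_stats,
    evaluate_signal,
    format_signal_table,
    screen_all_pts,
    soc_bubble_table,
    soc_profile,
)

from helpers import records_frame


def brute_force_cells(records: pd.DataFrame, drug: str, pt: str):
    """Independent oracle: count the 2x2 cells one record at a time."""
    a = b = c = d = 0
    for row in records.itertuples(index=False):
        if row.drug == drug and row.pt == pt:
            a += 1
        elif row.drug == drug:
            b += 1
        elif row.pt == pt:
            c += 1
        else:
            d += 1
    return a, b, c, d


class TestBuildContingency:
    def test_hand_enumerable(self):
        records = records_frame(
            [("r1", "X", "p1"), ("r1", "X", "p2"), ("r2", "Y", "p1"), ("r2", "Y", "p2")],
            target_drugs=("X", "Y"),
        )
        t = build_contingency(records, "X", "p1")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_exhaustive_recount_oracle(self, cleaned):
        records = cleaned["records"]
        assert len(records) >= 1000
        for drug in ("risankizumab", "guselkumab"):
            top = records[records["drug"] == drug]["pt"].value_counts().index[:5]
            for pt in top:
                t = build_contingency(records, drug, pt)
                assert (t.a, t.b, t.c, t.d) == brute_force_cells(records, drug, pt)

    def test_absent_pt(self):
        records = records_frame([("r1", "X", "p1")], target_drugs=("X",))
        t = build_contingency(records, "X", "nonexistent")
        assert t.a == 0 and t.c == 0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestStats:
    def test_perfect_independence(self):
        s = disproportionality_stats(ContingencyTable(1, 1, 1, 1))
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.chisq == pytest.approx(0.0)
        assert s.ic == pytest.approx(0.0)

    def test_direct_formula_evaluation(self):
        s = disproportionality_stats(ContingencyTable(20, 10, 10, 20))
        assert s.ror == pytest.approx(4.0)
        assert s.prr == pytest.approx(2.0)
        assert s.chisq == pytest.approx(60 * (400 - 100) ** 2 / 30 / 30 / 30 / 30)
        assert s.chisq == pytest.approx(6.6667, abs=1e-4)
        assert s.ic == pytest.approx(math.log2(4 / 3))
        assert s.ic == pytest.approx(0.415, abs=1e-3)

    def test_ci_brackets_point(self):
        s = disproportionality_stats(ContingencyTable(20, 10, 10, 20))
        assert s.ror_low <= s.ror <= s.ror_high
        assert s.prr_low <= s.prr <= s.prr_high

    def test_ror_geq_prr_when_above_one(self):
        s = disproportionality_stats(ContingencyTable(30, 70, 100, 900))
        assert s.prr > 1
        assert s.ror >= s.prr

    def test_zero_a_flags_ror_and_ic(self):
        s = disproportionality_stats(ContingencyTable(0, 10, 10, 20))
        assert math.isnan(s.ror) and math.isnan(s.ic)

    def test_zero_b_flags_ror_only(self):
        s = disproportionality_stats(ContingencyTable(5, 0, 10, 20))
        assert math.isnan(s.ror)
        assert not math.isnan(s.prr)
        assert not math.isnan(s.chisq)
        assert not math.isnan(s.ic)

    def test_no_infinities(self):
        for cells in [(0, 10, 10, 20), (5, 0, 10, 20), (5, 10, 0, 20), (5, 10, 10, 0)]:
            s = disproportionality_stats(ContingencyTable(*cells))
            for v in (s.ror, s.prr, s.chisq, s.ic, s.ic025):
                assert not math.isinf(v)

    def test_haldane_defines_everything(self):
        s = disproportionality_stats(ContingencyTable(5, 0, 10, 20), haldane=True)
        assert not math.isnan(s.ror)

    def test_independence_null_whenever_ad_equals_bc(self):
        for a, b, c, d in [(2, 4, 3, 6), (10, 10, 10, 10), (6, 3, 8, 4)]:
            s = disproportionality_stats(ContingencyTable(a, b, c, d))
            assert s.ror == pytest.approx(1.0)
            assert s.prr == pytest.approx(1.0)
            assert s.chisq == pytest.approx(0.0, abs=1e-12)
            assert s.ic == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_a_with_fixed_margins(self):
        # fixed margins: drug total 100, event total 60, N 1000
        drug_total, event_total, n = 100, 60, 1000
        prev = None
        for a in range(5, 56, 10):
            b = drug_total - a
            c = event_total - a
            d = n - drug_total - c
            s = disproportionality_stats(ContingencyTable(a, b, c, d))
            if prev is not None:
                assert s.ror > prev.ror
                assert s.prr > prev.prr
                assert s.ic > prev.ic
            prev = s

    def test_ic_gap_shrinks_with_a(self):
        gaps = []
        for a in (3, 10, 100, 1000):
            s = disproportionality_stats(ContingencyTable(a, 1000, 1000, 100000))
            gaps.append(s.ic - s.ic025)
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[0] == pytest.approx(3.3 / math.sqrt(3) + 2 * 3 ** -1.5)

    def test_large_margin_ror_prr_consistency(self):
        # small drug/event counts against a big background: ROR ~ PRR
        s = disproportionality_stats(ContingencyTable(50, 5000, 2000, 2_000_000))
        assert abs(s.ror - s.prr) / s.prr < 0.01


class TestEvaluateSignal:
    def _stats(self, n, ror_low=0.5, prr=1.0, chisq=0.0, ic025=-1.0):
        return SignalStats(
            n=n, ror=2.0, ror_low=ror_low, ror_high=9.0,
            prr=prr, prr_low=0.5, prr_high=9.0, chisq=chisq, ic=1.0, ic025=ic025,
        )

    def test_below_min_n_never_positive(self):
        s = self._stats(2, ror_low=50.0, prr=50.0, chisq=500.0, ic025=5.0)
        assert not evaluate_signal(s).positive

    def test_prr_thresholds_inclusive(self):
        s = self._stats(3, prr=2.0, chisq=4.0)
        flags = evaluate_signal(s)
        assert flags.prr and flags.positive

    def test_all_rules_fail(self):
        s = self._stats(5, ror_low=0.9, prr=1.5, chisq=3.0, ic025=-0.1)
        flags = evaluate_signal(s)
        assert not (flags.ror or flags.prr or flags.ic or flags.positive)

    def test_ror_rule_strict(self):
        s = self._stats(3, ror_low=1.0)
        assert not evaluate_signal(s).ror
        s = self._stats(3, ror_low=1.0001)
        assert evaluate_signal(s).ror


class TestScreen:
    def test_injected_pair_ranked_first(self, cleaned):
        res = screen_all_pts(cleaned["records"], "risankizumab")
        assert res.iloc[0]["pt"] == "pt 0050"
        assert res.iloc[0]["positive"]

    def test_excluded_pt_never_appears(self, cleaned):
        res = screen_all_pts(cleaned["records"], "risankizumab", exclusions=["pt 0050"])
        assert "pt 0050" not in set(res["pt"])

    def test_min_n_filters(self):
        records = records_frame(
            [("r1", "X", "p1"), ("r2", "X", "p2"), ("r3", "Y", "p1")], target_drugs=("X", "Y")
        )
        res = screen_all_pts(records, "X", criteria=SignalCriteria(min_n=3))
        assert len(res) == 0

    def test_screen_matches_scalar_path(self, cleaned):
        records = cleaned["records"]
        res = screen_all_pts(records, "guselkumab")
        for _, row in res.head(10).iterrows():
            t = build_contingency(records, "guselkumab", row["pt"])
            s = disproportionality_stats(t)
            assert row["n"] == s.n
            assert row["ror"] == pytest.approx(s.ror, nan_ok=True)
            assert row["chisq"] == pytest.approx(s.chisq, nan_ok=True)
            assert row["ic025"] == pytest.approx(s.ic025, nan_ok=True)

    def test_min_n_monotone_subset(self, cleaned):
        res3 = screen_all_pts(cleaned["records"], "risankizumab", criteria=SignalCriteria(min_n=3))
        res10 = screen_all_pts(cleaned["records"], "risankizumab", criteria=SignalCriteria(min_n=10))
        assert set(res10["pt"]) <= set(res3["pt"])


class TestSocProfile:
    def test_proportions(self):
        records = records_frame(
            [(f"r{i}", "X", "p1") for i in range(30)] + [(f"s{i}", "X", "p2") for i in range(70)],
            target_drugs=("X",),
        )
        prof = soc_profile(records, {"p1": "SOC-A", "p2": "SOC-B"}, drugs=["X"])
        by_soc = prof.set_index("soc")["proportion"]
        assert by_soc["SOC-A"] == pytest.approx(0.30)
        assert by_soc["SOC-B"] == pytest.approx(0.70)

    def test_proportions_sum_to_one(self, cleaned):
        mapping = {f"pt {i:04d}": f"soc-{i % 5}" for i in range(60)}
        prof = soc_profile(cleaned["records"], mapping)
        for _, grp in prof.groupby("drug"):
            assert grp["proportion"].sum() == pytest.approx(1.0)

    def test_unmapped_bucket(self):
        records = records_frame([("r1", "X", "p1")], target_drugs=("X",))
        prof = soc_profile(records, {}, drugs=["X"])
        assert list(prof["soc"]) == ["unmapped"]

    def test_bubble_table_recomputed_from_stats(self, cleaned):
        res = screen_all_pts(cleaned["records"], "risankizumab")
        bubble = soc_bubble_table(res, {})
        merged = res.merge(bubble, on="pt")
        ok = merged["ror"].notna()
        assert np.allclose(merged.loc[ok, "log2_ror"], np.log2(merged.loc[ok, "ror"]))
        assert np.allclose(merged.loc[ok, "sqrt_chisq"], np.sqrt(merged.loc[ok, "chisq"]))


class TestFormatting:
    def test_published_layout(self):
        res = screen_all_pts(
            records_frame(
                [(f"r{i}", "X", "p1") for i in range(20)]
                + [(f"r{i}", "X", "p2") for i in range(10)]
                + [(f"b{i}", "Z", "p1") for i in range(10)]
                + [(f"b{i}", "Z", "p2") for i in range(20)],
                target_drugs=("X",),
            ),
            "X",
        )
        fmt = format_signal_table(res)
        assert list(fmt.columns) == ["pt", "n", "ror_ci", "prr_ci", "chisq", "ic_ic025"]
        assert fmt.loc[0, "ror_ci"].startswith("4.00 (")
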