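"""ROR engine: contingency construction, estimation, signal rule, screen."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from adrscreen import (
    ContingencyTable,
    DisproportionalityModel,
    RorResult,
    RunConfig,
    build_contingency,
    builtin_categories,
    compute_ror,
    detect_signal,
)
from adrscreen.disproportionality import MissingDrugError, ZeroCellError, stars_for
from conftest import _row, combine, drug_block, FRAME_COLUMNS

import pandas as pd

DR, DI = builtin_categories()


def _fixture_30() -> pd.DataFrame:
    # target: 10 cases, 4 in DR; comparator: 20 cases, 2 in DR
    return combine(
        drug_block("T", 10, {"DR": {"drug resistance": 4}}),
        drug_block("C", 20, {"DR": {"pathogen resistance": 2}}),
    )


class TestBuildContingency:
    def test_manual_enumeration_of_thirty_case_fixture(self):
        table = build_contingency(_fixture_30(), "T", "C", DR)
        assert (table.a, table.b, table.c, table.d) == (4, 6, 2, 18)
        assert not table.corrected
        assert table.n_reports == 4

    def test_haldane_correction_on_zero_cell(self):
        frame = combine(
            drug_block("T", 11, {"DR": {"drug resistance": 5}}),
            drug_block("C", 11),
        )
        table = build_contingency(frame, "T", "C", DR, policy="haldane")
        assert table.corrected
        assert (table.a, table.b, table.c, table.d) == (5.5, 6.5, 0.5, 11.5)
        assert table.n_reports == 5

    def test_error_policy_refuses_zero_cell(self):
        frame = combine(drug_block("T", 5), drug_block("C", 5))
        with pytest.raises(ZeroCellError):
            build_contingency(frame, "T", "C", DR, policy="error")

    def test_missing_comparator_raises(self):
        with pytest.raises(MissingDrugError, match="NOPE"):
            build_contingency(_fixture_30(), "T", "NOPE", DR)

    def test_same_drug_pair_rejected(self):
        with pytest.raises(ValueError, match="same drug"):
            build_contingency(_fixture_30(), "T", "t", DR)

    def test_case_naming_both_drugs_counts_on_both_sides(self):
        both = pd.DataFrame(
            [_row("both-1", ["T", "C"], ["drug resistance"])], columns=FRAME_COLUMNS
        )
        table = build_contingency(combine(_fixture_30(), both), "T", "C", DR)
        assert (table.a, table.c) == (5, 3)

    def test_matches_per_case_loop_on_random_data(self, rng):
        from conftest import random_cases
        from adrscreen import case_in_category

        pts = ["Drug resistance", "Nausea", "Rash", "Drug ineffective"]
        cases = random_cases(rng, 150, ["T", "C", "X"], pts)
        table = build_contingency(cases, "T", "C", DR, policy="haldane")
        t = [c for c in cases if "t" in c.drug_keys]
        c_ = [c for c in cases if "c" in c.drug_keys]
        a = sum(case_in_category(x, DR) for x in t)
        c = sum(case_in_category(x, DR) for x in c_)
        expected = (a, len(t) - a, c, len(c_) - c)
        got = (table.a, table.b, table.c, table.d)
        if table.corrected:
            expected = tuple(v + 0.5 for v in expected)
        assert got == expected


class TestComputeRor:
    def test_perfectly_balanced_table(self):
        res = compute_ror(ContingencyTable(1, 1, 1, 1))
        assert res.ror == 1.0
        assert res.p_value == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1 / res.ci_high)

    def test_worked_example_exact_fractions(self):
        res = compute_ror(ContingencyTable(4, 6, 2, 18))
        assert res.ror == pytest.approx(6.0)
        assert res.se_ln == pytest.approx(math.sqrt(35 / 36))
        assert res.ci_low == pytest.approx(math.exp(math.log(6) - 1.96 * math.sqrt(35 / 36)))
        assert res.ci_high == pytest.approx(math.exp(math.log(6) + 1.96 * math.sqrt(35 / 36)))
        assert res.ci_low == pytest.approx(0.8686, abs=1e-4)

    def test_corrected_worked_example(self):
        res = compute_ror(ContingencyTable(5.5, 5.5, 0.5, 10.5, corrected=True))
        assert res.ror == pytest.approx(21.0)
        assert res.n_reports == 5

    def test_nonpositive_cell_rejected(self):
        with pytest.raises(ValueError):
            compute_ror(ContingencyTable(0, 5, 5, 5))

    def test_agrees_with_statsmodels_oracle(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, size=4)
            res = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            oracle = sm.stats.Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
            assert res.ror == pytest.approx(oracle.oddsratio)
            assert res.se_ln == pytest.approx(oracle.log_oddsratio_se)
            low, high = oracle.oddsratio_confint(0.05)
            # statsmodels uses the exact normal quantile, the engine the
            # conventional 1.96; both agree to ~1e-4 relative
            assert res.ci_low == pytest.approx(low, rel=1e-3)
            assert res.ci_high == pytest.approx(high, rel=1e-3)

    @given(
        st.tuples(*[st.integers(1, 500)] * 4),
        st.integers(1, 500),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_reciprocity_and_monotonicity(self, cells, bump):
        a, b, c, d = cells
        res = compute_ror(ContingencyTable(a, b, c, d))
        mirror = compute_ror(ContingencyTable(c, d, a, b))
        assert res.ror * mirror.ror == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1 / mirror.ci_high)
        bigger = compute_ror(ContingencyTable(a + bump, b, c, d))
        assert bigger.ror > res.ror
        assert res.ci_low <= res.ror <= res.ci_high

    def test_ci_width_shrinks_when_cells_scale_up(self):
        base = compute_ror(ContingencyTable(4, 6, 2, 18))
        scaled = compute_ror(ContingencyTable(40, 60, 20, 180))
        assert scaled.ror == pytest.approx(base.ror)
        assert (scaled.ci_high / scaled.ci_low) < (base.ci_high / base.ci_low)

    def test_star_thresholds(self):
        assert stars_for(0.2) == ""
        assert stars_for(0.049) == "*"
        assert stars_for(0.01) == "**"
        assert stars_for(0.001) == "***"
        assert stars_for(0.0001) == "****"


class TestSignalRule:
    def _result(self, n, ci_low):
        return RorResult(
            ror=max(ci_low, 1.0) + 1, se_ln=0.1, ci_low=ci_low,
            ci_high=100.0, p_value=0.001, n_reports=n, signal=False, stars="***",
        )

    def test_fewer_than_five_reports_never_signals(self):
        assert not detect_signal(self._result(4, 3.0))

    def test_lower_bound_at_or_below_one_never_signals(self):
        assert not detect_signal(self._result(50, 0.999))
        assert not detect_signal(self._result(50, 1.0))

    def test_highest_reported_comparison_is_a_signal(self):
        # 83 colistin resistance reports, CI lower bound 12.5741
        assert detect_signal(self._result(83, 12.5741))

    def test_boundary_five_reports_with_ci_above_one(self):
        assert detect_signal(self._result(5, 1.0001))


class TestScreen:
    def _frame(self):
        parts = [drug_block(f"T{i}", 30, {"DR": {"drug resistance": 6}, "DI": {"drug ineffective": 5}}) for i in range(3)]
        parts += [drug_block(f"C{i}", 40, {"DR": {"drug resistance": 4}, "DI": {"drug ineffective": 4}}) for i in range(10)]
        return combine(*parts)

    def _config(self):
        return RunConfig(
            target_drugs=[f"T{i}" for i in range(3)],
            comparator_drugs=[f"C{i}" for i in range(10)],
        )

    def test_cartesian_product_row_count(self):
        results = DisproportionalityModel(self._frame(), self._config()).fit()
        assert len(results.rows) == 60
        assert list(results.table.columns[:3]) == ["target", "comparator", "category"]

    def test_composition_identity_with_direct_calls(self):
        frame, config = self._frame(), self._config()
        results = DisproportionalityModel(frame, config).fit()
        direct = compute_ror(build_contingency(frame, "T1", "C3", DR))
        assert results.pair_result("T1", "C3", "DR") == direct

    def test_missing_drug_marks_row_unavailable_without_aborting(self):
        config = RunConfig(target_drugs=["T0"], comparator_drugs=["C0", "GHOST"])
        results = DisproportionalityModel(self._frame(), config).fit()
        assert len(results.rows) == 4
        bad = results.table[results.table.comparator == "GHOST"]
        assert (bad["error"] != "").all()
        good = results.table[results.table.comparator == "C0"]
        assert good["ror"].notna().all()

    def test_summary_mentions_signal_count(self):
        results = DisproportionalityModel(self._frame(), self._config()).fit()
        assert f"{results.n_signals} signal" in results.summary()
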