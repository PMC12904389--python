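"""Disproportionality statistics against independent high-precision oracles."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.contingency import ContingencyTable
from faerspv.published import TOP_PT_SIGNALS
from faerspv.stats import (compute_all, compute_bcpnn, compute_ebgm,
                           compute_prr, compute_ror, evaluate_signal,
                           recover_contingency, round_half_up)


def oracle(a, b, c, d):
    """Evaluate every formula with exact rational cores (independent path)."""
    a, b, c, d = (Fraction(x) for x in (a, b, c, d))
    n = a + b + c + d
    out = {}
    out["ror"] = a * d / (b * c)
    se = math.sqrt(float(1 / a + 1 / b + 1 / c + 1 / d))
    out["ror_ci"] = (float(out["ror"]) * math.exp(-1.96 * se),
                     float(out["ror"]) * math.exp(1.96 * se))
    out["prr"] = a * (c + d) / (c * (a + b))
    out["chi2"] = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    se_prr = math.sqrt(float(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)))
    out["prr_lower"] = float(out["prr"]) * math.exp(-1.96 * se_prr)
    core = a * n / ((a + c) * (a + b))
    out["ic"] = math.log2(float(core))
    r = n * n / ((a + b + 1) * (a + c + 1))
    out["r"] = r
    out["e_ic"] = math.log2(float(a * n * n / ((n + r) * (a + b) * (a + c))))
    bracket = (b + c + d + r - 1) / ((a + 1) * (n + r + 1)) \
        + (2 + b + c + 2 * d) / ((a + b + 1) * (n + r + 3))
    v = float(bracket) / math.log(2)
    out["v_ic"] = v
    out["ic025"] = out["e_ic"] - 2 * math.sqrt(v)
    out["ebgm"] = core
    out["ebgm05"] = float(core) * math.exp(-1.96 * se)
    return out


REF = oracle(3, 7, 97, 9893)
T_REF = ContingencyTable(3, 7, 97, 9893)


class TestPointEstimates:
    def test_reference_table_all_quantities(self):
        s = compute_all(T_REF)
        assert s.ror == pytest.approx(float(REF["ror"]), rel=1e-12)
        assert s.ror_ci == pytest.approx(REF["ror_ci"], rel=1e-12)
        assert s.prr == pytest.approx(float(REF["prr"]), rel=1e-12)
        assert s.chi2 == pytest.approx(float(REF["chi2"]), rel=1e-12)
        assert s.prr_ci[0] == pytest.approx(REF["prr_lower"], rel=1e-12)
        assert s.ic == pytest.approx(REF["ic"], rel=1e-12)
        assert s.r_shrink == pytest.approx(float(REF["r"]), rel=1e-12)
        assert s.e_ic == pytest.approx(REF["e_ic"], rel=1e-12)
        assert s.v_ic == pytest.approx(REF["v_ic"], rel=1e-12)
        assert s.ic025 == pytest.approx(REF["ic025"], rel=1e-10)
        assert s.ebgm == pytest.approx(30.0, abs=1e-12)  # exact rational 30
        assert s.ebgm05 == pytest.approx(REF["ebgm05"], rel=1e-12)

    def test_reference_values_have_expected_magnitudes(self):
        # frozen two-decimal values from the oracle
        s = compute_all(T_REF)
        assert round_half_up(s.ror) == 43.71
        assert round_half_up(s.prr) == 30.9
        assert round_half_up(s.chi2) == 85.03
        assert round_half_up(s.ic, 3) == 4.907
        assert round_half_up(s.ic025, 3) == 0.341
        assert round_half_up(s.ebgm05, 3) == 7.644

    @given(st.integers(1, 10_000))
    def test_uniform_table_neutrality(self, k):
        t = ContingencyTable(k, k, k, k)
        s = compute_all(t)
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.ebgm == pytest.approx(1.0)
        assert s.ic == pytest.approx(0.0, abs=1e-12)
        assert s.chi2 == pytest.approx(0.0, abs=1e-9)
        assert s.ror_ci[0] < 1 < s.ror_ci[1]

    def test_unit_table_ci_symmetry(self):
        ror, ci = compute_ror(ContingencyTable(1, 1, 1, 1))
        assert ror == 1.0
        assert ci[0] == pytest.approx(math.exp(-1.96 * 2))
        assert ci[1] == pytest.approx(math.exp(1.96 * 2))


class TestZeroCells:
    @pytest.mark.parametrize("cells", [(0, 5, 10, 100), (5, 0, 10, 100),
                                       (5, 10, 0, 100), (5, 10, 100, 0)])
    def test_zero_cell_marks_statistics_undefined(self, cells):
        s = compute_all(ContingencyTable(*cells))
        assert math.isnan(s.ror) and math.isnan(s.ebgm05)
        res = evaluate_signal(s)
        assert not res.combined

    def test_a_zero_fails_even_with_haldane(self):
        s = compute_all(ContingencyTable(0, 5, 10, 100), zero_cell="haldane")
        assert math.isfinite(s.ror)
        assert not evaluate_signal(s).combined  # count gate a >= 3

    def test_haldane_mode_defines_statistics(self):
        ror, ci = compute_ror(ContingencyTable(3, 0, 10, 100), zero_cell="haldane")
        assert math.isfinite(ror) and math.isfinite(ci[0])


class TestSignalRule:
    def test_reference_table_passes_all_four(self):
        res = evaluate_signal(compute_all(T_REF))
        assert (res.ror_pass, res.prr_pass, res.bcpnn_pass, res.ebgm_pass) == (
            True, True, True, True)
        assert res.combined

    def test_uniform_table_fails_all_four(self):
        res = evaluate_signal(compute_all(ContingencyTable(10, 10, 10, 10)))
        assert not any([res.ror_pass, res.prr_pass, res.bcpnn_pass, res.ebgm_pass])
        assert not res.combined

    def test_count_gate_blocks_a_of_two(self):
        # enormous ROR but only two co-reports
        t = ContingencyTable(2, 1, 1, 10_000)
        s = compute_all(t)
        assert s.ror > 100
        res = evaluate_signal(s)
        assert not res.ror_pass and not res.prr_pass

    def test_combined_is_conjunction(self):
        s = compute_all(ContingencyTable(3, 7, 97, 9893))
        res = evaluate_signal(s)
        assert res.combined == (res.ror_pass and res.prr_pass
                                and res.bcpnn_pass and res.ebgm_pass)


tables_strategy = st.tuples(
    st.integers(1, 500), st.integers(1, 5_000),
    st.integers(1, 5_000), st.integers(1, 500_000),
).map(lambda t: ContingencyTable(*t))


class TestInvariants:
    @settings(max_examples=300)
    @given(tables_strategy)
    def test_ic_equals_log2_ebgm_exactly(self, t):
        s = compute_all(t)
        assert s.ic == math.log2(s.ebgm)

    @settings(max_examples=200)
    @given(tables_strategy)
    def test_ci_brackets_point_estimates(self, t):
        s = compute_all(t)
        assert s.ror_ci[0] <= s.ror <= s.ror_ci[1]
        assert s.prr_ci[0] <= s.prr <= s.prr_ci[1]
        assert s.ebgm05 <= s.ebgm
        assert s.ic025 <= s.e_ic

    @settings(max_examples=100)
    @given(tables_strategy, st.integers(1, 50))
    def test_ror_and_prr_monotone_in_a(self, t, bump):
        lo = compute_all(t)
        hi = compute_all(ContingencyTable(t.a + bump, t.b, t.c, t.d))
        assert hi.ror > lo.ror
        assert hi.prr > lo.prr

    @settings(max_examples=100)
    @given(st.integers(1, 400), st.integers(1, 50), st.data())
    def test_ic_and_ebgm_monotone_when_background_dominates(self, a, bump, data):
        # IC/EBGM are monotone in a only while a stays below both margins
        # (the signal-detection regime); with a dominating b and c and d > 0
        # the shrinkage core aN/((a+c)(a+b)) can decrease in a.
        b = data.draw(st.integers(a + bump, 5_000))
        c = data.draw(st.integers(a + bump, 5_000))
        d = data.draw(st.integers(1, 500_000))
        lo = compute_all(ContingencyTable(a, b, c, d))
        hi = compute_all(ContingencyTable(a + bump, b, c, d))
        assert hi.ic > lo.ic
        assert hi.ebgm > lo.ebgm

    @settings(max_examples=200)
    @given(tables_strategy)
    def test_shrinkage_pulls_ebgm_toward_one_relative_to_ror(self, t):
        # exact algebra: EBGM <= ROR iff bc <= ad iff ROR >= 1
        s = compute_all(t)
        if s.ror >= 1:
            assert s.ebgm <= s.ror + 1e-12
        else:
            assert s.ebgm >= s.ror - 1e-12


class TestPublishedRows:
    @pytest.mark.parametrize("row", TOP_PT_SIGNALS, ids=lambda r: r.term)
    def test_printed_ic_is_log2_of_printed_ebgm(self, row):
        assert abs(math.log2(row.ebgm) - row.ic) <= 0.01

    @pytest.mark.parametrize("row", TOP_PT_SIGNALS, ids=lambda r: r.term)
    def test_printed_ebgm05_consistent_with_implied_se(self, row):
        se = math.log(row.ror_ci[1] / row.ror_ci[0]) / (2 * 1.96)
        ebgm05 = row.ebgm * math.exp(-1.96 * se)
        assert abs(ebgm05 - row.ebgm05) <= 0.02


class TestRecoverContingency:
    def test_round_trip_from_known_table(self):
        s = compute_all(T_REF)
        res = recover_contingency(3, s.ror, s.ror_ci, s.prr, s.ebgm)
        assert res.identifiable
        assert res.max_rel_error < 1e-3
        assert res.table.as_tuple() == (3, 7, 97, 9893)

    def test_published_gastrointestinal_haemorrhage_row(self):
        row = TOP_PT_SIGNALS[1]
        res = recover_contingency(row.n, row.ror, row.ror_ci, row.prr, row.ebgm)
        assert res.identifiable
        assert res.max_rel_error <= 0.01
        # recomputed statistics from the integer table agree with print
        s = compute_all(res.table)
        assert s.ror == pytest.approx(row.ror, rel=0.01)
        assert s.prr == pytest.approx(row.prr, rel=0.01)
        assert s.ebgm == pytest.approx(row.ebgm, rel=0.01)
        assert s.ror_ci[0] == pytest.approx(row.ror_ci[0], rel=0.01)
        assert s.ror_ci[1] == pytest.approx(row.ror_ci[1], rel=0.01)

    def test_contradictory_inputs_report_non_identifiability(self):
        res = recover_contingency(5, 100.0, (50.0, 200.0), 1.0, 1.0)
        assert not res.identifiable
        assert "inconsistent" in res.message or "no integer table" in res.message

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            recover_contingency(0, 2.0, (1.0, 4.0), 2.0, 2.0)
        with pytest.raises(ValueError):
            recover_contingency(3, -1.0, (1.0, 4.0), 2.0, 2.0)
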