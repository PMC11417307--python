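import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvtls import (
    ContingencyTable,
    RegimenQuery,
    TermSet,
    build_table,
    compute_ic,
    compute_ror,
    evaluate_signal,
    ic_from_counts,
    screen,
    time_scan,
)

from conftest import mk_report

TLS = "Tumour lysis syndrome"
TERMS = TermSet("tls", frozenset({TLS}))
QUERY = RegimenQuery(name="drugx", required_drugs=frozenset({"drugx"}))


def _reports(n_both, n_drug_only, n_event_only, n_neither, year=2020):
    reports = []
    i = 0
    for _ in range(n_both):
        reports.append(mk_report(i, drugs=["drugx"], reactions=[TLS], year=year)); i += 1
    for _ in range(n_drug_only):
        reports.append(mk_report(i, drugs=["drugx"], year=year)); i += 1
    for _ in range(n_event_only):
        reports.append(mk_report(i, drugs=["other"], reactions=[TLS], year=year)); i += 1
    for _ in range(n_neither):
        reports.append(mk_report(i, drugs=["other"], year=year)); i += 1
    return reports


class TestBuildTable:
    def test_empty_input_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            assert build_table([], QUERY, TERMS) == ContingencyTable(0, 0, 0, 0)

    def test_exhaustive_partition(self):
        table = build_table(_reports(3, 2, 1, 4), QUERY, TERMS)
        assert (table.a, table.b, table.c, table.d) == (3, 2, 1, 4)
        assert table.n_total == 10

    def test_every_report_has_event(self):
        table = build_table(_reports(3, 0, 5, 0), QUERY, TERMS)
        assert table.b == table.d == 0

    @given(
        counts=st.tuples(*[st.integers(min_value=0, max_value=8)] * 4).filter(
            lambda t: sum(t) > 0
        )
    )
    @settings(deadline=None, max_examples=30)
    def test_partition_conserves_report_count(self, counts):
        reports = _reports(*counts)
        table = build_table(reports, QUERY, TERMS)
        assert table.n_total == len(reports)


class TestRor:
    def test_symmetric_table_is_null(self):
        est = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert est.ror == pytest.approx(1.0)
        assert est.low < 1.0 < est.high

    def test_hand_computed_example(self):
        # ln 11 = 2.3979, SE = sqrt(0.1 + 1/90 + 0.01 + 1/9900) = 0.34816
        est = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert est.ror == pytest.approx(11.0)
        assert est.low == pytest.approx(5.5595846, rel=1e-6)
        assert est.high == pytest.approx(21.7642158, rel=1e-6)
        assert not est.corrected

    def test_zero_cell_continuity_correction(self):
        est = compute_ror(ContingencyTable(0, 5, 5, 100))
        assert est.corrected
        expected = (0.5 * 100.5) / (5.5 * 5.5)
        assert est.ror == pytest.approx(expected)

    def test_zero_cell_without_correction_is_undefined(self):
        est = compute_ror(ContingencyTable(0, 5, 5, 100), continuity=False)
        assert est.ror is None
        assert est.reason == "zero_cell"

    def test_brute_force_woolf_oracle_all_small_tables(self):
        # independent direct evaluation over every table with cells 0..6
        z = 1.959963984540054
        for a, b, c, d in itertools.product(range(7), repeat=4):
            est = compute_ror(ContingencyTable(a, b, c, d))
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if 0 in (a, b, c, d) else (a, b, c, d)
            )
            ror = aa * dd / (bb * cc)
            se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
            assert est.ror == pytest.approx(ror, abs=1e-9)
            assert est.low == pytest.approx(ror * math.exp(-z * se), abs=1e-9)
            assert est.high == pytest.approx(ror * math.exp(z * se), abs=1e-9)


class TestIc:
    def test_independence_gives_zero(self):
        assert ic_from_counts(8, 8.0).ic == 0.0

    def test_shrinkage_limit_at_zero(self):
        assert ic_from_counts(0, 0.0).ic == 0.0

    def test_direct_evaluation_a33_e1(self):
        est = ic_from_counts(33, 1.0)
        assert est.ic == pytest.approx(4.481126689736616, abs=1e-9)
        assert est.ic025 == pytest.approx(3.900658681980305, abs=1e-9)
        assert est.ic975 == pytest.approx(4.898362245733822, abs=1e-9)

    @given(
        a=st.integers(min_value=5, max_value=500),
        b=st.integers(min_value=0, max_value=500),
        c=st.integers(min_value=1, max_value=500),
        d=st.integers(min_value=0, max_value=5000),
    )
    @settings(deadline=None, max_examples=200)
    def test_ror_ic_concordance(self, a, b, c, d):
        # both statistics compare observed to expected co-reporting
        table = ContingencyTable(a, b, c, d)
        if table.expected < 1 or table.b == 0 or table.c == 0 or table.d == 0:
            return
        ror = compute_ror(table)
        ic = compute_ic(table)
        if abs(math.log(ror.ror)) > 0.05 and abs(ic.ic) > 0.05:
            assert math.copysign(1, math.log(ror.ror)) == math.copysign(1, ic.ic)

    @given(
        a=st.integers(min_value=1, max_value=1000),
        expected=st.floats(min_value=0.01, max_value=1000),
    )
    @settings(deadline=None, max_examples=200)
    def test_shrinkage_pulls_toward_zero(self, a, expected):
        ic = ic_from_counts(a, expected).ic
        assert abs(ic) <= abs(math.log2(a / expected)) + 1e-12

    def test_interval_ordering(self):
        est = ic_from_counts(12, 3.0)
        assert est.ic025 <= est.ic <= est.ic975


class TestEvaluateAndScan:
    def test_all_zero_table_not_significant(self):
        with pytest.warns(UserWarning):
            res = evaluate_signal([], QUERY, TERMS)
        assert not res.significant

    def test_screen_matches_per_pair_evaluation(self):
        reports = _reports(5, 7, 11, 40)
        other = RegimenQuery(name="other", required_drugs=frozenset({"other"}))
        screened = screen(reports, [QUERY, other], TERMS)
        for query, res in zip([QUERY, other], screened):
            solo = evaluate_signal(reports, query, TERMS)
            assert res.table == solo.table
            assert res.ic == solo.ic

    def test_single_window_equals_full_evaluation(self):
        reports = _reports(5, 5, 5, 35)
        [(_, scanned)] = time_scan(reports, QUERY, TERMS, [2023])
        full = evaluate_signal(reports, QUERY, TERMS)
        assert scanned.table == full.table

    def test_windows_without_new_reports_repeat(self):
        reports = _reports(5, 5, 5, 35, year=2018)
        results = time_scan(reports, QUERY, TERMS, [2019, 2020, 2021])
        tables = [res.table for _, res in results]
        assert tables[0] == tables[1] == tables[2]

    def test_signal_emerging_after_2019_crosses_in_later_windows(self):
        # 2016-2019: regimen and event never co-occur; 2020-2023: strong
        # co-occurrence appears.  The cumulative IC025 must cross zero
        # only in the later windows.
        reports = []
        i = 0
        for year in (2016, 2017, 2018, 2019):
            for rep in _reports(0, 5, 5, 90, year=year):
                rep.report_id = rep.case_id = f"y{year}-{i}"; i += 1
                reports.append(rep)
        for year in (2020, 2021, 2022, 2023):
            for rep in _reports(10, 5, 5, 80, year=year):
                rep.report_id = rep.case_id = f"y{year}-{i}"; i += 1
                reports.append(rep)
        results = dict(time_scan(reports, QUERY, TERMS, [2019, 2021, 2023]))
        assert results[2019].ic025 < 0
        assert results[2021].ic025 > 0
        assert results[2023].ic025 > 0

    def test_cumulative_and_periodic_modes_differ(self):
        reports = _reports(5, 5, 5, 35, year=2018) + [
            mk_report(1000 + i, drugs=["other"], year=2021) for i in range(10)
        ]
        cumulative = dict(time_scan(reports, QUERY, TERMS, [2018, 2021]))
        periodic = dict(time_scan(reports, QUERY, TERMS, [2018, 2021], cumulative=False))
        assert cumulative[2021].table.n_total == 60
        assert periodic[2021].table.n_total == 10
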