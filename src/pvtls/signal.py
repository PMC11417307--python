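"""Case/non-case disproportionality statistics: ROR and shrinkage IC.

For a regimen R and an event definition E, reports are cross-classified
into the 2x2 case/non-case table

    a = #(R and E)    b = #(R, not E)
    c = #(E, not R)   d = #(neither)

against "all other drugs in the database" as the comparator.

Two estimators are computed:

* the reporting odds ratio ROR = (a d)/(b c) with the Woolf (log-normal)
  95% CI, exp(ln ROR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d)); a zero cell
  triggers the classical +0.5 continuity correction of all four cells
  (the result is flagged as corrected);

* the Bayesian information component IC = log2((a + 0.5)/(E[a] + 0.5))
  with E[a] = (a+b)(a+c)/n, shrunk toward 0 for small counts, and the
  asymmetric credibility-interval approximation

      IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2.0 (a+0.5)^(-3/2)
      IC975 = IC + 2.4 (a+0.5)^(-1/2) + 0.5 (a+0.5)^(-3/2).

A pair is a signal under the joint criterion ROR025 > 1 AND IC025 > 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .model import RegimenQuery, Report, TermSet, match_event, match_regimen

Z_95 = 1.959963984540054

# Coefficients of the IC credibility-interval approximation.
_IC025_C1, _IC025_C2 = 3.3, 2.0
_IC975_C1, _IC975_C2 = 2.4, 0.5


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case 2x2 counts for one regimen-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cell counts must be non-negative integers")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of the (regimen, event) cell under independence."""
        n = self.n_total
        return (self.a + self.b) * (self.a + self.c) / n if n else 0.0


@dataclass(frozen=True)
class RorEstimate:
    ror: Optional[float]
    low: Optional[float]
    high: Optional[float]
    corrected: bool = False
    reason: Optional[str] = None


@dataclass(frozen=True)
class IcEstimate:
    ic: float
    ic025: float
    ic975: float


@dataclass
class SignalResult:
    """Joint ROR/IC disproportionality result for one regimen-event pair."""

    regimen: str = ""
    event_set: str = ""
    table: Optional[ContingencyTable] = None
    ror: Optional[float] = None
    ror_l: Optional[float] = None
    ror_u: Optional[float] = None
    ror_corrected: bool = False
    ic: float = 0.0
    ic025: float = 0.0
    ic975: float = 0.0
    significant: bool = False


def build_table(
    reports: Sequence[Report], query: RegimenQuery, terms: TermSet
) -> ContingencyTable:
    """Cross-classify deduplicated reports into the case/non-case table."""
    if not reports:
        warnings.warn("building contingency table from an empty report list")
        return ContingencyTable(0, 0, 0, 0)
    a = b = c = d = 0
    for rep in reports:
        in_regimen = match_regimen(rep, query)
        has_event = match_event(rep, terms)
        if in_regimen:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable, continuity: bool = True) -> RorEstimate:
    """ROR with Woolf 95% CI; +0.5 continuity correction on any zero cell."""
    cells = (table.a, table.b, table.c, table.d)
    corrected = False
    if 0 in cells:
        if not continuity:
            return RorEstimate(None, None, None, False, reason="zero_cell")
        cells = tuple(x + 0.5 for x in cells)
        corrected = True
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RorEstimate(
        ror=ror,
        low=math.exp(log_ror - Z_95 * se),
        high=math.exp(log_ror + Z_95 * se),
        corrected=corrected,
    )


def ic_from_counts(a: float, expected: float) -> IcEstimate:
    """Shrinkage IC (bits) from an observed and an expected count."""
    shrunk = a + 0.5
    ic = math.log2(shrunk / (expected + 0.5))
    ic025 = ic - _IC025_C1 * shrunk ** -0.5 - _IC025_C2 * shrunk ** -1.5
    ic975 = ic + _IC975_C1 * shrunk ** -0.5 + _IC975_C2 * shrunk ** -1.5
    return IcEstimate(ic=ic, ic025=ic025, ic975=ic975)


def compute_ic(table: ContingencyTable) -> IcEstimate:
    """Shrinkage IC with the asymmetric 95% credibility interval.

    The expected count is the independence margin product
    (a+b)(a+c)/n; the +0.5 shrinkage keeps every table finite.
    """
    if table.n_total < 1:
        raise ValueError("IC requires at least one report")
    return ic_from_counts(table.a, table.expected)


def result_from_table(
    table: ContingencyTable,
    regimen: str = "",
    event_set: str = "",
    continuity: bool = True,
) -> SignalResult:
    """Assemble both estimators and the joint signal flag for a table."""
    if table.n_total == 0:
        return SignalResult(regimen=regimen, event_set=event_set, table=table)
    ror = compute_ror(table, continuity=continuity)
    ic = compute_ic(table)
    significant = ror.low is not None and ror.low > 1.0 and ic.ic025 > 0.0
    return SignalResult(
        regimen=regimen,
        event_set=event_set,
        table=table,
        ror=ror.ror,
        ror_l=ror.low,
        ror_u=ror.high,
        ror_corrected=ror.corrected,
        ic=ic.ic,
        ic025=ic.ic025,
        ic975=ic.ic975,
        significant=significant,
    )


def evaluate_signal(
    reports: Sequence[Report],
    query: RegimenQuery,
    terms: TermSet,
    continuity: bool = True,
) -> SignalResult:
    """Build the case/non-case table for the pair and score it."""
    table = build_table(reports, query, terms)
    return result_from_table(table, regimen=query.name, event_set=terms.name, continuity=continuity)


def screen(
    reports: Sequence[Report],
    queries: Sequence[RegimenQuery],
    terms: TermSet,
    continuity: bool = True,
) -> list:
    """Score many regimens against one event set in a single pass.

    Equivalent to calling :func:`evaluate_signal` per query but computes
    each report's drug/reaction sets once, which matters on large
    synthetic screens.
    """
    folded = terms.folded()
    tallies = [[0, 0, 0, 0] for _ in queries]
    filters = [q.role_filter for q in queries]
    for rep in reports:
        all_names = rep.drug_names()
        terms_present = bool(rep.reaction_terms() & folded)
        for i, q in enumerate(queries):
            names = all_names if filters[i] is None else rep.drug_names(filters[i])
            in_regimen = q.required_drugs <= names
            if in_regimen:
                tallies[i][0 if terms_present else 1] += 1
            else:
                tallies[i][2 if terms_present else 3] += 1
    return [
        result_from_table(ContingencyTable(*tallies[i]), regimen=q.name, event_set=terms.name, continuity=continuity)
        for i, q in enumerate(queries)
    ]


def _window_key(window) -> tuple:
    """Normalize a window endpoint: year or (year, quarter)."""
    if isinstance(window, tuple):
        year, quarter = window
        return int(year), int(quarter)
    return int(window), 4


def time_scan(
    reports: Sequence[Report],
    query: RegimenQuery,
    terms: TermSet,
    windows: Sequence,
    cumulative: bool = True,
) -> list:
    """Signal per calendar window (yearly IC scan).

    ``windows`` is a list of period end-points, each a year or a
    ``(year, quarter)`` tuple.  In cumulative mode (default) each window
    scores all reports up to and including its end-point; otherwise only
    the reports strictly after the previous end-point.  Reports without
    a report year are ignored.
    """
    dated = [r for r in reports if r.report_year is not None]
    keyed = [((r.report_year, r.report_quarter or 4), r) for r in dated]
    ends = sorted(_window_key(w) for w in windows)
    out = []
    prev = None
    for window, end in zip(sorted(windows, key=_window_key), ends):
        if cumulative:
            subset = [r for k, r in keyed if k <= end]
        else:
            subset = [r for k, r in keyed if k <= end and (prev is None or k > prev)]
        if not subset:
            warnings.warn(f"time window {window!r} contains no reports")
            out.append((window, SignalResult(regimen=query.name, event_set=terms.name,
                                             table=ContingencyTable(0, 0, 0, 0))))
        else:
            out.append((window, evaluate_signal(subset, query, terms)))
        prev = end
    return out


def results_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Tabulate signal results (one row per regimen), Fig-1 style columns."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "regimen": r.regimen,
                "event_set": r.event_set,
                "a": t.a if t else 0,
                "n_regimen": (t.a + t.b) if t else 0,
                "ror": r.ror,
                "ror_l": r.ror_l,
                "ror_u": r.ror_u,
                "ic": r.ic,
                "ic025": r.ic025,
                "ic975": r.ic975,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
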