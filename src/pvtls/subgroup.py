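"""Two-group subgroup disproportionality via the IC difference (IC-delta).

The report set is split into two strata (e.g. male vs female, or age at
most 65 vs over 65); reports whose stratifying variable is unknown are
excluded.  Within each stratum its own case/non-case table is built --
the comparator is "all other drugs" *within the same stratum* -- and the
shrinkage IC computed.  The subgroup statistic is

    IC_delta = IC_a - IC_b,
    95% CI   = IC_delta +/- 1.96 sqrt(v_a + v_b),
    v        = (1 / ln 2)^2 / (a_cell + 0.5)   per stratum,

a delta-method variance on the shrunk observed count, summed over the
two independent strata.  A subgroup-specific signal difference is
declared when the CI excludes zero.  The sign convention (group_a minus
group_b) is carried explicitly in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .model import RegimenQuery, Report, Sex, TermSet
from .signal import Z_95, build_table, compute_ic

_LN2_SQ_INV = (1.0 / math.log(2.0)) ** 2


@dataclass(frozen=True)
class SubgroupResult:
    regimen: str
    event_set: str
    group_a: str
    group_b: str
    ic_a: float
    ic_b: float
    ic_delta: float
    ic_delta_025: float
    ic_delta_975: float
    significant: bool
    n_a: int
    n_b: int
    unstable: bool = False


def sex_stratifier(report: Report) -> Optional[str]:
    """Default sex split: group a = male, group b = female."""
    if report.sex is Sex.MALE:
        return "a"
    if report.sex is Sex.FEMALE:
        return "b"
    return None


def age_stratifier(cutoff: float = 65.0) -> Callable:
    """Age split at ``cutoff`` years: group a = at most cutoff, group b = older."""

    def _strat(report: Report) -> Optional[str]:
        if report.age_years is None:
            return None
        return "a" if report.age_years <= cutoff else "b"

    return _strat


def compute_ic_delta(
    reports: Sequence[Report],
    query: RegimenQuery,
    terms: TermSet,
    stratifier: Callable,
    group_labels: tuple = ("a", "b"),
) -> SubgroupResult:
    """IC difference between two strata with its 95% CI.

    ``stratifier`` maps a report to ``"a"``, ``"b"`` or ``None``
    (excluded).  A stratum with zero regimen-event reports still yields
    a CI through the +0.5 shrinkage but the result is flagged unstable.
    """
    stratum_a = [r for r in reports if stratifier(r) == "a"]
    stratum_b = [r for r in reports if stratifier(r) == "b"]
    table_a = build_table(stratum_a, query, terms) if stratum_a else None
    table_b = build_table(stratum_b, query, terms) if stratum_b else None
    if table_a is None or table_b is None or table_a.n_total == 0 or table_b.n_total == 0:
        raise ValueError("both strata must contain at least one report")
    ic_a = compute_ic(table_a).ic
    ic_b = compute_ic(table_b).ic
    delta = ic_a - ic_b
    var = _LN2_SQ_INV / (table_a.a + 0.5) + _LN2_SQ_INV / (table_b.a + 0.5)
    half = Z_95 * math.sqrt(var)
    low, high = delta - half, delta + half
    return SubgroupResult(
        regimen=query.name,
        event_set=terms.name,
        group_a=group_labels[0],
        group_b=group_labels[1],
        ic_a=ic_a,
        ic_b=ic_b,
        ic_delta=delta,
        ic_delta_025=low,
        ic_delta_975=high,
        significant=not (low <= 0.0 <= high),
        n_a=table_a.a,
        n_b=table_b.a,
        unstable=table_a.a == 0 or table_b.a == 0,
    )


def subgroup_by(
    reports: Sequence[Report],
    query: RegimenQuery,
    terms: TermSet,
    by: str,
    age_cutoff: float = 65.0,
) -> SubgroupResult:
    """Convenience wrapper: ``by`` is ``"sex"`` (male - female) or ``"age"``
    (at most ``age_cutoff`` minus older)."""
    if by == "sex":
        return compute_ic_delta(reports, query, terms, sex_stratifier, ("male", "female"))
    if by == "age":
        return compute_ic_delta(
            reports,
            query,
            terms,
            age_stratifier(age_cutoff),
            (f"<={age_cutoff:g}", f">{age_cutoff:g}"),
        )
    raise ValueError(f"unknown subgroup axis: {by!r}")
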