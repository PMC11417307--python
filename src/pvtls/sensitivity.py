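"""Sensitivity scenarios and signal-robustness grading.

Four confounding-control scenarios re-evaluate a regimen-event signal:

``competition_bias``
    Drop event-positive reports that also list a configured competitor
    drug known to cause the event (masking/competition control).  The
    competitor list is configurable; regimen drugs are always exempt.
``suspect_and_hcp``
    Restrict to healthcare-professional reports and count only drugs in
    suspect roles (primary/secondary suspect) toward regimen matching
    (exposure/information-bias control).
``smq_broad``
    Replace the narrow event definition with the broad SMQ-style PT
    list (co-reported-event control).
``preexisting_excluded``
    Drop reports whose medical history intersects a pre-existing-disease
    exclusion list, e.g. renal dysfunction or hyperuricemia
    (indication-bias control).

Robustness of a signal is graded by how many of the four scenario IC025
values stay above zero: 4/4 strong, 3/4 intermediate, otherwise weak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

from . import io as _io
from .model import (
    ConfigurationError,
    RegimenQuery,
    Report,
    SUSPECT_ROLES,
    ReporterType,
    TermSet,
    match_event,
    normalize_drug_name,
)
from .signal import SignalResult, evaluate_signal


class ScenarioName(str, Enum):
    COMPETITION_BIAS = "competition_bias"
    SUSPECT_AND_HCP = "suspect_and_hcp"
    SMQ_BROAD = "smq_broad"
    PREEXISTING_EXCLUDED = "preexisting_excluded"


#: Default competitor list for the competition-bias scenario: drugs with
#: well-described tumor-lysis liability outside the melanoma regimens.
DEFAULT_TLS_COMPETITORS = frozenset(
    {
        "venetoclax",
        "rituximab",
        "obinutuzumab",
        "ibrutinib",
        "cyclophosphamide",
        "cytarabine",
        "doxorubicin",
        "bortezomib",
        "carfilzomib",
        "lenalidomide",
    }
)


@dataclass(frozen=True)
class SensitivityScenario:
    """One sensitivity scenario with its scenario-specific configuration."""

    name: ScenarioName
    competitor_drugs: Optional[frozenset] = None
    excluded_preexisting: Optional[TermSet] = None
    broad_terms: Optional[TermSet] = None

    def __post_init__(self) -> None:
        name = ScenarioName(self.name)
        object.__setattr__(self, "name", name)
        if self.competitor_drugs is not None:
            if name is not ScenarioName.COMPETITION_BIAS:
                raise ConfigurationError("competitor_drugs only applies to competition_bias")
            object.__setattr__(
                self,
                "competitor_drugs",
                frozenset(normalize_drug_name(d) for d in self.competitor_drugs),
            )
        if self.excluded_preexisting is not None and name is not ScenarioName.PREEXISTING_EXCLUDED:
            raise ConfigurationError("excluded_preexisting only applies to preexisting_excluded")
        if self.broad_terms is not None and name is not ScenarioName.SMQ_BROAD:
            raise ConfigurationError("broad_terms only applies to smq_broad")


@dataclass(frozen=True)
class RobustnessGrade:
    """Count of significant scenarios (IC025 > 0) and its label."""

    n_significant: int
    label: str

    def __post_init__(self) -> None:
        expected = _label(self.n_significant)
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with {self.n_significant}/4")


def _label(n_significant: int) -> str:
    if n_significant == 4:
        return "strong"
    if n_significant == 3:
        return "intermediate"
    return "weak"


def default_scenarios(
    competitor_drugs: Optional[Sequence] = None,
    excluded_preexisting: Optional[TermSet] = None,
    broad_terms: Optional[TermSet] = None,
) -> list:
    """The four scenarios in their canonical order, with packaged defaults."""
    return [
        SensitivityScenario(
            ScenarioName.COMPETITION_BIAS,
            competitor_drugs=frozenset(
                competitor_drugs if competitor_drugs is not None else DEFAULT_TLS_COMPETITORS
            ),
        ),
        SensitivityScenario(ScenarioName.SUSPECT_AND_HCP),
        SensitivityScenario(
            ScenarioName.SMQ_BROAD,
            broad_terms=broad_terms or _io.builtin_term_set("tls_smq_broad_synthetic"),
        ),
        SensitivityScenario(
            ScenarioName.PREEXISTING_EXCLUDED,
            excluded_preexisting=excluded_preexisting
            or _io.builtin_term_set("preexisting_exclusions_default"),
        ),
    ]


def apply_scenario(
    reports: Sequence[Report],
    scenario: SensitivityScenario,
    query: RegimenQuery,
    terms: TermSet,
) -> tuple:
    """Apply one scenario; returns (filtered reports, effective terms, effective query)."""
    name = ScenarioName(scenario.name)
    if name is ScenarioName.COMPETITION_BIAS:
        competitors = (scenario.competitor_drugs or frozenset()) - query.required_drugs
        if not competitors:
            return list(reports), terms, query
        kept = [
            r
            for r in reports
            if not (match_event(r, terms) and r.drug_names() & competitors)
        ]
        return kept, terms, query
    if name is ScenarioName.SUSPECT_AND_HCP:
        kept = [r for r in reports if r.reporter_type is ReporterType.HEALTHCARE_PROFESSIONAL]
        return kept, terms, replace(query, role_filter=SUSPECT_ROLES)
    if name is ScenarioName.SMQ_BROAD:
        broad = scenario.broad_terms or _io.builtin_term_set("tls_smq_broad_synthetic")
        return list(reports), broad, query
    if name is ScenarioName.PREEXISTING_EXCLUDED:
        exclusion = scenario.excluded_preexisting or _io.builtin_term_set(
            "preexisting_exclusions_default"
        )
        folded = exclusion.folded()
        kept = [
            r
            for r in reports
            if not any(t.casefold() in folded for t in r.preexisting_terms)
        ]
        return kept, terms, query
    raise ConfigurationError(f"unknown scenario: {scenario.name!r}")


def run_sensitivity(
    reports: Sequence[Report],
    query: RegimenQuery,
    terms: TermSet,
    scenarios: Optional[Sequence[SensitivityScenario]] = None,
) -> tuple:
    """Evaluate the four scenarios independently; returns (results, grade)."""
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    results = []
    for scenario in scenarios:
        sub_reports, sub_terms, sub_query = apply_scenario(reports, scenario, query, terms)
        results.append(evaluate_signal(sub_reports, sub_query, sub_terms))
    return results, grade_robustness(results)


def grade_robustness(results: Sequence[SignalResult]) -> RobustnessGrade:
    """Grade signal robustness from the four scenario results.

    A scenario counts as significant when its IC025 exceeds 0.
    """
    if len(results) != 4:
        raise ValueError(f"expected exactly 4 scenario results, got {len(results)}")
    n = sum(1 for r in results if r.ic025 > 0)
    return RobustnessGrade(n_significant=n, label=_label(n))
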