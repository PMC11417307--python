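"""Domain model for spontaneous adverse-event reports.

A spontaneous report links one or more drugs to one or more adverse
reactions coded as MedDRA Preferred Terms (PTs), together with
demographics, seriousness outcomes and therapy/onset dates.  The model
mirrors the structure of FAERS case records: a *case* may be submitted
several times (versions); analyses run on the deduplicated set in which
only the latest version of each case survives.

Regimens (single drugs or co-reported combinations such as
encorafenib + binimetinib) are expressed as :class:`RegimenQuery`
objects; adverse events of interest as :class:`TermSet` objects, either
a narrow PT-level definition or a broad SMQ-style PT list.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence


class ConfigurationError(ValueError):
    """A query, scenario or generator configuration is invalid."""


class FormatError(ValueError):
    """An input table does not conform to the declared dialect."""


class ReporterType(str, Enum):
    HEALTHCARE_PROFESSIONAL = "healthcare_professional"
    OTHER = "other"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class DrugRole(str, Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class Outcome(str, Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    OTHER_SERIOUS = "other_serious"


class TermScope(str, Enum):
    PT_NARROW = "pt_narrow"
    SMQ_BROAD = "smq_broad"


#: FAERS drug role codes a reporter marks as causally suspected.
SUSPECT_ROLES = frozenset({DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT})

# Common salt/ester suffixes stripped during ingredient normalization.
_SALT_SUFFIXES = frozenset(
    {
        "hydrochloride",
        "dihydrochloride",
        "hydrobromide",
        "mesylate",
        "mesilate",
        "maleate",
        "dimaleate",
        "fumarate",
        "hemifumarate",
        "tartrate",
        "citrate",
        "phosphate",
        "sulfate",
        "sulphate",
        "sodium",
        "potassium",
        "calcium",
        "acetate",
        "besylate",
        "tosylate",
        "succinate",
        "hcl",
    }
)

# Small packaged brand-name -> ingredient synonym table for the melanoma
# regimens of interest; FAERS verbatim drug names are noisy and analyses
# run at ingredient level.
_SYNONYMS = {
    "braftovi": "encorafenib",
    "mektovi": "binimetinib",
    "opdivo": "nivolumab",
    "yervoy": "ipilimumab",
    "keytruda": "pembrolizumab",
    "zelboraf": "vemurafenib",
    "tafinlar": "dabrafenib",
    "mekinist": "trametinib",
    "cotellic": "cobimetinib",
    "dtic-dome": "dacarbazine",
    "venclexta": "venetoclax",
}


def normalize_drug_name(name: str) -> str:
    """Normalize a verbatim drug name to a comparable ingredient string.

    Lower-cases, trims and collapses whitespace, strips trailing salt
    suffixes and maps known brand names to their active ingredient.
    """
    tokens = name.strip().lower().split()
    while len(tokens) > 1 and tokens[-1] in _SALT_SUFFIXES:
        tokens = tokens[:-1]
    s = " ".join(tokens)
    return _SYNONYMS.get(s, s)


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report, normalized to ingredient level."""

    name: str
    role: DrugRole = DrugRole.PRIMARY_SUSPECT
    start_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        normalized = normalize_drug_name(self.name)
        if not normalized:
            raise ValueError("drug name empty after normalization")
        object.__setattr__(self, "name", normalized)


@dataclass(frozen=True)
class ReactionEntry:
    """One adverse reaction (MedDRA PT) of a report."""

    preferred_term: str
    onset_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        pt = self.preferred_term.strip()
        if not pt:
            raise ValueError("preferred term must be non-empty")
        object.__setattr__(self, "preferred_term", pt)


@dataclass
class Report:
    """One spontaneous adverse-event report (one case version)."""

    report_id: str
    case_id: str
    case_version: int = 1
    report_year: Optional[int] = None
    report_quarter: Optional[int] = None
    reporter_type: ReporterType = ReporterType.UNKNOWN
    age_years: Optional[float] = None
    sex: Sex = Sex.UNKNOWN
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    preexisting_terms: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.case_version < 1:
            raise ValueError("case_version must be >= 1")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        self.outcomes = frozenset(Outcome(o) for o in self.outcomes)

    def drug_names(self, role_filter: Optional[frozenset] = None) -> frozenset:
        """Set of normalized drug names, optionally restricted by role."""
        if role_filter is None:
            return frozenset(d.name for d in self.drugs)
        return frozenset(d.name for d in self.drugs if d.role in role_filter)

    def reaction_terms(self) -> frozenset:
        """Case-folded set of reported reaction PTs."""
        return frozenset(r.preferred_term.casefold() for r in self.reactions)


@dataclass(frozen=True)
class TermSet:
    """A named set of MedDRA PTs defining an adverse event of interest.

    Membership tests are case-insensitive; the original spellings are
    retained for display.
    """

    name: str
    preferred_terms: frozenset
    scope: TermScope = TermScope.PT_NARROW

    def __post_init__(self) -> None:
        terms = frozenset(t.strip() for t in self.preferred_terms if t.strip())
        if not terms:
            raise ValueError("term set must contain at least one PT")
        object.__setattr__(self, "preferred_terms", terms)
        object.__setattr__(self, "_folded", frozenset(t.casefold() for t in terms))

    def __contains__(self, pt: str) -> bool:
        return pt.strip().casefold() in self._folded  # type: ignore[attr-defined]

    def folded(self) -> frozenset:
        return self._folded  # type: ignore[attr-defined]


@dataclass(frozen=True)
class RegimenQuery:
    """A drug regimen: a report matches iff it co-reports every required drug.

    Combination regimens (e.g. encorafenib + binimetinib) are expressed
    as multi-drug queries; co-presence on the same report is the
    matching rule, with no date-window logic.  An optional ``role_filter``
    restricts which drug rows count (e.g. suspect roles only).
    """

    name: str
    required_drugs: frozenset
    role_filter: Optional[frozenset] = None

    def __post_init__(self) -> None:
        drugs = frozenset(normalize_drug_name(d) for d in self.required_drugs)
        if not drugs or any(not d for d in drugs):
            raise ConfigurationError("required_drugs must be a non-empty set of names")
        object.__setattr__(self, "required_drugs", drugs)
        if self.role_filter is not None:
            object.__setattr__(
                self, "role_filter", frozenset(DrugRole(r) for r in self.role_filter)
            )


def regimen(name: str, *drugs: str, role_filter: Optional[Iterable] = None) -> RegimenQuery:
    """Convenience constructor: ``regimen("enc+bin", "encorafenib", "binimetinib")``."""
    return RegimenQuery(
        name=name,
        required_drugs=frozenset(drugs) if drugs else frozenset({name}),
        role_filter=frozenset(role_filter) if role_filter is not None else None,
    )


def deduplicate(reports: Sequence[Report]) -> list:
    """Keep, per case, only the report with the highest case version.

    Later submissions win ties; the relative input order of the retained
    reports is preserved.  Idempotent.
    """
    best: dict = {}
    for idx, rep in enumerate(reports):
        kept = best.get(rep.case_id)
        if kept is None or rep.case_version >= kept[1].case_version:
            best[rep.case_id] = (idx, rep)
    return [rep for _, rep in sorted(best.values(), key=lambda t: t[0])]


def match_regimen(report: Report, query: RegimenQuery) -> bool:
    """True iff every required drug of the regimen is on the report.

    With a ``role_filter`` set, only drug rows in the permitted roles
    count toward co-presence.
    """
    if not query.required_drugs:
        raise ConfigurationError("regimen query has no required drugs")
    return query.required_drugs <= report.drug_names(query.role_filter)


def match_event(report: Report, terms: TermSet) -> bool:
    """True iff any reported reaction PT belongs to the term set."""
    folded = terms.folded()
    return any(r.preferred_term.casefold() in folded for r in report.reactions)
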