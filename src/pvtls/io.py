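"""Reading and writing spontaneous-report tables and PT term sets.

Two dialects are supported:

``faers_ascii``
    FAERS quarterly-extract style: ``$``-delimited DEMO/DRUG/REAC/OUTC/THER
    tables with the standard column names (``primaryid``, ``caseid``,
    ``caseversion``, ``occp_cod``, ``age``, ``sex``, ``event_dt``,
    ``start_dt``, ``role_cod``, ``drugname``, ``pt``, ``outc_cod``).
    Files are classified by their headers, so they may be passed in any
    order.  ``event_dt`` from DEMO is used as the onset date of every
    reaction of the report (FAERS carries no per-reaction onset); THER
    start dates are joined per drug via ``drug_seq``/``dsg_drug_seq``
    when present, otherwise the earliest start of the report is assigned
    to all its drugs.

``simple_tabular``
    One headered TSV per entity (``reports``, ``drugs``, ``reactions``)
    mirroring the model fields; produced by the synthetic generator and
    round-trip safe.

Dates follow the FAERS precision fallback (YYYY, YYYYMM, YYYYMMDD);
partial dates are unusable for latency computation and read as missing.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    DrugEntry,
    DrugRole,
    FormatError,
    Outcome,
    ReactionEntry,
    Report,
    ReporterType,
    Sex,
    TermScope,
    TermSet,
)

log = logging.getLogger(__name__)

_ROLE_CODES = {
    "PS": DrugRole.PRIMARY_SUSPECT,
    "SS": DrugRole.SECONDARY_SUSPECT,
    "C": DrugRole.CONCOMITANT,
    "I": DrugRole.INTERACTING,
}
_HCP_OCCUPATIONS = {"MD", "PH", "OT", "HP", "RN"}
_OTHER_OCCUPATIONS = {"CN", "LW"}
_OUTCOME_CODES = {
    "DE": Outcome.DEATH,
    "LT": Outcome.LIFE_THREATENING,
    "HO": Outcome.HOSPITALIZATION,
    "DS": Outcome.DISABILITY,
    "CA": Outcome.OTHER_SERIOUS,
    "RI": Outcome.OTHER_SERIOUS,
    "OT": Outcome.OTHER_SERIOUS,
}
# Age-unit codes -> factor converting to years.
_AGE_UNITS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def parse_faers_date(value: str) -> Optional[dt.date]:
    """Parse a FAERS date field; only full-precision YYYYMMDD yields a date."""
    digits = "".join(ch for ch in str(value).strip() if ch.isdigit())
    if len(digits) != 8:
        return None
    try:
        return dt.date(int(digits[:4]), int(digits[4:6]), int(digits[6:8]))
    except ValueError:
        return None


def faers_date_year(value: str) -> Optional[int]:
    """Year of a FAERS date at any precision (YYYY / YYYYMM / YYYYMMDD)."""
    digits = "".join(ch for ch in str(value).strip() if ch.isdigit())
    if len(digits) not in (4, 6, 8):
        return None
    year = int(digits[:4])
    return year if 1900 <= year <= 2100 else None


def _read_frame(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        warnings.warn(f"empty input file: {path}", stacklevel=3)
        return pd.DataFrame()
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame


def _require(frame: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    for col in columns:
        if col not in frame.columns:
            raise FormatError(f"{table} table is missing mandatory column '{col}'")


def _opt_float(value: str) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _opt_int(value: str) -> Optional[int]:
    try:
        return int(float(value))
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# faers_ascii dialect


def _classify_faers(frames: Sequence[pd.DataFrame]) -> dict:
    out: dict = {}
    for frame in frames:
        cols = set(frame.columns)
        if frame.empty and not cols:
            continue
        if {"drugname", "role_cod"} <= cols:
            out["drug"] = frame
        elif "pt" in cols:
            out["reac"] = frame
        elif "outc_cod" in cols:
            out["outc"] = frame
        elif "start_dt" in cols:
            out["ther"] = frame
        elif {"caseid"} <= cols or {"caseversion"} <= cols or "sex" in cols:
            out["demo"] = frame
    return out


def _read_faers(paths: Sequence) -> list:
    frames = [_read_frame(p, "$") for p in paths]
    tables = _classify_faers(frames)
    if "demo" not in tables:
        if all(f.empty for f in frames):
            return []
        raise FormatError("faers_ascii input has no DEMO table (missing column 'caseid')")
    demo = tables["demo"]
    _require(demo, ["primaryid", "caseid"], "DEMO")

    drugs: dict = {}
    starts: dict = {}
    if "ther" in tables:
        ther = tables["ther"]
        _require(ther, ["primaryid", "start_dt"], "THER")
        for row in ther.itertuples(index=False):
            pid = str(getattr(row, "primaryid"))
            date = parse_faers_date(getattr(row, "start_dt"))
            if date is None:
                continue
            seq = str(getattr(row, "dsg_drug_seq", "")) if "dsg_drug_seq" in ther.columns else ""
            starts.setdefault(pid, []).append((seq, date))
    if "drug" in tables:
        drug = tables["drug"]
        _require(drug, ["primaryid", "drugname", "role_cod"], "DRUG")
        has_seq = "drug_seq" in drug.columns
        for row in drug.itertuples(index=False):
            pid = str(getattr(row, "primaryid"))
            name = str(getattr(row, "drugname")).strip()
            if not name:
                continue
            role = _ROLE_CODES.get(str(getattr(row, "role_cod")).strip().upper(), DrugRole.CONCOMITANT)
            start = None
            per_report = starts.get(pid, [])
            if per_report:
                if has_seq:
                    seq = str(getattr(row, "drug_seq"))
                    matched = [d for s, d in per_report if s == seq]
                    start = min(matched) if matched else None
                if start is None and not has_seq:
                    start = min(d for _, d in per_report)
            drugs.setdefault(pid, []).append(DrugEntry(name=name, role=role, start_date=start))

    reactions: dict = {}
    if "reac" in tables:
        reac = tables["reac"]
        _require(reac, ["primaryid", "pt"], "REAC")
        for row in reac.itertuples(index=False):
            pid = str(getattr(row, "primaryid"))
            pt = str(getattr(row, "pt")).strip()
            if pt:
                reactions.setdefault(pid, []).append(pt)

    outcomes: dict = {}
    if "outc" in tables:
        outc = tables["outc"]
        _require(outc, ["primaryid", "outc_cod"], "OUTC")
        for row in outc.itertuples(index=False):
            pid = str(getattr(row, "primaryid"))
            code = _OUTCOME_CODES.get(str(getattr(row, "outc_cod")).strip().upper())
            if code is not None:
                outcomes.setdefault(pid, set()).add(code)

    reports = []
    demo_cols = set(demo.columns)
    for row in demo.itertuples(index=False):
        pid = str(getattr(row, "primaryid"))
        onset = parse_faers_date(getattr(row, "event_dt")) if "event_dt" in demo_cols else None
        year = quarter = None
        for col in ("rept_dt", "fda_dt", "init_fda_dt", "event_dt"):
            if col in demo_cols:
                year = faers_date_year(getattr(row, col))
                if year is not None:
                    date = parse_faers_date(getattr(row, col))
                    quarter = (date.month - 1) // 3 + 1 if date else None
                    break
        age = _opt_float(getattr(row, "age", "")) if "age" in demo_cols else None
        if age is not None and "age_cod" in demo_cols:
            age *= _AGE_UNITS.get(str(getattr(row, "age_cod")).strip().upper(), 1.0)
        sex_code = str(getattr(row, "sex", "")).strip().upper() if "sex" in demo_cols else ""
        occp = str(getattr(row, "occp_cod", "")).strip().upper() if "occp_cod" in demo_cols else ""
        if occp in _HCP_OCCUPATIONS:
            reporter = ReporterType.HEALTHCARE_PROFESSIONAL
        elif occp in _OTHER_OCCUPATIONS:
            reporter = ReporterType.OTHER
        else:
            reporter = ReporterType.UNKNOWN
        version = _opt_int(getattr(row, "caseversion", "")) if "caseversion" in demo_cols else None
        reports.append(
            Report(
                report_id=pid,
                case_id=str(getattr(row, "caseid")),
                case_version=version if version and version >= 1 else 1,
                report_year=year,
                report_quarter=quarter,
                reporter_type=reporter,
                age_years=age if age is None or age >= 0 else None,
                sex={"M": Sex.MALE, "F": Sex.FEMALE}.get(sex_code, Sex.UNKNOWN),
                outcomes=frozenset(outcomes.get(pid, set())),
                drugs=drugs.get(pid, []),
                reactions=[ReactionEntry(pt, onset_date=onset) for pt in reactions.get(pid, [])],
            )
        )
    log.info("faers_ascii: read %d reports from %d tables", len(reports), len(tables))
    return reports


# ---------------------------------------------------------------------------
# simple_tabular dialect

_REPORT_COLUMNS = [
    "report_id",
    "case_id",
    "case_version",
    "report_year",
    "report_quarter",
    "reporter_type",
    "age_years",
    "sex",
    "outcomes",
    "preexisting_terms",
]
_DRUG_COLUMNS = ["report_id", "name", "role", "start_date"]
_REACTION_COLUMNS = ["report_id", "preferred_term", "onset_date"]


def _iso_date(value: str) -> Optional[dt.date]:
    value = str(value).strip()
    if not value:
        return None
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        return None


def _read_simple(paths: Sequence) -> list:
    reports_frame = drugs_frame = reactions_frame = None
    for path in paths:
        frame = _read_frame(path, "\t")
        cols = set(frame.columns)
        if "case_id" in cols:
            reports_frame = frame
        elif "name" in cols and "role" in cols:
            drugs_frame = frame
        elif "preferred_term" in cols:
            reactions_frame = frame
        elif frame.empty:
            continue
        else:
            raise FormatError(f"unrecognized simple_tabular table with columns {sorted(cols)}")
    if reports_frame is None:
        return []
    _require(reports_frame, _REPORT_COLUMNS, "reports")

    drugs: dict = {}
    if drugs_frame is not None and not drugs_frame.empty:
        _require(drugs_frame, _DRUG_COLUMNS, "drugs")
        for row in drugs_frame.itertuples(index=False):
            name = str(row.name).strip()
            if not name:
                continue
            drugs.setdefault(str(row.report_id), []).append(
                DrugEntry(name=name, role=DrugRole(row.role), start_date=_iso_date(row.start_date))
            )
    reactions: dict = {}
    if reactions_frame is not None and not reactions_frame.empty:
        _require(reactions_frame, _REACTION_COLUMNS, "reactions")
        for row in reactions_frame.itertuples(index=False):
            pt = str(row.preferred_term).strip()
            if not pt:
                continue
            reactions.setdefault(str(row.report_id), []).append(
                ReactionEntry(pt, onset_date=_iso_date(row.onset_date))
            )

    out = []
    for row in reports_frame.itertuples(index=False):
        rid = str(row.report_id)
        out.append(
            Report(
                report_id=rid,
                case_id=str(row.case_id),
                case_version=_opt_int(row.case_version) or 1,
                report_year=_opt_int(row.report_year),
                report_quarter=_opt_int(row.report_quarter),
                reporter_type=ReporterType(row.reporter_type) if row.reporter_type else ReporterType.UNKNOWN,
                age_years=_opt_float(row.age_years),
                sex=Sex(row.sex) if row.sex else Sex.UNKNOWN,
                outcomes=frozenset(Outcome(o) for o in str(row.outcomes).split("|") if o),
                drugs=drugs.get(rid, []),
                reactions=reactions.get(rid, []),
                preexisting_terms=frozenset(
                    t for t in str(row.preexisting_terms).split("|") if t
                ),
            )
        )
    log.info("simple_tabular: read %d reports", len(out))
    return out


def read_reports(paths: Sequence, dialect: str = "simple_tabular") -> list:
    """Read spontaneous reports from delimited tables.

    Parameters
    ----------
    paths
        The table files of the dataset (any order; classified by header).
    dialect
        ``"faers_ascii"`` or ``"simple_tabular"``.
    """
    if dialect == "faers_ascii":
        return _read_faers(paths)
    if dialect == "simple_tabular":
        return _read_simple(paths)
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_simple_tabular(reports: Sequence[Report], out_dir) -> dict:
    """Write reports as the three simple_tabular TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, reac_rows = [], [], []
    for rep in reports:
        rep_rows.append(
            {
                "report_id": rep.report_id,
                "case_id": rep.case_id,
                "case_version": rep.case_version,
                "report_year": "" if rep.report_year is None else rep.report_year,
                "report_quarter": "" if rep.report_quarter is None else rep.report_quarter,
                "reporter_type": rep.reporter_type.value,
                "age_years": "" if rep.age_years is None else repr(rep.age_years),
                "sex": rep.sex.value,
                "outcomes": "|".join(sorted(o.value for o in rep.outcomes)),
                "preexisting_terms": "|".join(sorted(rep.preexisting_terms)),
            }
        )
        for d in rep.drugs:
            drug_rows.append(
                {
                    "report_id": rep.report_id,
                    "name": d.name,
                    "role": d.role.value,
                    "start_date": d.start_date.isoformat() if d.start_date else "",
                }
            )
        for r in rep.reactions:
            reac_rows.append(
                {
                    "report_id": rep.report_id,
                    "preferred_term": r.preferred_term,
                    "onset_date": r.onset_date.isoformat() if r.onset_date else "",
                }
            )
    paths = {
        "reports": out_dir / "reports.tsv",
        "drugs": out_dir / "drugs.tsv",
        "reactions": out_dir / "reactions.tsv",
    }
    pd.DataFrame(rep_rows, columns=_REPORT_COLUMNS).to_csv(paths["reports"], sep="\t", index=False)
    pd.DataFrame(drug_rows, columns=_DRUG_COLUMNS).to_csv(paths["drugs"], sep="\t", index=False)
    pd.DataFrame(reac_rows, columns=_REACTION_COLUMNS).to_csv(paths["reactions"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# term sets


def load_term_set(path) -> TermSet:
    """Load a term set from a plain-text file.

    Format: optional ``name:`` and ``scope:`` header lines, then one PT
    per line; ``#`` starts a comment.
    """
    path = Path(path)
    name = path.stem
    scope = TermScope.PT_NARROW
    terms = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lowered = line.lower()
        if lowered.startswith("name:"):
            name = line.split(":", 1)[1].strip()
        elif lowered.startswith("scope:"):
            scope = TermScope(line.split(":", 1)[1].strip())
        else:
            terms.append(line)
    return TermSet(name=name, preferred_terms=frozenset(terms), scope=scope)


def builtin_term_set(key: str) -> TermSet:
    """Load a packaged term set.

    Keys: ``tls_pt_narrow`` (the single TLS PT), ``tls_smq_broad_synthetic``
    (a synthetic, user-replaceable stand-in for the licensed 39-PT TLS SMQ
    broad list) and ``preexisting_exclusions_default`` (renal dysfunction /
    hyperuricemia history terms used by the indication-bias scenario).
    """
    base = resources.files("pvtls") / "termsets" / f"{key}.txt"
    with resources.as_file(base) as path:
        return load_term_set(path)
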