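"""Demographic/clinical descriptives and full-pipeline orchestration.

``summarize`` produces the characteristics table of the event cases of a
regimen: report-year bins, reporter type, age bins, sex and the
non-exclusive seriousness outcomes, each as (count, percent) with
percents rounded half-up to one decimal.  ``run_full_analysis`` chains
every pipeline stage -- screening, time scan, sensitivity, subgroup and
time-to-onset -- over a set of regimens and writes one machine-readable
table per stage plus a run manifest; reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .io import builtin_term_set, write_simple_tabular
from .model import (
    Outcome,
    RegimenQuery,
    Report,
    ReporterType,
    Sex,
    TermSet,
    deduplicate,
    match_event,
    match_regimen,
)
from .sensitivity import default_scenarios, run_sensitivity
from .signal import evaluate_signal, results_frame, screen, time_scan
from .subgroup import subgroup_by
from .tto import empirical_median, extract_latencies, select_model

YEAR_BINS = (
    ("pre-2006", None, 2005),
    ("2006-2009", 2006, 2009),
    ("2010-2013", 2010, 2013),
    ("2014-2018", 2014, 2018),
    ("2019-2023q3", 2019, 2023),
)
AGE_BINS = (
    ("0-14", 0.0, 15.0),
    ("15-24", 15.0, 25.0),
    ("25-65", 25.0, 66.0),
    (">65", 66.0, float("inf")),
)


def percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal (0.0 for empty totals)."""
    if total == 0:
        return 0.0
    value = Decimal(count * 100) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CharacteristicsSummary:
    """Counts and percents per stratum for the cases of one regimen."""

    regimen: str
    n_reports: int
    strata: dict  # family -> {category: (count, percent)}


def _year_bin(year: Optional[int]) -> str:
    if year is None:
        return "unavailable"
    for label, lo, hi in YEAR_BINS:
        if (lo is None or year >= lo) and year <= hi:
            return label
    return "post-2023"


def _age_bin(age: Optional[float]) -> str:
    if age is None:
        return "unavailable"
    for label, lo, hi in AGE_BINS:
        if lo <= age < hi or (hi == 66.0 and age == 65.0):
            return label
    return "unavailable"


def summarize(
    reports: Sequence[Report], query: RegimenQuery, terms: TermSet
) -> CharacteristicsSummary:
    """Characteristics of the reports matching both regimen and event."""
    cases = [r for r in reports if match_regimen(r, query) and match_event(r, terms)]
    n = len(cases)
    if n == 0:
        warnings.warn(f"no cases for regimen {query.name!r}; summary is empty")
    strata: dict = {}

    year_counts = {label: 0 for label, *_ in YEAR_BINS}
    year_counts["unavailable"] = 0
    for r in cases:
        year_counts[_year_bin(r.report_year)] = year_counts.get(_year_bin(r.report_year), 0) + 1
    strata["report_year"] = {k: (v, percent(v, n)) for k, v in year_counts.items()}

    reporter_counts = {rt.value: 0 for rt in ReporterType}
    for r in cases:
        reporter_counts[r.reporter_type.value] += 1
    strata["reporter"] = {k: (v, percent(v, n)) for k, v in reporter_counts.items()}

    age_counts = {label: 0 for label, *_ in AGE_BINS}
    age_counts["unavailable"] = 0
    for r in cases:
        age_counts[_age_bin(r.age_years)] += 1
    strata["age"] = {k: (v, percent(v, n)) for k, v in age_counts.items()}

    sex_counts = {s.value: 0 for s in Sex}
    for r in cases:
        sex_counts[r.sex.value] += 1
    strata["sex"] = {k: (v, percent(v, n)) for k, v in sex_counts.items()}

    outcome_counts = {o.value: 0 for o in Outcome}
    for r in cases:
        for o in r.outcomes:
            outcome_counts[o.value] += 1
    strata["outcome"] = {k: (v, percent(v, n)) for k, v in outcome_counts.items()}

    return CharacteristicsSummary(regimen=query.name, n_reports=n, strata=strata)


def summary_frame(summary: CharacteristicsSummary) -> pd.DataFrame:
    rows = []
    for family, cats in summary.strata.items():
        for category, (count, pct) in cats.items():
            rows.append(
                {
                    "regimen": summary.regimen,
                    "family": family,
                    "category": category,
                    "count": count,
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows, columns=["regimen", "family", "category", "count", "percent"])


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    regimens: Sequence[RegimenQuery]
    narrow_terms: Optional[TermSet] = None
    broad_terms: Optional[TermSet] = None
    windows: Sequence = (2020, 2021, 2022, 2023)
    subgroup_axes: Sequence[str] = ("age", "sex")
    competitor_drugs: Optional[Sequence[str]] = None
    preexisting_exclusions: Optional[TermSet] = None
    tto_min_n: int = 3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.narrow_terms is None:
            self.narrow_terms = builtin_term_set("tls_pt_narrow")
        if self.broad_terms is None:
            self.broad_terms = builtin_term_set("tls_smq_broad_synthetic")


@dataclass
class RunBundle:
    """All stage outputs of one full run, plus per-regimen errors."""

    signal: pd.DataFrame
    time_scan: pd.DataFrame
    sensitivity: pd.DataFrame
    subgroup: pd.DataFrame
    tto: pd.DataFrame
    descriptives: pd.DataFrame
    errors: dict
    manifest: dict

    @property
    def ok(self) -> bool:
        return not self.errors


def _config_hash(config: AnalysisConfig, n_reports: int) -> str:
    payload = {
        "regimens": sorted(
            (q.name, sorted(q.required_drugs), sorted(r.value for r in q.role_filter or []))
            for q in config.regimens
        ),
        "narrow": sorted(config.narrow_terms.preferred_terms),
        "broad": sorted(config.broad_terms.preferred_terms),
        "windows": [list(w) if isinstance(w, tuple) else w for w in config.windows],
        "subgroup_axes": list(config.subgroup_axes),
        "competitors": sorted(config.competitor_drugs or []),
        "tto_min_n": config.tto_min_n,
        "seed": config.seed,
        "n_reports": n_reports,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_full_analysis(
    reports: Sequence[Report],
    config: AnalysisConfig,
    out_dir=None,
) -> RunBundle:
    """Run every stage for every configured regimen.

    A stage failure for one regimen is recorded in ``errors`` and the
    remaining regimens continue.  With ``out_dir`` set, one TSV per
    stage and a JSON manifest are written; outputs are deterministic
    functions of the inputs.
    """
    reports = deduplicate(reports)
    terms = config.narrow_terms
    errors: dict = {}

    known_drugs = frozenset().union(*(r.drug_names() for r in reports)) if reports else frozenset()
    valid_regimens = []
    for query in config.regimens:
        missing = query.required_drugs - known_drugs
        if missing:
            errors[query.name] = f"ConfigurationError: drugs not in dataset: {sorted(missing)}"
        else:
            valid_regimens.append(query)

    signal_results = screen(reports, valid_regimens, terms)
    signal_df = results_frame(signal_results)

    scan_rows = []
    sens_rows = []
    sub_rows = []
    tto_rows = []
    desc_frames = []
    scenarios = default_scenarios(
        competitor_drugs=config.competitor_drugs,
        excluded_preexisting=config.preexisting_exclusions,
        broad_terms=config.broad_terms,
    )
    for query in valid_regimens:
        try:
            for window, res in time_scan(reports, query, terms, config.windows):
                scan_rows.append(
                    {
                        "regimen": query.name,
                        "window": str(window),
                        "a": res.table.a if res.table else 0,
                        "ic": res.ic,
                        "ic025": res.ic025,
                        "ic975": res.ic975,
                        "significant": res.significant,
                    }
                )
            results, grade = run_sensitivity(reports, query, terms, scenarios)
            for scenario, res in zip(scenarios, results):
                sens_rows.append(
                    {
                        "regimen": query.name,
                        "scenario": scenario.name.value,
                        "a": res.table.a if res.table else 0,
                        "n_regimen": (res.table.a + res.table.b) if res.table else 0,
                        "ic": res.ic,
                        "ic025": res.ic025,
                        "ic975": res.ic975,
                        "significant": res.ic025 > 0,
                    }
                )
            sens_rows.append(
                {
                    "regimen": query.name,
                    "scenario": "robustness",
                    "a": grade.n_significant,
                    "n_regimen": 4,
                    "ic": float("nan"),
                    "ic025": float("nan"),
                    "ic975": float("nan"),
                    "significant": grade.label,
                }
            )
            for axis in config.subgroup_axes:
                res = subgroup_by(reports, query, terms, by=axis)
                sub_rows.append(
                    {
                        "regimen": query.name,
                        "axis": axis,
                        "group_a": res.group_a,
                        "group_b": res.group_b,
                        "ic_a": res.ic_a,
                        "ic_b": res.ic_b,
                        "ic_delta": res.ic_delta,
                        "ic_delta_025": res.ic_delta_025,
                        "ic_delta_975": res.ic_delta_975,
                        "significant": res.significant,
                    }
                )
            samples = extract_latencies(reports, query, terms)
            for drug in sorted(query.required_drugs):
                drug_samples = [s for s in samples if s.drug == drug]
                if len(drug_samples) < config.tto_min_n:
                    continue
                fit = select_model(drug_samples)
                row = {
                    "regimen": query.name,
                    "drug": drug,
                    "n": fit.n,
                    "empirical_median_days": empirical_median(drug_samples),
                    "family": fit.family,
                    "model_median_days": fit.median_days,
                    "aic": fit.aic,
                    "failure_type": fit.failure_type or "",
                }
                for pname, value in fit.params.items():
                    low, high = fit.param_cis[pname]
                    row[pname] = value
                    row[f"{pname}_l"] = low
                    row[f"{pname}_u"] = high
                tto_rows.append(row)
            desc_frames.append(summary_frame(summarize(reports, query, terms)))
        except Exception as exc:  # per-regimen isolation is the contract
            errors[query.name] = f"{type(exc).__name__}: {exc}"

    bundle = RunBundle(
        signal=signal_df,
        time_scan=pd.DataFrame(scan_rows),
        sensitivity=pd.DataFrame(sens_rows),
        subgroup=pd.DataFrame(sub_rows),
        tto=pd.DataFrame(tto_rows),
        descriptives=(
            pd.concat(desc_frames, ignore_index=True) if desc_frames else pd.DataFrame()
        ),
        errors=errors,
        manifest={
            "package_version": __version__,
            "n_reports": len(reports),
            "n_regimens": len(list(config.regimens)),
            "seed": config.seed,
            "config_hash": _config_hash(config, len(reports)),
            "errors": errors,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for stage in ("signal", "time_scan", "sensitivity", "subgroup", "tto", "descriptives"):
            getattr(bundle, stage).to_csv(
                out_dir / f"{stage}.tsv", sep="\t", index=False, float_format="%.6g"
            )
        (out_dir / "manifest.json").write_text(
            json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
        )
    return bundle
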