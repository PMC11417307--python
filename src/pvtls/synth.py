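"""Seeded synthetic spontaneous-report generator with known ground truth.

Emulates a FAERS-like mixture of multi-drug, multi-reaction reports:
each report draws drugs independently from a marginal exposure catalog
(at least one drug enforced by redraw), each event PT is included with
probability ``min(1, baseline * rho)`` where ``rho`` is the largest
relative reporting ratio over matching (drug-set, PT) signal keys --
optionally modified per demographic stratum -- and drug-start/reaction
onset dates are placed so the latency of configured (drug, event)
co-occurrences follows a per-drug parametric law.  Demographics,
reporter type, report year and non-exclusive seriousness outcomes come
from categorical mixes; per-field missingness is applied last.

Everything is driven by a single integer seed: identical configurations
produce identical datasets.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .model import (
    ConfigurationError,
    DrugEntry,
    DrugRole,
    Outcome,
    ReactionEntry,
    Report,
    ReporterType,
    Sex,
    normalize_drug_name,
)

_LATENCY_FAMILIES = ("weibull", "lognormal", "gamma", "exponential")

#: Age-group sampling ranges in years (uniform within the drawn group).
AGE_BIN_RANGES = {
    "0-14": (0.0, 15.0),
    "15-24": (15.0, 25.0),
    "25-65": (25.0, 66.0),
    ">65": (66.0, 90.0),
}


@dataclass(frozen=True)
class LatencyLaw:
    """Parametric latency law for one drug.

    Parameter conventions: weibull ``scale``/``shape``; lognormal
    ``scale`` (= exp(mu)) / ``sigma``; gamma ``shape``/``scale``;
    exponential ``scale``.  All in days.
    """

    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family not in _LATENCY_FAMILIES:
            raise ConfigurationError(f"invalid latency family: {self.family!r}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "weibull":
            return p["scale"] * rng.weibull(p["shape"], size)
        if self.family == "lognormal":
            return rng.lognormal(np.log(p["scale"]), p["sigma"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        return rng.exponential(p["scale"], size)


@dataclass
class Demographics:
    """Categorical mixes; probabilities of each mix must sum to 1."""

    sex: dict = field(
        default_factory=lambda: {Sex.MALE: 0.42, Sex.FEMALE: 0.50, Sex.UNKNOWN: 0.08}
    )
    age_groups: dict = field(
        default_factory=lambda: {"0-14": 0.04, "15-24": 0.06, "25-65": 0.60, ">65": 0.30}
    )
    reporter: dict = field(
        default_factory=lambda: {
            ReporterType.HEALTHCARE_PROFESSIONAL: 0.55,
            ReporterType.OTHER: 0.40,
            ReporterType.UNKNOWN: 0.05,
        }
    )
    report_years: dict = field(
        default_factory=lambda: {y: 1.0 / 20.0 for y in range(2004, 2024)}
    )
    outcomes: dict = field(
        default_factory=lambda: {
            Outcome.DEATH: 0.10,
            Outcome.LIFE_THREATENING: 0.08,
            Outcome.HOSPITALIZATION: 0.35,
            Outcome.DISABILITY: 0.03,
            Outcome.OTHER_SERIOUS: 0.50,
        }
    )


@dataclass
class Missingness:
    """Per-field missing-data probabilities."""

    age: float = 0.10
    sex: float = 0.0  # unknown already part of the sex mix
    dates: float = 0.30


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic report generator."""

    seed: int = 0
    n_reports: int = 10_000
    drug_catalog: dict = field(default_factory=dict)
    co_exposure: dict = field(default_factory=dict)
    event_catalog: dict = field(default_factory=dict)
    signal_matrix: dict = field(default_factory=dict)
    stratum_effects: dict = field(default_factory=dict)
    latency_laws: dict = field(default_factory=dict)
    latency_events: Optional[frozenset] = None
    demographics: Demographics = field(default_factory=Demographics)
    missingness: Missingness = field(default_factory=Missingness)

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        self.drug_catalog = {
            normalize_drug_name(k): float(v) for k, v in self.drug_catalog.items()
        }
        for name, p in {**self.drug_catalog, **self.event_catalog}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability for {name!r} outside [0, 1]")
        co = {}
        for group, p in self.co_exposure.items():
            group = tuple(sorted(normalize_drug_name(d) for d in group))
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"co-exposure probability for {group} outside [0, 1]")
            for d in group:
                if d not in self.drug_catalog:
                    raise ConfigurationError(f"co-exposure drug {d!r} not in drug_catalog")
            co[group] = float(p)
        self.co_exposure = co
        matrix = {}
        for key, rho in self.signal_matrix.items():
            drugs, pt = key
            if isinstance(drugs, str):
                drugs = (drugs,)
            drugs = frozenset(normalize_drug_name(d) for d in drugs)
            if not np.isfinite(rho) or rho < 0:
                raise ConfigurationError(f"rho for {key!r} must be finite and >= 0")
            matrix[(drugs, pt)] = float(rho)
        self.signal_matrix = matrix
        effects = {}
        for key, axes in self.stratum_effects.items():
            drugs, pt = key
            if isinstance(drugs, str):
                drugs = (drugs,)
            effects[(frozenset(normalize_drug_name(d) for d in drugs), pt)] = axes
        self.stratum_effects = effects
        if self.latency_events is not None:
            self.latency_events = frozenset(self.latency_events)


def background_drug_catalog(n_drugs: int = 25, exposure: float = 0.1) -> dict:
    """A block of background co-medications.

    Spontaneous reports typically list several concomitant drugs; a
    background load of ``n_drugs * exposure`` expected drugs per report
    keeps the >=1-drug redraw from materially distorting the marginal
    exposure of the drugs of interest (the redraw conditions on at
    least one drug being present).
    """
    return {f"background{i:02d}": exposure for i in range(n_drugs)}


#: The event of interest used by the calibration/recovery study conditions.
TLS_PT = "Tumour lysis syndrome"


def null_screen_config(seed: int, n_reports: int = 20_000) -> SyntheticConfig:
    """Null study conditions (rho = 1 everywhere) for calibration checks.

    Eight drugs of interest at 1% exposure over a 2.5-drug background
    load, six events spanning rare (2%) to common (8%) baselines, and
    no injected associations: every drug-event pair flagged by the
    joint criterion is a false positive.
    """
    return SyntheticConfig(
        seed=seed,
        n_reports=n_reports,
        drug_catalog={
            **{f"drug{i}": 0.01 for i in range(8)},
            **background_drug_catalog(25, 0.1),
        },
        event_catalog={
            TLS_PT: 0.02,
            "Nausea": 0.08,
            "Rash": 0.05,
            "Headache": 0.06,
            "Pyrexia": 0.04,
            "Fatigue": 0.07,
        },
        signal_matrix={},
    )


def signal_recovery_config(seed: int, rho: float, n_reports: int = 30_000) -> SyntheticConfig:
    """Single injected association of strength ``rho`` for recovery checks.

    One drug of interest at 1% exposure, the event at a 2% baseline and
    a 2.5-drug background load; the expected case-cell count is about
    6*rho, so injected strengths of 2 and above keep it at or above the
    informative >=10 range.
    """
    return SyntheticConfig(
        seed=seed,
        n_reports=n_reports,
        drug_catalog={"drugx": 0.01, **background_drug_catalog(25, 0.1)},
        event_catalog={TLS_PT: 0.02, "Nausea": 0.08, "Rash": 0.05},
        signal_matrix={(("drugx",), TLS_PT): float(rho)},
    )


def default_config(seed: int = 0, n_reports: int = 20_000) -> SyntheticConfig:
    """Desk-scale FAERS-like study conditions.

    Melanoma regimens at ~1% exposure each against a background of
    common co-medications; tumor lysis syndrome at a 2% baseline
    reporting probability (scaled up from its FAERS-wide rarity so that
    expected cell counts are informative at this dataset size); injected
    TLS associations for the combination regimen and the checkpoint
    inhibitors; per-drug Weibull latency laws at their published
    melanoma-regimen values.
    """
    tls = "Tumour lysis syndrome"
    return SyntheticConfig(
        seed=seed,
        n_reports=n_reports,
        drug_catalog={
            # BRAF/MEK inhibitors are almost always co-prescribed; the
            # small marginal exposures cover monotherapy reports and the
            # co_exposure entry the combination regimen.
            "encorafenib": 0.002,
            "binimetinib": 0.002,
            "nivolumab": 0.012,
            "ipilimumab": 0.012,
            "dabrafenib": 0.010,
            "trametinib": 0.010,
            "vemurafenib": 0.010,
            "dacarbazine": 0.008,
            "pembrolizumab": 0.012,
            "venetoclax": 0.008,
            "metformin": 0.10,
            "atorvastatin": 0.10,
            "lisinopril": 0.08,
            "omeprazole": 0.10,
            "paracetamol": 0.12,
            **background_drug_catalog(20, 0.1),
        },
        co_exposure={
            ("encorafenib", "binimetinib"): 0.008,
            ("nivolumab", "ipilimumab"): 0.004,
            ("dabrafenib", "trametinib"): 0.006,
        },
        event_catalog={
            tls: 0.02,
            "Nausea": 0.10,
            "Fatigue": 0.08,
            "Rash": 0.06,
            "Diarrhoea": 0.08,
            "Headache": 0.07,
            "Pyrexia": 0.05,
            "Hyperkalaemia": 0.01,
        },
        signal_matrix={
            (("encorafenib", "binimetinib"), tls): 16.0,
            (("nivolumab",), tls): 4.0,
            (("ipilimumab",), tls): 4.0,
            (("venetoclax",), tls): 8.0,
        },
        latency_laws={
            "binimetinib": LatencyLaw("weibull", {"scale": 1.10, "shape": 0.85}),
            "encorafenib": LatencyLaw("weibull", {"scale": 0.97, "shape": 0.60}),
            "dabrafenib": LatencyLaw("weibull", {"scale": 0.97, "shape": 0.60}),
            "ipilimumab": LatencyLaw("weibull", {"scale": 30.79, "shape": 0.93}),
            "nivolumab": LatencyLaw("weibull", {"scale": 30.60, "shape": 1.28}),
        },
        latency_events=frozenset({tls}),
    )


def _choice(rng: np.random.Generator, categories: dict, size: int) -> np.ndarray:
    keys = list(categories.keys())
    probs = np.asarray(list(categories.values()), dtype=float)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ConfigurationError(f"categorical mix sums to {total}, expected 1")
    return rng.choice(len(keys), size=size, p=probs / total)


def generate(config: SyntheticConfig) -> list:
    """Generate a seeded synthetic dataset of spontaneous reports."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = sorted(config.drug_catalog)
    if not drug_names:
        raise ConfigurationError("drug_catalog must not be empty")
    drug_idx = {d: i for i, d in enumerate(drug_names)}
    drug_probs = np.array([config.drug_catalog[d] for d in drug_names])

    # Drug exposure; co-prescribed groups (e.g. a combination regimen)
    # are OR-ed in jointly, then every report must list at least one
    # drug (redraw of the independent part).
    exposure = rng.random((n, len(drug_names))) < drug_probs
    for group in sorted(config.co_exposure):
        joint = rng.random(n) < config.co_exposure[group]
        for d in group:
            exposure[joint, drug_idx[d]] = True
    empty = ~exposure.any(axis=1)
    tries = 0
    while empty.any():
        exposure[empty] = rng.random((int(empty.sum()), len(drug_names))) < drug_probs
        empty = ~exposure.any(axis=1)
        tries += 1
        if tries > 100_000:
            raise ConfigurationError("cannot satisfy >=1 drug per report; exposure probs too small")

    # Demographics.
    demo = config.demographics
    sex_keys = list(demo.sex.keys())
    sex_draw = _choice(rng, demo.sex, n)
    age_keys = list(demo.age_groups.keys())
    age_group_draw = _choice(rng, demo.age_groups, n)
    age_lo = np.array([AGE_BIN_RANGES[k][0] for k in age_keys])
    age_hi = np.array([AGE_BIN_RANGES[k][1] for k in age_keys])
    ages = age_lo[age_group_draw] + rng.random(n) * (
        age_hi[age_group_draw] - age_lo[age_group_draw]
    )
    reporter_keys = list(demo.reporter.keys())
    reporter_draw = _choice(rng, demo.reporter, n)
    year_keys = list(demo.report_years.keys())
    year_draw = _choice(rng, demo.report_years, n)
    quarters = rng.integers(1, 5, size=n)
    outcome_flags = {
        o: rng.random(n) < p for o, p in sorted(demo.outcomes.items(), key=lambda t: t[0].value)
    }

    # Per-report stratum categories for effect modification.
    sex_values = np.array([sex_keys[i].value for i in sex_draw])
    age_group_values = np.array([age_keys[i] for i in age_group_draw])

    # Events.
    event_names = sorted(config.event_catalog)
    events = np.zeros((n, len(event_names)), dtype=bool)
    key_masks = {
        drugs: exposure[:, [drug_idx[d] for d in drugs if d in drug_idx]].all(axis=1)
        if all(d in drug_idx for d in drugs)
        else np.zeros(n, dtype=bool)
        for drugs in {k[0] for k in config.signal_matrix}
    }
    for j, pt in enumerate(event_names):
        factor = np.ones(n)
        for (drugs, key_pt), rho in sorted(
            config.signal_matrix.items(), key=lambda kv: (sorted(kv[0][0]), kv[0][1])
        ):
            if key_pt != pt:
                continue
            mult = np.full(n, rho)
            axes = config.stratum_effects.get((drugs, key_pt), {})
            for axis, table in axes.items():
                values = sex_values if axis == "sex" else age_group_values
                axis_mult = np.array([table.get(v, 1.0) for v in values])
                mult = mult * axis_mult
            factor = np.where(key_masks[drugs], np.maximum(factor, mult), factor)
        p_eff = config.event_catalog[pt] * factor
        if np.any(p_eff > 1.0):
            warnings.warn(f"event probability for {pt!r} clamped to 1 after scaling")
            p_eff = np.clip(p_eff, 0.0, 1.0)
        events[:, j] = rng.random(n) < p_eff

    # Latency-bearing dates for configured (drug, event) co-occurrences.
    if config.latency_events is None:
        relevant_event = events.any(axis=1)
    else:
        cols = [j for j, pt in enumerate(event_names) if pt in config.latency_events]
        relevant_event = events[:, cols].any(axis=1) if cols else np.zeros(n, dtype=bool)
    date_missing = rng.random(n) < config.missingness.dates
    start_days: dict = {}
    for drug in sorted(config.latency_laws):
        if drug not in drug_idx:
            continue
        mask = exposure[:, drug_idx[drug]] & relevant_event
        idx = np.nonzero(mask)[0]
        if idx.size:
            lat = config.latency_laws[drug].sample(idx.size, rng)
            start_days[drug] = dict(zip(idx.tolist(), np.rint(lat).astype(int).tolist()))

    age_missing = rng.random(n) < config.missingness.age
    sex_missing = rng.random(n) < config.missingness.sex

    reports = []
    outcome_keys = list(outcome_flags.keys())
    for i in range(n):
        year = int(year_keys[year_draw[i]])
        quarter = int(quarters[i])
        onset = dt.date(year, 3 * quarter - 2, 15)
        has_dates = relevant_event[i] and not date_missing[i]
        drugs = []
        for d in drug_names:
            if not exposure[i, drug_idx[d]]:
                continue
            start = None
            if has_dates and d in start_days and i in start_days[d]:
                start = onset - dt.timedelta(days=start_days[d][i])
            drugs.append(DrugEntry(name=d, role=DrugRole.PRIMARY_SUSPECT, start_date=start))
        reactions = [
            ReactionEntry(pt, onset_date=onset if has_dates else None)
            for j, pt in enumerate(event_names)
            if events[i, j]
        ]
        reports.append(
            Report(
                report_id=f"S{config.seed}-{i:07d}",
                case_id=f"S{config.seed}-{i:07d}",
                case_version=1,
                report_year=year,
                report_quarter=quarter,
                reporter_type=reporter_keys[reporter_draw[i]],
                age_years=None if age_missing[i] else round(float(ages[i]), 1),
                sex=Sex.UNKNOWN if sex_missing[i] else sex_keys[sex_draw[i]],
                outcomes=frozenset(o for o in outcome_keys if outcome_flags[o][i]),
                drugs=drugs,
                reactions=reactions,
            )
        )
    return reports


def make_case_series_fixture() -> list:
    """Deterministic 33-report fixture for the encorafenib + binimetinib
    regimen with fixed demographic margins.

    Margins: report years 0/0/4/29 over the bins 2006-2009 / 2010-2013 /
    2014-2018 / 2019-2023q3; reporters 21 healthcare professionals and
    12 other; ages 21 in 25-65, 5 over 65, 7 unavailable; sex 8 male,
    15 female, 10 unknown; non-exclusive outcomes 3 death, 0 disability,
    20 hospitalization, 5 life-threatening, 30 other-serious.  Every
    report carries the TLS reaction with start/onset dates whose
    latencies have median 2.0 days.
    """
    years = [2015, 2016, 2017, 2018] + [2019] * 5 + [2020] * 6 + [2021] * 6 + [2022] * 6 + [2023] * 6
    ages: list = [
        34.0, 41.0, 47.0, 52.0, 58.0, 63.0, 29.0, 36.0, 44.0, 50.0, 55.0,
        61.0, 27.0, 38.0, 45.0, 53.0, 59.0, 64.0, 31.0, 42.0, 49.0,
        68.0, 71.0, 74.0, 77.0, 80.0,
    ] + [None] * 7
    latencies = ([1, 2, 3] * 11)[:33]
    reports = []
    for i in range(33):
        year = years[i]
        start = dt.date(year, 6, 1)
        onset = start + dt.timedelta(days=latencies[i])
        outcomes = set()
        if i < 3:
            outcomes.add(Outcome.DEATH)
        if i < 20:
            outcomes.add(Outcome.HOSPITALIZATION)
        if 3 <= i < 8:
            outcomes.add(Outcome.LIFE_THREATENING)
        if i < 30:
            outcomes.add(Outcome.OTHER_SERIOUS)
        reports.append(
            Report(
                report_id=f"EB{i:04d}",
                case_id=f"EB{i:04d}",
                case_version=1,
                report_year=year,
                report_quarter=(i % 4) + 1,
                reporter_type=(
                    ReporterType.HEALTHCARE_PROFESSIONAL if i < 21 else ReporterType.OTHER
                ),
                age_years=ages[i],
                sex=Sex.MALE if i < 8 else (Sex.FEMALE if i < 23 else Sex.UNKNOWN),
                outcomes=frozenset(outcomes),
                drugs=[
                    DrugEntry("encorafenib", DrugRole.PRIMARY_SUSPECT, start_date=start),
                    DrugEntry("binimetinib", DrugRole.SECONDARY_SUSPECT, start_date=start),
                ],
                reactions=[ReactionEntry("Tumour lysis syndrome", onset_date=onset)],
            )
        )
    return reports
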