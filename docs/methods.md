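# Methods

## Data model and ingestion

A spontaneous report carries demographics (age in years, sex, reporter
type), a report year/quarter, non-exclusive seriousness outcomes, a list
of drug rows (normalized ingredient name, FAERS role code, optional start
date), reaction rows (MedDRA Preferred Term, optional onset date) and a
set of medical-history PTs. Cases may be submitted repeatedly; analyses
run on the deduplicated set keeping, per case identifier, the highest
case version (later submissions win ties, input order otherwise
preserved — the operation is idempotent).

Drug names are normalized by case-folding, whitespace collapsing,
trailing salt-suffix stripping and a small packaged brand→ingredient
synonym table; FAERS verbatim names are noisy and all analyses operate
at ingredient level. Combination regimens match by co-presence of every
required drug on the same report, with no date-window logic; an optional
role filter restricts which drug rows count (used by the suspect-role
sensitivity scenario). Dates follow the FAERS precision fallback (YYYY,
YYYYMM, YYYYMMDD); partial dates are unusable for latency and read as
missing. Unknown reporter, sex or age is kept as an explicit unknown
category, never silently dropped, except where a stage states otherwise
(subgroup strata exclude unknowns by construction).

In the `faers_ascii` dialect, DEMO's `event_dt` serves as the onset date
of every reaction of the report (FAERS has no per-reaction onset), and
THER start dates join per drug via `drug_seq`/`dsg_drug_seq` when those
columns exist, otherwise the earliest start of the report is assigned to
all its drugs.

## Disproportionality

The case/non-case table (a, b, c, d) uses all other drugs in the dataset
as comparator. ROR = ad/bc with the Woolf (log-normal) 95% CI; any zero
cell triggers the classical +0.5 continuity correction of all four cells
and the result is flagged (this preserves rows in summary tables rather
than dropping them; correction can be disabled, in which case a zero
cell yields an undefined result with a reason code). The IC is the
shrinkage form IC = log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/n, with the
published asymmetric credibility-interval approximation (coefficients
3.3 and 2.0 below, 2.4 and 0.5 above, on (a+0.5)^−½ and (a+0.5)^−³ᐟ²).
These are the de-facto standard frequentist and Bayesian estimators of
the signal-detection literature; users comparing against other IC
variants (full-posterior BCPNN, EBGM) should expect small interval
differences — those variants are deliberately out of scope.

The joint criterion (ROR₀₂₅ > 1 AND IC₀₂₅ > 0) declares a signal. The
yearly time scan evaluates the signal on the cumulative dataset up to
each window end by default; a per-period mode is available behind a flag
since either construction is defensible for surveillance plots.

## Sensitivity scenarios and robustness

The four scenarios are applied independently (not stacked), mirroring
how such columns are usually reported side by side:

1. **competition_bias** — drop event-positive reports co-listing a
   configured competitor drug. The competitor list ships as
   configuration (default: venetoclax-class and other literature-known
   TLS-associated drugs) because "any other drug" would empty the
   dataset; regimen drugs are always exempt.
2. **suspect_and_hcp** — healthcare-professional reports only, and only
   suspect-role (primary/secondary) drug rows count toward the regimen.
3. **smq_broad** — the narrow PT definition is replaced by the broad
   SMQ-style list. The packaged 39-PT list is an explicitly *synthetic*
   placeholder (the licensed MedDRA SMQ export cannot be redistributed)
   and is user-replaceable via a plain-text term-set file.
4. **preexisting_excluded** — drop reports whose medical history
   intersects the exclusion list (default: renal dysfunction and
   hyperuricemia terms; configurable).

Robustness counts scenarios with IC₀₂₅ > 0: 4 → strong, 3 →
intermediate, ≤2 → weak. The mapping of 2/4 to weak is an extrapolation
beyond the grades observed in published tables (4/4, 3/4, 1/4) and is
noted here for that reason.

## Subgroup ICΔ

Strata (male vs female; age ≤65 vs >65, cutoff configurable) each build
their own case/non-case table — the comparator is other drugs *within
the stratum* — and ICΔ = IC_a − IC_b. The variance of each stratum's IC
is approximated by the delta method on the shrunk observed count,
v = (1/ln 2)²/(a + 0.5), and the 95% CI is ICΔ ± 1.96·√(v_a + v_b);
strata are independent so variances add. This approximation matches the
CI-width behaviour of the IC interval above; no single canonical ICΔ
variance exists in the methods literature, so the formula is stated
prominently rather than hidden. The sign convention is explicit in every
result (defaults: male − female, ≤65 − >65). Reports with unknown sex or
age are excluded from both strata. A stratum with a zero case cell still
yields a CI through the shrinkage but the result is flagged unstable.

## Time-to-onset

Latency = onset − start in days, per regimen drug, for deduplicated
reports matching regimen and event. Negative latencies are excluded;
same-day onsets map to 0.5 days because every candidate family needs
positive support (an exclusion mode exists behind a flag). No censoring
or truncation adjustment is attempted — observed latencies only.

Four families are fitted by maximum likelihood (exponential closed form;
log-normal closed form; Weibull and gamma via the scipy fixed-location
MLE). Parameter 95% CIs come from the numerically observed information
of the *log*-parameters (central differences, step 1e-4), guaranteeing
positive bounds. Model selection minimizes AIC = 2k − 2ℓ; ties break
toward fewer parameters, then the fixed order exponential, Weibull,
gamma, log-normal. Anderson–Darling statistics against each fitted law
are reported as diagnostics but never drive selection — AIC is
reproducible and likelihood-based across non-nested families, whereas
"the best goodness-of-fit statistic" is not a single criterion. The
Weibull failure type is random when the β CI contains 1, else early
(β < 1) or wear-out (β > 1). Both the empirical median (midpoint rule
for even n) and the fitted median (the model's quantile function;
α·(ln 2)^(1/β) for Weibull) are reported, since either may be meant by a
published "median days".

## Synthetic generator

The generator emulates FAERS-like structure with known ground truth:

- **Drugs** drawn independently per report from marginal exposure
  probabilities, plus optional *co-exposure groups* (a combination
  regimen such as a BRAF/MEK pair is co-prescribed in reality, and
  independent draws would make its co-occurrence quadratically rare);
  at least one drug per report is enforced by redrawing empty rows,
  which is why a realistic background load of ~2.5 concomitant drugs
  per report matters — with a sparse catalog the redraw would visibly
  inflate the marginal exposures of the drugs of interest.
- **Events** included with probability min(1, baseline × ρ), ρ being
  the *maximum* relative reporting ratio over matching (drug-set, PT)
  signal keys (maximum, not product, keeps probabilities interpretable
  when keys overlap), optionally modified per demographic stratum
  (`stratum_effects`) to inject subgroup-specific over-reporting.
- **Latency**: when a drug with a configured law co-occurs with a
  latency-relevant event, the reaction onset is anchored to the report
  period and the drug start set so that onset − start follows the law
  (rounded to whole days, as date arithmetic demands); other dates stay
  missing, matching FAERS sparsity.
- **Demographics** from categorical mixes (sex, age group with uniform
  age within group, reporter, report year, independent non-exclusive
  outcome flags) and per-field missingness applied last.

Identical configurations and seeds yield identical datasets.

### Study conditions

The packaged conditions are desk-scale choices made once:

- `null_screen_config`: 20 000 reports, eight drugs of interest at 1%
  exposure, six events with 2–8% baselines, no injected associations.
- `signal_recovery_config`: 30 000 reports, one drug at 1% exposure,
  the event at a 2% baseline, one injected ρ. The 2% TLS baseline is
  scaled up from the event's FAERS-wide rarity (~5·10⁻⁴) so the
  expected case cell (≈6ρ) is informative at this dataset size; the 1%
  exposure keeps the background contamination of the expected count
  small enough that IC ≈ log₂ρ holds to within a few tenths of a bit.
- Latency laws default to the published per-drug Weibull fits for the
  melanoma regimens (e.g. nivolumab scale 30.60 d, shape 1.28).

What passing tests on these data do **not** show: real FAERS reporting
dynamics (stimulated reporting, the Weber effect, duplicate submissions
beyond case versioning, verbatim-to-PT coding noise, masking by the
full drug universe) are not modelled, so calibration and recovery
results demonstrate correctness of the estimators, not performance on
the real database. Headline database-wide statistics are likewise not
reproducible at desk scale because the full curated extract's margins
are not public.

The packaged 33-report combination-regimen fixture fixes its
demographic margins to the published characteristics column of the
encorafenib + binimetinib TLS case series (the published sex row is
internally inconsistent — its counts sum to 30 of 33 — so the fixture
assigns the three unaccounted reports to unknown sex, leaving every
printed numerator intact).

## Numerical choices and degenerate inputs

- Percents in characteristics tables round half-up to one decimal
  (`Decimal` arithmetic, matching how published tables round).
- Empty report lists yield all-zero tables with a warning, never an
  exception; all-zero tables are never significant.
- IC is finite for every table thanks to the +0.5 shrinkage, including
  a = E = 0 (IC = 0).
- Fits refuse n < 3; non-convergence raises with diagnostics rather
  than returning garbage.
- Seeds below 2³¹ everywhere; replicate streams derive from
  `numpy.random.SeedSequence.spawn`.

## Known limitations

- The ICΔ variance is an approximation; alternative two-group detectors
  (relative ROR, OR-based) are not implemented.
- No EBGM/MGPS or full-posterior BCPNN.
- The SMQ-broad term list is a synthetic stand-in until the user
  supplies a licensed export.
- Time-to-onset fits ignore reporting-delay censoring, which biases
  latency laws toward shorter onsets for recently approved drugs.
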