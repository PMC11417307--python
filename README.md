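# pvtls

Pharmacovigilance signal analysis of **tumor lysis syndrome (TLS)** with
melanoma drug regimens on FAERS-style spontaneous adverse-event reports.

TLS is a metabolic emergency (hyperuricemia, hyperkalemia, hypocalcemia,
hyperphosphatemia) triggered by rapid tumor-cell breakdown under effective
anticancer therapy. Spontaneous-report databases such as FAERS allow
screening for disproportionate TLS reporting with specific regimens —
including co-reported combinations like encorafenib + binimetinib — long
before dedicated studies exist. `pvtls` packages that analysis end to end
for epidemiologists and drug-safety scientists: report ingestion and
deduplication, case/non-case disproportionality, sensitivity scenarios
with robustness grading, subgroup comparisons, and parametric
time-to-onset modelling, plus a seeded synthetic report generator so the
whole pipeline is testable without any database download.

## Methods at a glance

For a regimen *R* and event definition *E*, reports are cross-classified
into the case/non-case 2×2 table (a, b, c, d) with "all other drugs" as
comparator, and two disproportionality statistics are computed:

- **Reporting odds ratio**: ROR = ad/bc with the Woolf 95% CI
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); any zero cell triggers a
  flagged +0.5 continuity correction.
- **Information component** (Bayesian shrinkage):
  IC = log₂((a + 0.5)/(E[a] + 0.5)) with E[a] = (a+b)(a+c)/n, and the
  asymmetric interval IC₀₂₅ = IC − 3.3(a+0.5)^−½ − 2(a+0.5)^−³ᐟ²,
  IC₉₇₅ = IC + 2.4(a+0.5)^−½ + 0.5(a+0.5)^−³ᐟ².

A pair is a **signal** when ROR₀₂₅ > 1 and IC₀₂₅ > 0. Four sensitivity
scenarios (competition-bias removal, suspect-role + healthcare-professional
restriction, SMQ-broad event definition, pre-existing-disease exclusion)
re-evaluate the signal; robustness is graded strong (4/4 scenarios with
IC₀₂₅ > 0), intermediate (3/4) or weak (≤2/4). Subgroup over-reporting
(male vs female, age ≤65 vs >65) uses ICΔ = IC_a − IC_b with
CI = ICΔ ± 1.96·√(v_a + v_b), v = (1/ln 2)²/(a + 0.5) per stratum.
Time-to-onset (days from drug start to reaction onset) is fitted by
maximum likelihood under Weibull, log-normal, gamma and exponential laws,
selected by AIC; the Weibull shape β classifies the hazard (β < 1 early
failure, CI ∋ 1 random, β > 1 wear-out), and the Weibull median is
α·(ln 2)^(1/β).

## Worked example

Generate a 20 000-report synthetic dataset (seeded, with a known injected
TLS association for the combination regimen) and screen three regimens:

```sh
pvtls synth --out demo --seed 7 --n-reports 20000
pvtls signal --data demo \
    --regimen "encorafenib+binimetinib=encorafenib+binimetinib" \
    --regimen nivolumab --regimen dacarbazine
```

```text
regimen                  event_set      a   n_regimen  ror     ror_l   ror_u  ic      ic025   ic975  significant
encorafenib+binimetinib  tls_pt_narrow  37  136        15.77   10.69   23.26  3.273   2.725   3.667  True
nivolumab                tls_pt_narrow  26  312        3.709   2.457   5.599  1.683   1.027   2.153  True
dacarbazine              tls_pt_narrow  2   176        0.4488  0.111   1.814  -0.9631 -3.556  0.6813 False
```

The combination regimen (generator ground truth: a 16-fold TLS reporting
ratio) is flagged with IC₀₂₅ = 2.7 bits; dacarbazine, with no injected
association and only 2 co-reports, is not. The four sensitivity scenarios
keep the combination signal:

```sh
pvtls sensitivity --data demo --regimen "encorafenib+binimetinib=encorafenib+binimetinib"
```

```text
tls_pt_narrow            36/135  ic=3.306  ic025=2.751
tls_pt_narrow            22/69   ic=3.260  ic025=2.546
tls_smq_broad_synthetic  40/136  ic=2.969  ic025=2.443
tls_pt_narrow            37/136  ic=3.273  ic025=2.725
robustness  4/4  strong
```

and the latency of TLS with nivolumab (generated from a Weibull with a
30.6-day scale) is recovered with a ~25-day median:

```text
nivolumab  n=17  median=25.0d  exponential  scale=29.1 (18.1-46.7)  model_median=20.14d
```

`pvtls run --data demo --regimen ... --out results/` executes every stage
and writes one TSV per stage plus a JSON manifest; reruns are
byte-identical.

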