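import pytest

from pvtls import (
    ConfigurationError,
    DrugRole,
    ReporterType,
    ScenarioName,
    SensitivityScenario,
    SignalResult,
    TermSet,
    apply_scenario,
    grade_robustness,
    match_regimen,
    regimen,
    run_sensitivity,
)
from pvtls.model import DrugEntry

from conftest import mk_report

TLS = "Tumour lysis syndrome"
TERMS = TermSet("tls", frozenset({TLS}))
QUERY = regimen("enc+bin", "encorafenib", "binimetinib")


def _sig(ic025):
    return SignalResult(ic025=ic025)


class TestCompetitionBias:
    def test_event_reports_with_competitor_are_dropped(self):
        # 5 event reports, 2 list the competitor -> 3 remain (plus the
        # event-free report, which competition never removes)
        reports = [
            mk_report(0, drugs=["encorafenib", "binimetinib"], reactions=[TLS]),
            mk_report(1, drugs=["encorafenib", "binimetinib", "venetoclax"], reactions=[TLS]),
            mk_report(2, drugs=["other", "venetoclax"], reactions=[TLS]),
            mk_report(3, drugs=["other"], reactions=[TLS]),
            mk_report(4, drugs=["other"], reactions=[TLS]),
            mk_report(5, drugs=["venetoclax"]),
        ]
        scenario = SensitivityScenario(
            ScenarioName.COMPETITION_BIAS, competitor_drugs=frozenset({"venetoclax"})
        )
        kept, terms, query = apply_scenario(reports, scenario, QUERY, TERMS)
        assert {r.report_id for r in kept} == {"r0", "r3", "r4", "r5"}
        assert terms is TERMS and query is QUERY

    def test_empty_competitor_list_is_identity(self):
        reports = [mk_report(0, drugs=["venetoclax"], reactions=[TLS])]
        scenario = SensitivityScenario(
            ScenarioName.COMPETITION_BIAS, competitor_drugs=frozenset()
        )
        kept, _, _ = apply_scenario(reports, scenario, QUERY, TERMS)
        assert kept == reports

    def test_regimen_drugs_are_exempt_competitors(self):
        reports = [mk_report(0, drugs=["encorafenib", "binimetinib"], reactions=[TLS])]
        scenario = SensitivityScenario(
            ScenarioName.COMPETITION_BIAS,
            competitor_drugs=frozenset({"encorafenib", "binimetinib"}),
        )
        kept, _, _ = apply_scenario(reports, scenario, QUERY, TERMS)
        assert kept == reports


class TestSuspectAndHcp:
    def test_consumer_report_excluded_and_roles_restricted(self):
        hcp = mk_report(
            0,
            drugs=[DrugEntry("encorafenib"), DrugEntry("binimetinib", DrugRole.CONCOMITANT)],
            reactions=[TLS],
            reporter=ReporterType.HEALTHCARE_PROFESSIONAL,
        )
        consumer = mk_report(
            1, drugs=["encorafenib", "binimetinib"], reactions=[TLS],
            reporter=ReporterType.OTHER,
        )
        scenario = SensitivityScenario(ScenarioName.SUSPECT_AND_HCP)
        kept, _, query = apply_scenario([hcp, consumer], scenario, QUERY, TERMS)
        assert [r.report_id for r in kept] == ["r0"]
        # the concomitant binimetinib row no longer satisfies the regimen
        assert not match_regimen(hcp, query)


class TestSmqBroadAndPreexisting:
    def test_smq_broad_replaces_terms(self, smq_terms):
        scenario = SensitivityScenario(ScenarioName.SMQ_BROAD, broad_terms=smq_terms)
        kept, terms, _ = apply_scenario([mk_report(0, drugs=["a"])], scenario, QUERY, TERMS)
        assert terms is smq_terms
        assert "Hyperkalaemia" in terms

    def test_preexisting_disease_reports_dropped(self):
        exclusion = TermSet("excl", frozenset({"Hyperuricaemia", "Renal failure"}))
        reports = [
            mk_report(0, drugs=["a"], preexisting=["Hyperuricaemia"]),
            mk_report(1, drugs=["a"], preexisting=["Diabetes mellitus"]),
            mk_report(2, drugs=["a"]),
        ]
        scenario = SensitivityScenario(
            ScenarioName.PREEXISTING_EXCLUDED, excluded_preexisting=exclusion
        )
        kept, _, _ = apply_scenario(reports, scenario, QUERY, TERMS)
        assert {r.report_id for r in kept} == {"r1", "r2"}

    def test_scenario_field_validation(self):
        with pytest.raises(ConfigurationError):
            SensitivityScenario(
                ScenarioName.SMQ_BROAD, competitor_drugs=frozenset({"venetoclax"})
            )


class TestFilterProperties:
    def test_outputs_are_subsets_of_inputs(self, smq_terms):
        reports = [
            mk_report(i, drugs=["encorafenib", "binimetinib"], reactions=[TLS],
                      reporter=ReporterType.HEALTHCARE_PROFESSIONAL if i % 2 else ReporterType.OTHER,
                      preexisting=["Gout"] if i % 3 == 0 else ())
            for i in range(12)
        ]
        ids = {r.report_id for r in reports}
        from pvtls.sensitivity import default_scenarios

        for scenario in default_scenarios(broad_terms=smq_terms):
            kept, _, _ = apply_scenario(reports, scenario, QUERY, TERMS)
            assert {r.report_id for r in kept} <= ids

    def test_run_sensitivity_returns_four_results_and_grade(self, smq_terms):
        reports = [
            mk_report(i, drugs=["encorafenib", "binimetinib"], reactions=[TLS],
                      reporter=ReporterType.HEALTHCARE_PROFESSIONAL)
            for i in range(10)
        ] + [mk_report(100 + i, drugs=["other"]) for i in range(50)]
        results, grade = run_sensitivity(reports, QUERY, TERMS)
        assert len(results) == 4
        assert grade.label == ("strong" if grade.n_significant == 4 else grade.label)


class TestGradeRobustness:
    def test_published_combination_row_grades_strong(self):
        # IC025 per scenario: 3.25, 3.05, 6.96, 3.06 -> 4/4
        grade = grade_robustness([_sig(3.25), _sig(3.05), _sig(6.96), _sig(3.06)])
        assert grade.n_significant == 4
        assert grade.label == "strong"

    def test_published_single_agent_row_grades_intermediate(self):
        # IC025 per scenario: -1.86, 0.49, 7.43, 0.49 -> 3/4
        grade = grade_robustness([_sig(-1.86), _sig(0.49), _sig(7.43), _sig(0.49)])
        assert grade.n_significant == 3
        assert grade.label == "intermediate"

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_low_counts_grade_weak(self, n):
        values = [0.5] * n + [-0.5] * (4 - n)
        assert grade_robustness([_sig(v) for v in values]).label == "weak"

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            grade_robustness([_sig(1.0)] * 3)
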