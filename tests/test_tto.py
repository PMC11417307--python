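import datetime as dt
import math

import numpy as np
import pytest

from pvtls import TermSet, classify_failure_type, fit_family, regimen, select_model
from pvtls.model import DrugEntry, ReactionEntry
from pvtls.tto import (
    TTOFit,
    anderson_darling,
    empirical_median,
    extract_latencies,
    FitError,
)

from conftest import mk_report

TLS = "Tumour lysis syndrome"
TERMS = TermSet("tls", frozenset({TLS}))
QUERY = regimen("drugx")

SIX_POINTS = [1.2, 3.4, 0.7, 9.8, 4.1, 2.0]


def _dated_report(i, start, onset):
    return mk_report(
        i,
        drugs=[DrugEntry("drugx", start_date=start)],
        reactions=[ReactionEntry(TLS, onset_date=onset)],
    )


class TestExtractLatencies:
    def test_date_arithmetic(self):
        rep = _dated_report(0, dt.date(2021, 3, 1), dt.date(2021, 3, 3))
        [sample] = extract_latencies([rep], QUERY, TERMS)
        assert sample.days == 2.0
        assert sample.drug == "drugx"

    def test_onset_before_start_excluded(self):
        rep = _dated_report(0, dt.date(2021, 3, 10), dt.date(2021, 3, 3))
        assert extract_latencies([rep], QUERY, TERMS) == []

    def test_same_day_onset_maps_to_half_day(self):
        rep = _dated_report(0, dt.date(2021, 3, 1), dt.date(2021, 3, 1))
        [sample] = extract_latencies([rep], QUERY, TERMS)
        assert sample.days == 0.5
        assert extract_latencies([rep], QUERY, TERMS, zero_day="exclude") == []

    def test_missing_dates_skipped(self):
        rep = mk_report(0, drugs=["drugx"], reactions=[TLS])
        assert extract_latencies([rep], QUERY, TERMS) == []

    def test_non_regimen_drugs_ignored(self):
        rep = mk_report(
            0,
            drugs=[
                DrugEntry("drugx", start_date=dt.date(2021, 3, 1)),
                DrugEntry("other", start_date=dt.date(2021, 1, 1)),
            ],
            reactions=[ReactionEntry(TLS, onset_date=dt.date(2021, 3, 4))],
        )
        samples = extract_latencies([rep], QUERY, TERMS)
        assert [s.days for s in samples] == [3.0]


class TestFitFamily:
    def test_exponential_data_weibull_shape_ci_contains_one(self):
        rng = np.random.default_rng(5)
        fit = fit_family(rng.exponential(10.0, 2000), "weibull")
        low, high = fit.param_cis["shape"]
        assert low < 1.0 < high
        assert classify_failure_type(fit) == "random"

    def test_weibull_mle_matches_grid_search_oracle(self):
        # independent brute-force maximization of the Weibull likelihood
        fit = fit_family(SIX_POINTS, "weibull")
        x = np.asarray(SIX_POINTS)

        def loglik(scale, shape):
            return float(
                len(x) * (math.log(shape) - shape * math.log(scale))
                + (shape - 1) * np.sum(np.log(x))
                - np.sum((x / scale) ** shape)
            )

        scales = np.linspace(0.5, 15.0, 400)
        shapes = np.linspace(0.2, 5.0, 400)
        best = max(
            ((loglik(a, b), a, b) for a in scales for b in shapes), key=lambda t: t[0]
        )
        # refine around the coarse optimum
        scales = np.linspace(best[1] - 0.1, best[1] + 0.1, 200)
        shapes = np.linspace(best[2] - 0.05, best[2] + 0.05, 200)
        best = max(
            ((loglik(a, b), a, b) for a in scales for b in shapes), key=lambda t: t[0]
        )
        assert fit.params["scale"] == pytest.approx(best[1], rel=1e-3)
        assert fit.params["shape"] == pytest.approx(best[2], rel=1e-3)
        assert fit.log_lik == pytest.approx(best[0], abs=1e-3)

    def test_weibull_median_closed_form(self):
        fit = fit_family(SIX_POINTS, "weibull")
        alpha, beta = fit.params["scale"], fit.params["shape"]
        assert fit.median_days == pytest.approx(alpha * math.log(2) ** (1 / beta), abs=1e-9)

    def test_published_weibull_median_value(self):
        # alpha = 30.60 d, beta = 1.28 -> median 22.98 d
        assert 30.60 * math.log(2) ** (1 / 1.28) == pytest.approx(22.9809, abs=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        x = 5.0 * rng.weibull(1.4, 300)
        f1 = fit_family(x, "weibull")
        f3 = fit_family(3.0 * x, "weibull")
        assert f3.params["scale"] == pytest.approx(3.0 * f1.params["scale"], rel=1e-4)
        assert f3.params["shape"] == pytest.approx(f1.params["shape"], rel=1e-4)

    def test_aic_definition(self):
        fit = fit_family(SIX_POINTS, "gamma")
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_lik)
        expo = fit_family(SIX_POINTS, "exponential")
        assert expo.aic == pytest.approx(2 * 1 - 2 * expo.log_lik)

    def test_too_few_samples_refused(self):
        with pytest.raises(ValueError):
            fit_family([1.0, 2.0], "weibull")

    def test_positive_ci_bounds_for_all_families(self):
        rng = np.random.default_rng(17)
        x = rng.gamma(2.0, 5.0, 200)
        for family in ("exponential", "weibull", "gamma", "lognormal"):
            fit = fit_family(x, family)
            for low, high in fit.param_cis.values():
                assert 0 < low <= high


class TestSelectModel:
    def test_decreasing_hazard_prefers_weibull_or_gamma(self):
        rng = np.random.default_rng(21)
        x = 10.0 * rng.weibull(0.5, 500)
        fit = select_model(x)
        assert fit.family in {"weibull", "gamma"}
        for other in fit.diagnostics["fits"].values():
            assert fit.aic <= other.aic

    def test_exponential_data_keeps_exponential_competitive(self):
        rng = np.random.default_rng(22)
        x = rng.exponential(10.0, 500)
        fit = select_model(x)
        expo = fit.diagnostics["fits"]["exponential"]
        assert expo.aic <= fit.aic + 2.0

    def test_diagnostics_carry_ad_statistics(self):
        rng = np.random.default_rng(23)
        fit = select_model(rng.exponential(5.0, 100))
        assert set(fit.diagnostics["ad"]) == set(fit.diagnostics["fits"])
        assert all(np.isfinite(v) for v in fit.diagnostics["ad"].values())

    def test_anderson_darling_smaller_for_true_family(self):
        rng = np.random.default_rng(29)
        x = rng.lognormal(2.0, 1.0, 400)
        ln_fit = fit_family(x, "lognormal")
        ex_fit = fit_family(x, "exponential")
        assert anderson_darling(x, ln_fit) < anderson_darling(x, ex_fit)


class TestClassifyFailureType:
    @pytest.mark.parametrize(
        "beta, ci, expected",
        [
            (1.28, (0.98, 1.64), "random"),
            (0.60, (0.45, 0.85), "early"),
            (2.0, (1.5, 2.5), "wear_out"),
        ],
    )
    def test_published_classification_rule(self, beta, ci, expected):
        fit = TTOFit(
            family="weibull",
            params={"scale": 30.0, "shape": beta},
            param_cis={"scale": (20.0, 40.0), "shape": ci},
            log_lik=0.0,
            aic=4.0,
            n=41,
            median_days=20.0,
        )
        assert classify_failure_type(fit) == expected

    def test_non_weibull_rejected(self):
        fit = TTOFit(
            family="gamma",
            params={"shape": 1.0, "scale": 2.0},
            param_cis={"shape": (0.5, 2.0), "scale": (1.0, 4.0)},
            log_lik=0.0,
            aic=4.0,
            n=10,
            median_days=1.0,
        )
        with pytest.raises(ValueError):
            classify_failure_type(fit)


def test_empirical_median_midpoint_rule():
    assert empirical_median([1.0, 2.0, 3.0, 10.0]) == 2.5
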