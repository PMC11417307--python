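"""Parametric time-to-onset (latency) modelling of adverse events.

Latency is the number of days from drug start to reaction onset.  Four
positive-support families are fitted by maximum likelihood -- Weibull,
log-normal, gamma and exponential -- and the reporting model is chosen
by minimum AIC (Anderson-Darling statistics are reported as diagnostics
but do not drive selection).

For the Weibull family (scale alpha in days, shape beta) the shape
parameter classifies the hazard over time: beta < 1 early-failure
(decreasing hazard), 95% CI of beta containing 1 random-failure
(exponential-like), beta > 1 wear-out (increasing hazard).  The Weibull
median is alpha * (ln 2)^(1/beta).

Parameter 95% CIs come from the observed information of the
log-parameters (delta method), so all bounds are positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

Z_95 = 1.959963984540054

#: Family order used for AIC tie-breaking (fewest parameters first).
FAMILY_ORDER = ("exponential", "weibull", "gamma", "lognormal")


class FitError(RuntimeError):
    """Maximum-likelihood fitting failed; carries optimizer diagnostics."""


@dataclass(frozen=True)
class LatencySample:
    """One drug-event latency observation in days (strictly positive)."""

    drug: str
    days: float

    def __post_init__(self) -> None:
        if not self.days > 0:
            raise ValueError("latency must be positive (days)")


@dataclass
class TTOFit:
    """A fitted parametric latency model."""

    family: str
    params: dict
    param_cis: dict
    log_lik: float
    aic: float
    n: int
    median_days: float
    failure_type: Optional[str] = None
    diagnostics: Optional[dict] = None


_PARAM_NAMES = {
    "exponential": ("scale",),
    "weibull": ("scale", "shape"),
    "gamma": ("shape", "scale"),
    "lognormal": ("scale", "sigma"),
}


def _frozen(family: str, params: dict):
    if family == "exponential":
        return stats.expon(scale=params["scale"])
    if family == "weibull":
        return stats.weibull_min(c=params["shape"], scale=params["scale"])
    if family == "gamma":
        return stats.gamma(a=params["shape"], scale=params["scale"])
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=params["scale"])
    raise ValueError(f"unknown family: {family!r}")


def _mle(family: str, x: np.ndarray) -> dict:
    if family == "exponential":
        return {"scale": float(np.mean(x))}
    if family == "weibull":
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        return {"scale": float(scale), "shape": float(c)}
    if family == "gamma":
        a, _, scale = stats.gamma.fit(x, floc=0)
        return {"shape": float(a), "scale": float(scale)}
    if family == "lognormal":
        logs = np.log(x)
        mu = float(np.mean(logs))
        sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
        return {"scale": math.exp(mu), "sigma": max(sigma, 1e-12)}
    raise ValueError(f"unknown family: {family!r}")


def _nll(family: str, names: tuple, theta: np.ndarray, x: np.ndarray) -> float:
    params = {name: math.exp(t) for name, t in zip(names, theta)}
    logpdf = _frozen(family, params).logpdf(x)
    if not np.all(np.isfinite(logpdf)):
        return float("inf")
    return float(-np.sum(logpdf))


def _log_param_cis(family: str, params: dict, x: np.ndarray) -> dict:
    """95% CIs from the numerically observed information on log-parameters."""
    names = _PARAM_NAMES[family]
    theta = np.array([math.log(params[n]) for n in names])
    k = len(theta)
    h = 1e-4
    hess = np.empty((k, k))
    f0 = _nll(family, names, theta, x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            if i == j:
                fp = _nll(family, names, theta + ei, x)
                fm = _nll(family, names, theta - ei, x)
                hess[i, i] = (fp - 2 * f0 + fm) / h**2
            else:
                fpp = _nll(family, names, theta + ei + ej, x)
                fpm = _nll(family, names, theta + ei - ej, x)
                fmp = _nll(family, names, theta - ei + ej, x)
                fmm = _nll(family, names, theta - ei - ej, x)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return {n: (float("nan"), float("nan")) for n in names}
    return {
        n: (math.exp(t - Z_95 * s), math.exp(t + Z_95 * s))
        for n, t, s in zip(names, theta, se)
    }


def extract_latencies(
    reports: Sequence,
    query,
    terms,
    zero_day: str = "half",
) -> list:
    """Latency samples (days) for reports matching a regimen and event.

    For each matching report with a usable reaction onset date, one
    sample is produced per regimen drug carrying a start date:
    ``days = onset - start``.  Negative latencies are excluded; zero-day
    onsets map to 0.5 days (``zero_day="half"``, every family needs
    positive support) or are excluded (``zero_day="exclude"``).
    Exclusion counts are logged by reason.
    """
    from .model import match_event, match_regimen  # local import avoids cycle

    samples = []
    excluded = {"negative": 0, "zero": 0, "missing_dates": 0}
    folded = terms.folded()
    for rep in reports:
        if not (match_regimen(rep, query) and match_event(rep, terms)):
            continue
        onsets = [
            r.onset_date
            for r in rep.reactions
            if r.onset_date is not None and r.preferred_term.casefold() in folded
        ]
        onset = min(onsets) if onsets else None
        for drug in rep.drugs:
            if drug.name not in query.required_drugs:
                continue
            if onset is None or drug.start_date is None:
                excluded["missing_dates"] += 1
                continue
            days = float((onset - drug.start_date).days)
            if days < 0:
                excluded["negative"] += 1
            elif days == 0:
                excluded["zero"] += 1
                if zero_day == "half":
                    samples.append(LatencySample(drug=drug.name, days=0.5))
            else:
                samples.append(LatencySample(drug=drug.name, days=days))
    log.info("extract_latencies: %d samples, excluded %s", len(samples), excluded)
    return samples


def _as_days(samples) -> np.ndarray:
    x = np.asarray(
        [s.days if isinstance(s, LatencySample) else float(s) for s in samples],
        dtype=float,
    )
    if x.size < 3:
        raise ValueError("at least 3 latency samples are required for fitting")
    if np.any(x <= 0):
        raise ValueError("latencies must be strictly positive")
    return x


def fit_family(samples, family: str) -> TTOFit:
    """Maximum-likelihood fit of one parametric family to latency samples."""
    if family not in _PARAM_NAMES:
        raise ValueError(f"unknown family: {family!r}")
    x = _as_days(samples)
    params = _mle(family, x)
    if not all(np.isfinite(v) and v > 0 for v in params.values()):
        raise FitError(f"{family} fit did not converge: params={params}")
    frozen = _frozen(family, params)
    log_lik = float(np.sum(frozen.logpdf(x)))
    if not np.isfinite(log_lik):
        raise FitError(f"{family} fit has non-finite likelihood at {params}")
    k = len(params)
    fit = TTOFit(
        family=family,
        params=params,
        param_cis=_log_param_cis(family, params, x),
        log_lik=log_lik,
        aic=2 * k - 2 * log_lik,
        n=int(x.size),
        median_days=float(frozen.ppf(0.5)),
    )
    if family == "weibull":
        fit.failure_type = classify_failure_type(fit)
    return fit


def anderson_darling(samples, fit: TTOFit) -> float:
    """Anderson-Darling statistic of the samples against the fitted law."""
    x = np.sort(_as_days(samples))
    n = x.size
    z = np.clip(_frozen(fit.family, fit.params).cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1]))))


def select_model(samples, families: Sequence[str] = FAMILY_ORDER) -> TTOFit:
    """Fit all candidate families and return the minimum-AIC fit.

    Ties break toward fewer parameters, then the fixed family order.
    All fits, their AD statistics and any per-family failures are kept
    in the returned fit's ``diagnostics``.
    """
    fits: dict = {}
    errors: dict = {}
    for family in families:
        try:
            fits[family] = fit_family(samples, family)
        except (FitError, ValueError) as exc:
            errors[family] = str(exc)
    if not fits:
        raise FitError(f"all families failed to fit: {errors}")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    best_family = min(
        fits, key=lambda f: (fits[f].aic, len(fits[f].params), order.get(f, 99))
    )
    best = fits[best_family]
    best.diagnostics = {
        "fits": fits,
        "ad": {f: anderson_darling(samples, fit) for f, fit in fits.items()},
        "errors": errors,
    }
    return best


def classify_failure_type(fit: TTOFit) -> str:
    """Weibull hazard classification from the shape parameter.

    ``random`` if the 95% CI of beta contains 1, else ``early`` when
    beta < 1, else ``wear_out``.
    """
    if fit.family != "weibull":
        raise ValueError("failure-type classification requires a Weibull fit")
    beta = fit.params["shape"]
    low, high = fit.param_cis["shape"]
    if math.isfinite(low) and math.isfinite(high) and low <= 1.0 <= high:
        return "random"
    return "early" if beta < 1.0 else "wear_out"


def empirical_median(samples) -> float:
    """Sample median of the latencies (midpoint rule for even n)."""
    x = np.asarray(
        [s.days if isinstance(s, LatencySample) else float(s) for s in samples],
        dtype=float,
    )
    if x.size == 0:
        raise ValueError("no latency samples")
    return float(np.median(x))


def plot_fit(samples, fit: TTOFit, path) -> None:
    """Diagnostic plot: latency histogram with the fitted density overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = _as_days(samples)
    grid = np.linspace(0.0, float(np.percentile(x, 99)) * 1.2 + 1.0, 400)[1:]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(x, bins=min(30, max(5, x.size // 5)), density=True, alpha=0.5, label="observed")
    ax.plot(grid, _frozen(fit.family, fit.params).pdf(grid), label=f"{fit.family} fit")
    ax.set_xlabel("time to onset (days)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
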