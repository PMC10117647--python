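"""Random-search calibration of the model to disease-free survival curves.

The free parameters are the premalignant fitnesses (r1, rS-1), the
malignant birth/death rates (rS, dS) and the three per-step mutation
probabilities (sampled log-uniformly).  A candidate is scored by the
log-MSR between the percentile grid of its simulated cohort and the
clinical grid; the best of ``n_samples`` random candidates is reported
as a carcinogenic profile together with a log-rank p value against the
clinical sample.  One model time unit is calibrated to one month, so a
fitted ``dS`` reads directly as tissue turnover cycles per month.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .model_core import ModelParameters, RngLike
from .survival import (PercentileGrid, SurvivalSample, in_silico_cohort,
                       km_estimate, log_msr, logrank_test, percentile_times)

__all__ = [
    "PENALTY_OBJECTIVE",
    "ParameterRanges",
    "FitResult",
    "CancerProfile",
    "sample_parameters",
    "evaluate_candidate",
    "random_search",
    "synthesize_cohort",
    "integrated_mutation_rate",
    "turnover_per_month",
    "hits_regression",
    "HitsRegression",
]

#: objective assigned to candidates whose cohort yields no usable
#: percentile grid (e.g. nothing ever initiates), keeping the search total
PENALTY_OBJECTIVE = 1e6


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling bounds per fitted parameter (mutation bounds in log10).

    Defaults bracket the fitted tumor-specific profiles: fitnesses near
    neutral, malignant growth well above death, mutation probabilities
    spanning 1e-5 to 1e-2 per division.
    """

    r1: Tuple[float, float] = (0.85, 1.15)
    rS1: Tuple[float, float] = (0.85, 1.15)
    rS: Tuple[float, float] = (2.0, 9.0)
    dS: Tuple[float, float] = (1.0, 4.5)
    log10_mu1: Tuple[float, float] = (-5.0, -2.0)
    log10_muS1: Tuple[float, float] = (-5.0, -2.0)
    log10_muS: Tuple[float, float] = (-5.0, -2.0)

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"inverted bounds for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class CancerProfile:
    """One fitted carcinogenic profile (a row of the bundled fixture).

    Mutation rates are stored in log10; ``SQ`` is the fit quality
    (sum of squared log residuals at the optimum), ``p_value`` the
    log-rank p between the fitted simulated curve and the clinical one.
    """

    code: str
    name: str
    source: str
    SQ: float
    r1: float
    rS1: float
    rS: float
    dS: float
    log10_mu1: float
    log10_muS1: float
    log10_muS: float
    log10_muI: float
    p_value: float


@dataclass(frozen=True)
class FitResult:
    best: ModelParameters
    objective: float
    logrank_p: float
    n_samples: int
    audit: Tuple[Dict[str, float], ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.logrank_p <= 1.0:
            raise ValueError("p value must lie in [0, 1]")


_FITTED_FIELDS = ("r1", "rS1", "rS", "dS")
_LOG_FIELDS = ("log10_mu1", "log10_muS1", "log10_muS")


def sample_parameters(ranges: ParameterRanges, rng: np.random.Generator,
                      base: ModelParameters) -> ModelParameters:
    """Draw one candidate: uniform within bounds, log-uniform for the
    mutation probabilities; structural values (N, d, r0, thresholds)
    come from ``base``."""
    draws = {}
    for name in _FITTED_FIELDS:
        lo, hi = getattr(ranges, name)
        draws[name] = float(rng.uniform(lo, hi)) if hi > lo else lo
    for name in _LOG_FIELDS:
        lo, hi = getattr(ranges, name)
        exp = float(rng.uniform(lo, hi)) if hi > lo else lo
        draws[name.replace("log10_", "")] = 10.0 ** exp
    return dataclasses.replace(base, **draws)


def evaluate_candidate(params: ModelParameters,
                       clinical_grid: PercentileGrid,
                       engine: str = "well_mixed",
                       n_runs: int = 200,
                       rng: RngLike = None,
                       dims=None) -> float:
    """log-MSR of a candidate's simulated percentile grid vs the clinical one.

    Quantiles the clinical curve reached but the simulated curve did not
    (the candidate under-recurs within the horizon) are imputed at the
    candidate's censoring horizon — a lower bound on the unreached time —
    so weakly recurring candidates are penalised smoothly instead of
    being scored on their few early events only.  Candidates whose
    cohorts never recur (no events, or no overlapping usable quantiles)
    receive :data:`PENALTY_OBJECTIVE` instead of an exception so random
    search stays total.
    """
    if n_runs < 25:
        raise ValueError("n_runs must be >= 25 to populate a 4% grid")
    cohort = in_silico_cohort(params, engine=engine, n_runs=n_runs,
                              rng=rng, dims=dims)
    if not cohort.events.any():
        return PENALTY_OBJECTIVE
    try:
        grid = percentile_times(km_estimate(cohort))
        unreached = (np.isnan(grid.times) & np.isfinite(clinical_grid.times)
                     & (clinical_grid.times > 0))
        if unreached.any():
            grid = PercentileGrid(grid.percents,
                                  np.where(unreached, params.max_time,
                                           grid.times))
        return log_msr(grid, clinical_grid)
    except ValueError:
        return PENALTY_OBJECTIVE


def random_search(clinical: SurvivalSample,
                  ranges: ParameterRanges,
                  n_samples: int = 1000,
                  n_runs: int = 200,
                  engine: str = "spatial",
                  rng: RngLike = None,
                  base: Optional[ModelParameters] = None,
                  dims=None,
                  keep_audit: bool = True) -> FitResult:
    """Minimise the log-MSR over ``n_samples`` random candidates.

    Returns the argmin with its objective and a log-rank p value between
    the clinical sample and a fresh cohort simulated at the best
    parameters (matched to the clinical sample size).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if base is None:
        base = ModelParameters(N=2500, d=1.0, r0=1.0, rS=2.0, dS=1.0,
                               max_time=500.0)
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator)
                                else rng.integers(2 ** 31))
    clinical_grid = percentile_times(km_estimate(clinical))
    best_params, best_obj = None, np.inf
    audit: List[Dict[str, float]] = []
    for k in range(n_samples):
        cand = sample_parameters(ranges, rng, base)
        seed = int(rng.integers(2 ** 31))
        obj = evaluate_candidate(cand, clinical_grid, engine=engine,
                                 n_runs=n_runs, rng=seed, dims=dims)
        if keep_audit:
            entry = {f: getattr(cand, f) for f in _FITTED_FIELDS}
            entry.update({f: getattr(cand, f.replace("log10_", ""))
                          for f in _LOG_FIELDS})
            entry["objective"] = obj
            audit.append(entry)
        if obj < best_obj:
            best_params, best_obj = cand, obj
    if best_params is None or best_obj >= PENALTY_OBJECTIVE:
        raise RuntimeError(
            "random search failed: every candidate was penalised "
            "(no simulated cohort produced usable recurrence times)")
    check = in_silico_cohort(best_params, engine=engine,
                             n_runs=len(clinical),
                             rng=int(rng.integers(2 ** 31)), dims=dims)
    _, p = logrank_test(clinical, check)
    return FitResult(best_params, best_obj, p, n_samples, tuple(audit))


def synthesize_cohort(true_params: ModelParameters, n_patients: int,
                      censor_fraction: float = 0.0,
                      engine: str = "well_mixed",
                      rng: RngLike = None, dims=None) -> SurvivalSample:
    """Generate a synthetic disease-free-survival table from known
    parameters, emulating a clinical export.

    Each patient is one full simulated run; a ``censor_fraction`` subset
    is administratively censored at a uniform random time below its
    event time, mimicking patients lost to follow-up.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0.0 <= censor_fraction < 1.0:
        raise ValueError("censor_fraction must be in [0, 1)")
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator)
                                else rng.integers(2 ** 31))
    cohort = in_silico_cohort(true_params, engine=engine, n_runs=n_patients,
                              rng=int(rng.integers(2 ** 31)), dims=dims)
    times = cohort.times.copy()
    events = cohort.events.copy()
    n_censor = int(round(censor_fraction * n_patients))
    if n_censor:
        idx = rng.choice(n_patients, size=n_censor, replace=False)
        times[idx] = rng.uniform(0.0, times[idx])
        events[idx] = False
    ids = np.array([f"SYN{i:05d}" for i in range(n_patients)])
    return SurvivalSample(times, events, patient_ids=ids)


def integrated_mutation_rate(profile: CancerProfile) -> float:
    """log10 of the integrated mutation rate mu1 * muS-1 * muS, a proxy
    for the number of mutational hits required for carcinogenesis."""
    parts = (profile.log10_mu1, profile.log10_muS1, profile.log10_muS)
    if any(p is None or not math.isfinite(p) for p in parts):
        raise ValueError("profile is missing a per-step mutation rate")
    return float(sum(parts))


def turnover_per_month(profile: CancerProfile) -> float:
    """Tissue turnover cycles per month, read off the fitted dS under the
    one-model-time-unit-per-month calibration."""
    return float(profile.dS)


@dataclass(frozen=True)
class HitsRegression:
    """OLS of published mutational hit counts on log10 integrated
    mutation rate."""

    slope: float
    intercept: float
    p_value: float
    n: int

    def predict(self, log10_muI) -> np.ndarray:
        """Predicted hit count for new integrated mutation rates."""
        x = np.asarray(log10_muI, dtype=float)
        return self.intercept + self.slope * x


def hits_regression(pairs: Sequence[Tuple[float, float]]) -> HitsRegression:
    """Fit hit count ~ log10 muI by ordinary least squares.

    Requires at least three pairs with non-constant x; the p value is
    the two-sided slope-significance test.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (log10_muI, hits) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; slope is unidentifiable")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return HitsRegression(slope=float(fit.params[1]),
                          intercept=float(fit.params[0]),
                          p_value=float(fit.pvalues[1]),
                          n=len(x))
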