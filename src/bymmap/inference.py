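"""Reported quantities: smoothed-SMR distribution summaries, rate ratios,
and the full unadjusted/adjusted model set over methods.

The distribution summary mirrors the usual disease-mapping presentation:
per method, the count and share of deaths, then the mean, SD, 5th, 50th and
95th percentiles of the areas' smoothed SMRs, and the mid-90% ratio (the
95th percentile divided by the 5th) as a scale-free dispersion measure.
Percentiles use the linear-interpolation convention (numpy default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BYMModel, PriorSpec, transform_covariates
from .sampler import PosteriorSamples, SamplerConfig, fit_bym
from .results import BYMResults
from .spatial import SpatialStructure

logger = logging.getLogger(__name__)


@dataclass
class DistributionSummary:
    """Summary of one method's smoothed-SMR distribution across areas."""

    n: int
    percent: float
    mean: float
    sd: float
    p5: float
    median: float
    p95: float
    mid90_ratio: float

    def as_row(self) -> dict:
        return {"n": self.n, "percent": self.percent, "mean": self.mean,
                "sd": self.sd, "p5": self.p5, "median": self.median,
                "p95": self.p95, "mid90_ratio": self.mid90_ratio}


def mid90_ratio(p95: float, p5: float) -> float:
    """Dispersion over the mid-90% range: the 95th percentile over the 5th."""
    if p5 <= 0:
        raise ValueError("mid-90% ratio needs a positive 5th percentile")
    return p95 / p5


def summarize_distribution(smrs, n_deaths: int | None = None,
                           total_deaths: int | None = None) -> DistributionSummary:
    """Distribution summary of per-area (smoothed) SMRs for one method."""
    x = np.asarray(smrs, dtype=float)
    if x.size == 0:
        raise ValueError("empty SMR vector")
    if np.any(x <= 0):
        raise ValueError("smoothed SMRs must be positive (exp link)")
    p5, med, p95 = np.percentile(x, [5, 50, 95])
    percent = float("nan")
    if n_deaths is not None and total_deaths:
        percent = 100.0 * n_deaths / total_deaths
    return DistributionSummary(
        n=int(n_deaths) if n_deaths is not None else x.size,
        percent=percent, mean=float(x.mean()),
        sd=float(x.std(ddof=1)), p5=float(p5), median=float(med),
        p95=float(p95), mid90_ratio=mid90_ratio(float(p95), float(p5)),
    )


def method_shares(counts: dict) -> pd.Series:
    """Percentage share of each method among the total count."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return pd.Series({m: 100.0 * c / total for m, c in counts.items()})


def smoothed_smr(samples: PosteriorSamples) -> pd.Series:
    """Posterior mean of exp(alpha + u_i + v_i) from covariate-free samples."""
    if samples.covariate_names:
        raise ValueError("smoothed SMRs require the covariate-free fit")
    log_theta = samples.alpha[:, :, None]
    if samples.u is not None:
        log_theta = log_theta + samples.u
    if samples.v is not None:
        log_theta = log_theta + samples.v
    theta = np.exp(log_theta).mean(axis=(0, 1))
    return pd.Series(theta, index=pd.Index(samples.area_ids, name="area_id"),
                     name="smoothed_smr")


def rate_ratios(samples: PosteriorSamples, covariate_names=None) -> pd.DataFrame:
    """RR (posterior mean of exp beta) and 95% CrI per covariate."""
    names = covariate_names or samples.covariate_names
    rows = []
    for name in names:
        draws = np.exp(samples.beta_draws(name))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append({"covariate": name, "rr": float(draws.mean()),
                     "lo": float(lo), "hi": float(hi),
                     "excludes_one": bool(not (lo <= 1.0 <= hi))})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# The full model set (unadjusted and adjusted analyses across methods)

DEFAULT_SOCIOECONOMIC = ("divorced_pct", "median_income")
DEFAULT_ACCESSIBILITY = ("single_person_pct", "sixth_floor_pct", "river")


def run_model_set(
    area_frame,
    graph,
    methods=None,
    accessibility=DEFAULT_ACCESSIBILITY,
    socioeconomic=DEFAULT_SOCIOECONOMIC,
    prior: PriorSpec = PriorSpec(),
    sampler_config: SamplerConfig | None = None,
    skew_threshold: float = 1.0,
    zscore_binary: bool = True,
    never_log=(),
    smoothing: bool = True,
):
    """Fit the full analysis over methods and covariate sets.

    Per method ("overall" plus each method group with any deaths):
    (a) a covariate-free model for smoothed SMRs (Table-1 style block),
    (b) one model per covariate alone (unadjusted analysis),
    (c) one model per accessibility indicator plus the two socioeconomic
        covariates (adjusted analysis).

    Returns ``(results, table1, fits)``: a long-format DataFrame of RR rows,
    a per-method distribution-summary DataFrame, and the dict of
    :class:`BYMResults` keyed by (method, model label).
    """
    sampler_config = sampler_config or SamplerConfig()
    if methods is None:
        methods = ["overall"] + list(area_frame.methods)
    structure = SpatialStructure(graph, list(area_frame.area_ids))
    total_deaths = int(area_frame.observed.to_numpy().sum())
    cov = transform_covariates(
        area_frame.covariates[list(dict.fromkeys([*socioeconomic, *accessibility]))],
        skew_threshold=skew_threshold, zscore_binary=zscore_binary,
        never_log=never_log,
    )

    def _fit(method, columns):
        O, E = area_frame.counts(method)
        X = cov.X[list(columns)] if columns else None
        model = BYMModel(O, E, X=X, structure=structure, prior=prior,
                         area_ids=list(area_frame.area_ids), method=method)
        return BYMResults(model, fit_bym(model, sampler_config))

    rows, table1_rows, fits = [], {}, {}
    for method in methods:
        O, _ = area_frame.counts(method)
        n_deaths = int(O.sum())
        if n_deaths == 0:
            logger.warning("method %r has zero total deaths; skipped", method)
            continue
        if smoothing:
            res0 = _fit(method, None)
            fits[(method, "smoothing")] = res0
            table1_rows[method] = summarize_distribution(
                res0.smoothed_smr().to_numpy(), n_deaths=n_deaths,
                total_deaths=total_deaths).as_row()
            table1_rows[method]["rhat_max"] = res0.convergence.max_rhat
        for covname in [*socioeconomic, *accessibility]:
            res = _fit(method, [covname])
            fits[(method, f"unadjusted:{covname}")] = res
            rr = res.rate_ratios().loc[covname]
            rows.append({"method": method, "covariate": covname,
                         "model_set": "unadjusted", **rr.to_dict(),
                         "rhat_max": res.convergence.max_rhat,
                         "converged": res.converged,
                         "logged": cov.transforms[covname] == "log"})
        for covname in accessibility:
            cols = [*socioeconomic, covname]
            res = _fit(method, cols)
            fits[(method, f"adjusted:{covname}")] = res
            rr = res.rate_ratios().loc[covname]
            rows.append({"method": method, "covariate": covname,
                         "model_set": "adjusted", **rr.to_dict(),
                         "rhat_max": res.convergence.max_rhat,
                         "converged": res.converged,
                         "logged": cov.transforms[covname] == "log"})
    results = pd.DataFrame(rows)
    table1 = pd.DataFrame(table1_rows).T if table1_rows else pd.DataFrame()
    return results, table1, fits
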