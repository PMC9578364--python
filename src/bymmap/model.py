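"""The BYM (Besag-York-Mollié) Poisson model: likelihood, priors, transforms.

The model for one cause-of-death method is

    O_i ~ Poisson(E_i * exp(eta_i)),   eta_i = alpha + x_i' beta + u_i + v_i

with E_i the expected count entering as an offset, u an intrinsic CAR
(pairwise-difference) spatially structured effect identified by a sum-to-zero
constraint per connected component, and v an exchangeable Normal(0, sigma_v^2)
unstructured effect.  The random-effect scales carry either independent
Uniform(0, 5) priors on the standard deviations (main analysis) or
Gamma(0.01, 0.01) priors on the precisions (sensitivity analysis).
Covariates enter as z scores, log-transformed first when skewed, so a unit
change in a coefficient is a rate ratio per one SD of the (possibly logged)
covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .spatial import SpatialStructure

UNIFORM_SD = "uniform_sd"
GAMMA_PRECISION = "gamma_precision"


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the two random-effect scales.

    ``uniform_sd``: sigma_u, sigma_v ~ Uniform(a, b) independently.
    ``gamma_precision``: 1/sigma^2 ~ Gamma(shape=a, rate=b) independently.
    """

    family: str = UNIFORM_SD
    params: tuple = (0.0, 5.0)

    def __post_init__(self) -> None:
        if self.family not in (UNIFORM_SD, GAMMA_PRECISION):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == UNIFORM_SD:
            a, b = self.params
            if not (0 <= a < b):
                raise ValueError("uniform_sd needs 0 <= lower < upper")
        else:
            a, b = self.params
            if a <= 0 or b <= 0:
                raise ValueError("gamma_precision needs positive shape and rate")


DEFAULT_GAMMA_PRIOR = PriorSpec(GAMMA_PRECISION, (0.01, 0.01))


@dataclass
class BYMState:
    """One point in parameter space."""

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    sigma_u: float
    sigma_v: float

    def copy(self) -> "BYMState":
        return BYMState(self.alpha, self.beta.copy(), self.u.copy(),
                        self.v.copy(), self.sigma_u, self.sigma_v)


# ---------------------------------------------------------------------------
# Covariate transforms

@dataclass
class CovariateMatrix:
    """Analysis-scale covariates plus the transform bookkeeping."""

    X: pd.DataFrame
    transforms: dict  # column -> "none" | "log"
    means: dict
    sds: dict
    binary: dict  # column -> bool (binary on the raw scale)

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)


def transform_covariates(
    raw: pd.DataFrame,
    skew_threshold: float = 1.0,
    zscore_binary: bool = True,
    never_log=(),
) -> CovariateMatrix:
    """Log-transform skewed columns, then z-score everything.

    Continuous columns whose sample skewness exceeds ``skew_threshold`` in
    absolute value are natural-log transformed first.  Binary (0/1) columns
    are never logged; by default they are z-scored too, so "per one SD"
    applies uniformly across covariates (set ``zscore_binary=False`` to keep
    them on the raw 0/1 scale).  Columns named in ``never_log`` skip the log
    rule regardless of skewness (e.g. distances that legitimately contain
    zeros).
    """
    X = {}
    transforms, means, sds, binary = {}, {}, {}, {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"covariate {col!r} contains non-finite values")
        is_binary = set(np.unique(x)) <= {0.0, 1.0}
        binary[col] = bool(is_binary)
        tr = "none"
        if (not is_binary and col not in never_log and x.std() > 0
                and abs(stats.skew(x)) > skew_threshold):
            if np.any(x <= 0):
                raise ValueError(
                    f"covariate {col!r} is skewed but has nonpositive values; "
                    "add an offset or disable the log transform"
                )
            x = np.log(x)
            tr = "log"
        transforms[col] = tr
        if is_binary and not zscore_binary:
            means[col], sds[col] = 0.0, 1.0
            X[col] = x
            continue
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"covariate {col!r} is constant; cannot z-score")
        means[col], sds[col] = mu, sd
        X[col] = (x - mu) / sd
    return CovariateMatrix(
        X=pd.DataFrame(X, index=raw.index),
        transforms=transforms, means=means, sds=sds, binary=binary,
    )


# ---------------------------------------------------------------------------
# Log densities

def poisson_loglik(O, E, eta) -> float:
    """Poisson log-likelihood with a log expected-count offset.

    sum_i [ O_i (log E_i + eta_i) - E_i exp(eta_i) - log O_i! ]
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    return float(np.sum(O * (np.log(E) + eta) - E * np.exp(eta) - special.gammaln(O + 1)))


def icar_logpdf(u, structure, sigma_u: float) -> float:
    """Unnormalized intrinsic-CAR log density in pairwise-difference form.

    -(1 / 2 sigma_u^2) * sum_edges (u_i - u_j)^2 + (rank / 2) * log(1 / sigma_u^2)

    where rank = n - (number of connected components).  ``structure`` may be
    a networkx graph or a precomputed :class:`SpatialStructure`; ``u`` must
    sum to zero over each component with >= 2 nodes, and isolates must carry
    u = 0 (their structured effect is fixed).
    """
    u = np.asarray(u, dtype=float)
    if not isinstance(structure, SpatialStructure):
        structure = SpatialStructure(structure, list(structure.nodes))
    if sigma_u <= 0:
        raise ValueError("sigma_u must be positive")
    if u.shape != (structure.n,):
        raise ValueError("u length must equal the number of areas")
    for c in structure.components:
        if len(c) == 1:
            if abs(u[c[0]]) > 1e-9:
                raise ValueError("isolated area must have structured effect 0")
        elif abs(u[c].sum()) > 1e-6 * max(1.0, np.abs(u[c]).max()):
            raise ValueError("u must sum to zero within each connected component")
    ss = structure.pairwise_ss(u)
    return -ss / (2.0 * sigma_u**2) - structure.rank * math.log(sigma_u)


def log_prior(state: BYMState, prior: PriorSpec) -> float:
    """Log prior for the scale parameters (flat on alpha and beta).

    Under ``gamma_precision`` the value is the Gamma(shape, rate) log density
    evaluated at the precisions tau = sigma^-2 (no change-of-variable
    Jacobian; the sampler updates tau directly by conjugate Gibbs).
    """
    if state.sigma_u <= 0 or state.sigma_v <= 0:
        return -math.inf
    a, b = prior.params
    if prior.family == UNIFORM_SD:
        ok = a < state.sigma_u < b and a < state.sigma_v < b
        return 0.0 if ok else -math.inf
    lp = 0.0
    for sigma in (state.sigma_u, state.sigma_v):
        tau = sigma**-2
        lp += a * math.log(b) - special.gammaln(a) + (a - 1) * math.log(tau) - b * tau
    return float(lp)


# ---------------------------------------------------------------------------
# The model object

class BYMModel:
    """A BYM Poisson model for one method's counts, ready to fit by MCMC.

    Parameters
    ----------
    observed, expected
        Per-area counts; ``expected`` must be strictly positive.
    X
        Analysis-scale (transformed, z-scored) covariate matrix or None for
        the covariate-free smoothing model.
    structure
        :class:`SpatialStructure` (or networkx graph + area_ids) for the ICAR
        term, or None to drop the structured effect.
    prior
        :class:`PriorSpec` for the random-effect scales.
    include_structured, include_unstructured
        Drop either random effect entirely (used by oracle tests).
    fix_sigma_u, fix_sigma_v
        Freeze a scale at a known value instead of sampling it.
    beta_prior_sd
        None for flat (improper) priors on alpha and beta, or a positive
        number for independent Normal(0, sd^2) priors.
    """

    def __init__(
        self,
        observed,
        expected,
        X=None,
        structure=None,
        prior: PriorSpec = PriorSpec(),
        include_structured: bool = True,
        include_unstructured: bool = True,
        fix_sigma_u: float | None = None,
        fix_sigma_v: float | None = None,
        beta_prior_sd: float | None = None,
        covariate_names=None,
        area_ids=None,
        method: str = "",
    ) -> None:
        self.O = np.asarray(observed, dtype=float).ravel()
        self.E = np.asarray(expected, dtype=float).ravel()
        if self.O.shape != self.E.shape:
            raise ValueError("observed and expected must have equal length")
        if np.any(self.E <= 0):
            raise ValueError("expected counts must be strictly positive")
        if np.any(self.O < 0):
            raise ValueError("observed counts must be nonnegative")
        self.n = self.O.size
        if X is None:
            self.X = None
            self.covariate_names = []
        else:
            if isinstance(X, pd.DataFrame):
                covariate_names = list(X.columns)
                X = X.to_numpy(dtype=float)
            self.X = np.atleast_2d(np.asarray(X, dtype=float))
            if self.X.shape[0] != self.n:
                raise ValueError("X row count must equal the number of areas")
            self.covariate_names = list(covariate_names or
                                        [f"x{j}" for j in range(self.X.shape[1])])
        self.p = 0 if self.X is None else self.X.shape[1]
        if structure is not None and not isinstance(structure, SpatialStructure):
            structure = SpatialStructure(structure, area_ids or list(structure.nodes))
        if include_structured and structure is None:
            raise ValueError("a spatial structure is required for the structured effect")
        self.structure = structure if include_structured else None
        self.include_structured = include_structured
        self.include_unstructured = include_unstructured
        self.prior = prior
        self.fix_sigma_u = fix_sigma_u
        self.fix_sigma_v = fix_sigma_v
        self.beta_prior_sd = beta_prior_sd
        self.area_ids = list(area_ids) if area_ids is not None else (
            structure.area_ids if structure is not None else list(range(self.n)))
        self.method = method

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_area_frame(
        cls,
        area_frame,
        method: str,
        graph,
        covariates=None,
        skew_threshold: float = 1.0,
        zscore_binary: bool = True,
        **kwargs,
    ) -> "BYMModel":
        """Build the model for one method from an AreaFrame and a graph.

        ``covariates`` is a list of raw covariate column names; they are
        transformed (log if skewed, then z-scored) here so coefficients read
        as log rate ratios per one SD.
        """
        O, E = area_frame.counts(method)
        if O.sum() == 0:
            raise ValueError(f"method {method!r} has zero total deaths")
        structure = (graph if isinstance(graph, SpatialStructure)
                     else SpatialStructure(graph, list(area_frame.area_ids)))
        X = None
        names = None
        if covariates:
            cov = transform_covariates(
                area_frame.covariates[list(covariates)],
                skew_threshold=skew_threshold, zscore_binary=zscore_binary,
            )
            X = cov.X.to_numpy(dtype=float)
            names = cov.names
        return cls(O, E, X=X, structure=structure, covariate_names=names,
                   area_ids=list(area_frame.area_ids), method=method, **kwargs)

    # -- densities ----------------------------------------------------------

    def linear_predictor(self, state: BYMState) -> np.ndarray:
        eta = np.full(self.n, state.alpha)
        if self.p:
            eta = eta + self.X @ state.beta
        if self.include_structured:
            eta = eta + state.u
        if self.include_unstructured:
            eta = eta + state.v
        return eta

    def log_posterior(self, state: BYMState) -> float:
        """Joint log density (up to a constant) used by the sampler and tests."""
        lp = poisson_loglik(self.O, self.E, self.linear_predictor(state))
        if self.include_structured:
            lp += icar_logpdf(state.u, self.structure, state.sigma_u)
        if self.include_unstructured:
            sv = state.sigma_v
            lp += -self.n * math.log(sv) - float(state.v @ state.v) / (2 * sv**2)
        if self.beta_prior_sd is not None:
            sd = self.beta_prior_sd
            lp += -(state.alpha**2) / (2 * sd**2)
            if self.p:
                lp += -float(state.beta @ state.beta) / (2 * sd**2)
        if self.include_structured or self.include_unstructured:
            lp += log_prior(state, self.prior)
        return lp

    # -- fitting ------------------------------------------------------------

    def fit(self, sampler_config=None, seed=None, **kwargs):
        """Fit by Metropolis-within-Gibbs MCMC; returns :class:`BYMResults`."""
        from .results import BYMResults
        from .sampler import SamplerConfig, fit_bym

        if sampler_config is None:
            sampler_config = SamplerConfig(**kwargs) if kwargs else SamplerConfig()
        if seed is not None:
            sampler_config = sampler_config.with_seed(seed)
        samples = fit_bym(self, sampler_config)
        return BYMResults(self, samples)
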