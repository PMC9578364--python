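"""Metropolis-within-Gibbs sampler for the BYM model.

Every scalar parameter (alpha, each beta_j) and every random-effect entry
(u_i, v_i) gets a single-site adaptive Gaussian random-walk Metropolis
update.  Sites of u are scanned by graph-colour class: within a class no two
areas are adjacent, so the single-site acceptance ratios are mutually
independent given the rest of the state and can be evaluated in one
vectorised pass — numerically identical to a sequential single-site scan
ordered by colour.  The v updates factorise over all areas at once.

Scales: under the gamma-precision prior the precisions are conjugate and are
updated by Gibbs; under the uniform-SD prior, random-walk Metropolis on
log sigma with the support enforced.  Proposal scales adapt toward a 0.44
acceptance rate (Robbins-Monro on the log scale) during burn-in only.

After each sweep u is re-centred to sum to zero per connected component; the
overall mean removed is transferred to the intercept so the fitted rates are
unchanged on connected maps.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GAMMA_PRECISION, UNIFORM_SD, BYMModel, BYMState


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 2
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    adapt_interval: int = 50
    target_acceptance: float = 0.44
    rhat_threshold: float = 1.1
    keep_effects: bool = True  # retain u/v draws (needed for smoothed SMRs)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 < self.target_acceptance < 1):
            raise ValueError("target_acceptance must be in (0, 1)")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def with_seed(self, seed: int) -> "SamplerConfig":
        return dataclasses.replace(self, seed=int(seed))


@dataclass
class PosteriorSamples:
    """Retained multi-chain draws plus sampler bookkeeping."""

    alpha: np.ndarray              # (chains, draws)
    beta: np.ndarray               # (chains, draws, p)
    sigma_u: np.ndarray | None     # (chains, draws)
    sigma_v: np.ndarray | None
    u: np.ndarray | None           # (chains, draws, n)
    v: np.ndarray | None
    covariate_names: list
    area_ids: list
    acceptance: dict
    config: SamplerConfig
    method: str = ""

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def scalar_draws(self) -> dict:
        """Monitored scalar parameters as name -> (chains, draws) arrays."""
        out = {"alpha": self.alpha}
        for j, name in enumerate(self.covariate_names):
            out[f"beta[{name}]"] = self.beta[:, :, j]
        if self.sigma_u is not None:
            out["sigma_u"] = self.sigma_u
        if self.sigma_v is not None:
            out["sigma_v"] = self.sigma_v
        return out

    def flat(self, name: str) -> np.ndarray:
        return self.scalar_draws()[name].ravel()

    def beta_draws(self, name: str) -> np.ndarray:
        j = self.covariate_names.index(name)
        return self.beta[:, :, j].ravel()

    def to_dataframe(self, include_effects: bool = False) -> pd.DataFrame:
        """Long format (chain, iteration, parameter, value) for persistence."""
        rows = []
        draws = dict(self.scalar_draws())
        if include_effects and self.u is not None:
            for k, aid in enumerate(self.area_ids):
                draws[f"u[{aid}]"] = self.u[:, :, k]
        if include_effects and self.v is not None:
            for k, aid in enumerate(self.area_ids):
                draws[f"v[{aid}]"] = self.v[:, :, k]
        for name, arr in draws.items():
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(arr.shape[1]),
                    "parameter": name, "value": arr[c],
                }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ConvergenceReport:
    """Gelman-Rubin potential scale reduction factors per monitored scalar."""

    table: pd.DataFrame  # index parameter; columns rhat, converged, undefined
    threshold: float

    @property
    def converged(self) -> bool:
        ok = self.table.loc[~self.table["undefined"], "converged"]
        return bool(ok.all())

    @property
    def max_rhat(self) -> float:
        vals = self.table.loc[~self.table["undefined"], "rhat"]
        return float(vals.max()) if len(vals) else float("nan")


def gelman_rubin(chains) -> float:
    """Classic potential scale reduction factor from >= 2 equal-length chains.

    With W the mean within-chain sample variance and B/n the sample variance
    of the chain means, returns sqrt(((n-1)/n * W + B/n) / W).  Returns NaN
    when W == 0 (degenerate chains).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = x.shape
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return float("nan")
    vhat = (n - 1) / n * W + B_over_n
    return float(math.sqrt(vhat / W))


def convergence_report(samples: PosteriorSamples,
                       threshold: float | None = None) -> ConvergenceReport:
    threshold = threshold if threshold is not None else samples.config.rhat_threshold
    rows = {}
    for name, arr in samples.scalar_draws().items():
        if arr.shape[0] >= 2 and arr.shape[1] >= 2:
            r = gelman_rubin(arr)
        else:
            r = float("nan")
        undefined = not np.isfinite(r)
        rows[name] = {"rhat": r, "converged": bool(not undefined and r < threshold),
                      "undefined": undefined}
    table = pd.DataFrame(rows).T
    table["rhat"] = table["rhat"].astype(float)
    table["converged"] = table["converged"].astype(bool)
    table["undefined"] = table["undefined"].astype(bool)
    return ConvergenceReport(table=table, threshold=float(threshold))


# ---------------------------------------------------------------------------
# Chain internals

class _Adapt:
    """Robbins-Monro log-scale adaptation toward a target acceptance rate."""

    def __init__(self, shape, target: float, init: float = 0.1) -> None:
        self.log_s = np.full(shape, math.log(init)) if shape else math.log(init)
        self.count = np.zeros(shape) if shape else 0.0
        self.target = target
        self.batch = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, interval: int) -> None:
        self.batch += 1
        rate = self.count / interval
        step = (rate - self.target) / math.sqrt(self.batch)
        self.log_s = np.clip(self.log_s + step, math.log(1e-4), math.log(50.0))
        self.count = self.count * 0.0


def _initial_state(model: BYMModel, chain: int) -> BYMState:
    total_o = model.O.sum()
    alpha = math.log((total_o if total_o > 0 else 0.5) / model.E.sum())
    beta = np.zeros(model.p)
    u = np.zeros(model.n)
    v = np.zeros(model.n)
    sigma_u = model.fix_sigma_u if model.fix_sigma_u is not None else 0.5
    sigma_v = model.fix_sigma_v if model.fix_sigma_v is not None else 0.5
    if chain > 0:
        # overdispersed start: shift each scalar by one prior-scale unit
        alpha += 0.5 * chain
        beta = beta + 0.5 * chain
        if model.fix_sigma_u is None:
            sigma_u = 1.0 * chain
        if model.fix_sigma_v is None:
            sigma_v = 1.0 * chain
    return BYMState(alpha, beta, u, v, float(sigma_u), float(sigma_v))


def _check_finite_init(model: BYMModel, state: BYMState) -> None:
    from .model import icar_logpdf, log_prior, poisson_loglik

    terms = {"poisson log-likelihood":
             poisson_loglik(model.O, model.E, model.linear_predictor(state))}
    if model.include_structured:
        terms["ICAR log density"] = icar_logpdf(state.u, model.structure, state.sigma_u)
    if model.include_unstructured:
        terms["unstructured-effect log density"] = (
            -model.n * math.log(state.sigma_v)
            - float(state.v @ state.v) / (2 * state.sigma_v**2))
    if model.include_structured or model.include_unstructured:
        terms["scale prior"] = log_prior(state, model.prior)
    for name, val in terms.items():
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite log-posterior at initialization: {name} = {val}")


def _sigma_gibbs_uniform(rank, ss, lo, hi, rng):
    """Exact draw from the scale's full conditional under a Uniform(lo, hi)
    prior on sigma.

    The conditional density is p(sigma) ~ sigma^-rank exp(-ss / (2 sigma^2))
    on (lo, hi); in tau = sigma^-2 this is Gamma(rank/2 - 1/2, rate=ss/2)
    truncated to sigma's support, sampled by inverse CDF.  Returns None when
    the Gamma shape is nonpositive (rank <= 1) so the caller can fall back
    to a Metropolis step.
    """
    from scipy.special import gammainc, gammaincinv

    shape = rank / 2.0 - 0.5
    if shape <= 0 or ss <= 0:
        return None
    rate = ss / 2.0
    f_lo = gammainc(shape, rate * hi**-2)  # sigma < hi  <=>  tau > hi^-2
    f_hi = 1.0 if lo <= 0 else float(gammainc(shape, rate * lo**-2))
    if not np.isfinite(f_lo) or f_hi - f_lo <= 1e-14:
        return None
    q = f_lo + rng.random() * (f_hi - f_lo)
    tau = float(gammaincinv(shape, q)) / rate
    if not np.isfinite(tau) or tau <= 0:
        return None
    return tau**-0.5


def _sigma_rw_update(lam, scale, rank, ss, lo, hi, rng):
    """RW Metropolis on log sigma for the uniform-SD prior.

    Target in lambda = log sigma: -rank*lambda - ss / (2 e^{2 lambda}) + lambda
    (the +lambda is the Jacobian of the log transform), restricted to
    sigma in (lo, hi).
    """
    def logtarget(x: float) -> float:
        try:
            pen = 0.5 * ss * math.exp(-2 * x)
        except OverflowError:
            return -math.inf
        return -rank * x - pen + x

    prop = lam + scale * rng.standard_normal()
    sig = math.exp(prop)
    if not (lo < sig < hi):
        return lam, False
    if math.log(rng.random()) < logtarget(prop) - logtarget(lam):
        return prop, True
    return lam, False


def _run_chain(model: BYMModel, cfg: SamplerConfig, chain: int):
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, chain])
    state = _initial_state(model, chain)
    _check_finite_init(model, state)
    n, p = model.n, model.p
    O, E, X = model.O, model.E, model.X
    st = model.structure
    target = cfg.target_acceptance

    a_alpha = _Adapt((), target)
    a_beta = _Adapt((p,), target) if p else None
    a_u = _Adapt((n,), target, init=0.5) if model.include_structured else None
    a_v = _Adapt((n,), target, init=0.5) if model.include_unstructured else None
    a_su = (_Adapt((), target, init=0.3)
            if model.include_structured and model.fix_sigma_u is None
            and model.prior.family == UNIFORM_SD else None)
    a_sv = (_Adapt((), target, init=0.3)
            if model.include_unstructured and model.fix_sigma_v is None
            and model.prior.family == UNIFORM_SD else None)

    eta = model.linear_predictor(state)
    Eexp = E * np.exp(eta)
    Osum = O.sum()
    prior_a, prior_b = model.prior.params
    bsd = model.beta_prior_sd

    n_keep = cfg.n_retained_per_chain
    out_alpha = np.empty(n_keep)
    out_beta = np.empty((n_keep, p))
    out_su = np.empty(n_keep) if model.include_structured and model.fix_sigma_u is None else None
    out_sv = np.empty(n_keep) if model.include_unstructured and model.fix_sigma_v is None else None
    out_u = np.empty((n_keep, n)) if cfg.keep_effects and model.include_structured else None
    out_v = np.empty((n_keep, n)) if cfg.keep_effects and model.include_unstructured else None
    post_counts = {"alpha": 0, "beta": np.zeros(p), "u": np.zeros(n), "v": np.zeros(n),
                   "sigma_u": 0, "sigma_v": 0}
    rw_attempts = {"sigma_u": 0, "sigma_v": 0}  # Metropolis fallback only
    n_post = 0
    kept = 0

    for it in range(cfg.n_iter):
        in_burn = it < cfg.burn_in
        # -- intercept -----------------------------------------------------
        d = a_alpha.scale * rng.standard_normal()
        dll = Osum * d - math.expm1(d) * Eexp.sum()
        if bsd is not None:
            dll += -((state.alpha + d) ** 2 - state.alpha**2) / (2 * bsd**2)
        if math.log(rng.random()) < dll:
            state.alpha += d
            eta += d
            Eexp *= math.exp(d)
            a_alpha.count += 1
            if not in_burn:
                post_counts["alpha"] += 1
        # -- coefficients --------------------------------------------------
        for j in range(p):
            d = a_beta.scale[j] * rng.standard_normal()
            xd = X[:, j] * d
            dll = float(O @ xd - Eexp @ np.expm1(xd))
            if bsd is not None:
                dll += -((state.beta[j] + d) ** 2 - state.beta[j] ** 2) / (2 * bsd**2)
            if math.log(rng.random()) < dll:
                state.beta[j] += d
                eta += xd
                Eexp *= np.exp(xd)
                a_beta.count[j] += 1
                if not in_burn:
                    post_counts["beta"][j] += 1
        # -- structured effect (colour-class single-site scan) -------------
        if model.include_structured:
            inv2s = 1.0 / (2 * state.sigma_u**2)
            for cls in st.colour_classes:
                du = a_u.scale[cls] * rng.standard_normal(cls.size)
                uk = state.u[cls]
                Wu = st.W[cls] @ state.u
                deg = st.degree[cls]
                unew = uk + du
                dll = (O[cls] * du - Eexp[cls] * np.expm1(du)
                       - inv2s * ((deg * unew**2 - 2 * unew * Wu)
                                  - (deg * uk**2 - 2 * uk * Wu)))
                acc = np.log(rng.random(cls.size)) < dll
                idx = cls[acc]
                state.u[idx] = unew[acc]
                eta[idx] += du[acc]
                Eexp[idx] *= np.exp(du[acc])
                a_u.count[idx] += 1
                if not in_burn:
                    post_counts["u"][idx] += 1
        # -- unstructured effect (all sites factorise) ---------------------
        if model.include_unstructured:
            dv = a_v.scale * rng.standard_normal(n)
            vnew = state.v + dv
            dll = (O * dv - Eexp * np.expm1(dv)
                   - (vnew**2 - state.v**2) / (2 * state.sigma_v**2))
            acc = np.log(rng.random(n)) < dll
            state.v[acc] = vnew[acc]
            eta[acc] += dv[acc]
            Eexp[acc] *= np.exp(dv[acc])
            a_v.count[acc] += 1
            if not in_burn:
                post_counts["v"][acc] += 1
        # -- re-centre u; transfer the mean to the intercept ---------------
        if model.include_structured:
            state.u, shift = st.center(state.u)
            state.alpha += shift
            eta = model.linear_predictor(state)
            Eexp = E * np.exp(eta)
        # -- scales --------------------------------------------------------
        if model.include_structured and model.fix_sigma_u is None:
            ss = st.pairwise_ss(state.u)
            if model.prior.family == GAMMA_PRECISION:
                tau = rng.gamma(prior_a + st.rank / 2.0, 1.0 / (prior_b + ss / 2.0))
                state.sigma_u = float(tau) ** -0.5
            else:
                sig = _sigma_gibbs_uniform(st.rank, ss, prior_a, prior_b, rng)
                if sig is not None:
                    state.sigma_u = sig
                else:
                    lam, acc = _sigma_rw_update(math.log(state.sigma_u),
                                                a_su.scale, st.rank, ss,
                                                prior_a, prior_b, rng)
                    state.sigma_u = math.exp(lam)
                    if not in_burn:
                        rw_attempts["sigma_u"] += 1
                    if acc:
                        a_su.count += 1
                        if not in_burn:
                            post_counts["sigma_u"] += 1
        if model.include_unstructured and model.fix_sigma_v is None:
            ss = float(state.v @ state.v)
            if model.prior.family == GAMMA_PRECISION:
                tau = rng.gamma(prior_a + n / 2.0, 1.0 / (prior_b + ss / 2.0))
                state.sigma_v = float(tau) ** -0.5
            else:
                sig = _sigma_gibbs_uniform(n, ss, prior_a, prior_b, rng)
                if sig is not None:
                    state.sigma_v = sig
                else:
                    lam, acc = _sigma_rw_update(math.log(state.sigma_v),
                                                a_sv.scale, n, ss,
                                                prior_a, prior_b, rng)
                    state.sigma_v = math.exp(lam)
                    if not in_burn:
                        rw_attempts["sigma_v"] += 1
                    if acc:
                        a_sv.count += 1
                        if not in_burn:
                            post_counts["sigma_v"] += 1
        # -- adaptation (burn-in only) -------------------------------------
        if in_burn and (it + 1) % cfg.adapt_interval == 0:
            for ad in (a_alpha, a_beta, a_u, a_v, a_su, a_sv):
                if ad is not None:
                    ad.update(cfg.adapt_interval)
        if not model.include_structured and (it + 1) % 500 == 0:
            eta = model.linear_predictor(state)  # guard against float drift
            Eexp = E * np.exp(eta)
        if not in_burn:
            n_post += 1
            if (it - cfg.burn_in + 1) % cfg.thin == 0:
                out_alpha[kept] = state.alpha
                if p:
                    out_beta[kept] = state.beta
                if out_su is not None:
                    out_su[kept] = state.sigma_u
                if out_sv is not None:
                    out_sv[kept] = state.sigma_v
                if out_u is not None:
                    out_u[kept] = state.u
                if out_v is not None:
                    out_v[kept] = state.v
                kept += 1

    rates = {"alpha": post_counts["alpha"] / n_post}
    for j in range(p):
        rates[f"beta[{model.covariate_names[j]}]"] = post_counts["beta"][j] / n_post
    if model.include_structured:
        free = ~st.isolate_mask
        if free.any():
            rates["u_mean"] = float(post_counts["u"][free].mean() / n_post)
    if model.include_unstructured:
        rates["v_mean"] = float(post_counts["v"].mean() / n_post)
    for key in ("sigma_u", "sigma_v"):
        if rw_attempts[key]:
            rates[key] = post_counts[key] / rw_attempts[key]
    return out_alpha, out_beta, out_su, out_sv, out_u, out_v, rates


def fit_bym(model: BYMModel, config: SamplerConfig) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains; deterministic given seed."""
    alphas, betas, sus, svs, us, vs, rates = [], [], [], [], [], [], []
    for chain in range(config.n_chains):
        a, b, su, sv, u, v, r = _run_chain(model, config, chain)
        alphas.append(a)
        betas.append(b)
        sus.append(su)
        svs.append(sv)
        us.append(u)
        vs.append(v)
        rates.append(r)
    stack = lambda xs: None if xs[0] is None else np.stack(xs)
    keys = sorted(set().union(*[r.keys() for r in rates]))
    acceptance = {k: float(np.mean([r[k] for r in rates if k in r])) for k in keys}
    return PosteriorSamples(
        alpha=np.stack(alphas), beta=np.stack(betas),
        sigma_u=stack(sus), sigma_v=stack(svs),
        u=stack(us), v=stack(vs),
        covariate_names=list(model.covariate_names),
        area_ids=list(model.area_ids),
        acceptance=acceptance, config=config, method=model.method,
    )
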