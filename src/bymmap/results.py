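"""Posterior summaries: the BYMResults object returned by BYMModel.fit()."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .sampler import ConvergenceReport, PosteriorSamples, convergence_report


class BYMResults:
    """Posterior estimates, uncertainties and diagnostics for one BYM fit.

    Carries the fitted :class:`~bymmap.model.BYMModel`, the retained
    :class:`~bymmap.sampler.PosteriorSamples`, and a Gelman-Rubin
    :class:`~bymmap.sampler.ConvergenceReport`.
    """

    def __init__(self, model, samples: PosteriorSamples) -> None:
        self.model = model
        self.samples = samples
        self.convergence: ConvergenceReport = convergence_report(samples)
        self.warnings: list[str] = []
        if samples.n_retained < 100:
            msg = f"only {samples.n_retained} retained draws; summaries are unstable"
            self.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

    # -- area-level --------------------------------------------------------

    def smoothed_smr(self) -> pd.Series:
        """Posterior mean relative risk exp(alpha + u_i + v_i) per area.

        Only defined for the covariate-free smoothing model; with covariates
        in the linear predictor the area risk is no longer the SMR.
        """
        if self.model.p:
            raise ValueError(
                "smoothed SMRs come from the covariate-free model; "
                "refit without covariates"
            )
        s = self.samples
        log_theta = s.alpha[:, :, None]
        if s.u is not None:
            log_theta = log_theta + s.u
        if s.v is not None:
            log_theta = log_theta + s.v
        theta = np.exp(log_theta).mean(axis=(0, 1))
        return pd.Series(theta, index=pd.Index(s.area_ids, name="area_id"),
                         name="smoothed_smr")

    # -- covariate effects --------------------------------------------------

    def rate_ratios(self, point: str = "mean_of_exp") -> pd.DataFrame:
        """RR per one SD with 95% credible interval for each covariate.

        RR is the posterior mean of exp(beta) (``point="mean_of_exp"``, the
        convention of monitoring the transformed node) or exp of the
        posterior mean (``point="exp_of_mean"``).  The CrI is the 2.5th and
        97.5th percentile of the exp(beta) draws; ``excludes_one`` marks
        intervals not covering 1 (the bolding rule in reported tables).
        """
        rows = []
        for name in self.samples.covariate_names:
            draws = np.exp(self.samples.beta_draws(name))
            if point == "mean_of_exp":
                rr = float(draws.mean())
            elif point == "exp_of_mean":
                rr = float(np.exp(np.log(draws).mean()))
            else:
                raise ValueError(f"unknown point summary {point!r}")
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append({"covariate": name, "rr": rr, "lo": float(lo),
                         "hi": float(hi), "excludes_one": bool(not (lo <= 1.0 <= hi))})
        return pd.DataFrame(rows).set_index("covariate")

    # -- diagnostics ---------------------------------------------------------

    @property
    def rhat(self) -> pd.Series:
        return self.convergence.table["rhat"]

    @property
    def converged(self) -> bool:
        return self.convergence.converged

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, 95% CrI and R-hat per monitored scalar."""
        rows = {}
        for name, arr in self.samples.scalar_draws().items():
            flat = arr.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows[name] = {
                "mean": float(flat.mean()), "sd": float(flat.std(ddof=1)),
                "2.5%": float(lo), "97.5%": float(hi),
                "rhat": float(self.convergence.table.loc[name, "rhat"]),
            }
        return pd.DataFrame(rows).T

    def __repr__(self) -> str:
        tag = self.model.method or "BYM"
        return (f"<BYMResults {tag}: {self.samples.n_retained} draws, "
                f"max R-hat {self.convergence.max_rhat:.3f}>")
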