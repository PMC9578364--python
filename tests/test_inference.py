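"""Smoothed SMRs, distribution summaries, rate ratios and the model set."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bymmap import (
    BYMModel,
    SamplerConfig,
    fit_bym,
    method_shares,
    mid90_ratio,
    rate_ratios,
    run_model_set,
    smoothed_smr,
    summarize_distribution,
)
from bymmap.results import BYMResults
from bymmap.sampler import PosteriorSamples

FAST = SamplerConfig(n_chains=2, n_iter=1200, burn_in=600, thin=2, seed=7)


def make_samples(alpha, beta=None, u=None, v=None, names=(), area_ids=(0,)):
    """Hand-built PosteriorSamples for degenerate / synthetic posteriors."""
    alpha = np.asarray(alpha, dtype=float)
    C, T = alpha.shape
    p = len(names)
    if beta is None:
        beta = np.zeros((C, T, p))
    cfg = SamplerConfig(n_chains=max(C, 1), n_iter=2 * T or 2, burn_in=T or 1,
                        thin=1, seed=0)
    return PosteriorSamples(
        alpha=alpha, beta=np.asarray(beta, dtype=float),
        sigma_u=None, sigma_v=None,
        u=None if u is None else np.asarray(u, dtype=float),
        v=None if v is None else np.asarray(v, dtype=float),
        covariate_names=list(names), area_ids=list(area_ids),
        acceptance={}, config=cfg)


# -- distribution summaries --------------------------------------------------

def test_mid90_ratio_from_printed_percentiles():
    # hanging row: 1.27 / 0.83 -> 1.53; other-methods row: 1.47 / 0.73 -> 2.01
    assert mid90_ratio(1.27, 0.83) == pytest.approx(1.53, abs=0.005)
    assert mid90_ratio(1.47, 0.73) == pytest.approx(2.01, abs=0.005)
    with pytest.raises(ValueError):
        mid90_ratio(1.0, 0.0)


def test_method_shares_from_printed_counts():
    counts = {"hanging": 892, "charcoal_burning": 859, "jumping": 566,
              "drowning": 275, "other": 402}
    shares = method_shares(counts)
    assert shares["hanging"] == pytest.approx(29.8, abs=0.05)
    assert shares["charcoal_burning"] == pytest.approx(28.7, abs=0.05)
    assert shares["jumping"] == pytest.approx(18.9, abs=0.05)
    assert shares["drowning"] == pytest.approx(9.2, abs=0.05)
    assert shares["other"] == pytest.approx(13.4, abs=0.05)
    top4 = shares.drop("other").sum()
    assert top4 == pytest.approx(86.6, abs=0.05)


def test_summarize_distribution_constant_vector():
    s = summarize_distribution(np.full(20, 1.3), n_deaths=10, total_deaths=40)
    assert s.mid90_ratio == pytest.approx(1.0)
    assert s.sd == pytest.approx(0.0, abs=1e-12)
    assert s.percent == pytest.approx(25.0)
    assert s.p5 == s.median == s.p95 == pytest.approx(1.3)


def test_summarize_distribution_orders_percentiles(rng):
    x = rng.lognormal(0, 0.3, 500)
    s = summarize_distribution(x)
    assert s.p5 <= s.median <= s.p95
    assert s.mid90_ratio >= 1.0
    with pytest.raises(ValueError):
        summarize_distribution(np.array([1.0, -0.5]))
    with pytest.raises(ValueError):
        summarize_distribution([])


@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
@settings(max_examples=25, deadline=None)
def test_summary_invariances(seed, c):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0, 0.4, 60)
    s = summarize_distribution(x)
    # permutation invariance
    s_perm = summarize_distribution(rng.permutation(x))
    assert s_perm.mid90_ratio == pytest.approx(s.mid90_ratio)
    assert s_perm.median == pytest.approx(s.median)
    # the mid-90% ratio is scale-free
    s_scaled = summarize_distribution(c * x)
    assert s_scaled.mid90_ratio == pytest.approx(s.mid90_ratio, rel=1e-9)


# -- smoothed SMRs and rate ratios -------------------------------------------

def test_smoothed_smr_degenerate_posterior_is_one():
    samples = make_samples(alpha=np.zeros((2, 50)), u=np.zeros((2, 50, 3)),
                           v=np.zeros((2, 50, 3)), area_ids=["a", "b", "c"])
    out = smoothed_smr(samples)
    np.testing.assert_allclose(out.to_numpy(), 1.0)


def test_smoothed_smr_rejects_covariate_models():
    samples = make_samples(alpha=np.zeros((2, 10)), names=["z"],
                           beta=np.zeros((2, 10, 1)))
    with pytest.raises(ValueError, match="covariate-free"):
        smoothed_smr(samples)


def test_rate_ratio_point_mass():
    beta = np.full((2, 200, 1), np.log(2.0))
    samples = make_samples(alpha=np.zeros((2, 200)), beta=beta, names=["z"])
    rr = rate_ratios(samples).loc["z"]
    assert rr["rr"] == pytest.approx(2.0)
    assert rr["lo"] == pytest.approx(2.0)
    assert rr["hi"] == pytest.approx(2.0)
    assert rr["excludes_one"]


def test_rate_ratio_narrow_null_posterior_contains_one(rng):
    draws = rng.normal(0.0, 0.01, (2, 5000, 1))
    samples = make_samples(alpha=np.zeros((2, 5000)), beta=draws, names=["z"])
    rr = rate_ratios(samples).loc["z"]
    # closed-form normal quantiles: CrI ~ exp(0 +/- 1.96 * 0.01) straddles 1
    assert rr["lo"] == pytest.approx(np.exp(-1.96 * 0.01), abs=0.002)
    assert rr["hi"] == pytest.approx(np.exp(+1.96 * 0.01), abs=0.002)
    assert not rr["excludes_one"]


def test_single_area_smoothed_smr_matches_quadrature_oracle():
    """Posterior mean of exp(alpha) for one area against the quadrature
    oracle of the flat-prior Poisson posterior."""
    O, E = 14.0, 9.0
    model = BYMModel([O], [E], include_structured=False,
                     include_unstructured=False)
    cfg = SamplerConfig(n_chains=2, n_iter=22_000, burn_in=2_000, thin=4, seed=13)
    res = BYMResults(model, fit_bym(model, cfg))
    got = res.smoothed_smr().iloc[0]
    grid = np.linspace(-3, 3.5, 6001)
    w = np.exp(O * grid - E * np.exp(grid))
    oracle = float(np.trapezoid(np.exp(grid) * w, grid) / np.trapezoid(w, grid))
    assert got == pytest.approx(oracle, rel=0.01)


def test_results_summary_and_cri_ordering(small_study):
    area_frame, _, _, graph = small_study
    model = BYMModel.from_area_frame(area_frame, "hanging", graph,
                                     covariates=["divorced_pct"])
    res = model.fit(FAST)
    rr = res.rate_ratios().loc["divorced_pct"]
    assert rr["lo"] <= rr["rr"] <= rr["hi"]
    s = res.summary()
    assert {"mean", "sd", "2.5%", "97.5%", "rhat"} <= set(s.columns)
    assert "beta[divorced_pct]" in s.index


def test_shrinkage_of_smoothed_vs_raw(small_study):
    area_frame, _, _, graph = small_study
    model = BYMModel.from_area_frame(area_frame, "overall", graph)
    res = model.fit(dataclasses.replace(FAST, n_iter=2000, burn_in=1000))
    smoothed = res.smoothed_smr().to_numpy()
    raw = area_frame.raw_smr("overall").to_numpy()
    assert smoothed.var(ddof=1) < raw.var(ddof=1)


# -- the model set -----------------------------------------------------------

def test_run_model_set_structure(small_study):
    area_frame, _, _, graph = small_study
    fast = SamplerConfig(n_chains=2, n_iter=600, burn_in=300, thin=3, seed=3,
                         keep_effects=True)
    results, table1, fits = run_model_set(
        area_frame, graph, methods=["overall", "hanging"],
        sampler_config=fast)
    # 5 unadjusted + 3 adjusted rows per method
    assert len(results) == 2 * (5 + 3)
    assert set(results["model_set"]) == {"unadjusted", "adjusted"}
    assert set(results.columns) >= {"method", "covariate", "model_set", "rr",
                                    "lo", "hi", "excludes_one", "rhat_max",
                                    "converged", "logged"}
    assert list(table1.index) == ["overall", "hanging"]
    assert table1.loc["hanging", "n"] == area_frame.observed["hanging"].sum()
    # skewed covariates are marked as logged, the binary river flag is not
    logged = results.set_index("covariate")["logged"]
    assert logged.loc["river"].eq(False).all()
    assert logged.loc["divorced_pct"].eq(True).all()


def test_run_model_set_distance_sensitivity_variant(small_study):
    """Swapping the binary river flag for centroid-to-river distance (which
    contains exact zeros) must fit cleanly with the log rule suppressed."""
    import copy

    from bymmap.spatial import centroid_river_distance

    area_frame, geoms, _, graph = small_study
    af = copy.deepcopy(area_frame)
    af.covariates["river"] = centroid_river_distance(geoms)
    fast = SamplerConfig(n_chains=2, n_iter=400, burn_in=200, thin=2, seed=6)
    results, _, _ = run_model_set(af, graph, methods=["drowning"],
                                  sampler_config=fast, never_log=("river",),
                                  smoothing=False)
    row = results.set_index(["covariate", "model_set"]).loc[("river", "adjusted")]
    assert np.isfinite(row["rr"])
    assert not row["logged"]


def test_run_model_set_skips_zero_death_methods(small_study, caplog):
    import copy

    area_frame, _, _, graph = small_study
    af = copy.deepcopy(area_frame)
    af.observed["drowning"] = 0
    fast = SamplerConfig(n_chains=2, n_iter=400, burn_in=200, thin=2, seed=3)
    with caplog.at_level("WARNING"):
        results, table1, _ = run_model_set(af, graph, methods=["drowning"],
                                           sampler_config=fast)
    assert results.empty
    assert "zero total deaths" in caplog.text
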