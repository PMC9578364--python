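"""Covariate transforms, likelihood, ICAR density and priors."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from bymmap.model import (
    BYMModel,
    BYMState,
    PriorSpec,
    DEFAULT_GAMMA_PRIOR,
    icar_logpdf,
    log_prior,
    poisson_loglik,
    transform_covariates,
)
from bymmap.spatial import SpatialStructure


# -- transforms --------------------------------------------------------------

def test_transform_z_scores_simple_column():
    cov = transform_covariates(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    np.testing.assert_allclose(cov.X["x"], [-1.0, 0.0, 1.0])
    assert cov.transforms["x"] == "none"


def test_transform_rejects_constant_column():
    with pytest.raises(ValueError, match="constant"):
        transform_covariates(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


def test_transform_logs_skewed_column_and_reduces_skewness():
    raw = pd.DataFrame({"x": [1.0, 1.0, 1.0, 100.0]})
    cov = transform_covariates(raw)
    assert cov.transforms["x"] == "log"
    assert abs(stats.skew(np.log(raw["x"]))) < abs(stats.skew(raw["x"]))
    assert cov.X["x"].mean() == pytest.approx(0.0, abs=1e-12)
    assert cov.X["x"].std(ddof=1) == pytest.approx(1.0)


def test_transform_skewed_nonpositive_column_raises():
    raw = pd.DataFrame({"x": [0.0, 0.0, 0.0, 100.0]})
    with pytest.raises(ValueError, match="offset"):
        transform_covariates(raw)


def test_transform_binary_column_never_logged():
    raw = pd.DataFrame({"b": [0.0] * 9 + [1.0]})  # skewness > 1 but binary
    cov = transform_covariates(raw)
    assert cov.transforms["b"] == "none"
    assert cov.binary["b"]
    assert cov.X["b"].std(ddof=1) == pytest.approx(1.0)
    kept = transform_covariates(raw, zscore_binary=False)
    assert set(kept.X["b"]) == {0.0, 1.0}


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_transform_idempotent_on_standardized_columns(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(40)
    z = (x - x.mean()) / x.std(ddof=1)
    if abs(stats.skew(z)) > 1.0:  # rare; the rule would (correctly) log it
        return
    out = transform_covariates(pd.DataFrame({"x": z}))
    np.testing.assert_allclose(out.X["x"], z, atol=1e-9)


# -- Poisson likelihood ------------------------------------------------------

def test_poisson_loglik_zero_counts_closed_form():
    E = np.array([1.5, 2.5, 3.0])
    assert poisson_loglik(np.zeros(3), E, np.zeros(3)) == pytest.approx(-E.sum())


def test_poisson_loglik_hand_example():
    # O=2, E=1, eta=0: 2*0 - 1 - log 2! = -1 - log 2
    assert poisson_loglik([2], [1.0], [0.0]) == pytest.approx(-1 - math.log(2))


def test_poisson_loglik_offset_identifiability_symmetry():
    rng = np.random.default_rng(0)
    O = rng.poisson(5, 10)
    E = rng.uniform(1, 3, 10)
    eta = rng.normal(0, 0.3, 10)
    c = 0.7  # adding c to alpha and subtracting from v leaves eta unchanged
    assert poisson_loglik(O, E, eta + c - c) == pytest.approx(
        poisson_loglik(O, E, eta))
    with pytest.raises(ValueError):
        poisson_loglik(O, np.zeros(10), eta)


# -- ICAR density ------------------------------------------------------------

def path_structure(n):
    g = nx.path_graph(n)
    return SpatialStructure(g, list(range(n)))


def test_icar_constant_u_is_mode():
    st3 = path_structure(3)
    assert st3.pairwise_ss(np.zeros(3)) == 0.0
    assert icar_logpdf(np.zeros(3), st3, 1.0) == pytest.approx(0.0)


def test_icar_three_node_path_hand_example():
    # u=(0,1,-1), sigma=1: pairwise sum (0-1)^2 + (1+1)^2 = 5 -> -2.5
    st3 = path_structure(3)
    assert icar_logpdf(np.array([0.0, 1.0, -1.0]), st3, 1.0) == pytest.approx(-2.5)


def test_icar_sigma_exponent_uses_rank():
    st3 = path_structure(3)
    u = np.array([0.0, 1.0, -1.0])
    sigma = 2.0
    expected = -5.0 / (2 * sigma**2) - (3 - 1) * math.log(sigma)
    assert icar_logpdf(u, st3, sigma) == pytest.approx(expected)


def test_icar_rejects_uncentred_and_isolates():
    st3 = path_structure(3)
    with pytest.raises(ValueError, match="sum to zero"):
        icar_logpdf(np.array([1.0, 1.0, 1.0]), st3, 1.0)
    g = nx.Graph()
    g.add_nodes_from([0, 1, 2])
    g.add_edge(0, 1)
    iso = SpatialStructure(g, [0, 1, 2])
    with pytest.raises(ValueError, match="solated"):
        icar_logpdf(np.array([0.5, -0.5, 0.3]), iso, 1.0)
    # zero on the isolate is fine
    assert np.isfinite(icar_logpdf(np.array([0.5, -0.5, 0.0]), iso, 1.0))


def constrained_gaussian_logpdf(u, graph, sigma):
    """Independent oracle: multivariate normal restricted to the sum-to-zero
    subspace with precision (D - W) / sigma^2, via eigen-decomposition."""
    nodes = list(graph.nodes)
    n = len(nodes)
    W = nx.to_numpy_array(graph, nodelist=nodes)
    L = np.diag(W.sum(axis=1)) - W
    lam, Q = np.linalg.eigh(L / sigma**2)
    pos = lam > 1e-10
    z = Q[:, pos].T @ u
    return float(-0.5 * z @ (lam[pos] * z) + 0.5 * np.sum(np.log(lam[pos]))
                 - 0.5 * pos.sum() * math.log(2 * math.pi))


def test_icar_matches_constrained_gaussian_oracle_up_to_constant():
    """On a connected graph the pairwise-difference form differs from the
    eigen-decomposition oracle only by a (u, sigma)-independent constant."""
    rng = np.random.default_rng(3)
    g = nx.cycle_graph(5)
    g.add_edge(0, 2)
    struct = SpatialStructure(g, list(range(5)))
    diffs = []
    for _ in range(6):
        u = rng.normal(0, 1, 5)
        u -= u.mean()
        sigma = rng.uniform(0.3, 2.5)
        diffs.append(icar_logpdf(u, struct, sigma)
                     - constrained_gaussian_logpdf(u, g, sigma))
    assert np.ptp(diffs) < 1e-8


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_icar_invariant_to_recentred_constant_shift(seed):
    rng = np.random.default_rng(seed)
    struct = path_structure(6)
    u = rng.normal(0, 1, 6)
    u -= u.mean()
    shifted, _ = struct.center(u + rng.normal())
    assert icar_logpdf(shifted, struct, 0.8) == pytest.approx(
        icar_logpdf(u, struct, 0.8), abs=1e-9)


# -- priors ------------------------------------------------------------------

def make_state(su, sv):
    return BYMState(0.0, np.zeros(1), np.zeros(2), np.zeros(2), su, sv)


def test_uniform_sd_prior_support():
    prior = PriorSpec()
    assert log_prior(make_state(1.0, 1.0), prior) == 0.0
    assert log_prior(make_state(6.0, 1.0), prior) == -math.inf
    assert log_prior(make_state(1.0, 5.5), prior) == -math.inf


def test_gamma_precision_prior_closed_form():
    a = b = 0.01
    # at tau = 1: a log b - log Gamma(a) + (a-1) log 1 - b
    expected_one = a * math.log(b) - gammaln(a) - b
    assert log_prior(make_state(1.0, 1.0), DEFAULT_GAMMA_PRIOR) == pytest.approx(
        2 * expected_one)
    # cross-check against scipy's gamma density at a non-unit precision
    sigma = 0.7
    tau = sigma**-2
    expected = 2 * stats.gamma.logpdf(tau, a, scale=1 / b)
    assert log_prior(make_state(sigma, sigma), DEFAULT_GAMMA_PRIOR) == pytest.approx(
        expected)


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec("lognormal_sd")
    with pytest.raises(ValueError):
        PriorSpec("uniform_sd", (5.0, 1.0))
    with pytest.raises(ValueError):
        PriorSpec("gamma_precision", (0.0, 0.01))


# -- model object ------------------------------------------------------------

def test_model_rejects_bad_inputs():
    g = nx.path_graph(3)
    struct = SpatialStructure(g, [0, 1, 2])
    with pytest.raises(ValueError, match="positive"):
        BYMModel([1, 2, 3], [1.0, 0.0, 1.0], structure=struct)
    with pytest.raises(ValueError, match="spatial structure"):
        BYMModel([1, 2, 3], [1.0, 1.0, 1.0], structure=None)


def test_log_posterior_decreases_for_extreme_intercepts():
    g = nx.path_graph(4)
    struct = SpatialStructure(g, list(range(4)))
    model = BYMModel([2, 3, 1, 4], np.full(4, 2.0), structure=struct)
    base = BYMState(0.0, np.zeros(0), np.zeros(4), np.zeros(4), 0.5, 0.5)
    lp0 = model.log_posterior(base)
    for alpha in (8.0, -8.0):
        s = base.copy()
        s.alpha = alpha
        assert model.log_posterior(s) < lp0
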