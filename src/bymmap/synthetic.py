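"""Synthetic small-area study generator with known BYM structure.

Emulates the structure of a city-wide neighbourhood suicide study: 432
areas on a rectangular lattice, right-skewed age-structured populations
(median population aged 10+ near 5,050), two socioeconomic covariates, three
means-accessibility covariates (two skewed proportions and a binary river
corridor flag covering ~22.2% of areas), and method-specific death counts

    O_{i,m} ~ Poisson(E_{i,m} * exp(alpha_m + x_i' beta_m + u_{m,i} + v_{m,i}))

with u an exact ICAR draw (spectral sampling on the sum-to-zero subspace of
the lattice Laplacian) and v i.i.d. normal.  Everything downstream of the
generator — classification, standardization, adjacency, model fitting —
can therefore be tested against known ground truth.

Expected counts come from a fixed log-linear-in-age reference rate schedule
scaled so the region-wide expected total per method matches the configured
method totals.  The AreaFrame the generator returns, however, recomputes its
expected counts by internal indirect standardization from the *realized*
synthetic deaths, exactly as the pipeline would from registry files; the
reference-schedule expectations are kept in the returned truth object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .model import transform_covariates
from .spatial import GeometrySet, SpatialStructure, build_adjacency
from .standardize import AGE_BANDS, METHODS, AreaFrame, build_area_frame

# Fixed age composition (share of the 10+ population per 5-year band) and a
# canonical ICD-10 code per method used when expanding counts to records.
_AGE_WEIGHTS = np.array(
    [6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 8.5, 8.0, 7.5, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.5]
)
_AGE_WEIGHTS = _AGE_WEIGHTS / _AGE_WEIGHTS.sum()

_METHOD_CODE = {
    "charcoal_burning": "X67",
    "hanging": "X70",
    "drowning": "X71",
    "jumping": "X80",
    "other": "X64",
}

#: Region-wide expected deaths per method over the study period, matching the
#: printed method counts of the emulated study (hanging 892, charcoal 859,
#: jumping 566, drowning 275, other 402 of 2,994).
DEFAULT_METHOD_TOTALS = {
    "hanging": 892.0,
    "charcoal_burning": 859.0,
    "jumping": 566.0,
    "drowning": 275.0,
    "other": 402.0,
}

COVARIATES = ("divorced_pct", "median_income", "single_person_pct",
              "sixth_floor_pct", "river")

# Default covariate effects (log RR per one SD on the analysis scale),
# encoding the emulated study's adjusted-effect pattern: socioeconomic
# gradients on every method, plus one method-specific accessibility effect
# each for charcoal burning, jumping and drowning.
def _default_beta() -> dict:
    beta = {m: {c: 0.0 for c in COVARIATES} for m in METHODS}
    for m in METHODS:
        beta[m]["divorced_pct"] = np.log(1.10)
        beta[m]["median_income"] = np.log(0.81)
    beta["charcoal_burning"]["single_person_pct"] = np.log(1.13)
    beta["jumping"]["sixth_floor_pct"] = np.log(1.16)
    beta["drowning"]["river"] = np.log(1.27)
    return beta


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults emulate the real study."""

    n_areas: int = 432
    grid_rows: int = 18
    grid_cols: int = 24
    age_bands: tuple = AGE_BANDS
    median_population: float = 5050.0
    population_log_sd: float = 1.10  # 5th-95th span ~ (840, 31300)/5050
    methods: tuple = METHODS
    method_totals: dict = field(default_factory=lambda: dict(DEFAULT_METHOD_TOTALS))
    true_alpha: dict = field(default_factory=lambda: {m: 0.0 for m in METHODS})
    true_beta: dict = field(default_factory=_default_beta)
    true_sigma_u: float = 0.3
    true_sigma_v: float = 0.2
    river_fraction: float = 0.222
    years: int = 7
    seed: int = 0
    age_rate_slope: float = 0.08  # log-linear increase per 5-year band

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be positive")
        if self.grid_rows * self.grid_cols < self.n_areas:
            raise ValueError("grid_rows * grid_cols must be >= n_areas")
        if self.median_population <= 0:
            raise ValueError("median_population must be positive")
        if not (0.0 <= self.river_fraction <= 1.0):
            raise ValueError("river_fraction must lie in [0, 1]")
        if self.true_sigma_u < 0 or self.true_sigma_v < 0:
            raise ValueError("true sigmas must be nonnegative")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for m, bm in self.true_beta.items():
            if m not in self.methods:
                raise ValueError(f"true_beta for unknown method {m!r}")
            unknown = set(bm) - set(COVARIATES)
            if unknown:
                raise ValueError(f"true_beta for unknown covariates {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    theta: pd.DataFrame          # area x method true relative risks
    u: pd.DataFrame              # area x method structured effects (sum zero)
    v: pd.DataFrame              # area x method unstructured effects
    covariates_raw: pd.DataFrame
    covariates_analysis: pd.DataFrame  # transformed + z-scored, effects applied here
    expected_reference: pd.DataFrame   # E from the reference rate schedule
    alpha: dict
    beta: dict
    config: SyntheticConfig


def _lattice_cells(config: SyntheticConfig):
    """(row, col) of each area, row-major, first n_areas cells."""
    cells = [(r, c) for r in range(config.grid_rows) for c in range(config.grid_cols)]
    return cells[: config.n_areas]


def _area_ids(n: int) -> list:
    return [f"A{k:04d}" for k in range(n)]


def _river_flags(config: SyntheticConfig) -> np.ndarray:
    """Serpentine corridor of exactly round(fraction * n) areas.

    Cells are ranked column by column from the left edge, rows alternating
    direction (a serpentine), so the flagged set is a contiguous corridor of
    lattice columns and consecutive flagged cells are rook-adjacent.
    """
    cells = _lattice_cells(config)
    index = {cell: k for k, cell in enumerate(cells)}
    k_flag = int(round(config.river_fraction * config.n_areas))
    order = []
    for c in range(config.grid_cols):
        rows = range(config.grid_rows) if c % 2 == 0 else range(config.grid_rows - 1, -1, -1)
        for r in rows:
            if (r, c) in index:
                order.append((r, c))
    flags = np.zeros(config.n_areas, dtype=int)
    for cell in order[:k_flag]:
        flags[index[cell]] = 1
    return flags


def _geometry(config: SyntheticConfig, flags: np.ndarray) -> GeometrySet:
    cells = _lattice_cells(config)
    ids = _area_ids(config.n_areas)
    areas = {}
    for aid, (r, c) in zip(ids, cells):
        areas[aid] = box(c, -(r + 1), c + 1, -r)  # unit squares, y downward by row
    rivers = []
    if flags.any():
        index = {cell: k for k, cell in enumerate(cells)}
        order = []
        for c in range(config.grid_cols):
            rows = range(config.grid_rows) if c % 2 == 0 else range(config.grid_rows - 1, -1, -1)
            for r in rows:
                if (r, c) in index and flags[index[(r, c)]]:
                    order.append((r, c))
        pts = [(c + 0.5, -(r + 0.5)) for r, c in order]
        if len(pts) >= 2:
            rivers = [LineString(pts)]
        else:  # a single flagged cell: short segment inside it
            (x, y), = pts
            rivers = [LineString([(x - 0.25, y), (x + 0.25, y)])]
    return GeometrySet(areas=areas, rivers=rivers)


def _icar_sample(structure: SpatialStructure, sigma: float, n_draws: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Exact draws from the ICAR prior on the sum-to-zero subspace.

    Spectral sampling: with L = D - W and positive eigenpairs (lam_k, q_k),
    u = sigma * sum_k lam_k^{-1/2} z_k q_k, independent per draw.  Isolates
    and component means carry no variation (u = 0 there).
    """
    n = structure.n
    if sigma == 0 or structure.rank == 0:
        return np.zeros((n_draws, n))
    L = np.diag(structure.degree) - structure.W.toarray()
    lam, Q = np.linalg.eigh(L)
    pos = lam > 1e-8
    z = rng.standard_normal((n_draws, int(pos.sum())))
    u = (z / np.sqrt(lam[pos])) @ Q[:, pos].T * sigma
    # eigenvectors are orthogonal to each component's indicator: already
    # sum-to-zero per component; kill float residue exactly
    for c in structure.components:
        if len(c) >= 2:
            u[:, c] -= u[:, c].mean(axis=1, keepdims=True)
    return u


def simulate_study(config: SyntheticConfig):
    """Generate one synthetic study.

    Returns ``(area_frame, geometry, truth)``; deterministic given the
    config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_areas
    ids = _area_ids(n)
    bands = list(config.age_bands)
    n_bands = len(bands)
    if n_bands != _AGE_WEIGHTS.size:
        age_w = np.ones(n_bands) / n_bands
    else:
        age_w = _AGE_WEIGHTS

    # populations: log-normal, rescaled so the sample median hits the target
    pop = rng.lognormal(mean=np.log(config.median_population),
                        sigma=config.population_log_sd, size=n)
    pop *= config.median_population / np.median(pop)
    person_years = np.outer(pop, age_w) * config.years  # area x band
    populations = pd.DataFrame(person_years, index=pd.Index(ids, name="area_id"),
                               columns=bands)

    # geometry, adjacency, river corridor
    flags = _river_flags(config)
    geoms = _geometry(config, flags)
    graph = build_adjacency(geoms, contiguity="rook")
    structure = SpatialStructure(graph, ids)

    # covariates
    raw = pd.DataFrame(
        {
            "divorced_pct": rng.lognormal(np.log(5.0), 0.5, n),
            "median_income": rng.normal(600.0, 100.0, n).clip(min=50.0),
            "single_person_pct": rng.lognormal(np.log(10.0), 0.5, n),
            "sixth_floor_pct": rng.lognormal(np.log(20.0), 0.6, n),
            "river": flags.astype(float),
        },
        index=pd.Index(ids, name="area_id"),
    )
    analysis = transform_covariates(raw).X

    # reference expected counts: log-linear-in-age schedule scaled per method
    shape = np.exp(config.age_rate_slope * np.arange(n_bands))
    band_exposure = person_years @ shape  # area totals under unit scale
    e_ref = {}
    for m in config.methods:
        total = config.method_totals.get(m, 0.0)
        scale = total / band_exposure.sum() if band_exposure.sum() > 0 else 0.0
        e_ref[m] = band_exposure * scale
    expected_ref = pd.DataFrame(e_ref, index=populations.index)

    # random effects and counts
    u_draws = _icar_sample(structure, config.true_sigma_u, len(config.methods), rng)
    v_draws = config.true_sigma_v * rng.standard_normal((len(config.methods), n))
    theta, u_df, v_df, obs = {}, {}, {}, {}
    death_rows = []
    band_probs = person_years * shape  # proportional age distribution of E
    band_probs = band_probs / band_probs.sum(axis=1, keepdims=True)
    band_ages = [int(b.split("-")[0]) if "-" in b else int(b.rstrip("+")) for b in bands]
    for k, m in enumerate(config.methods):
        beta_m = np.array([config.true_beta.get(m, {}).get(c, 0.0) for c in analysis.columns])
        log_theta = (config.true_alpha.get(m, 0.0)
                     + analysis.to_numpy() @ beta_m + u_draws[k] + v_draws[k])
        theta[m] = np.exp(log_theta)
        u_df[m], v_df[m] = u_draws[k], v_draws[k]
        counts = rng.poisson(expected_ref[m].to_numpy() * theta[m])
        obs[m] = counts
        for i, aid in enumerate(ids):
            if counts[i] == 0:
                continue
            per_band = rng.multinomial(counts[i], band_probs[i])
            for b_idx in np.nonzero(per_band)[0]:
                death_rows.append(
                    {"area_id": aid, "age": band_ages[b_idx] + 2,
                     "icd10_code": _METHOD_CODE[m], "count": int(per_band[b_idx])}
                )
    deaths = pd.DataFrame(death_rows,
                          columns=["area_id", "age", "icd10_code", "count"])

    area_frame = build_area_frame(deaths, populations, raw, bands=tuple(bands))
    area_frame.meta["deaths"] = deaths  # registry-format table for write_study
    truth = SyntheticTruth(
        theta=pd.DataFrame(theta, index=populations.index),
        u=pd.DataFrame(u_df, index=populations.index),
        v=pd.DataFrame(v_df, index=populations.index),
        covariates_raw=raw,
        covariates_analysis=analysis,
        expected_reference=expected_ref,
        alpha=dict(config.true_alpha),
        beta={m: dict(config.true_beta.get(m, {})) for m in config.methods},
        config=config,
    )
    return area_frame, geoms, truth


def write_study(area_frame: AreaFrame, geoms: GeometrySet, truth: SyntheticTruth,
                out_dir) -> dict:
    """Persist a simulated study as the CSV/GeoJSON files the pipeline reads."""
    import json
    import os

    from .spatial import write_geometry_set

    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("deaths", "deaths.csv"), ("population", "population.csv"),
        ("covariates", "covariates.csv"), ("areas", "areas.geojson"),
        ("rivers", "rivers.geojson"), ("truth", "truth.json"),
    ]}
    cfg = truth.config
    deaths = area_frame.meta.get("deaths")
    if deaths is None:
        raise ValueError("area frame carries no registry-format deaths table")
    deaths.to_csv(paths["deaths"], index=False)
    pop_long = area_frame.population.stack().rename("person_years").reset_index()
    pop_long.columns = ["area_id", "age_band", "person_years"]
    pop_long.to_csv(paths["population"], index=False)
    area_frame.covariates.to_csv(paths["covariates"])
    write_geometry_set(geoms, paths["areas"], paths["rivers"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "alpha": truth.alpha,
            "beta": truth.beta,
            "sigma_u": cfg.true_sigma_u,
            "sigma_v": cfg.true_sigma_v,
            "seed": cfg.seed,
            "theta": {m: truth.theta[m].round(6).tolist() for m in truth.theta},
        }, fh, indent=1)
    return paths
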