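# bymmap

Small-area disease mapping for method-specific mortality: indirect age
standardization, contiguity and river-accessibility indicators from
polygons, and a Besag–York–Mollié (BYM) Bayesian hierarchical Poisson
model fitted from scratch by Markov-chain Monte Carlo.

## Who this is for

Spatial epidemiologists analysing counts of a rare outcome (here:
method-specific suicide deaths) across many small administrative areas — a
setting where raw standardized mortality ratios (SMRs) are dominated by
Poisson noise and must be smoothed, and where area-level covariates (such
as indicators of how accessible a suicide method is) are related to rates
via rate ratios with credible intervals. The package also ships a
synthetic-study generator emulating a 432-neighbourhood city, so the whole
pipeline is testable end to end with known ground truth and no restricted
registry data.

## The model

For areas *i* = 1…n and one cause-of-death method,

    O_i ~ Poisson(E_i · θ_i),    log θ_i = α + x_iᵀβ + u_i + v_i

- `O_i` — observed deaths; `E_i` — expected deaths by **internal indirect
  age standardization** in 5-year bands (the study region over the full
  period is its own standard, so Σ E = Σ O and the regional SMR is 1),
  entering as an offset;
- `u` — spatially **structured** random effect with an intrinsic CAR
  (pairwise-difference) prior over the rook-contiguity graph, identified by
  a sum-to-zero constraint per connected component;
- `v` — **unstructured** exchangeable Normal(0, σ_v²) effect;
- scales: σ_u, σ_v ~ Uniform(0, 5) (main), or 1/σ² ~ Gamma(0.01, 0.01)
  (sensitivity);
- covariates are z-scored (log-transformed first when sample skewness
  exceeds 1), so exp(β_j) is a **rate ratio per one SD**.

Fitting is Metropolis-within-Gibbs: adaptive single-site random-walk
updates for α, each β_j and each u_i, v_i (the u scan is organised by graph
colour class so conditionally independent sites update vectorised), exact
Gibbs draws for the scales, two overdispersed chains, and Gelman–Rubin
R̂ diagnostics. The covariate-free fit yields **smoothed SMRs**
(posterior means of exp(α + u_i + v_i)); covariate fits yield RRs with 95%
credible intervals, unadjusted and adjusted for two socioeconomic
covariates.

## Worked example

```python
import bymmap as bm

cfg = bm.SyntheticConfig(seed=1)               # 432-area default study
frame, geoms, truth = bm.simulate_study(cfg)
graph = bm.build_adjacency(geoms)              # rook contiguity

# smoothed SMRs from the covariate-free model
model = bm.BYMModel.from_area_frame(frame, "charcoal_burning", graph)
res = model.fit(n_chains=2, n_iter=5000, burn_in=2500, thin=2, seed=1)
smr = res.smoothed_smr()
print(bm.summarize_distribution(smr, n_deaths=int(frame.observed["charcoal_burning"].sum()),
                                total_deaths=int(frame.observed.to_numpy().sum())))

# adjusted rate ratio for an accessibility covariate
adj = bm.BYMModel.from_area_frame(
    frame, "charcoal_burning", graph,
    covariates=["divorced_pct", "median_income", "single_person_pct"])
print(adj.fit(n_chains=2, n_iter=5000, burn_in=2500, thin=2, seed=1)
         .rate_ratios().round(3))
```

Output (abridged):

```
DistributionSummary(n=887, percent=27.14, mean=1.011, sd=0.194,
                    p5=0.757, median=0.983, p95=1.345, mid90_ratio=1.776)
                      rr     lo     hi  excludes_one
covariate
divorced_pct       1.061  0.982  1.148         False
median_income      0.835  0.768  0.899          True
single_person_pct  1.143  1.054  1.234          True
```

The distribution summary says this method accounts for 27% of simulated
deaths and its smoothed SMRs span a 1.78-fold mid-90% range (95th over 5th
percentile) across areas. The rate-ratio table reads: one SD higher
(log) single-person-household share multiplies the charcoal-burning rate
by 1.14 (95% CrI 1.05–1.23) after adjustment for the two socioeconomic
covariates — the interval excludes 1 and brackets the generator's true
adjusted RR of 1.13 (`exp(truth.beta["charcoal_burning"]["single_person_pct"])`).

The same pipeline runs from files via the CLI:

```sh
bymmap simulate --seed 1 --out data/
bymmap standardize --data data/ --out std/
bymmap adjacency --data data/ --out adj/
bymmap fit --data data/ --out fit/ --seed 1 --chains 2 --iters 5000 --burn-in 2500
bymmap summarize --results fit/
```

with `--prior gamma_precision` and `--river-covariate distance` switching
the sensitivity analyses and `--contiguity queen` the adjacency rule.

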