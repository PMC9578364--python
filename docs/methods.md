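# Methods

This note documents the statistical machinery in `bymmap`: the model, its
priors and transforms, the sampler, the synthetic-study generator, the
numerical conventions, and what the validation studies do and do not show.

## Standardization

Deaths are classified from ICD-10 codes into five method groups. Certified
suicides (X60–X84) are combined with deaths of undetermined intent
(Y10–Y34), suffocation injuries (W75, W76, W83, W84) and pesticide-poisoning
injuries (X48), reflecting the well-documented misclassification of
suicides in Taiwanese vital registration. Method mapping: charcoal burning
X67/Y17; hanging X70/Y20/W75/W76/W83/W84; drowning X71/Y21; jumping
X80/Y30; everything else in those ranges (plus X48) is "other". Records
below age 10 are excluded; counts are aggregated over the full study
period before modelling.

Expected counts use internal indirect standardization in 5-year age bands
("10–14" … "85+"; the open-ended top band is the conventional choice since
only the band width is given by the design):

E_{i,m} = Σ_a n_{i,a} · D_{a,m} / N_a,

with n the area-by-band person-periods and D, N the region-wide band
totals. Using the study region itself as the standard forces
Σ_i E_{i,m} = Σ_i O_{i,m} exactly, so smoothed SMRs centre near 1 and the
intercept absorbs only residual level. E is invariant to rescaling all
populations (rates scale inversely), a property the tests exercise.

## The BYM model

Per method, O_i ~ Poisson(E_i exp(η_i)) with
η_i = α + x_iᵀβ + u_i + v_i.

- **u (structured):** intrinsic CAR in pairwise-difference form,
  log p(u | σ_u) = −(1/2σ_u²) Σ_{(i,j)∈edges} (u_i − u_j)² − rank·log σ_u,
  where rank = n − (number of connected components). The density is
  improper (constant per component mean); identification comes from
  re-centring u to sum to zero per component after every sweep, with the
  removed overall mean transferred to α (on a connected map η is exactly
  preserved). Isolated areas get u ≡ 0 — the ICAR conditional is undefined
  for them — and contribute only through v.
- **v (unstructured):** i.i.d. Normal(0, σ_v²).
- **Priors:** σ_u, σ_v ~ Uniform(0, 5) in the main analysis;
  1/σ² ~ Gamma(0.01, 0.01) (rate parameterization) as the sensitivity
  alternative. α and β carry flat improper priors by default
  (`beta_prior_sd` switches to Normal(0, sd²); vague-normal is the classic
  BUGS convention, flat is the limit and is proper here because the
  Poisson likelihood is log-concave in α, β).
- **Covariates:** continuous columns with |sample skewness| > 1 are
  natural-log transformed, then all columns are z-scored (sample SD,
  ddof 1), so exp(β) is a rate ratio per one SD of the analysis-scale
  variable. The binary river flag is z-scored by default so "per one SD"
  reads uniformly across indicators; `zscore_binary=False` keeps it 0/1.
  The transform record is carried through to the results table (the
  `logged` column).

## Spatial structure

Adjacency is rook contiguity — an edge where two polygons share a boundary
intersection of positive length — with queen (any shared point) as an
option; geometry predicates are shapely, the graph is networkx. The two
river indicators mirror the two accessibility definitions: a binary flag
(any river polyline intersects the area polygon or its boundary) and a
continuous centroid-to-nearest-river Euclidean distance. Coordinates are
assumed planar/projected; no geodesic computation is attempted. The flag
and the distance are deliberately not cross-constrained: the flag uses the
polygon, the distance uses the centroid, and a river can clip a corner of
a large area whose centroid is far away.

## Sampler

Metropolis-within-Gibbs, deterministic given the seed:

- α, each β_j: scalar adaptive Gaussian random-walk Metropolis.
- u: single-site random-walk updates organised by graph-colour class
  (greedy colouring). Within a class no two areas are adjacent, so the
  single-site acceptance ratios are mutually independent given the rest of
  the state; evaluating a class in one vectorised pass is numerically
  identical to a sequential site-by-site scan ordered by colour, and is
  what makes 432-area fits take seconds rather than minutes.
- v: all sites factorise given the rest; one vectorised pass.
- Scales: under the gamma-precision prior, conjugate Gibbs
  (τ_u ~ Gamma(a + rank/2, b + S_u/2) with S_u the pairwise sum of squared
  differences; τ_v ~ Gamma(a + n/2, b + Σv²/2)). Under the uniform-SD
  prior, the full conditional in τ = σ⁻² is Gamma(rank/2 − 1/2, S/2)
  truncated to σ ∈ (0, 5), which is sampled *exactly* by inverse CDF;
  a random-walk step on log σ is kept as fallback for degenerate shapes
  (rank ≤ 1). The exact draw matters: the split of total heterogeneity
  between u and v is weakly identified, and Metropolis scale updates mix
  through that ridge very slowly at moderate chain lengths.
- Adaptation: Robbins–Monro on the log proposal scale toward 0.44
  acceptance (the single-site optimum), batched every `adapt_interval`
  iterations during burn-in only; scales are frozen afterwards, so the
  retained chain is a fixed Markov kernel.
- Initialization: α = log(ΣO/ΣE), β = u = v = 0, σ = 0.5; chain 2 starts
  overdispersed (+0.5 on α and β, σ = 1) so R̂ is meaningful.
- Defaults: 2 chains × 20,000 iterations, 10,000 burn-in, thinning 5.
  These are implementation choices, not quantities inherited from any
  dataset; the replicate studies below use 2 × 5,000 (burn-in 2,500,
  thinning 2), which the recovery results show is sufficient for the
  regression coefficients (R̂ ≈ 1.00) though the scale parameters can
  still show R̂ above 1.1 there — fits carry their full R̂ table and a
  `converged` flag rather than hiding this.

Convergence is monitored by the classic Gelman–Rubin PSRF on retained
draws, R̂ = sqrt(((n−1)/n·W + B/n)/W), threshold 1.1 (the conventional
cutoff); W = 0 is reported as undefined rather than silently passed. Rows
failing the threshold are flagged, never dropped.

## Reported quantities

- **Smoothed SMRs**: posterior means of exp(α + u_i + v_i) from the
  covariate-free fit (requesting them from a covariate model is an error:
  with covariates the area term is no longer the SMR). Smoothing is
  global-and-local shrinkage; the validation suite verifies
  var(smoothed) < var(raw).
- **Distribution summaries**: n, percent share, mean, SD, 5th/50th/95th
  percentiles (numpy's linear-interpolation convention) and the mid-90%
  ratio p95/p5 — scale-free, permutation-invariant, and equal to 1 for a
  constant vector.
- **Rate ratios**: RR = posterior mean of exp(β) (the convention of
  monitoring the transformed node; exp-of-mean is available), 95% CrI from
  the 2.5th/97.5th percentiles of the exp(β) draws, and an `excludes_one`
  flag. Fewer than 100 retained draws triggers a recorded warning.
- **Model set**: per method (overall + each group with any deaths): the
  covariate-free smoothing fit, one single-covariate model per covariate
  ("unadjusted" — the two socioeconomic rows are single-covariate models,
  the simplest reading of a table that lists them under one unadjusted
  block), and one model per accessibility indicator adjusted for the two
  socioeconomic covariates. Zero-death methods are skipped with a logged
  message.

## Synthetic-study generator

The generator emulates the *structure* of a dense-city neighbourhood
study, not any real geography:

- 432 unit-square areas on an 18×24 lattice (any lattice ≥ n_areas works);
  rook adjacency arises from the returned polygons.
- Populations aged 10+: log-normal with σ_log = 1.10 — chosen so the
  5th–95th range spans roughly (840, 31,300) around the median — rescaled
  so the sample median hits the 5,050 target exactly; a fixed age
  composition shared across areas; person-years = population × 7 years.
  (The emulated study's printed mean/SD/range are mutually inconsistent
  with any two-parameter distribution; the quantile span is the feature
  that matters for standardization and is the one matched.)
- Covariates: a right-skewed "divorced/separated" share and a symmetric
  "median income" (socioeconomic); right-skewed single-person-household
  and sixth-floor-or-above shares, and a binary river flag
  (accessibility). The river corridor covers exactly
  round(0.222 · n_areas) cells, assigned serpentine-wise along contiguous
  lattice columns; the returned river polyline threads those cells'
  centres, so on a complete lattice the geometric flag reproduces the
  covariate exactly.
- Expected counts: a fixed log-linear-in-age reference schedule (slope
  0.08 per band — any positive schedule serves; the shape only has to make
  E > 0 and vary by age) scaled so region-wide expected totals equal the
  configured per-method totals (defaults 892/859/566/275/402, the printed
  method counts of the emulated study).
- Truth: u drawn exactly from the ICAR prior by spectral sampling on the
  sum-to-zero subspace of the lattice Laplacian (feasible at these sizes);
  v i.i.d. normal; default σ_u = 0.3, σ_v = 0.2; default covariate
  effects encode the emulated study's adjusted-effect pattern
  (single-person → charcoal 1.13, sixth-floor → jumping 1.16,
  river → drowning 1.27, divorced 1.10 and income 0.81 on all methods),
  applied on the analysis (z-score) scale so recovery comparisons are
  direct. Counts are Poisson; deaths are expanded to a registry-like
  (area, age, code, count) table by multinomial allocation across bands.
- The returned analysis table recomputes E by internal indirect
  standardization from the realized deaths — exactly what the pipeline
  would do with registry files — while the reference-schedule E lives in
  the truth object.

What the generator does *not* emulate: real Taipei geography or demography,
spatial covariate autocorrelation, method-specific age profiles, within-
period time trends, or migration. Passing recovery tests therefore shows
the estimator is correct under the model's own assumptions, not that those
assumptions hold in any particular registry.

## Validation studies

- **Recovery** (50 replicates, 432 areas, true RR 1.15 on one
  accessibility covariate, σ_u = 0.3, σ_v = 0.2, 2 chains × 5,000): the
  replicate-averaged posterior mean of β against log 1.15, and 95% CrI
  coverage of the truth. Averaging over replicates separates estimator
  bias from single-draw data noise (a single 432-area draw moves the
  posterior mean by ±0.05 routinely).
- **Shrinkage** (default study): variance of smoothed vs raw SMRs.
- **Specificity** (20 replicates, charcoal-only single-person effect,
  RR 1.3): the adjusted charcoal cell must flag and the adjusted hanging
  cell must not. The 1.3 effect size is chosen as the smallest a study of
  this size detects near-certainly (posterior SD of β ≈ 0.05); a 1.13
  effect has roughly 65% power here and could not meet an
  80%-of-replicates bar for any correct implementation.

## Numerical conventions and edge cases

- Percentiles: linear interpolation everywhere (numpy default).
- Sample SDs use ddof = 1; z-scoring tolerance 1e-9.
- Degenerate inputs raise early with named offenders: non-positive E,
  deaths in zero-population bands, constant or non-positive-under-log
  covariates, duplicate area ids, invalid polygons, isolates with nonzero
  structured effect, non-finite initial log-posterior.
- Seeds: every stochastic entry point takes one; chains use
  independently-seeded generators derived from (seed, chain index);
  identical config + seed is bit-reproducible.

## Known limitations

- Single-site Metropolis mixes the u/v variance split slowly; at short
  chain lengths σ_u and σ_v can carry R̂ > 1.1 even when α and β have
  converged. Longer runs (the 20,000-iteration default) resolve this.
- The ICAR density is unnormalized (constant omitted); fine for MCMC and
  all tests, but not for marginal-likelihood comparison across graphs.
- No proper-CAR/Leroux/BYM2 reparameterization, no spatially varying
  coefficients, no multiple-testing adjustment (none is part of the
  emulated design).
- Queen-vs-rook is exposed but the model graph and the river join use
  whichever is configured; no attempt is made to infer the "right" rule
  from data.
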