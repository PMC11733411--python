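# Methods

This note documents the models and procedures implemented in `tradefd`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Ledger filtering and whole-organism equivalents

A shipment ledger row carries a year, species, term/unit, quantity,
exporter, importer, optional origin, and single-letter source and purpose
codes.  The analysis set is defined by a `FilterSpec`: wild-sourced records
are source codes W, X and R; captive-produced records are C, D and F;
commercial purposes default to {P, T}; the default year window is 2000–2020.
A record is treated as a re-export — and dropped by default — when its
origin field is non-blank and differs from the exporter, the standard
ledger convention.  Species delisted mid-period can be supplied as a
`species → year` map; their records in later years are excluded.

Terms and units are made comparable by conversion to whole-organism
equivalents.  The shipped default table is deliberately minimal and
documented: count-like terms (live, bodies, skins, skulls, trophies) convert
one-for-one, paired items by a configurable factor, mass terms (meat in kg
or g) divide by species body mass in grams, and residual derivative terms
are dropped with a logged event.  The default is a stand-in: published
conversion tables for specific ledgers should be supplied as a `WOETable`
when available.  Unknown (term, unit) combinations follow a configurable
policy — drop-and-log (default) or hard error.  `to_woe` is homogeneous of
degree 1 in quantity, and aggregation conserves WOE exactly: matrix row sums
equal the filtered ledger total at every grouping level.

Assemblage matrices always carry the full species pool as columns, so
species never recorded in trade appear as all-zero columns — the pool, not
the traded subset, defines the functional space.  Threat stratification maps
CR/EN/VU to "threatened" and NT/LC to "non-threatened"; Data Deficient and
unassessed species are excluded from threat-stratified matrices (only).

The sparse-assemblage rule drops rows with fewer than `min_species` traded
species (default 4: a convex hull in an `m`-axis space needs at least
`m + 1` affinely independent points, and the default space has 3 axes).  The
exclusion report records the dropped keys, their species counts, and their
share of total WOE volume.

## Traits, imputation, standardization

Four traits: body mass (g), clutch size (count), maximum longevity (years),
habitat breadth (count of occupied habitat categories, supplied as data —
no API calls).  Body mass, clutch size and longevity are log10-transformed;
habitat breadth is used raw.  All z-scoring uses the sample SD (n − 1).

Missing values are imputed by chained equations with predictive-mean
matching (PMM), without phylogenetic information.  Each incomplete trait is
regressed in turn on all other traits (linear model on the transformed
scale); coefficients are perturbed by a draw from their approximate sampling
distribution (type-1 matching), and each missing cell receives the
*observed* value of a donor sampled uniformly from the `k = 5` nearest
predicted values.  Donor-based imputation keeps habitat breadth integral and
all values positive.  Defaults: 4 imputations, 10 iterations.  Whether to
impute on the log or raw scale is genuinely open; log scale is the default
(`log_scale=False` switches) because the traits are log-normal-ish and the
linear conditional models are better specified there.  Downstream analyses
can be run per imputation to report imputation spread; observed cells are
never modified, and results are reproducible under a fixed seed.

## Functional space

PCA is computed on the sample covariance of the z-scored traits (already
unit variance, so this equals the correlation PCA) of the **full pool** —
traded and non-traded species alike — matching the idea that the space
describes everything that could be traded.  Axis signs are fixed by making
the largest-magnitude loading of each axis positive, so repeated runs are
bit-identical.  Axis-count quality combines cumulative % variance with the
mean squared deviation (MSD) between full trait-space pairwise distances and
reduced-space distances over all species pairs; MSD is zero at full rank and
non-increasing in `m` (nested projections), and a mean-absolute variant is
available.  The pool centroid and pool hull volume are stored with the
space; because the traits are centred, the centroid is numerically the
origin.

## Functional diversity metrics

- **FRic** is the convex-hull volume (Qhull) of the present species'
  coordinates.  It is presence-based: volumes only decide membership.
  Reporting is in % of the pool hull by default — printed FRic values are
  then bounded by 100 and comparable across pools — with the raw volume
  available (`mode="raw"`).  Affinely degenerate species sets yield volume 0
  with a degeneracy flag rather than an exception.
- **FSpe** is the volume-share-weighted mean Euclidean distance to the
  *unweighted pool centroid* (not the assemblage centroid), left
  unstandardized by default.  It is invariant to rescaling all volumes.
- **SES FRic** standardizes observed FRic against `n_rand = 999` random
  assemblages: each draws, without replacement from the full pool, as many
  species as the observed assemblage holds.  The scheme also prescribes
  permuting the observed volumes onto the sampled species; since FRic is
  presence-based this permutation cannot change any null value, so the
  implementation samples species only (the `volume_assignment` field
  documents the scheme for abundance-based extensions).  SES is undefined —
  and flagged, not silently returned — when the null SD is zero.  |SES| > 2
  (strict) is classified as significant under- or over-dispersion.
- **Hotspots** are keys at or above the (100 − pct)-th percentile of the
  defined metric values, with numpy's linear-interpolation percentile and an
  inclusive cutoff; ties at the cutoff are all included.  For values 1..100
  at pct = 5 the cutoff is 95.05, admitting exactly {96..100}.
- Randomization uses one master seed; each assemblage derives a substream
  from a CRC-32 hash of its key, so results are independent of evaluation
  order and safe to parallelize.

## Trait–trade models

One standardized trait per model (multi-trait fits are deliberately not the
default).  Presence: Bernoulli with
`logit P = α + β z + γ year_c + u_year + u_taxon`; volume, on traded rows
only: negative binomial (NB2) with the same linear structure on the log
mean.  WOE volumes are real-valued; the NB response is the volume rounded to
the nearest integer, floored at 1.  Year enters both as a centred/scaled
continuous effect and as a factor-level varying intercept; the taxonomic
grouping defaults to family-level labels.  Continental models add
per-continent trait slopes (the quantity of interest), treatment-coded
continent intercepts, and year-by-continent controls; species × year ×
continent rows are restricted to continents where the species occurs, so an
absence row means "could have been traded from there but was not".

Priors are zero-centred and weakly regularizing: Normal(0, 1.5) on fixed
effects and half-Normal(0, 1) on the group SDs.  The NB dispersion prior is
placed on the *inverse* shape κ = 1/φ (half-Normal(0, 1)): κ = 0 is the
Poisson limit, so the prior shrinks toward equidispersion and lets the
posterior concentrate at a large shape when the data are Poisson-like — a
zero-centred prior directly on φ would forbid exactly that behaviour.  All
scales are configurable.

**Backend.**  The default is a deterministic marginal-Laplace approximation
in the style of glmmTMB/INLA.  The varying intercepts `u` are integrated out
by an inner Newton solve of the penalized likelihood (step-halving,
gradient tolerance 1e-8), giving the Laplace marginal
`log p(y | ψ) ≈ ℓ(u*) − ½ u*ᵀ Σ⁻¹ u* − Σ_g n_g log σ_g − ½ log det H` for
the outer parameters ψ = (fixed effects, log σ per group, log κ).  The
outer posterior is maximized (L-BFGS-B, box bounds log σ ∈ [−6, 4],
log κ ∈ [−10, 6]) and approximated by a Gaussian at its mode via a central
finite-difference Hessian (eigenvalues floored at 1e-8); posterior draws of
ψ are completed with conditional Gaussian draws of `u` and arranged into 4
chains × 500 draws so the usual summaries apply.  A joint-mode Laplace was
rejected during development: the centred parameterization's joint mode
degenerates at σ → 0 (the hierarchical funnel) and the non-centred one
inflates σ along the `u = σ·ũ` ridge; the marginal Laplace recovers
generator group SDs and gives calibrated posterior predictive checks.  An
`emcee` ensemble sampler over the same marginal posterior is available via
`method="emcee"` when a full MCMC posterior is wanted.

Convergence is reported per parameter via split-Rhat; any Rhat ≥ 1.05, a
failed optimization, a non-positive-definite Hessian, or implausibly large
fixed effects flags the fit as non-converged (with a warning) — never a
silent return.  Complete separation of the presence response by the trait
raises an error with no estimate.  Direction certainty flags fixed effects
with ≥ 97.5% of posterior mass on the median's side of zero.  Posterior
predictive checks simulate replicate responses from the posterior draws and
report upper-tail probabilities for summary statistics (mean and zero
fraction for presence; mean, max and variance/mean dispersion for volume);
a constant observed response is flagged as degenerate.

Per-SD coefficients are rescaled to per-order-of-magnitude effects by
dividing by the SD of the log10 trait values (raw-scale SD for habitat
breadth), using the SDs stored at standardization; for the volume model,
`100·(exp(β_per-magnitude) − 1)` gives the percentage change in expected
volume per 10× trait increase.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study's conditions by default: a pool of 1125 species across 40
taxonomic groups on six continents, 96 exporting and 146 importing
countries, trade years 2000–2020.  Traits are drawn from a latent
multivariate normal on the log10 scale (means/SDs: mass 2.0/0.85 log10 g,
clutch 0.9/0.35, longevity 1.15/0.30; correlations mass–longevity 0.55,
mass–clutch 0.35, clutch–longevity 0.20) with habitat breadth linked through
a Gaussian copula to a shifted Poisson (λ = 3) — values chosen once as
realistic for a reptile-like pool.  Missingness defaults reproduce the
empirical coverage of reptile trait compilations (longevity 68.5%, habitat
breadth 60.5%, mass 99.4%, clutch 88.9% complete), MCAR by default with a
MAR-on-mass option (smaller-bodied species likelier missing, mean rate
preserved).

Trade presence per species-year is Bernoulli in the standardized true
traits plus year and taxon effects (SD 0.3 each); the baseline logit −4.75
is calibrated so that about 26% of a full pool is ever traded across the 21
years, matching the traded fraction of the real listed-reptile pool.
Volumes are zero-truncated negative binomial and are decomposed into
shipment records with valid codes whose quantities sum exactly to the drawn
volume; exporters are drawn from the species' home continents with
Dirichlet-distributed market shares (concentration 0.3), so trade is
concentrated in few countries as real ledgers are.  A configurable fraction
of decoy records (non-commercial purpose, seized source, re-export origin)
is appended and labelled in a sidecar truth table, giving the filters an
exact ground truth.  All randomness flows through one seeded generator.

What the generator does **not** emulate: real species, country or term
inventories beyond plausible placeholders; taxonomy-linked trait structure
(taxon groups are assigned independently of traits); temporal trends in
listing coverage; reporting artefacts such as permit-vs-shipment inflation
or laundering.  Passing tests therefore demonstrate that the pipeline's
logic and inference are correct under the assumed data-generating process,
not that any particular empirical estimate is right.

## Problem sizes used in tests and the acceptance script

Desk-scale runs keep the full logic while staying fast: SES calibration uses
a 300-species pool, richness-20 assemblages and 999 randomizations (200
outer replicates); trait-filtered sign checks use the top body-mass decile
at richness 20 (100 replicates); model recovery uses 20 replicate studies of
800 species × 5 years with generating coefficients 1.2 (presence, body
mass) and 0.3 (volume, clutch size); the acceptance script additionally
builds the full 1125-species pool for the functional space and ledger
aggregation.  These sizes are the package's own choices for routine runs;
every stage accepts larger inputs unchanged.

## Known limitations

- The marginal-Laplace posterior is an approximation; its intervals are
  accurate for the fixed effects at these data sizes (verified by coverage
  tests) but can understate skewness in the group-SD posteriors.  Use the
  emcee backend when exact posteriors matter.
- The default WOE table is a documented stand-in, not a published mapping.
- FRic in high dimensions (m > ~8) would hit Qhull's cost wall; the
  intended use is m ≤ 4.
- PMM imputation assumes approximately linear conditional relations on the
  log scale and cannot extrapolate beyond observed donor values.
- SES FRic inherits the known richness-dependence of hull-based metrics at
  very low richness (near m + 1 species), where the null SD is large.
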