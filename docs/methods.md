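# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the `quollmove`
pipeline. The pipeline reconstructs a complete movement-ecology
analysis for a small nocturnal mesopredator (the northern quoll,
*Dasyurus hallucatus*) tracked with GPS collars and tri-axial
accelerometers in an active mining landscape: telemetry screening,
energy-expenditure proxies, broad-scale range composition, fine-scale
step selection, and path models linking habitat to energetics.

## Telemetry screening

Fixes arrive on a 30-min nocturnal schedule (18:00–06:00 local, a
possible 24 per night). Screening is a fixed cascade, each stage
counted separately so the cleaning report decomposes removals exactly:

1. **HDOP.** Fixes with horizontal dilution of precision strictly
   greater than 10 are removed; a fix at exactly 10 is kept.
2. **Speed.** A single forward pass per individual removes any fix
   whose distance from the last *retained* fix exceeds 4.5 m/s (a
   literature ceiling for the species) times the elapsed time; a speed
   of exactly 4.5 m/s is kept. The forward pass is deterministic and
   order-stable; a globally optimal screen would differ only on
   pathological inputs and is not attempted.
3. **Exclusion windows.** Half-open local-time windows `[start, end)`
   drop trap nights and similar artefacts.
4. **Bursts.** Sequences split at gaps longer than 30 min plus a ±3 min
   tolerance (collar schedules drift; tolerance 0 reproduces the
   literal more-than-30-min rule), and bursts with fewer than three
   locations are dropped — the minimum needed for a turning angle.

Steps connect consecutive fixes within a burst. Turning angles are
counter-clockwise positive in `(-π, π]`, measured against the previous
step's heading; the first step of a burst has no turning angle and is
kept as a step but excluded from angle fitting. Timestamps are stored
UTC; the night window is evaluated through a fixed UTC offset
(default +8 h — the study region has no daylight saving, so a constant
offset is exact). Coordinates must be projected planar metres;
longitude/latitude input is rejected rather than re-projected.

## VeDBA

Each 5-s accelerometer sample is split per axis into a static
component — a running mean over two consecutive samples (10 s), with
`static[0] = raw[0]` at segment starts and the window restarting across
gaps — and a dynamic component `A = |raw − static|`. The vectorial
dynamic body acceleration is `VeDBA = sqrt(A_x² + A_y² + A_z²)`. The
absolute values are redundant under the square, but are retained in the
audit columns because that is how the quantity is conventionally
defined. VeDBA rather than ODBA because the vector norm is invariant
to fixed rotations of the sensor frame, which matters for collars that
can spin about the neck; the suite verifies this invariance to 1e-9
under random rotations of a gravity-only signal.

Per-step means use samples with `t_start < t ≤ t_end` (a sample at a
fix instant belongs to the step ending there), intersected with the
nocturnal window; diurnal samples are discarded. Temperature is
averaged over exactly the same masked samples.

## Home ranges and the used/available design

The movement range of an individual is the 95% isopleth of a fixed
bivariate Gaussian kernel density estimate. The bandwidth follows the
*ad hoc* rule: start at the bivariate reference bandwidth
`h_ref = σ̂ n^(−1/6)` with `σ̂² = (var_x + var_y)/2`, shrink in steps of
`0.05·h_ref`, and return the smallest bandwidth whose isopleth is still
one rook-connected region without interior holes (if `h_ref` itself
fragments, return `h_ref`). Step size, connectivity rule and isopleth
level are all arguments. The KDE is evaluated as cell masses on a grid
padded 3.5h beyond the point bounding box at resolution `h/4`, capped
at 512 cells per axis; points are binned before convolution, which at
that resolution changes 95% areas by well under the 2% refinement
tolerance the suite enforces. Isopleth cells are selected greedily by
descending mass with row-major tie-breaking, making areas bit-for-bit
reproducible at a fixed resolution.

Availability follows the buffered-MCP design: each individual's 100%
minimum convex polygon is buffered by the equal-area radius of the
largest observed range minus the focal range's own radius, and five
circular available ranges of the focal range's area are centred
uniformly at random inside the buffered region (9 observed + 45
available ranges in the study design). Circles may overlap anything,
including the observed range; cells beyond the mapped raster are
excluded from summaries and reported as an unmapped fraction. Zonal
summaries use cell-centre membership: habitat cover proportions over
the five analysed classes (water is excluded from numerators but kept
in the denominator), median TRI on the TRI grid's own (coarser) cells,
and means of the distance layers.

The sequential-area asymptote check recomputes the 95% area at 10-fix
increments using one common bandwidth (chosen on the full point set, so
the sequence reflects accumulating fixes rather than bandwidth
re-selection) and declares an asymptote when the last three areas
pairwise differ by less than 5% — the tolerance is a package choice, as
the qualitative check has no standard criterion.

## Broad-scale models

Habitat cover fractions are compared between observed and available
ranges with zero-inflated beta mixed regressions: a point mass at zero
whose probability differs by range type, a Beta(μφ, (1−μ)φ) component
with `logit μ = β₀ + β₁·observed + u_individual`, and
`u ~ N(0, σ_u²)`. The random intercept sits on the mean submodel only,
keeping the likelihood integral one-dimensional; it is evaluated with
15-node Gauss–Hermite quadrature on the fixed grid `u = σ_u·t` (cluster
sizes are six, where the fixed grid is accurate far below the Wald CI
width; a mode-adaptive grid would change nothing detectable).
Exact ones are squeezed by `y' = (y(n−1)+0.5)/n`. Optimisation is
L-BFGS-B on `(β₀, β₁, log φ, logit π_obs, logit π_avail, log σ_u)`;
standard errors come from the numerical Hessian inverted over the
informative interior block — nuisance parameters on a bound (σ_u → 0)
or in a flat region (a zero-inflation logit with no zeros to fit) are
excluded, since their singular directions would otherwise poison the
covariance. Continuous summaries use Gaussian linear mixed models with
a random intercept per individual, estimated by ML; when the variance
component estimates to exactly zero the profiled mixed fit degenerates
and the model collapses to OLS, which is the ML solution there. All
contrasts are classified by whether the Wald 95% CI excludes zero.

These models are estimated by maximum likelihood with Wald intervals —
the package's single largest methodological substitution relative to a
Bayesian fit of the same structures — so validation is parameter
recovery on simulated data (bias and CI coverage at the 54-range design
size), not posterior matching.

## Integrated step-selection functions

Observed steps are pooled by season (no individual random slopes — the
study-sized data cannot support mixed conditional models, and the
pooled fit is the documented design). A tentative selection-free
kernel is fit to observed steps: gamma step lengths by ML and a von
Mises turning-angle concentration by solving `I₁(κ)/I₀(κ) = mean cos
ta` (κ capped at 500 for degenerate inputs). Five available steps per
observed step share its start point and stratum, with lengths and turns
drawn from the tentative kernel; at burst starts the previous heading
is undefined and a uniform heading is used — mirroring what the
estimator can know there.

End-of-step covariates are habitat class (dummy-coded, rocky as
reference, so each habitat coefficient is a log relative selection
strength against rocky terrain), TRI, distance from mining disturbance
and distance from rocky habitat, plus `log10(step length)` and
`cos(turning angle)`. Steps ending off-raster or on water are flagged:
a flagged observed step drops its whole stratum, a flagged available
step drops only itself. Strata whose rows share identical covariates
carry no information and are dropped with a count.

The stratified conditional-logistic partial likelihood is maximised by
Newton–Raphson with analytic score and Hessian, step-halving line
search, convergence at `max |score| < 1e-8`, and covariance from the
inverse negative Hessian. Complete separation makes the partial
likelihood monotone with a score decaying like `exp(−β)`, so the
divergence detector fires at `|β| > 15` (configurable) and names the
offending covariate. Model selection uses
`AICc = −2lnL + 2K + 2K(K+1)/(n−K−1)` with `n` equal to the number of
strata, over a configurable candidate menu (global, habitat-only,
terrain-only, movement-only, null by default; ΔAICc < 2 marks
substantial support). Age enters only as interactions with
`log10(sl)` and `cos(ta)` in the non-breeding season.

The movement kernel is updated with the fitted movement coefficients:
`k = k₀ + β_log10(sl)/ln 10` (the design matrix is base-10, the gamma
shape is natural-log), `κ = κ₀ + β_cos(ta)`; the scale is untouched
because no linear step-length covariate is in the model. RSS between
covariate vectors is `exp(βᵀΔz)` with delta-method intervals, verified
against a parametric bootstrap of the coefficient Gaussian.

## Energetics path models

For each per-step environmental summary (along-path habitat
proportions sampled at half the habitat cell size with both endpoints
included, median TRI and mean distances over the same sample points), a
two-equation path model is fit on the identical complete-case subset:
step length on the environmental variable and mean temperature, and
mean VeDBA on those plus step length, both Gaussian mixed models with a
random intercept per individual. Each equation reports conditional
`R² = (σ²_fixed + σ²_random)/(σ²_fixed + σ²_random + σ²_residual)` with
`σ²_fixed` the variance of the fixed-effect linear predictor, and
relevant-range standardised coefficients `β·range(x)/range(y)` using
observed min–max ranges (recorded in the output for audit).

Effects on mean VeDBA decompose as `direct = pcor(env, VeDBA | sl)`,
`indirect = pcor(sl, VeDBA | env)`, `total = direct + indirect`, with
partial correlations computed by the residual method on pooled
observations (the closed three-variable form is an exact oracle in the
tests). Pooling ignores the grouping structure by default; a switch
residualises on individual means first for a within-individual
decomposition. A total effect is read as the change per unit increase
of the min-max-scaled predictor (0.086 ≍ "8.6% per unit increase") — a
formatting convention, not a second computation. The season model adds
breeding (=1) as an exogenous predictor of temperature, step length and
VeDBA. Directed-separation tests (Fisher's C) exist as an optional
diagnostic and are off by default; the two-equation models are
saturated, so the default pipeline has no testable independence claims.

## The synthetic-data generator

The generator is the inverse of the step-selection estimator, so every
downstream stage has a recoverable ground truth.

**Landscape.** Six habitat classes (spinifex grassland, riparian,
rocky, mine pits & waste dumps, other disturbed land, water) on a 10 m
grid, default 400×400 cells (4×4 km). Class mosaics come from per-class
smoothed Gaussian fields whose offsets are iterated until the argmax
mosaic matches target cover (default 44/7/25/11/11/2%). The patch
correlation length defaults to 24 cells (~240 m): mine pits, waste
dumps and rocky ridges span hundreds of metres, and patches much
smaller than a typical step would make endpoint covariates unrealistically
noisy. TRI lives on its own 12.5 m grid as a smooth non-negative field
uplifted on rocky cells (rocky median ≈ 1.5 vs ≈ 0.4 elsewhere,
mirroring the field contrast that rocky terrain is the most rugged);
distance layers are exact Euclidean cell-centre distances, zero on the
source class. NDVI is a smooth field with class-specific means
(riparian greenest, mining classes lowest).

**Movement.** At each nocturnal 30-min epoch, M = 100 candidate
endpoints are drawn from gamma(k, θ) × vonMises(0, κ) about the
previous heading and one is selected with probability ∝ exp(βᵀz); the
finite candidate set introduces a small, documented bias that standard
SSF simulation practice accepts. Defaults: k = 0.8, θ = 150 m (mean
step 120 m, right-skewed), κ = 0.5 (weak persistence), β = spinifex
−1.0, riparian −0.4, pits & waste −0.8, other disturbed −0.6, TRI
+0.5, with water strongly avoided (finite log-weight −10). These
movement parameters are generator inventions recorded in `truth.json`,
not estimates from any animal. Animals den in a random rocky cell,
start each night there with a uniform heading, and sit at the den by
day; if every candidate is off-raster the draw is retried, falling back
to uniform headings as an animal turning at a barrier. The default
design is 4 breeding + 5 non-breeding individuals × 20 nights.

**GPS degradation.** Isotropic Gaussian position noise with per-axis
σ = 8.3 m (the magnitude reported for stationary test collars),
Bernoulli fix failure (default 5%), and an HDOP mixture placing 2% of
mass above the screening threshold of 10 — those poor fixes also carry
3× noise, and their removal costs ~3% of the data, matching the
screening loss observed with real collars.

**Accelerometer.** 5-s samples, 24 h/day: a gravity projection in the
collar frame plus zero-mean Gaussian dynamics with standard deviation
`dyn_scale × activity`, clipped at the sensor's ±4 g. Activity is the
realised step length over the kernel mean step length — a deliberate,
exactly linear tie, so any apparent habitat→VeDBA effect in the
synthetic data flows only through β-driven habitat occupancy and the
path models have a known answer (direct ≈ 0, indirect ≈ the
sl–VeDBA correlation). Collar orientation is random per deployment and
fixed by default, which makes the two-sample static decomposition exact
(the dyn_scale = 0 identity); an optional slow rotation emulates collar
spin for robustness experiments. Temperature follows a sinusoidal diel
cycle (mean 25 °C, amplitude 8 °C, afternoon peak).

**What the generator does not emulate** — and hence what passing tests
do not show about field data: behavioural states (rest/forage/travel
mixtures), temperature-dependent movement, den-site fidelity beyond a
single den, serially correlated GPS error, collar-rotation artefacts in
the default accelerometer stream, and terrain-driven movement costs.
Estimator validation on this generator demonstrates statistical
correctness of the pipeline, not ecological realism of any parameter.

## Validation benchmarks and problem sizes

- **Step-selection recovery.** 100 replicates, each a fresh landscape
  and a fresh 9-individual × 20-night study (~3,200 strata after
  cleaning), fix failures and HDOP screening active, exact positions
  for retained fixes: all |bias| ≤ 0.15 (observed ≤ 0.04) and pooled
  Wald 95% CI coverage within [0.88, 0.99]. With position noise at
  σ = 8.3 m the strongest habitat coefficients attenuate by ~0.2 —
  classical measurement-error attenuation, reported by the acceptance
  script as its own quantity (`issf_attenuation_max_abs_bias_gps83`)
  rather than folded into the recovery benchmark, since it is a
  property of GPS error, not of the estimator.
- **Mixed-model recovery.** 200 replicates (tests) at the 54-range,
  9-individual design: effect bias < 10%, CI coverage ≥ 0.9 for both
  the zero-inflated beta and Gaussian mixed models.
- **Closed forms.** KDE 95% area vs the Gaussian convolution formula
  `5.991π(σ² + h²)` at 20,000 points; conditional-logistic Newton vs
  brute-force 1-D maximisation; partial correlations vs the
  three-variable identity; VeDBA hand identities.
- **Determinism.** Two seeded end-to-end runs are byte-identical.

Problem sizes throughout (replicate counts, landscape dimensions,
nights) are the study's own design sizes or the smallest sizes at which
the corresponding statistical property is cleanly measurable.

## Known limitations

- Frequentist ML replaces the Bayesian estimation of the original
  model structures; interval semantics differ accordingly.
- The zero-inflation submodel carries no random effect, and π is
  estimated per range type only.
- The speed filter is a forward pass; it does not revisit earlier
  decisions after a removal.
- Available-range circles are not constrained away from water.
- GeoTIFF input is not supported; rasters use the package's documented
  plain-text grid dialect.
- The simplified-model menu for AICc selection is configuration, not a
  claim about any published candidate set.
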