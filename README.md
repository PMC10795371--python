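# quollmove

Movement ecology of a small nocturnal mesopredator in a mining
landscape, as a tested, reusable Python pipeline. `quollmove` covers
the full chain from raw collar data to ecological inference for
GPS + accelerometer studies of the northern quoll (*Dasyurus
hallucatus*) and similar species:

- **Telemetry screening** — HDOP and speed filters, exclusion windows,
  burst construction, conversion to 30-min movement steps.
- **Energetics** — vectorial dynamic body acceleration
  (`VeDBA = √(A_x² + A_y² + A_z²)`, with `A` the absolute dynamic
  component after subtracting a two-sample running-mean static
  acceleration) aggregated onto observed steps.
- **Broad-scale space use** — fixed-kernel utilisation distributions at
  the 95% isopleth with the shrink-until-fragmentation *ad hoc*
  bandwidth, 100% MCPs, buffered availability regions, random circular
  available ranges, zonal raster summaries; observed-vs-available
  contrasts via zero-inflated beta and Gaussian mixed models.
- **Fine-scale habitat selection** — integrated step-selection
  functions: a tentative gamma × von Mises movement kernel, five
  available steps per stratum, stratified conditional logistic
  regression `L(β) = Π_s exp(βᵀz_obs)/Σ_j exp(βᵀz_j)` maximised by
  Newton–Raphson, AICc model selection, movement-kernel updating
  (`k = k₀ + β_log₁₀sl/ln 10`, `κ = κ₀ + β_cos ta`), and relative
  selection strength `RSS = exp(βᵀΔz)` with delta-method CIs.
- **Energy-expenditure path models** — piecewise two-equation mixed
  models (step length ← environment + temperature; mean VeDBA ←
  environment + temperature + step length), relevant-range standardised
  coefficients, conditional R², and total effects decomposed into
  direct and step-length-mediated partial correlations.
- **Synthetic data with known truth** — a six-class mining-landscape
  generator (habitat, TRI, distance-to-disturbance, distance-to-rocky,
  NDVI) and a habitat-selective trajectory/accelerometer simulator, so
  every estimator in the pipeline is validated by parameter recovery.

Who it is for: movement ecologists who want the whole used/available
workflow — from fix tables to selection coefficients and energetic
costs — in one place, with every stage unit-tested against independent
oracles, and simulation folk who need a step-selection test bench with
a controllable ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data. The first two stages:

```bash
python analysis/01_simulate_study.py
python analysis/02_clean_gps.py
```

```
simulated 9 individuals
  nocturnal epochs: 4329, retained fixes: 4139 (95.6% fix success)
  accelerometer samples: 3113640
  true selection coefficients: {'spinifex': -1.0, 'riparian': -0.4,
  'pits_waste': -0.8, 'other_disturbed': -0.6, 'tri': 0.5}
screened 4139 fixes -> 3938 (74 HDOP, 0 speed, 127 in short bursts)
observed steps: 3603 (3268 with defined turning angles)
```

Nine collared individuals (4 breeding-season, 5 non-breeding) are
tracked for 20 nights at 30-min nocturnal fixes on a 4 × 4 km landscape;
the cleaning report decomposes every removal (74 fixes screened for
HDOP > 10, 127 lost in bursts too short to carry a turning angle).
After `analysis/06_issf.py` fits the seasonal step-selection models:

```
non-breeding: 1819 strata; global AICc 6223.3 (dAICc of best alternative 10.6)
  spinifex           -0.747 [-1.096, -0.398] (truth -1.00)
  riparian           -0.472 [-0.940, -0.003] (truth -0.40)
  pits_waste         -0.324 [-0.855, +0.206] (truth -0.80)
  other_disturbed    -0.403 [-0.880, +0.075] (truth -0.60)
  tri                +0.485 [+0.327, +0.644] (truth +0.50)
```

Each habitat coefficient is a log relative selection strength against
rocky habitat (the reference class): `exp(-0.747) ≈ 0.47` means a step
ending in spinifex is selected at roughly half the rate of an otherwise
identical step ending on rock. The generator's true coefficients sit
inside every interval; at the single-season sample size (~1,800
strata) the intervals are wide, which is exactly why the full
benchmark (`tests/test_acceptance.py`) measures bias and coverage over
100 replicates of the complete design. `analysis/07_energetics.py`
then shows the path-model decomposition recovering the generator's
design — habitat affects mean VeDBA only through step length (direct
≈ 0, step-length-mediated indirect ≈ 1).

The same stages are available as a CLI for external data
(`quollmove simulate | clean | vedba | ranges | broadscale | issf |
psem | report`), reading and writing CSV/JSON with a run manifest per
command.

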