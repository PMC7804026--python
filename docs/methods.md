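# Methods

This note documents the models, decision rules, defaults and numerical
choices behind `respirocod`, and what the validation studies do and do not
demonstrate.

## The measurement model

A batch respirometer holds a wastewater–sludge mixture (nitrification
suppressed with allyl-thiourea) and reseals the vessel in short cycles
(typically 4 min, DO logged every 10 s). Within a sealed cycle the DO
decline is linear to good approximation and its slope is the volumetric
oxygen uptake rate. `our_extraction` fits an ordinary least-squares line
per cycle, discards the first 10 s (probe settling; configurable), rejects
cycles with r² < 0.95 (configurable; a constant-DO cycle is assigned
r² = 0 so the gate removes it), and reports OUR = −slope × 3600 at the
cycle start time. Assigning the point to the cycle start keeps the first,
highest OUR at t = 0, matching how respirograms are conventionally
tabulated.

With nitrification suppressed, total respiration decomposes as
`OUR = OUR_ex + OUR_en`: exogenous (substrate-driven) plus endogenous
(biomass self-respiration, a flat plateau once external substrate is
gone). All timestamps are minutes, OUR is mg O₂/(L·h), COD is mg/L;
integrations divide by 60 internally.

## Endogenous-onset detection (t₂)

The endogenous phase is the terminal portion of the curve "without an
obvious change trend". That phrase needs two quantitative readings, and
the detector applies both to a suffix window grown backward from the end
of the series:

- **trend gate** — the classical Mann–Kendall test on the suffix must not
  be significant. Critical values default to the one-sided set applied to
  |Z| (1.28/1.64/2.32 at 90/95/99%) that applied trend-testing practice
  in this field quotes; the standard two-sided set is available as
  `critical_set="two-sided"`. MK alone is magnitude-blind: on noiseless
  model output an infinitesimal monotone drift is "significant", so the
  test cannot be the only gate.
- **level gate** — a candidate point must lie inside an acceptance band
  around the current plateau mean: the wider of a 5% relative floor
  (`level_tol`) and a two-sided t prediction interval for one new
  observation. The t interval adapts the band to the sensor noise present
  in the plateau; the relative floor is the "obvious change" criterion
  that takes over when noise is negligible.

Two robustness devices matter on long noisy records. The initial terminal
window scales with series length (`max(min_window, n/10)` points) so the
band is estimated from a stable sample; and a stop requires *two*
consecutive failing candidates, tested against the same uncontaminated
window, so a single aberrant sample cannot end the plateau. After the
scan, the retained window must itself be level — its range must be
explainable by the relative floor or by its point-to-point scatter —
otherwise the series has no endogenous plateau and an error is raised.
`min_window` defaults to 3, the smallest suffix on which the sequential
statistics are defined.

The sequential Mann–Kendall machinery (`S_k`, `E[S_k] = k(k−1)/4`,
`var[S_k] = k(k−1)(2k+5)/72`, UF, and UB from the reversed series,
negated and re-aligned) is computed alongside, and the UF/UB intersection
(mutation point) is reported in the audit trail with a flag for whether
it lies inside the confidence band. The suffix scan, not the mutation
point, decides t₂: the suffix scan is the rule tied directly to the
definition of the endogenous phase, and the UF/UB curves of a monotone
series need not intersect at all. `UF₁` is defined as 0 (its variance
vanishes at k = 1). `Var(S)` carries no tie correction — ties are rare in
OUR data at instrument resolution; with heavy ties the test is slightly
conservative.

The endogenous baseline OUR_en is the arithmetic mean of the plateau.
Inside the full pipeline, a guard applies for plateaus of ≥ 8 points: the
mean is taken over the far half, because the scan's t₂ is
detection-limited — the first plateau points may carry exogenous signal
smaller than the acceptance band. The plateau's standard deviation also
provides the pipeline's sensor-noise estimate.

## Hydrolysis stage and t₁

SBCOD degradation follows the saturating (surface-limited) hydrolysis
law

    dXs/dt = −k_h · X_H · (Xs/X_H) / (Xs/X_H + k_x)
    OUR_ex(t) = (1 − Y_H) · (−dXs/dt)

with k_h the maximum specific hydrolysis rate (g COD_Xs/(g COD_XH·d)) and
k_x the dimensionless switching (half-saturation) constant. The source
rate law prints one symbol in both roles, which is dimensionally
inconsistent; the two-constant form is the standard ASM parameterization
and is what the module implements. The ODE separates and has the exact
implicit solution `(Xs0 − Xs) + k_x·X_H·ln(Xs0/Xs) = k_h·X_H·t`, solved
in closed form with the Lambert W function (asymptotic expansion refined
by Newton steps where the exponential argument would overflow). This is
exact, fast enough for the hundreds of refits the t₁ scan performs, and
is verified in the tests against an independent Runge–Kutta integration
at rtol 1e−10.

`fit_hydrolysis` estimates (k_h, k_x, Xs0) by least squares on the
baseline-subtracted window, log-parameterized for positivity,
multi-started from five log-spaced initializations (seeded; default seed
20210112). X_H is **not identifiable** from a single OUR window — it
enters only through products and ratios — so it is a fixed input,
defaulting to MLVSS 2000 mg/L × 1.42 g COD/g VSS; fitted k_h and Xs0 are
conditional on it. The endogenous baseline is subtracted before fitting
(the law describes exogenous respiration only) and observations are
floored at zero.

t₁ is found by backward extension: starting from the 4 points immediately
before t₂, earlier points are prepended one at a time and the law
refitted. Extension stops at *fitting distortion*, quantified as

- window RMSE above `max(rel_tol · mean(OUR_ex,obs), 2 · σ_noise)` with
  `rel_tol = 0.10`, or
- the newly added point's standardized residual above 4,

confirmed by a second consecutive failing window (one aberrant sample is
not distortion). The noise floor `σ_noise` (from the endogenous plateau)
keeps the relative criterion meaningful where the exogenous signal sits
near the sensor scatter; the residual threshold of 4 keeps the false-stop
probability negligible across the hundreds of sequential windows a dense
record produces. All thresholds are configurable; all fits are returned
for audit.

## Quantification

RBCOD = area of OUR_ex over `[0, t₁]` divided by (1 − Y_H); SBCOD the same
over `[t₁, t₂]`. Y_H defaults to 0.68. Integration is trapezoidal on the
observed points with linear interpolation at fractional bounds; the
endogenous baseline is subtracted (and the integrand floored at 0) by
default — Eq.-wise, the substrate balance concerns exogenous respiration
only — with `subtract_baseline=False` available for the unsubtracted
convention, and a smoothing-spline pre-fit behind `smooth=True` for users
who prefer integrating a fitted curve. Integration starts at the first
sample; the initial OUR peak is not back-extrapolated. A COD time series,
when supplied, yields per-segment mean degradation rates
`(COD_start − COD_end)/Δt` at the detected breakpoints; filter-fraction
arithmetic (CCOD = TCOD − PCOD − SCOD with percentages) is provided for
the physical fractionation that accompanies such tests.

## Simulator

`simulate` integrates a minimal two-substrate batch model: Monod uptake
of Ss at `(μ_max/Y_H)·Ss/(K_s+Ss)·X_H`, hydrolysis of Xs by the law
above, endogenous respiration `1.42·b_H·X_H`, and constant biomass (a
short-batch approximation; growth over such tests is a few percent).
Hydrolysis carries a repression factor `k_i/(k_i + Ss)` representing
preferential uptake of readily biodegradable substrate: hydrolysis
turnover is low while Ss is abundant. This factor is what produces the
cleanly staged respirogram the characterization method presumes — without
it the hydrolysis oxygen consumed during the RBCOD limb is booked into
the RBCOD integral and no integration boundary can recover both pools.
Setting `k_i` large disables it.

Defaults emulate a domestic-wastewater batch: 40 mg/L RBCOD + 150 mg/L
SBCOD on 2840 mg COD/L biomass (2000 mg/L MLVSS), b_H chosen so the
endogenous plateau sits at ≈ 11.5 mg O₂/(L·h), μ_max = 1.0/d and
k_h = 0.5/d as effective rates conditional on X_H being the whole
COD-based biomass, k_s = 1 and k_i = 0.5 mg/L for a sharp stage handover,
440 min duration (past depletion), 2-min sampling, additive Gaussian
sensor noise at 2% of the noiseless peak (truncated at zero), all
randomness from one integer seed. Ground truth carried with each run:
the noiseless OUR decomposition, t₁\* (Ss-driven OUR falls below 5% of
hydrolysis-driven OUR), t₂\* (exogenous OUR falls below 2% of
endogenous), and the initial pools. The DO emitter replays the noiseless
OUR as sealed 4-min cycles from 8 mg/L, flooring at zero with a warning.

What the simulator does **not** emulate: inert COD (scenario scaling
interprets S₀/X₀ over the biodegradable pools), biomass growth and
storage phenomena, temperature/pH excursions, probe drift or
autocorrelated sensor error, and partial nitrification breakthrough.
Passing recovery tests therefore demonstrate correctness of the
segmentation and integration machinery under the stated kinetics, not
robustness to every artefact of real respirograms.

## Validation studies

`studies.s0x0_recovery_study` spans S₀/X₀ = 0.2–1.0 (20 scenarios, 2%
noise, seeded): each batch is sized to reach the endogenous plateau (a
coarse probe run is lengthened until t₂\* exists, then the final grid
uses ≈ 192 samples — high-load scenarios are many-hour batches, which is
exactly why such ratios are impractical in the laboratory), simulated,
re-characterized blind, and compared with ground truth. Median relative
recovery errors of both fractions are a few percent; individual
high-load or unlucky-noise runs can fail segmentation, and failures are
recorded as results rather than raised. `hydrolysis_recovery_study`
refits the hydrolysis law on 50 noisy windows (σ = 2% of peak OUR_ex)
and reports the k_h and Xs0 error distributions.

## Bundled reference data

Four small series from a published domestic-wastewater batch test ship
with the package: the 17-point forward OUR table, its sequential-scan
variant, the reversed series, and the mixture-COD decay
(387.5 → 108.2 mg/L over 80 min). The two forward variants differ at
t = 35 min (17.2 vs 17.9 mg O₂/(L·h)) because the source tabulations
disagree there; both are preserved rather than silently reconciled. Two
further published numbers are knowingly not reproduced:

- the reverse-scan tabulation's final row (S′₁₇ = 32, UF′ = −2.97) is
  inconsistent with its own rank column, which sums to 132 and implies
  UF′ = +5.27 (necessarily positive for the ascending reversed series);
  the implementation follows the defining count, and the corresponding
  acceptance test documents the discrepancy as a failing assertion;
- the headline fractions 37.13/144.38 mg/L are not derivable from the
  printed OUR table by trapezoidal integration at Y_H = 0.68 under either
  baseline convention (the integration curve and bounds behind them are
  unstated, and the printed quartic fit's coefficients are internally
  inconsistent), so fraction recovery is validated against simulator
  ground truth instead.

## Known limitations

- t₂ is detection-limited: exogenous respiration smaller than the
  plateau acceptance band is indistinguishable from the plateau, so a
  slowly vanishing hydrolysis tail is partly truncated (the guard on the
  baseline mean removes most of the resulting bias).
- X_H, k_h and k_x are jointly unidentifiable from one window; only
  conditional estimates are reported.
- The distortion rule assumes roughly homoscedastic sensor noise; purely
  multiplicative error would call for weighted fitting.
- No tie correction in Var(S); heavily quantized OUR data would make the
  trend gate conservative.
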