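# Methods

## Toxin conversion–clearance model

The transformation of hypoglycin B (HGB) into hypoglycin A (HGA) in a
closed batch culture is modelled as a two-compartment first-order system:
HGB is hydrolysed with rate constant k (1/h) and the liberated HGA is
cleared with rate constant l (1/h),

    HGB'(t) = −k·HGB(t)
    HGA'(t) =  k·HGB(t) − l·HGA(t),

with measured initial values HGA₀, HGB₀. For l ≠ k the initial-value
problem has the closed form

    HGB(t) = HGB₀·e^(−kt)
    HGA(t) = (k/(l−k))·HGB₀·e^(−kt) + (HGA₀ − (k/(l−k))·HGB₀)·e^(−lt),

the Bateman solution of sequential first-order steps. Assumptions: the
vessel is closed (no inflow/outflow), both steps are first order and
time-homogeneous, and all HGB mass converts to HGA (no parallel loss of
HGB). Clearance is phenomenological — it aggregates microbial uptake,
chemical transformation and binding without distinguishing them.

**Confluent branch.** The closed form degenerates at l = k. When
|l − k| / max(k, l) < 1e−8 the implementation switches to the analytic
limit (HGA₀ + k·HGB₀·t)·e^(−kt). The switch point is far above the
~1e−16/(Δ·t) relative rounding error of the direct formula near the
boundary, so the curve is continuous across it to better than 1e−6
relative (tested).

**Peak time.** Setting HGA'(t*) = 0 gives
t* = ln(−l·B/(k·A)) / (l − k) with A = (k/(l−k))·HGB₀ and B = HGA₀ − A
(confluent case: t* = (HGB₀ − HGA₀)/(k·HGB₀)). When the expression is not
finite and positive — HGA non-increasing from t = 0, or l = 0 so HGA never
decreases — no interior peak exists and `hga_peak_time` returns `None`
rather than raising.

**Numerical oracle.** `simulate_numeric` integrates the ODE system with
fixed-step classical Runge–Kutta (default step 1e−3 h, sub-dividing each
grid interval so every grid point is hit exactly). It exists purely as an
independent check on the closed form; the two agree to better than 1e−5
relative over 0–48 h on randomized parameter sets (tested at step 0.01,
where the 4th-order error is already far below the tolerance).

**Fitting.** `ConversionClearanceModel` minimises the pooled, unweighted
sum of squared residuals of both analytes in raw concentration units
(trust-region reflective least squares, non-negativity bounds, k > 0).
Initial guesses are data-driven: HGA₀/HGB₀ from the t = 0 means, k from the
two-point log slope of the HGB means, l from the post-peak log slope of the
HGA means; 10 additional multistarts perturb this guess by ±50 % (seeded),
and the best optimum is kept. `mode="means"` averages replicate fermenters
per time point before fitting — the alternative estimation route in which
the initial-value problem is solved against per-time mean values.
Observations flagged censored (below the quantification limit) are dropped
from the objective by default; a `censoring="half_limit"` option
substitutes limit/2 instead. A design in which HGB is never observed above
zero leaves k unidentifiable; the fit is returned with `converged=False`
and a diagnostic message rather than an exception, so pipelines can record
the failure and continue.

**Decay fits.** `ExponentialDecayModel` fits C(t) = C₀·e^(−kt) by least
squares from a log-linear start and reports t½ = ln 2 / k. Non-decaying
data drives k ≤ 0; such fits are flagged invalid, not raised.

**Confidence intervals.** All fits report heteroscedasticity-robust
(sandwich) Wald 95 % intervals: (J'J)⁻¹ J' diag(r²) J (J'J)⁻¹ with an
n/(n−p) small-sample correction and a t quantile, where J is the Jacobian
and r the residuals at the optimum. Concentration-like data have noise that
scales with the signal; the homoscedastic Wald covariance then under-covers
the parameters tied to the high-signal region (we measured ≈84–89 %
coverage for the Gompertz asymptote under 2 % multiplicative noise),
whereas the sandwich form stays calibrated under either noise shape
(93–97 % measured across both models). This is the package's design choice;
the interval method behind published batch-culture fits is generally not
reported.

## Gas production

Automated pressure modules record cumulative headspace pressure at a 5 min
interval. Processing follows the field's standard order:

1. **Blank correction** in the pressure domain: subtract the pointwise mean
   of the blank fermenters (inoculum without substrate); blanks on
   different grids are linearly interpolated. Corrected values may be
   negative and are preserved.
2. **Downsampling** to a 0.5 h analysis grid (last observation at or before
   each grid point; t = 0 kept).
3. **Ideal-gas conversion**: n = P·V_headspace/(R·T) moles per psi, turned
   into volume at 22,414 mL/mol (STP, the default implied by using
   Avogadro's law) or at incubation temperature/1 atm via
   `reference="incubation"`. Default headspace 106 mL, incubation 39 °C.
4. **Normalisation** to mL per g substrate dry matter, then a least-squares
   fit of the Gompertz curve.

The Gompertz curve is parameterised by the interpretable triple (a, b, c):
a is the asymptotic gas production (mL/g DM), b the time (h) at which a/3
has been produced, and c the additional time after b at which 0.70·a has
been produced. These two constraints fix the location/scale pair of the
base curve G(t) = a·exp(−exp(−(t−m)/s)) uniquely:

    s = c / ln(ln 3 / ln(10/7)),    m = b + s·ln(ln 3).

Because the parameterisation is defined (and tested) through the
constraints G(b) = a/3 and G(b+c) = 0.70·a rather than one specific
algebraic rearrangement, any equivalent form of the re-parameterised
Gompertz satisfies the same contracts. Automatic pressure release around a
1.5 psi threshold and argon purging are hardware behaviours of the
recording module; the package (and its simulator) treats the recorded
cumulative pressure as already accumulated and does not model valve events.

## Fermentation statistics

NH₃ is reported as the difference between a test fermenter and the mean of
the blank fermenters at the same sampling time, because buffer and inoculum
contribute a large ammonia background; negative differences (net ammonia
incorporation into microbial protein) are meaningful and preserved. The
C2:C3 ratio is formed per fermenter and sampling time *before* any
averaging — the mean of ratios, not the ratio of means, which is what the
published per-variant ratio values imply. Correlation matrices at a chosen
sampling time (default 24 h, the last point before toxin levels fall below
the measurement range) support Pearson, Spearman, and tie-corrected Kendall
τ-b, with the conventional two-sided p-value approximations (t for
Pearson/Spearman, normal for Kendall) and star annotation at
0.05/0.01/0.001 without multiplicity correction. Pairing is
pairwise-complete per fermenter; constant columns yield missing (not
erroneous) coefficients.

## Synthetic experiment generator

The generator reproduces the study design: 4 consecutive runs, three
substrate variants (CSM cellulose–starch control, PCM spiked pure HGA +
MCPrG mixture, SMS milled sycamore seeds on a CSM base) incubated in
duplicate, destructive sampling at 0/1/2/4/8/24/48 h, four blank fermenters
per run, and autoclaved-medium controls sampled at 0/48 h with rate
constants attenuated 0.25× (configurable; heat inactivation slows but does
not abolish the transformation, and no attenuated rate is published).

Generating truths (all configurable):

* SMS toxins: HGA₀ = 4.7, HGB₀ = 19.9 µg/mL from the measured initial
  concentrations; k = 0.10/h, l = 0.036/h chosen so the model peaks at
  ≈13.7 h and retains ≈6.1 µg/mL HGA at 48 h, consistent with the measured
  trajectory (5.6 ± 1.5 µg/mL) — no rate constants are published, so these
  two are the generator's calibration. SMS MCPrG decays from 1.2 to
  0.32 µg/mL over 48 h (k = ln(1.2/0.32)/48 ≈ 0.0275/h).
* PCM toxins: HGA 564 ng/mL with t½ = 2.05 h, MCPrG 432 ng/mL with
  t½ = 2.20 h, the reported initial values and mean half-lives.
* Gas: per-variant Gompertz truths (200, 18.6, 8.5), (272, 17.5, 10.7) and
  (453, 43.5, 32.1) for CSM/PCM/SMS; substrate DM 0.2/0.2/0.3 g; pressure
  curves built by inverting the ideal-gas conversion on the 5-min grid, on
  top of a linear blank drift (0.01 psi/h) plus additive Gaussian recording
  noise (SD 0.02 psi).
* Metabolites: each pH/redox/SCFA/NH₃ trajectory interpolates its variant's
  measured 0 h and 48 h anchor values along the variant's normalised
  gas-production shape (metabolite accumulation tracks fermentation
  activity), with additive Gaussian noise at the published per-variant
  standard errors; pH is clamped to the physiological 6.0–8.0 window. NH₃
  is generated as a raw concentration (background 11→17 mmol/L plus the
  anchored difference), so the blank-difference operation recovers the
  anchors.

Noise families are chosen, not published: multiplicative lognormal with
unit mean for concentrations (non-negative support; CV per analyte set to
the published 0 h SD/mean ratio and held constant over time, since
time-resolved dispersions exist only in figures), additive Gaussian for
pH/redox/SCFA. Values below the quantification limit (0.5 ng/mL, the
lowest matrix-matched calibration level) are flagged censored and carry the
limit. Each fermenter draws from its own `SeedSequence`-derived stream, so
subsetting runs or variants leaves the remaining draws untouched, and a
(config, seed) pair regenerates bit-identical datasets.

What the generator does *not* emulate: between-run variance structure (a
single pooled CV; the published values cannot separate run from fermenter
variance), LC-MS/MS peak areas and calibration chemistry, microbial
community dynamics, pressure-release valve events, and any toxin effect on
fermentation (toxin and metabolite noise are independent, matching the
study's finding of no effect). Passing tests therefore demonstrate correct
recovery of the stated kinetic structure under realistic noise levels — not
robustness to the unmodelled features of real rumen fluid.

## Problem sizes and numerical choices

The interval-coverage study runs 200 seeded repetitions of the full
4-run × 2-duplicate design at 10 % CV noise (it completes in seconds);
closed-form/oracle agreement is checked on 100 seeded parameter sets with
RK4 at step 0.01 h over 0–48 h; generator fidelity is checked on 500
fermenters. Optimiser tolerances are 1e−12–1e−13 (xtol/ftol/gtol);
parameters are bounded non-negative with k strictly positive; the
downsampler uses a 1e−9 h tolerance when matching grid points; fits are
performed in the unit of the input table (ng/mL by default from the
generator) with explicit 10³ conversion between ng/mL and µg/mL and no
silent rescaling.

## Known limitations

* Clearance is a single lumped first-order sink; no mechanistic sub-models
  for adsorption or metabolite formation (the study detected no MCPA/MCPF
  conjugates).
* One curve per fit: runs and duplicates are pooled, with no random-effects
  hierarchy across runs.
* The Gompertz asymptote extrapolates poorly when gas production has not
  plateaued within the recorded window (the seed-substrate variant); this
  shows up as wide intervals, which the package reports but does not
  otherwise flag.
* Wald-type intervals (even robust ones) are asymptotic; at small n they
  can under-cover, and the package makes no profile-likelihood or bootstrap
  alternative available.
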