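# rumentox

Kinetic analysis of sycamore-maple toxin transformation and gas production
in ruminal-fluid batch cultures.

Sycamore maple (*Acer pseudoplatanus*) seeds carry hypoglycin A (HGA), its
γ-glutamyl dipeptide hypoglycin B (HGB) and methylene cyclopropyl glycine
(MCPrG) — the toxins behind atypical myopathy in grazing horses. When milled
seeds are incubated in buffered ruminal fluid, HGB is hydrolysed to HGA
while HGA itself is slowly cleared, so the HGA concentration first rises,
peaks, and then falls. `rumentox` implements the quantitative toolkit for
such batch-culture experiments:

* **Conversion–clearance kinetics** — the two-compartment first-order
  system

  ```
  dHGB/dt = −k·HGB          dHGA/dt = k·HGB − l·HGA
  ```

  with its closed-form (Bateman-type) solution, a Runge–Kutta oracle, the
  closed-form time of peak HGA, and joint nonlinear least-squares estimation
  of (HGA₀, HGB₀, k, l) from both analyte series.
* **Exponential decay** — C(t) = C₀·e^(−kt) fits with half-life t½ = ln 2 / k,
  for pure-toxin incubations.
* **Gas production** — ideal-gas conversion of cumulative headspace pressure
  (psi) to gas volume, blank correction, downsampling of 5-minute recordings
  to a 0.5 h analysis grid, and the re-parameterised Gompertz curve
  G(t) = a·exp(−exp(−(t−m)/s)), expressed through the interpretable triple
  (a = asymptotic mL gas/g dry matter, b = time to a/3, c = extra time to
  0.70·a).
* **Fermentation statistics** — blank-referenced NH₃ differences,
  per-fermenter C2:C3 (acetic:propionic) ratios, and Pearson / Spearman /
  Kendall τ-b correlation matrices with significance stars.
* **Synthetic experiments** — a fully seeded generator that emulates the
  study design (4 runs, duplicate fermenters per variant, sampling at
  0/1/2/4/8/24/48 h, CSM/PCM/SMS variants plus blanks and autoclaved
  controls) so every stage is testable without laboratory data.

The fits are scikit-learn-style estimators (`ConversionClearanceModel`,
`ExponentialDecayModel`, `GompertzGasModel`: `fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling; module-level functions (`fit_conversion_model`,
`fit_gompertz`, …) are thin wrappers over them that accept tidy CSV tables.

## Worked example

```python
import rumentox as rt

config = rt.ExperimentConfig()                # the default study design
data = rt.generate_dataset(config, seed=1)    # toxins + gas + metabolites

# joint conversion-clearance fit on the seed-incubation (SMS) toxin series
sms = data.toxins.query("variant == 'SMS' and medium == 'vital'")
res = rt.fit_conversion_model(sms[sms.analyte == "HGA"],
                              sms[sms.analyte == "HGB"])
print(res.estimates)   # ng/mL and 1/h
# {'hga0': 4370.76, 'hgb0': 21305.50, 'k': 0.1025, 'l': 0.0392}

p = rt.ToxinKineticParams(**{k: res.estimates[k] for k in ("hga0", "hgb0", "k", "l")},
                          unit="ng/mL")
print(round(rt.hga_peak_time(p), 1))          # -> 13.3  (hours to maximal HGA)

# gas-production kinetics: blank-correct, downsample, convert, fit
from rumentox.pipeline import process_and_fit_gas
import json
gas = process_and_fit_gas(data.gas_curves, data.gas_blanks)
print(json.loads(gas["SMS"]["fit"])["parameters"])
# {'a': 451.6, 'b': 43.4, 'c': 32.0}   # mL/g DM, h, h  (truth: 453, 43.5, 32.1)

# half-life of pure HGA in the spiked (PCM) incubations
pcm = data.toxins.query("variant == 'PCM' and medium == 'vital' and analyte == 'HGA'")
print(round(rt.fit_exponential_decay(pcm).half_life, 2))   # -> 1.65 h
```

The recovered rate constants (k = 0.103/h, l = 0.039/h) sit close to the
generating truth (0.10, 0.036) and place the HGA peak at 13.3 h; the
per-seed half-life estimate scatters around the 2.05 h generating truth
(1.65 h at this seed; the mean over 20 seeds is 2.07 h).

The same pipeline runs from the shell:

```bash
rumentox run --seed 1 --out results/       # simulate → fit → correlate
rumentox simulate --seed 1 --out data/     # just the synthetic CSV tables
rumentox recover --n-reps 200 --seed 1 --out results/   # CI coverage study
```

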