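# rhythmshift

Analysis of 24-hour rhythms in targeted metabolomics time series collected
under shifted sleep–wake schedules (e.g. simulated night-shift protocols),
for chronobiologists and metabolomics analysts.

A typical study samples plasma every 2 h over 24 h from the same subjects at
baseline and again after their sleep period has been delayed by several
hours. The questions the package answers:

* Which metabolites show a 24-h rhythm at the group level, in each condition?
* Of the metabolites rhythmic in both conditions, which track the shifted
  **behavioural** cycle (sleep–wake, fasting–feeding) and which stay locked
  to the **endogenous circadian clock** (melatonin phase)?
* Which metabolites change overall level between conditions?
* How heterogeneous are the rhythms and their phase shifts across subjects?
* Which metabolite classes are overrepresented among any of these hit lists?

## The model

Rhythm detection uses the linearised mixed-effects cosinor. For metabolite
*k*, the log2 concentration of subject *i* at time *t<sub>ij</sub>* is

> y<sub>ijk</sub> = a<sub>k</sub> + b<sub>k</sub> cos(2πt<sub>ij</sub>/24) +
> c<sub>k</sub> sin(2πt<sub>ij</sub>/24) + η<sub>ik</sub> + ε<sub>ijk</sub>

with a random mesor η<sub>ik</sub> ~ N(0, σ<sub>u</sub>²) per subject and
residual ε<sub>ijk</sub> ~ N(0, σ<sub>e</sub>²), fit by maximum likelihood.
Rhythmicity is the likelihood-ratio test against b = c = 0 (χ², 2 df),
Benjamini–Hochberg corrected across metabolites. Amplitude and acrophase
follow from the coefficients: A = √(b²+c²), φ = (24/2π)·atan2(c, b), so the
fit is a + A·cos(2π(t−φ)/24) and φ is the time of peak.

The same model fitted against three different time axes does the causal
bookkeeping: *relative time* (hours after habitual sleep onset) for
detection, and — for metabolites rhythmic in both conditions — *circadian
time* (hours after melatonin phase) versus *behavioural time* (hours after
lights-off) on pooled data. A metabolite is **circadian-influenced** when the
circadian model is significant (BH q < 0.05) and has the lower BIC, and
**behaviour-influenced** in the mirror case.

Per-subject series get a fixed-effects cosinor with the zero-amplitude
F-test, corrected by permutation (time-shuffled series, pooled empirical
null). Phase shifts between conditions live on [−12, +12) h with negative =
delay; they are summarised with circular statistics (circular mean/SD,
Rayleigh and Rao spacing tests, circular–circular correlation). Class
overrepresentation uses one-sided Fisher exact tests.

## Worked example

Simulate a study with the default design — 9 subjects, 13 timepoints × 2
conditions (229 samples after random dropout), 130 metabolites of which 30
follow the behavioural cycle, 10 the circadian clock and 90 are flat, with a
10-h schedule delay — then run the whole analysis:

```python
from rhythmshift.simulate import SimulationConfig, simulate_dataset
from rhythmshift.pipeline import PipelineConfig, run_full_pipeline

samples, matrix, truth = simulate_dataset(SimulationConfig(seed=7))
manifest = run_full_pipeline(PipelineConfig(seed=7, n_perm=200),
                             samples=samples, matrix=matrix)
print(manifest["stages"]["group_rhythmicity"])
print(manifest["stages"]["classification"]["labels"])
print(manifest["stages"]["classification"]["behavioural_shift"]["mean_shift_h"])
```

prints

```
{'n_rhythmic_baseline': 41, 'n_rhythmic_nightshift': 41, 'n_rhythmic_both': 40,
 'overlap_p': 3.1168931445653323e-31}
{'behavioural': 30, 'circadian': 10}
-9.92
```

All 40 truly rhythmic metabolites are recovered in both conditions (plus one
false positive per condition, in line with FDR 0.05), the overlap is
(unsurprisingly) extreme, every metabolite gets its generating regime back
as its label, and the behaviour-influenced set shows a mean phase *delay* of
9.9 h — the imposed 10-h schedule delay, attenuated slightly by fit noise.
The circadian-influenced set shows no shift.

The same stages are exposed as a CLI (`rhythmshift simulate | preprocess |
group | classify | individual | enrich | run-all`); `run-all` writes per-stage
TSVs plus a `manifest.json` that is byte-identical across reruns with the
same seed.

To analyse real data, provide three delimited tables (samples, metabolites,
concentrations — see `rhythmshift.io_preprocess`) with per-subject habitual
sleep onset, per-condition lights-off, and melatonin phase; concentrations
in µM (or log2 µM with `already_log2`). Metabolites below the limit of
detection in more than 10% of samples are dropped; remaining censored values
are imputed at half the minimum detected concentration.

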