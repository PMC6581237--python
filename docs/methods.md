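# Methods

## Data model and preprocessing

A study is three tables: sample annotations, metabolite annotations, and
concentrations. Concentrations are micromolar and are log2-transformed on
load (skippable via `already_log2` when a table is already on the log2
scale). Two missingness mechanisms are kept strictly apart:

* **Below-LOD censoring** — the assay could not detect the analyte. A
  metabolite is retained only if it is above the LOD in at least 90% of its
  measurements (removal when the censored fraction strictly exceeds
  `max_below_frac = 0.10`, computed over non-missing cells); surviving
  censored cells are imputed at 50% of the metabolite's minimum detected
  concentration, i.e. `min − 1` on the log2 scale. Imputed values therefore
  never exceed the minimum detected value, and the filter is idempotent.
* **Missing at random** — a sample was not measured. These cells stay NaN and
  each fit drops them row-wise. They are *not* imputed, because the censoring
  rule would bias them low.

Every sample carries three time coordinates, each reduced to [0, 24):
relative time (hours after the subject's habitual sleep onset — the
detection axis, so subjects with different bedtimes align), behavioural time
(hours after lights-off in that condition) and circadian time (hours after
the subject's melatonin phase, which is assumed not to move between
conditions). When melatonin phases are absent, circadian time is NaN and the
classification stage refuses to run rather than substituting another axis.

## Group-level rhythm detection

The mixed-effects cosinor (fixed `1, cos, sin` at a fixed 24-h period;
random intercept per subject) is estimated by **maximum likelihood**, not
REML, so the likelihood-ratio test against the reduced model b = c = 0 is
valid; BIC is `−2ℓ + k·ln(n)` with n = observations and k = 5 (three fixed
effects, two variances). The random-intercept structure lets the likelihood
be profiled down to the variance ratio λ = σ<sub>u</sub>²/σ<sub>e</sub>²
(Sherman–Morrison inversion per subject block), which is maximised as a
bounded scalar problem over log λ (tolerance 1e−8); the boundary λ = 0
(plain OLS) is always evaluated and kept when it wins, so a variance
component estimated at zero is a legitimate result. This profiled fit agrees
with statsmodels `MixedLM(reml=False)` to ~1e−7 in coefficients and
log-likelihood (cross-checked in the test suite) while being ~2 orders of
magnitude faster, which is what makes 1,000-metabolite calibration runs and
permutation studies cheap. A fit that fails to converge is flagged and
propagated downstream as non-rhythmic with a warning rather than aborting a
whole screen.

P-values are Benjamini–Hochberg corrected per condition; the rhythmic set is
q < 0.05. With 9 subjects and 13 timepoints the chi-square(2) reference is
only asymptotic; null simulations at the study's design put the empirical
type-I error at roughly 0.05–0.06 at α = 0.05 (slightly anticonservative,
as expected for an ML-based LRT at this sample size).

## Circadian- vs behaviour-influenced classification

Restricted to metabolites rhythmic in both conditions. Each is refit twice
on pooled both-condition data — once on circadian time, once on behavioural
time — sharing a single (b, c) pair across conditions, which is exactly what
makes the axes informative: a rhythm locked to the schedule is coherent on
behavioural time but smeared on circadian time after a 10-h delay, and vice
versa. LRT p-values are BH-corrected **separately within each model family**
(a design choice; the scoping of the correction is otherwise ambiguous).
Labels: `circadian` iff q_circadian < 0.05 and BIC_circadian <
BIC_behavioural; `behavioural` in the mirror case; otherwise `neither`.
Both rule sets can fail (neither model significant, or significance and BIC
disagree); they cannot both succeed since the BIC comparison breaks the tie.

## Overall level change

Per metabolite, `log2 value ~ condition + (1 | subject)` by ML with a
chi-square(1) LRT on the condition term, BH across metabolites. The LRT was
chosen over a Wald test for consistency with the rhythmicity machinery.
Direction (`up`/`down`) is only assigned at q < 0.05.

## Individual-level analysis

Per (subject, condition, metabolite) series: OLS cosinor and the classical
zero-amplitude F-test (joint b = c = 0; df 2 and n − 3). Multiplicity within
a subject/condition is handled by permutation: each metabolite's time labels
are shuffled `n_perm = 1000` times (equivalently, the response is permuted
against the fixed design), the null F statistics are **pooled across that
subject/condition's metabolites**, and the corrected p is
`(1 + #{F_null ≥ F_obs}) / (1 + n_null)`. Pooling gives a null sample of
~130,000 rather than 1,000 per metabolite, stabilising the far tail; the +1
ensures p > 0 and validity. A per-metabolite null is available
(`scheme="per_metabolite"`). Corrected p-values are monotone in the observed
F within a subject/condition by construction, and all shuffles derive from a
single seeded generator, so results are bit-reproducible.

Summaries: pairwise rhythmic-set overlap between subjects as Jaccard
percentage (100·|A∩B|/|A∪B| — symmetric, matching a symmetric heatmap;
intersection-over-minimum available via `method="min"`); per-metabolite
circular variance of individual phase estimates, restricted to metabolites
rhythmic at uncorrected p < 0.05 in ≥ 3 subjects; per-subject phase-shift
vectors with a Rayleigh test each (subjects with < 3 commonly rhythmic
metabolites are skipped), and an across-subject Rayleigh test on the
per-subject circular mean shifts.

## Circular statistics

Angles are hours × 2π/24. Circular SD is √(−2 ln R̄) converted back to
hours. The Rayleigh p-value is the classical approximation with the
finite-n correction terms; different packages differ in the higher-order
terms at the third decimal for small n. The Rao spacing p-value is a seeded
Monte-Carlo tail probability (default 10,000 uniform draws) rather than
table lookup, so any n works. Circular–circular correlation is the
Jammalamadaka–SenGupta coefficient with its asymptotic normal p.

Phase differences between conditions are `φ_baseline − φ_shifted` wrapped to
**[−12, +12)**: negative = delay (the shifted rhythm peaks later), which is
the direction a delayed schedule induces. A tie at exactly ±12 h maps to
−12 so a full half-cycle displacement is reported as a 12-h delay.

## Enrichment

One-sided ("greater") Fisher exact test per metabolite class on the 2×2
membership table, unadjusted across classes with significance at p < 0.05
(overrepresentation is a screening question here, and the class count is
small); two-sided available by flag. The residual "other" class stays in the
universe but is not tested by default.

## Synthetic data generator

Emulates the target design: 9 subjects, samples every 2 h over 24 h
(13 nominal timepoints including both endpoints) in two conditions, a 10-h
lights-off delay in the night-shift condition, ~2.1% of samples dropped
completely at random (229 of 234 retained), 130 metabolites cycled over the
7 chemical classes: 30 behaviour-driven, 10 circadian-driven, 90 arrhythmic.
Log2 values are mesor (uniform 2–8 log2 µM) + subject intercept (SD 0.5) +
A·cos(2π(t_axis − φ)/24) + Gaussian noise (SD 0.25), i.e. lognormal
concentrations; amplitudes are uniform on 0.2–1.0 log2 units, bracketing the
0.2-ish median amplitudes typical of plasma metabolite rhythms while giving
a usable range of signal-to-noise. The driving axis t_axis is behavioural
time for behavioural metabolites and circadian time for circadian ones; a
per-subject **adaptation fraction** scales how far each subject's
behavioural rhythms actually move with the schedule (1 = fully shifted,
0 = not at all), which reproduces heterogeneous individual phase-shift
signatures. Habitual sleep onsets are N(23:00, 0.75 h) and melatonin phases
sit ~2 h before sleep onset with 0.5 h jitter, so the circadian and
behavioural axes are decorrelated across subjects only through the schedule
shift — exactly the contrast the classification exploits. Optional
below-LOD censoring flags each metabolite's lowest `lod_quantile` of values.

What the generator does **not** emulate: correlated metabolite networks,
class-specific kinetics or meal responses, autocorrelated within-series
noise, non-sinusoidal waveforms, and condition effects on amplitude or
mesor. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to real-data violations
of it.

## Numerical and design choices

* Period fixed at 24 h throughout; no period estimation.
* λ optimised on log scale within e<sup>±14</sup>; degenerate noiseless
  input makes the ML likelihood unbounded (σ<sub>e</sub> → 0) — tests use
  small jitter instead, and real data never hits this.
* Zero amplitude: the acrophase is returned as NaN (flagged undefined),
  never as 0 h, and a vanishing resultant likewise yields an undefined
  circular mean with variance 1.
* Constant series: F = 0, p = 1 (non-rhythmic), not an error; an entirely
  below-LOD metabolite is removed with a warning, not an error.
* Duplicate (metabolite, sample) measurements are a hard error; sampling-time
  duplicates within a subject are tolerated as distinct samples.
* `run-all` recomputes all stages per invocation and records a config hash
  in the manifest; at this problem scale (seconds per stage) a result cache
  adds failure modes without buying anything.
* Problem sizes in the validation scripts (1,000 null metabolites for
  type-I calibration, 200 metabolites for phase recovery, 10,000 replicates
  for uniformity-test calibration, n_perm = 1,000) are chosen so binomial /
  Monte-Carlo error is small against the property being checked.

## Known limitations

* The chi-square LRT reference is asymptotic in subjects; with very few
  subjects (< 5) it grows more anticonservative.
* The classification needs melatonin phase; there is deliberately no
  fallback axis.
* Permutation correction controls a per-family error rate empirically; it is
  not an FDR and is not exchangeable with BH q-values.
* The wide-format concentration loader assumes the first column names the
  metabolite.
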