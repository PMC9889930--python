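# eegdr

An EEG-based depression-recognition (DR) toolkit for clinical neurophysiology
research, combining four things a depression biomarker study needs:

1. **Signal features** — for each analysis epoch of a resting-state EEG
   channel, seven candidate depression markers: maximum, sample variance,
   excess kurtosis, skewness, the detrended fluctuation analysis (DFA)
   scaling exponent α, the Higuchi fractal dimension (HFD), and the
   normalised spectral entropy of the Welch power spectrum.
2. **A classification pipeline** — SMOTE class balancing, z-score
   normalisation and one of four feature-selection routes (all features,
   L1-penalised linear, tree-ensemble importance, FDR-corrected Welch
   tests), evaluated with repeated stratified 5-fold cross-validation
   (Accuracy, Recall, Precision; all resampling, normalisation and
   selection refit inside each training fold).
3. **Clinical scales** — deterministic HAMD-24 scoring with 7-factor
   subscores, severity bands and the anxious-depression subtype gate
   (anxiety/somatization factor ≥ 7 → A-MDD, ≤ 2 → NA-MDD), and TAS-20
   scoring with reverse-coded items, DIF/DDF/EOT factors and alexithymia
   bands.
4. **Hormone rhythms** — circadian-rhythm-disorder (CRD) classification of
   three-timepoint (08:00/16:00/24:00) ACTH/cortisol profiles by
   50%-decline rules, the diurnal cortisol slope, and cohort incidence with
   a 2×2 chi-square.

Because clinical EEG cohorts are rarely shareable, the package ships a
first-class synthetic-data module (`eegdr.synthetic`) that generates every
input it consumes from explicit seeds: noise classes with analytically
known DFA exponents (α = (β+1)/2 for 1/f^β spectra), two-group EEG cohorts
with injected alpha-band power effects, questionnaire cohorts with
configured group means, and hormone cohorts with an exact constructed CRD
fraction.

## The core statistics

For a mean-centred epoch x₁…x_N, the DFA profile is Y(k) = Σ_{i≤k}(x_i − x̄).
For each box size n the profile is split into ⌊N/n⌋ boxes, a linear trend is
removed per box, and F(n) = √(mean squared residual). The scaling exponent α
is the slope of log F(n) on log n; white noise gives α = 0.5, long-range
correlated signals α > 0.5.

The Higuchi dimension builds k-decimated curve lengths
L_m(k) = [Σ|x(m+ik) − x(m+(i−1)k)|]·(N−1)/(⌊(N−m)/k⌋·k²), averages over
offsets m, and takes D = −slope of ln L(k) vs ln k ∈ [1, 2].

Spectral entropy is H = −Σ p_f ln p_f / ln B, where p_f is the normalised
Welch power spectrum over B non-DC bins: 1 for a flat spectrum, → 0 for a
line spectrum.

## Worked example

```python
import numpy as np
from eegdr import synthetic, features, pipeline, scales, rhythm

# 1. simulate a small two-group resting-EEG cohort (8-13 Hz power effect)
spec = synthetic.CohortSpec(n_per_group=10, n_channels=8, sampling_rate=250.0,
                            duration=20.0,
                            effect=synthetic.BandPowerEffect(channels=(0, 1, 2)),
                            seed=42)
cohort = synthetic.gen_eeg_cohort(spec)

# 2. epoch (4 s windows) and extract the seven features per epoch
table = features.extract_cohort_features(cohort.recordings)
labels = {r.subject_id: int(l) for r, l in zip(cohort.recordings, cohort.labels)}
m = pipeline.assemble_matrix(table, labels)
print("feature matrix:", m.X.shape)

# 3. repeated stratified 5-fold CV with tree-based selection
report = pipeline.cross_validate(m, selection_method="tree", repeats=10, seed=42)
print({k: round(v, 3) for k, v in report.pooled.items()})

# 4. clinical scales
res = scales.score_tas([3] * 20)
print("TAS total:", res.total, res.factor_scores, res.band)

# 5. hormone rhythm
profiles = synthetic.gen_hormone_cohort(100, 0.72, seed=1) + \
           synthetic.gen_hormone_cohort(100, 0.51, seed=2)
summary = rhythm.cohort_incidence(profiles, ["A-MDD"] * 100 + ["NA-MDD"] * 100)
print("CRD incidence:", summary["incidence"]["COR"],
      "chi2 =", round(summary["chi2"]["COR"], 3))
```

prints

```
feature matrix: (20, 56)
{'accuracy': 0.975, 'recall': 0.95, 'precision': 1.0}
TAS total: 60 {'DIF': 21, 'DDF': 15, 'EOT': 24} moderate
CRD incidence: {'A-MDD': 0.72, 'NA-MDD': 0.51} chi2 = 9.313
```

The feature matrix has one row per subject (channel×feature columns, here
8×7 = 56). With the injected alpha-band effect the pipeline separates the
groups almost perfectly (pooled accuracy 0.975 over 10×5-fold CV). The
all-3s TAS-20 response scores 60 (moderate alexithymia) because reverse
items map 3 → 3. The hormone cohorts classify to exactly their constructed
72% / 51% CRD incidences, and the 2×2 chi-square (9.31) flags the group
difference.

A `dr` command-line interface wraps the same functionality
(`dr extract`, `dr crossval`, `dr compare-selection`, `dr train`,
`dr predict`, `dr score-scales`, `dr rhythm`); see `dr --help`.

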