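# Methods

## Scope and data model

The toolkit treats depression recognition as a supervised two-class problem
on per-subject EEG feature vectors, flanked by two deterministic clinical
components (questionnaire scoring, hormone-rhythm classification). A
`Recording` is a channels × samples array with a sampling rate; analysis
operates on fixed-length single-channel `Epoch`s. Features are aggregated to
one row per subject (mean over epochs per channel × feature) by default; a
per-epoch mode exists for users who prefer to classify epochs directly, at
the cost of non-independent rows within subjects.

## Feature estimators

**Moments.** Variance uses the 1/(n−1) denominator. Excess kurtosis uses the
hybrid estimator `(1/(n−1)) Σ(x−x̄)⁴ / SD⁴ − 3` with SD² the 1/(n−1)
variance — not the unbiased G₂ form — so a Gaussian series is centred on 0
(verified to ±0.05 over 100 series of n = 10⁴). Skewness is the population
moment ratio m₃/m₂^{3/2} with the standard sign convention (positive = right
tail heavier); descriptions of the sign convention vary in the clinical
literature, so the convention is stated here once and tested.

**DFA.** Linear (first-order) detrending per box; non-overlapping boxes;
F(n) is the root mean square of residuals over all covered points, and the
trailing partial box is excluded at each scale. Box sizes default to ~12
log-spaced integers from 4 to N/4 — published descriptions of the usable
range vary and are sometimes self-contradictory; this range guarantees ≥ 4
boxes at the largest scale and ≥ 4 usable scales for any N ≥ 64, which keeps
the log–log fit stable. Natural logarithms are used in every log–log fit. On
4-s epochs (1000 samples at 250 Hz) the white-noise exponent estimates at
0.5 with a small positive finite-size bias (≈ +0.02 at n = 4096), well
inside the tolerance used in the tests.

**Higuchi fractal dimension.** The standard construction with k_max = 10
(the precondition N ≥ 10·k_max keeps ⌊(N−m)/k⌋ ≥ 9 segments at the largest
interval). Estimates are clipped to [1, 2] with a flag; the clip only
triggers for signals outside the real-valued-series regime. A pure sinusoid
needs many cycles and a period well above k_max samples to approach 1; the
test signals use 5 Hz at 250 Hz (period 50 samples, 20 cycles per epoch).

**Spectral entropy.** Shannon entropy of the Welch PSD (Hann window,
segments of min(N, 256) samples, 50% overlap), DC bin dropped, normalised by
ln(#bins) to [0, 1]. A single-periodogram definition is noisier for long
epochs; Welch averaging makes the white-noise value concentrate near 1,
which is what makes the flat-vs-peaky contrast a usable feature. The
entropy is invariant under amplitude scaling by construction.

Vectorised batch implementations (all epochs of equal length at once) are
the production path; the test suite holds them to 1e-10 agreement with
literal step-by-step reference implementations.

## Classification pipeline

Order inside every training fold: **SMOTE → normalise → select → fit**.
Oversampling precedes normalisation so synthetic points are interpolated in
the original feature space rather than a fold-dependent z-space; selection
sees balanced, normalised data. All four stages are refit per fold; test
rows only pass through the frozen normaliser and classifier (a perturbation
test asserts bit-identical fold parameters when test rows change).

- **SMOTE**: canonical form — synthetic minority row = x_i + u·(x_j − x_i),
  u ~ U(0,1), x_j one of x_i's k = 5 nearest minority neighbours
  (Euclidean), generated until classes balance. Inside CV, k is capped at
  (minority fold count − 1) so small folds remain usable.
- **Normalisation**: per-feature z-score; constant features dropped with a
  warning.
- **Selection routes**: `all`; `l1` (liblinear logistic with L1 penalty,
  strength 1.0 by default, non-zero coefficients kept); `tree` (random
  forest, 200 trees, importances above the mean — mean/median/absolute
  thresholds available; ties resolved by canonical column order); `fdr`
  (per-feature Welch t-tests, Benjamini–Hochberg at α = 0.05).
- **Classifier**: L2-regularised logistic regression (C = 1) by default —
  a linear probabilistic model keeps the selection-route comparison
  interpretable; random-forest and k-NN alternatives are configurable.
- **Metrics**: pooled over all folds and per repeat; positive class =
  depressed/A-MDD (label 1). An empty selection falls back to all features
  rather than fitting a zero-dimensional model.

Stratified folds preserve class proportions within ±1 sample; the full
report (metrics, per-fold selected features, normaliser parameters) is
bit-reproducible from (matrix, config, seed).

## Clinical scales

HAMD-24: total = Σ items; bands severe (> 35), definite (20–35), possible
(8–19), normal (< 8). The printed band edges in common clinical summaries
overlap at 8 and 20; both boundaries resolve upward (20 → definite,
8 → possible), consistent with the ≥ 21 inclusion convention for definite
depression, and are configurable. The 7-factor item map and the 0–2 vs 0–4
per-item ranges ship as an editable `HamdConfig` following the standard
Chinese 24-item factor structure (externally sourced convention — the
factor map is not derivable from scoring rules alone). The subtype gate
reads the anxiety/somatization factor: ≥ 7 A-MDD, ≤ 2 NA-MDD, 3–6
indeterminate (excluded by design in two-group studies).

TAS-20: reverse items {4, 5, 10, 18, 19} map v → 6 − v; factors
DIF {1,3,6,7,9,13,14}, DDF {2,4,11,12,17}, EOT {5,8,10,15,16,18,19,20}
partition the items exactly (asserted), so factor scores sum to the total.
Bands: ≤ 51 non-alexithymia, 52–60 moderate, ≥ 61 severe — the moderate
band is stated inconsistently in parts of the literature; 52–60 is the
unique choice exhaustive against its neighbours.

## Hormone rhythms

A profile is rhythm-disturbed when a later timepoint fails to fall below
50% of an earlier one: c16 ≥ 0.5·c8, or c24 ≥ 0.5·c16, or c24 ≥ 0.5·c8
(inclusive comparisons; threshold and rule subset configurable). This
operationalises the expected halving of cortisol across the waking day;
verbatim clinical statements of the rule are often typographically mangled,
so the rule is stated here explicitly and exposed as configuration. The
rule is evaluated per analyte (ACTH and COR separately) and both are
reported. The diurnal slope is (c8 − c24)/16 h, positive = declining; a
three-point regression definition is provided and agrees exactly on
time-collinear profiles. Cohort incidence comes with a Pearson 2×2
chi-square (no continuity correction by default; a degenerate margin gives
χ² = 0).

## Synthetic data: what it emulates and what it does not

- **Noise classes**: 1/f^β Gaussian noise by FFT spectral shaping
  (Hermitian symmetry, O(n log n), exact target slope), standardised to
  unit variance. These give the feature estimators analytically known
  targets (DFA α = (β+1)/2).
- **EEG cohorts**: per-channel pink-noise background (σ ≈ 10 µV, lognormal
  15% between-subject jitter); the affected group receives an additive
  sinusoid at a per-subject frequency uniform in the effect band (default
  8–13 Hz — alpha-band power alteration being the classic depression EEG
  finding) on designated channels, amplitude = rel_amplitude × background σ
  with N(1, 0.25) subject jitter. Default study configuration: 250 Hz, 16
  channels, 60 s, 6 affected channels, rel_amplitude 1.0. This produces a
  strong but not trivial group difference: pooled CV accuracy ≥ 0.75 at
  n = 30/30 (observed ≈ 0.98), i.e. the qualitative regime of a
  high-accuracy clinical classifier.
- **Questionnaire cohorts**: per subject a target total ~ N(µ_g, σ_g),
  rounded and clipped to the admissible range, then distributed over items
  by random unit increments within per-item ranges — totals are exact by
  construction, item response *profiles* are not psychometrically
  structured (no item difficulty or factor correlation).
- **Hormone cohorts**: direct construction — c8 lognormal around 400 nmol/L
  (COR) or 40 pg/mL (ACTH); decline ratios drawn strictly inside (0.15–0.45)
  or outside (0.55–1.10) the threshold, so CRD status is exact by
  construction and re-verified against the classifier at generation time.

Passing tests on these cohorts demonstrates that the estimators and the
pipeline recover *known, injected* structure without leakage. They do not
show robustness to real EEG artifacts (blinks, muscle, electrode drift),
montage/reference effects, non-Gaussian item responses, or pharmacological
hormone dynamics — none of which are modelled.

## Numerical and design choices

- Epoch default 4 s, zero overlap: ≥ 1000 samples at 250 Hz gives stable
  DFA/HFD estimates while still yielding 15 epochs per 60-s channel.
- EDF writing uses one data record spanning the whole signal and a
  symmetric per-channel physical range set from max|value|, maximising
  16-bit quantisation resolution; reading goes through mne and assumes µV.
- Degenerate inputs: constant epochs raise a degenerate-input error naming
  the epoch (kurtosis/skewness undefined); DFA drops box sizes with < 2
  boxes and errors below 4 usable sizes; FDR skips zero-variance features.
- Problem sizes in the test suite (cohort n = 30/group, 200 FDR
  permutations, 50 noise seeds) were chosen once as the smallest sizes at
  which the distributional checks are stable.

## Known limitations

- The per-subject mean over epochs discards within-subject variance; a
  mixed-effects treatment is out of scope.
- SMOTE in the original feature space can generate implausible points when
  features live on very different scales; users with heterogeneous feature
  sets may prefer to pre-scale before assembly.
- The four selection routes are compared under one default classifier;
  route × classifier interactions are not explored.
- Band-power, connectivity and entropy-variant features (sample/approximate
  entropy) are deliberately not included in the feature set.
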