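# Methods

## Generative model

A trial is synthesized per channel as an innovation process passed through a
linear shaping stage and a condition-dependent distortion.

**Innovation.** Samples are drawn i.i.d. from a two-component scale mixture:
with probability `w` a Laplacian (variance 1), otherwise a Gaussian
(variance 1). Surface EMG amplitude distributions are commonly described as
lying between Gaussian and Laplacian, with the weighting reported to depend
on contraction intensity; the generator makes `w` a linear function of the
MVC level across `laplacian_weight_range` (default 0.2 → 0.8, tending toward
Laplacian at high intensity — the literature also reports the opposite trend,
so both direction and range are configurable).

**Shaping.** The innovation is split into a broadband component (4th-order
Butterworth band-pass, 20–450 Hz, matching the conditioning band used
downstream) and a resonant component (IIR peak filter, Q = 5) at the
condition's `spectral_peak`. Both are RMS-normalised and mixed with the
resonant component at relative weight 0.8, then the sum is normalised to unit
RMS. This reproduces the two gross spectral facts that matter for the
confound — a broadband 20–450 Hz envelope and a firing-rate peak that
migrates from ~10 Hz to ~40 Hz with intensity — without modelling motor-unit
recruitment or firing trains, which are out of scope.

**Activation envelopes.** Each subject has a classes × channels amplitude
matrix drawn uniformly on [0.1, 1.0] mV with a per-subject scale on
[0.7, 1.3]; the no-motion row sits at the noise floor. Repeated contractions
receive per-trial, per-channel lognormal amplitude jitter
(`trial_amplitude_jitter`, sigma 0.2): real repetitions of the same gesture
are never amplitude-identical, and without this term the intra-condition
task saturates at 100%.

**Position confound.** Condition `k` (index distance `k` from the reference,
which is the first listed condition) mixes channels through
`W = (1 − α)I + αM`, `M` a seeded row-stochastic matrix unique to each
(subject, position); the reference keeps `W = I`. Stabilization activity —
band-limited noise at `β·k` mV RMS — is added on a seeded half of the
channels, reflecting that postural muscles share space with only some
recording sites. α and β have no signal-level values in the source
literature (the effect is only quantified in accuracy), so the defaults
(α = 0.5, β = 0.3) were calibrated once against the benchmark's own
acceptance conditions: they are the smallest round values that pull the
condition-matched task off its ceiling (~94% intra with TD + LDA) while
keeping inter-condition performance well above chance (~57%), producing the
qualitative degradation ordering robustly across seeds.

**Intensity confound.** Level `ℓ ∈ (0, 1]` applies gain `ℓ^γ` (γ = 1 by
default: the linear amplitude–force relationship is the testable default,
and γ is exposed because nonlinear relationships are also reported), moves
`spectral_peak` linearly across `peak_shift_range` (default 10–40 Hz) between
the lowest and highest configured levels, and interpolates the Laplacian
weight likewise. No channel mixing and no baseline activity are applied.

**Determinism.** All randomness derives from `SeedSequence` streams keyed by
`(config.seed, stream tag, subject, condition, class, rep)`; identical
configs give bit-identical datasets, and every trial can be regenerated in
isolation from its own seed.

## Conditioning and segmentation

Zero-phase (forward–backward) filtering throughout — the analysis is
offline, so the phase distortion of causal filtering is avoidable. Defaults:
50 Hz notch at Q = 30 (only the centre frequency is conventionally reported;
Q = 30 gives a ~1.7 Hz stopband), 20–450 Hz 4th-order Butterworth band-pass
(10 Hz high-pass variants exist in the literature; both edges are
configurable), integer-ratio decimation to 1000 Hz, and 150 ms windows with
50 ms increments. A recording of `N` samples yields `⌊(N − L)/I⌋ + 1`
windows; windows never span trial boundaries; too-short recordings are
skipped with a warning.

## Feature conventions

The literature names these features but rarely prints formulas; the package
fixes one testable convention per feature (documented in
`features.py`) and verifies each against an independently coded
direct-formula oracle. Notable choices:

- **Thresholds.** ZC/SSC use threshold 0 (maximises determinism on synthetic
  data); WAMP uses 0.02 mV. All configurable per feature set.
- **LS** is the second L-moment (L-scale) of the raw window; whether the
  low-sampling-frequency sets intend the raw or rectified signal is not
  derivable from the source, so raw is the default and the choice is
  configurable at the call level (pass the rectified window).
- **AR4** solves the Yule–Walker equations on the biased autocovariance of
  the demeaned window; coefficients follow the `x_t ≈ Σ aᵢ x_{t−i}`
  convention.
- **SampEn** uses m = 2, r = 0.2·SD, Chebyshev distance with tolerance
  `≤ r`, natural log, self-matches excluded, and the m-template count
  restricted to the same N − m templates as the (m+1)-count. Zero-variance
  windows return 0; a zero (m+1)-match count is floored at one match so the
  value stays finite on highly regular windows.
- **TDPSD** builds the six descriptors from the root moments
  m0 = √Σx², m2 = √Σ(Δx)², m4 = √Σ(Δ²x)², each power-rescaled
  `m ← m^0.1/0.1`: log m0, log(m0−m2), log(m0−m4), sparseness
  log(m0/√((m0−m2)(m0−m4))), irregularity log(m2/√(m0·m4)), and the
  waveform-length ratio log(Σ|Δx|/Σ|Δ²x|). The same descriptors are computed
  from `log(x² + ε)` and each pair (a, b) is fused as `−2ab/(a² + b²)`.
  The cited construction in the literature may differ in detail, so a
  raw-descriptors-only variant (`TDPSD_RAW`) is exposed alongside the fused
  default. Log arguments are clamped in magnitude at ε = 1e-12 and clamps
  are counted (`features.clamp_count`).
- **Degenerate windows** (silent no-motion data) never produce non-finite
  features: SampEn, MOB and COMP fall back to 0 and log-domain features
  clamp at ε.

## Evaluation

- **TER/accuracy** per the standard total-error definition; accuracy is
  always exactly 100 − TER.
- **AER** uses an explicit no-motion class id, never a positional index.
  The published formula's denominator literally reads "pₙ ≠ 1"; the intended
  reading (predictions different from the no-motion class) is the default,
  and the literal variant is selectable (`printed_denominator=True`) rather
  than silently corrected.
- **DBI** implements the printed formulas exactly: mean *squared*
  within-cluster deviation and *squared* Euclidean separation, even though
  prose descriptions call them standard deviation and Euclidean distance;
  `squared=False` selects the square-root variants. The average runs over
  each cluster's worst overlap (one term per cluster), the reading consistent
  with the accompanying prose; a pairs-count normalisation would make every
  summand identical. Coincident cluster means yield +inf with a warning.
- **Frameworks.** All train/test condition configurations are enumerated
  exhaustively; `multi_vs_all` caps the subset enumeration (default 1000)
  with seeded subsampling beyond it. Leave-one-trial-out is applied uniformly:
  the test set is always the held-out repetition, which is always excluded
  from training, including in the disjoint-condition frameworks where there
  is no leakage either way — keeping fold sizes comparable across frameworks.
- **Classifiers.** Features are z-scored with training-split statistics
  only. QDA carries a small shrinkage (reg_param = 1e-4) because overlapping
  windows make class covariances near-singular. kNN voting ties resolve to
  the smallest class label (sorted class order). The random forest is seeded
  from the experiment seed. Default hyperparameters when tuning is skipped:
  k = 5, C = 1, 100 trees; grid search, when used, scores candidates by
  intra-framework mean accuracy on a tuning subject that is then barred from
  evaluation.
- **Aggregation.** Per-split rows carry accuracy/TER/AER (AER is missing,
  never 0, where all predictions are no-motion). Summaries report
  Mean ± SD (Min, Max) across splits; because the spread can be taken across
  subjects, training conditions, or folds, `EvalResult.by_group` exposes all
  three groupings, and between-framework comparisons use the subject-averaged
  mean. Formal ANOVA machinery is deliberately left to standard packages.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* said to drive both confounds
(channel re-mixing, stabilization baseline, amplitude gain, spectral-peak
shift, distribution shift) with controllable magnitude, balanced classes,
and stationary windows. It does not reproduce motor-unit recruitment
dynamics, electrode-skin impedance drift, fatigue, transient contraction
onsets, or inter-subject anatomy; passing trends here demonstrate that the
pipeline *detects and orders* confound-induced degradation as expected, not
that any particular accuracy value will transfer to real recordings. The
published study's absolute accuracies come from six laboratory datasets
without public accessions and are not reproducible here; the benchmark
targets the qualitative structure (intra > single-vs-all > inter;
multi-vs-all rising with training coverage yet staying at or below the
intra ceiling), which the default conditions reproduce robustly across
seeds.

## Problem sizes

The shipped studies use 2 subjects, 1 s trials (18 windows per trial at
150/50 ms), the D1-shaped position grid (8 channels × 8 motions × 10 reps ×
5 positions) and D4-shaped intensity grid (8 channels × 7 motions × 4 reps ×
7 levels 20–80% MVC), chosen so a full study runs in seconds on one core
while every framework still has hundreds of folds. Subject count and trial
length scale freely through the config.
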