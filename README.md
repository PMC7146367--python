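# emgconfounds

Surface electromyography (EMG) pattern recognition decodes hand and wrist
gestures from multi-channel muscle signals, and works remarkably well —
until the conditions of use drift away from the conditions of training.
Two intrinsic confounds dominate in practice: the **limb position effect**
(stabilization muscle activity and shifting electrode/fibre topography change
the recorded patterns when the arm moves through space) and the **contraction
intensity effect** (signal amplitude, the low-frequency power peak, and the
amplitude distribution all change with contraction force). `emgconfounds` is
a self-contained benchmark of that degradation: a synthetic EMG generator that
carries both confound mechanisms with controllable strength, the standard
conditioning/windowing chain, the named time-domain feature sets, five
classical classifiers, and the four cross-validation frameworks used to
quantify confound sensitivity.

It is aimed at myoelectric-control researchers who want a controlled,
fully reproducible testbed for robustness claims — every effect magnitude is a
config parameter and every run is bit-exact under a fixed seed — and at
practitioners who need reference implementations of the evaluation statistics
and feature catalogs.

## The model and the statistics

**Generator.** Each trial of channel data is a Gaussian/Laplacian amplitude
mixture shaped into the 20–450 Hz EMG band with an added resonant
low-frequency peak, scaled by a per-class, per-channel activation envelope
with per-trial lognormal jitter. Position conditions apply a row-stochastic
channel re-mixing `W = (1 − α)·I + α·M` and inject band-limited stabilization
activity on half the channels, growing with distance from the reference
position. Intensity conditions at MVC fraction `ℓ` apply gain `ℓ^γ`, move the
low-frequency spectral peak linearly across 10→40 Hz, and shift the mixture
weight toward Laplacian.

**Evaluation.** With predictions `pₙ` and labels `lₙ` over `N` test windows
and no-motion class NM:

    TER = 100% · #{pₙ ≠ lₙ} / N
    AER = 100% · #{pₙ ≠ lₙ ∧ pₙ ≠ NM} / #{pₙ ≠ NM}

Feature-space separability uses the Davies–Bouldin index with within-cluster
dispersion `Sᵢ = (1/Nᵢ) Σⱼ (xⱼ−μᵢ)ᵀ(xⱼ−μᵢ)`, separation
`Dᵢⱼ = (μᵢ−μⱼ)ᵀ(μᵢ−μⱼ)`, overlap `Rᵢⱼ = (Sᵢ+Sⱼ)/Dᵢⱼ`, averaging each
cluster's worst overlap. Four frameworks are crossed with within-subject
leave-one-trial-out folds: **x vs x** (intra-condition, the upper limit),
**x vs y** (disjoint conditions, the lower limit), **x vs all** (train one,
test all), and **N vs all** (train on N conditions, test all).

Feature sets: TD (MAV, ZC, SSC, WL), TDAR (TD + AR4), TSTD (MAVFD, DASDV,
WAMP, ZC, MFL, SampEn, TDPSD), LSF4 (LS, MFL, MSR, WAMP), LSF9 (LSF4 + ZC,
RMS, IEMG, DASDV, VAR), TDPSD, and Hjorth (ACT, MOB, COMP). Classifiers:
LDA, QDA, kNN, linear SVM, random forest.

## Worked example

```python
from emgconfounds import (ClassifierSpec, extract_set, generate_dataset,
                          run_experiment, segment)
from emgconfounds.synth import d1_like_config

cfg = d1_like_config(n_subjects=2, seed=1)       # 8 ch, 8 motions, 5 positions
features = extract_set(segment(generate_dataset(cfg)), "TD")
for fw in ("intra", "single_vs_all", "inter"):
    res = run_experiment(features, fw, ClassifierSpec("lda"), seed=1)
    print(fw, round(res.mean_accuracy(), 2))
```

prints

```
intra 94.31
single_vs_all 65.44
inter 58.22
```

i.e. a classifier that scores 94% when trained and tested in the same limb
position keeps only ~58% when the positions are disjoint, and ~65% in the
realistic train-one-test-everywhere setting — the degradation the benchmark
exists to expose. The `analysis/` scripts run the full position and intensity
studies in order (`01_simulate_datasets.py` … `05_report_trends.py`) and
write tidy tables plus a Markdown report under `results/`; the `emgconfounds`
CLI (`simulate | preprocess | extract | evaluate | report`, or `run`) drives
the same pipeline from a YAML config — see `examples/d1_small.yaml`.

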