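"""Cross-validation frameworks, classifiers, and the evaluation statistics
(total error rate, active error rate, Davies-Bouldin index).

Four frameworks probe sensitivity to a confounding condition (limb position or
contraction intensity):

* ``intra`` (x vs x): train and test in the same condition — the upper
  performance limit;
* ``inter`` (x vs y): train and test in disjoint conditions — the lower limit;
* ``single_vs_all`` (x vs all): train in one condition, test in all;
* ``multi_vs_all`` (N vs all): train in N conditions, test in all.

Every framework is crossed with leave-one-trial-out cross-validation within
each subject: the test set always comes from the held-out repetition only, and
training data never include that repetition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "FRAMEWORKS",
    "SplitPlan",
    "PredictionRecord",
    "ClassifierSpec",
    "EvalResult",
    "UndefinedActiveErrorRate",
    "make_splits",
    "ter",
    "aer",
    "dbi",
    "fit_predict",
    "run_experiment",
    "tune_hyperparameters",
]

FRAMEWORKS = ("intra", "inter", "single_vs_all", "multi_vs_all")


class UndefinedActiveErrorRate(ValueError):
    """AER is undefined when no active-class prediction exists (denominator 0);
    callers report it as missing, never as 0."""


@dataclass(frozen=True)
class SplitPlan:
    framework: str
    train_conditions: tuple
    test_conditions: tuple
    held_out_trial: int
    subject_id: int

    def __post_init__(self):
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"unknown framework {self.framework!r}")
        tr, te = set(self.train_conditions), set(self.test_conditions)
        if self.framework == "intra" and tr != te:
            raise ValueError("intra requires train == test conditions")
        if self.framework == "inter" and tr & te:
            raise ValueError("inter requires disjoint train/test conditions")
        if self.framework == "single_vs_all" and len(tr) != 1:
            raise ValueError("single_vs_all trains on exactly one condition")


@dataclass(frozen=True)
class PredictionRecord:
    p: np.ndarray  # predicted classes
    l: np.ndarray  # true classes
    no_motion_class: object

    def __post_init__(self):
        p = np.asarray(self.p)
        l = np.asarray(self.l)
        if p.shape != l.shape or p.ndim != 1:
            raise ValueError("p and l must be 1-D vectors of equal length")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "l", l)

    @property
    def n(self) -> int:
        return self.p.size


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the five classifiers with its hyperparameters.

    ``tuning_subjects`` records subjects consumed by hyperparameter tuning;
    they are barred from downstream evaluation.
    """

    name: str
    k: int = 5
    c: float = 1.0
    n_trees: int = 100
    seed: int = 0
    hyperparameter_grid: dict = field(default_factory=dict)
    tuning_subjects: tuple = ()

    _SUPPORTED = ("lda", "qda", "knn", "svm_linear", "rf")

    def __post_init__(self):
        if self.name not in self._SUPPORTED:
            raise ValueError(f"unknown classifier {self.name!r}")

    def build(self):
        if self.name == "lda":
            clf = LinearDiscriminantAnalysis()
        elif self.name == "qda":
            # small shrinkage keeps near-singular class covariances invertible
            clf = QuadraticDiscriminantAnalysis(reg_param=1e-4)
        elif self.name == "knn":
            clf = KNeighborsClassifier(n_neighbors=self.k)
        elif self.name == "svm_linear":
            clf = SVC(kernel="linear", C=self.c)
        else:
            clf = RandomForestClassifier(n_estimators=self.n_trees, random_state=self.seed)
        # features are z-scored with training-set statistics only
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def make_splits(
    framework: str,
    conditions,
    trials,
    subject_id: int,
    n_train: int | None = None,
    *,
    max_train_sets: int = 1000,
    seed: int = 0,
) -> list[SplitPlan]:
    """Enumerate every train/test assignment of one framework for one subject.

    All configurations of training and testing conditions are crossed with
    leave-one-trial-out folds.  ``multi_vs_all`` enumerates training-condition
    subsets exhaustively up to ``max_train_sets`` and then subsamples with the
    given seed.
    """
    conditions = list(conditions)
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("leave-one-trial-out needs at least 2 trials")
    plans: list[SplitPlan] = []
    if framework == "intra":
        combos = [((c,), (c,)) for c in conditions]
    elif framework == "inter":
        combos = [((x,), (y,)) for x in conditions for y in conditions if x != y]
    elif framework == "single_vs_all":
        combos = [((x,), tuple(conditions)) for x in conditions]
    elif framework == "multi_vs_all":
        if n_train is None:
            raise ValueError("multi_vs_all requires n_train")
        if not (1 <= n_train <= len(conditions)):
            raise ValueError("n_train must lie in [1, number of conditions]")
        subsets = list(itertools.combinations(conditions, n_train))
        if len(subsets) > max_train_sets:
            rng = np.random.default_rng(seed)
            keep = rng.choice(len(subsets), size=max_train_sets, replace=False)
            subsets = [subsets[i] for i in sorted(keep)]
        combos = [(s, tuple(conditions)) for s in subsets]
    else:
        raise ValueError(f"unknown framework {framework!r}")
    for train_c, test_c in combos:
        for t in trials:
            plans.append(
                SplitPlan(
                    framework=framework,
                    train_conditions=tuple(train_c),
                    test_conditions=tuple(test_c),
                    held_out_trial=t,
                    subject_id=subject_id,
                )
            )
    return plans


def ter(record: PredictionRecord) -> float:
    """Total error rate (%): share of all misclassified observations."""
    if record.n == 0:
        raise ValueError("empty prediction record")
    return 100.0 * np.count_nonzero(record.p != record.l) / record.n


def aer(record: PredictionRecord, *, printed_denominator: bool = False) -> float:
    """Active error rate (%): misclassifications among active-class
    predictions, ignoring false predictions of the no-motion class.

    ``printed_denominator=True`` selects the literal published denominator
    (predictions differing from the class *indexed 1*) instead of the intended
    no-motion id.
    """
    if record.n == 0:
        raise ValueError("empty prediction record")
    if printed_denominator:
        active = record.p != 1
    else:
        active = record.p != record.no_motion_class
    denom = int(np.count_nonzero(active))
    if denom == 0:
        raise UndefinedActiveErrorRate("all predictions are the no-motion class")
    num = int(np.count_nonzero((record.p != record.l) & (record.p != record.no_motion_class)))
    return 100.0 * num / denom


def dbi(features, cluster_labels, *, squared: bool = True) -> float:
    """Davies-Bouldin separability index; lower means better-separated classes.

    With ``squared=True`` (default) the within-cluster dispersion is the mean
    *squared* deviation and the between-cluster separation the *squared*
    Euclidean distance, matching the published formulas; ``squared=False``
    selects the square-root (RMS deviation / Euclidean distance) variant.
    Coincident cluster means yield +inf with a warning rather than an error.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    labels = np.asarray(cluster_labels)
    if x.ndim != 2 or x.shape[0] != labels.size:
        raise ValueError("features and cluster labels misaligned")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("DBI needs at least 2 clusters")
    mus, dispersions = [], []
    for c in classes:
        xi = x[labels == c]
        mu = xi.mean(axis=0)
        s = float(np.mean(np.sum((xi - mu) ** 2, axis=1)))
        if not squared:
            s = float(np.sqrt(s))
        mus.append(mu)
        dispersions.append(s)
    mus = np.asarray(mus)
    k = classes.size
    worst = np.empty(k)
    degenerate = False
    for i in range(k):
        r_max = -np.inf
        for j in range(k):
            if i == j:
                continue
            d = float(np.sum((mus[i] - mus[j]) ** 2))
            if not squared:
                d = float(np.sqrt(d))
            if d == 0.0:
                degenerate = True
                r = np.inf
            else:
                r = (dispersions[i] + dispersions[j]) / d
            r_max = max(r_max, r)
        worst[i] = r_max
    if degenerate:
        warnings.warn("coincident cluster means: DBI is infinite", RuntimeWarning)
    return float(np.mean(worst))


def fit_predict(
    spec: ClassifierSpec,
    train: FeatureMatrix,
    test: FeatureMatrix,
    *,
    no_motion_class="no_motion",
) -> PredictionRecord:
    """Fit the classifier on the training rows and predict the test rows."""
    if train.values.shape[1] != test.values.shape[1]:
        raise ValueError("train/test dimensionality mismatch")
    if np.unique(train.motion_label).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    model = spec.build()
    model.fit(train.values, train.motion_label)
    pred = model.predict(test.values)
    return PredictionRecord(p=pred, l=test.motion_label, no_motion_class=no_motion_class)


@dataclass
class EvalResult:
    """Per-split rows plus aggregation helpers (accuracy = 100 - TER exactly)."""

    rows: pd.DataFrame

    def summary(self) -> dict:
        acc = self.rows["accuracy"]
        return {
            "mean": float(acc.mean()),
            "sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
            "min": float(acc.min()),
            "max": float(acc.max()),
            "n_splits": int(len(acc)),
        }

    def subject_average(self) -> pd.Series:
        """Mean accuracy per subject across all folds and test conditions."""
        return self.rows.groupby("subject_id")["accuracy"].mean()

    def mean_accuracy(self) -> float:
        """Subject-averaged mean accuracy (each subject weighted equally)."""
        return float(self.subject_average().mean())

    def by_group(self, level: str) -> pd.DataFrame:
        """Accuracy mean/SD grouped by 'subject_id', 'train_conditions', or
        'held_out_trial' — the groupings over which spread can be reported."""
        g = self.rows.groupby(level)["accuracy"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})

    def render_row(self) -> str:
        s = self.summary()
        return f"{s['mean']:.1f} ± {s['sd']:.1f} ({s['min']:.1f}, {s['max']:.1f})"


def _check_tuning_disjoint(spec: ClassifierSpec, features: FeatureMatrix) -> None:
    overlap = set(spec.tuning_subjects) & set(np.unique(features.subject_id).tolist())
    if overlap:
        raise ValueError(f"tuning subjects {sorted(overlap)} reused in evaluation data")


def run_experiment(
    features: FeatureMatrix,
    framework: str,
    spec: ClassifierSpec,
    *,
    n_train: int | None = None,
    no_motion_class="no_motion",
    max_train_sets: int = 1000,
    seed: int = 0,
) -> EvalResult:
    """Execute one framework over every subject with leave-one-trial-out folds.

    Returns one row per split with accuracy, TER and AER (AER is NaN where
    undefined).  Accuracy always equals 100 - TER.
    """
    _check_tuning_disjoint(spec, features)
    rows = []
    for subject in np.unique(features.subject_id):
        s_mask = features.subject_id == subject
        conditions = list(dict.fromkeys(features.condition_value[s_mask]))
        trials = sorted(set(features.trial_index[s_mask].tolist()))
        plans = make_splits(
            framework, conditions, trials, int(subject), n_train,
            max_train_sets=max_train_sets, seed=seed,
        )
        for plan in plans:
            train_mask = (
                s_mask
                & np.isin(features.condition_value, list(plan.train_conditions))
                & (features.trial_index != plan.held_out_trial)
            )
            test_mask = (
                s_mask
                & np.isin(features.condition_value, list(plan.test_conditions))
                & (features.trial_index == plan.held_out_trial)
            )
            record = fit_predict(
                spec, features.subset(train_mask), features.subset(test_mask),
                no_motion_class=no_motion_class,
            )
            t = ter(record)
            try:
                a = aer(record)
            except UndefinedActiveErrorRate:
                a = np.nan
            rows.append(
                {
                    "subject_id": plan.subject_id,
                    "framework": framework,
                    "train_conditions": "|".join(map(str, plan.train_conditions)),
                    "test_conditions": "|".join(map(str, plan.test_conditions)),
                    "n_train_conditions": len(plan.train_conditions),
                    "held_out_trial": plan.held_out_trial,
                    "accuracy": 100.0 - t,
                    "ter": t,
                    "aer": a,
                }
            )
    return EvalResult(rows=pd.DataFrame(rows))


def tune_hyperparameters(
    spec: ClassifierSpec,
    tuning_features: FeatureMatrix,
    *,
    no_motion_class="no_motion",
) -> ClassifierSpec:
    """Grid-search the classifier hyperparameters on a held-aside tuning
    subject, scoring by intra-framework mean accuracy; the returned spec
    records the tuning subjects so they cannot leak into evaluation."""
    grid = spec.hyperparameter_grid or {}
    names = sorted(grid)
    candidates = [dict(zip(names, combo)) for combo in itertools.product(*(grid[n] for n in names))] or [{}]
    best_spec, best_acc = None, -np.inf
    for cand in candidates:
        trial_spec = replace(spec, **cand)
        result = run_experiment(tuning_features, "intra", trial_spec,
                                no_motion_class=no_motion_class)
        acc = result.mean_accuracy()
        if acc > best_acc:
            best_acc, best_spec = acc, trial_spec
    tuned_on = tuple(sorted(set(np.unique(tuning_features.subject_id).tolist())))
    return replace(best_spec, tuning_subjects=tuned_on)
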