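#!/usr/bin/env python
"""Evaluate the four cross-validation frameworks on both studies.

For each feature set (TD, LSF4) and the LDA classifier this runs intra
(x vs x), inter (x vs y) and single-vs-all (x vs all) with leave-one-trial-out
folds within each subject, plus the multi-vs-all (N vs all) training-set-size
sweep for the position study.  Per-split rows go to scratch/, and the tidy
summary tables to results/.
"""

import json
from pathlib import Path

import pandas as pd

from emgconfounds import ClassifierSpec, run_experiment
from emgconfounds import io as eio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SETS = ("TD", "LSF4")
FRAMEWORKS = ("intra", "single_vs_all", "inter")
SEED = 1


def main():
    RESULTS.mkdir(exist_ok=True)
    summary_rows = []
    sweep_rows = []
    for study in ("position", "intensity"):
        for set_name in SETS:
            fm = eio.load_features_csv(SCRATCH / study / "features" / f"{set_name}.csv")
            spec = ClassifierSpec("lda", seed=SEED)
            for fw in FRAMEWORKS:
                res = run_experiment(fm, fw, spec, seed=SEED)
                res.rows.to_csv(SCRATCH / study / f"rows_{set_name}_lda_{fw}.csv",
                                index=False)
                s = res.summary()
                summary_rows.append({
                    "study": study, "feature_set": set_name, "classifier": "lda",
                    "framework": fw, "subject_avg_accuracy": round(res.mean_accuracy(), 2),
                    "mean": round(s["mean"], 2), "sd": round(s["sd"], 2),
                    "min": round(s["min"], 2), "max": round(s["max"], 2),
                    "n_splits": s["n_splits"],
                })
                print(f"{study}/{set_name}/lda/{fw}: "
                      f"{s['mean']:.1f} ± {s['sd']:.1f} ({s['min']:.1f}, {s['max']:.1f})")
        # training-set-size sweep (N vs all) on the TD set
        fm = eio.load_features_csv(SCRATCH / study / "features" / "TD.csv")
        n_conditions = len(set(fm.condition_value))
        for k in range(1, n_conditions + 1):
            res = run_experiment(fm, "multi_vs_all", ClassifierSpec("lda", seed=SEED),
                                 n_train=k, max_train_sets=15, seed=SEED)
            sweep_rows.append({
                "study": study, "n_train_conditions": k,
                "subject_avg_accuracy": round(res.mean_accuracy(), 2),
                "n_splits": len(res.rows),
            })
            print(f"{study}/TD/lda/multi_vs_all n_train={k}: "
                  f"{sweep_rows[-1]['subject_avg_accuracy']:.2f}%")

    pd.DataFrame(summary_rows).to_csv(RESULTS / "framework_summary.csv", index=False)
    pd.DataFrame(sweep_rows).to_csv(RESULTS / "multi_vs_all_sweep.csv", index=False)
    print(f"wrote {RESULTS / 'framework_summary.csv'} and {RESULTS / 'multi_vs_all_sweep.csv'}")


if __name__ == "__main__":
    main()
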