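#!/usr/bin/env python
"""Extract the TD and LSF4 feature sets from both window stacks.

TD (MAV, ZC, SSC, WL) is the classical low-cost baseline; LSF4 (LS, MFL, MSR,
WAMP) targets low-sampling-rate robustness.  Feature tables land as CSV under
scratch/analysis/<study>/features/.
"""

from pathlib import Path

from emgconfounds import extract_set
from emgconfounds import io as eio

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
SETS = ("TD", "LSF4")


def main():
    for name in ("position", "intensity"):
        windows = eio.load_windows_hdf5(SCRATCH / name / "windows.h5")
        for set_name in SETS:
            fm = extract_set(windows, set_name)
            path = SCRATCH / name / "features" / f"{set_name}.csv"
            eio.save_features_csv(fm, path)
            print(f"{name}/{set_name}: {fm.values.shape[0]} windows x "
                  f"{fm.values.shape[1]} features -> {path}")


if __name__ == "__main__":
    main()
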