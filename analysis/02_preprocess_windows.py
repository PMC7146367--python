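#!/usr/bin/env python
"""Condition and segment both datasets.

Applies the standard chain — 50 Hz notch, 20–450 Hz band-pass, (no
downsampling needed at 1000 Hz), 150 ms windows with 50 ms increments — and
stores the window stacks as HDF5 under scratch/analysis/.
"""

from pathlib import Path

from emgconfounds import io as eio
from emgconfounds.preprocess import preprocess_chain

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"


def main():
    for name in ("position", "intensity"):
        recs = eio.load_dataset(SCRATCH / name / "dataset")
        windows = preprocess_chain(recs, window_ms=150.0, increment_ms=50.0)
        path = SCRATCH / name / "windows.h5"
        eio.save_windows_hdf5(windows, path)
        print(f"{name}: {len(recs)} recordings -> {windows.n_windows} windows "
              f"({windows.n_channels} channels x {windows.windows.shape[2]} samples) -> {path}")


if __name__ == "__main__":
    main()
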