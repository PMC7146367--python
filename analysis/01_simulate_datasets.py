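#!/usr/bin/env python
"""Generate the two synthetic confound datasets.

Position study: D1-shaped (8 channels, 8 motions, 10 reps, 5 limb positions,
1000 Hz).  Intensity study: D4-shaped (8 channels, 7 motions, 4 reps, 7 MVC
levels 20%..80% in 10% steps, 1000 Hz).  Both use 2 subjects and 1 s trials.
Raw recordings land under scratch/analysis/ (CSV + JSON sidecars).
"""

from pathlib import Path

from emgconfounds import generate_dataset
from emgconfounds import io as eio
from emgconfounds.synth import d1_like_config, d4_like_config

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
SEED = 1


def main():
    for name, cfg in (
        ("position", d1_like_config(n_subjects=2, seed=SEED)),
        ("intensity", d4_like_config(n_subjects=2, seed=SEED + 1)),
    ):
        recs = generate_dataset(cfg)
        out = SCRATCH / name / "dataset"
        eio.save_dataset(recs, out)
        print(
            f"{name}: {len(recs)} recordings "
            f"({cfg.n_subjects} subjects x {len(cfg.conditions)} conditions x "
            f"{len(cfg.motion_classes)} motions x {cfg.reps_per_condition} reps) -> {out}"
        )


if __name__ == "__main__":
    main()
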