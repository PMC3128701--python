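#!/usr/bin/env python
"""Sensitivity and specificity of the mapping on planted-deficit cohorts.

Fifty seeded cohorts carry the study-anchored effect (carriers average
~48 s between presses vs ~33 s in controls).  For each, the mapping runs
on the deficit measure and on a matched null measure; the summary reports
the detection rate (significant voxels inside the planted region), stray
flags outside the planted region / carrier lesions, and the Jaccard
overlap between significant voxels and the coverable part of the planted
region.  Writes results/recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from anacom.experiments import planted_recovery

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    s = planted_recovery(n_replicates=50, base_seed=seed)
    print(f"detection: {s.n_detected}/{s.n_replicates} "
          f"({100 * s.detection_rate:.0f}%)")
    print(f"significant voxels outside planted+carriers: "
          f"{s.n_outside_effect} (effect map), {s.n_outside_null} (null map)")
    print(f"median Jaccard with coverable planted region: "
          f"{np.median(s.jaccard):.2f}")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "replicate": range(s.n_replicates),
        "jaccard": s.jaccard,
    }).to_csv(OUT / "recovery.csv", index=False)
    summary = pd.DataFrame([{
        "n_replicates": s.n_replicates, "n_detected": s.n_detected,
        "detection_rate": s.detection_rate,
        "outside_effect": s.n_outside_effect,
        "outside_null": s.n_outside_null,
    }])
    summary.to_csv(OUT / "recovery_summary.csv", index=False)


if __name__ == "__main__":
    main()
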