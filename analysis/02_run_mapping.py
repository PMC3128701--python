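#!/usr/bin/env python
"""Run the lesion-symptom mapping on the simulated cohort.

Consumes results/cohort/ (run 01_simulate_cohort.py first), maps every
behavioural measure, and writes p-maps, significance maps and region
reports under results/mapping/.  Expected outcome: the time-based
inter-press measures flag subregions at the planted right-frontopolar
site; the unshifted TE1 measure flags nothing.
"""

import json
from pathlib import Path

from anacom.core import run_anacom
from anacom.imaging import read_masks_dir, write_stat_map
from anacom.reports import regions_to_frame, write_region_report
from anacom.subjects import measure_columns, read_subject_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = ROOT / "cohort"
    out = ROOT / "mapping"
    out.mkdir(parents=True, exist_ok=True)
    masks = read_masks_dir(cohort / "masks")
    subjects = read_subject_table(cohort / "subjects.csv")
    truth = json.loads((cohort / "ground_truth.json").read_text())
    planted = {tuple(v) for v in truth["planted_region_voxels"]}

    for measure in measure_columns(subjects):
        result = run_anacom(masks, subjects, measure)
        write_stat_map(result.stat_map, out / f"{measure}_p.nii")
        write_region_report(result, out / f"regions_{measure}.csv",
                            out / f"regions_{measure}.json")
        frame = regions_to_frame(result)
        in_planted = sum(
            any(tuple(v) in planted for v in r.subregion.voxels)
            for r in result.tested if r.significant_after_holm)
        print(f"{measure}: {len(frame)} significant subregion(s) "
              f"(H={result.holm.H:.2e}), {in_planted} overlapping the "
              f"planted region")
        if len(frame):
            print(frame.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
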