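# anacom

Voxel-based lesion-symptom mapping in which patients lesioned in a brain
subregion are compared to **healthy controls**, together with the
behavioural scoring of a prospective-memory task battery and a synthetic
lesion-cohort generator with known ground truth.

## Who this is for

Lesion-study researchers who have per-patient binary lesion masks
normalised to a common template (MNI space, NIfTI-1) and per-subject
behavioural scores, and who want to ask: *damage to which voxels is
associated with a deficit on this measure?* Classic voxel-based
lesion-symptom mapping splits patients into lesioned vs spared at each
voxel; the procedure implemented here instead tests each group of
identically-covered voxels against a healthy control sample, so a region
is testable with as few as three lesioned patients.

## The procedure

Per behavioural measure:

1. superimpose the binary masks into an **overlap map** (per-voxel lesion
   count);
2. group covered voxels into **coverage-pattern subregions** — maximal
   voxel sets lesioned in exactly the same patients — and keep those with
   ≥ 3 covering lesions;
3. test each subregion's patients against the controls with a two-sided
   **Wilcoxon rank-sum** test (exact for small tie-free samples,
   tie-corrected normal approximation otherwise);
4. correct the family of subregion p-values of the map with the
   **Bonferroni–Holm** step-down procedure at α = 0.05;
5. write a per-voxel p-map, a significance map, and a region report with
   MNI centroid coordinates, raw p, the effective Holm threshold *H*,
   patient count and size.

The scoring side turns timestamped trial streams into the analysed
measures: ongoing-task accuracy and RT, event-based prospective-memory
accuracy (15 targets on a fixed schedule embedded in 242 ongoing trials),
the time-based mean inter-press interval (instructed interval 30 s),
press-count ratio and stopwatch checks, and the two time-estimation totals
(ideal 100 s). See `docs/methods.md` for definitions and conventions.

## Worked example

Simulate a study-scale cohort (45 patients, 107 controls, a planted
right-frontopolar deficit region whose carriers average ≈ 48 s between
presses vs ≈ 33 s in controls) and map every measure:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_run_mapping.py
```

which prints, for the time-based picture measure:

```
tb_pictures_interpress_s: 6 significant subregion(s) (H=5.00e-03), 4 overlapping the planted region
label  x  y   z    p_raw     H  n_patients  size_mm3
      20 57  -1 0.000508 0.005           6    1208.0
      20 56  -4 0.000930 0.005           5    1544.0
      24 55 -14 0.001597 0.005           4     232.0
...
te1_total_s: 0 significant subregion(s) (H=3.13e-03), 0 overlapping the planted region
```

The top subregions sit at MNI (20, 57, −1) — the planted sphere was
centred at (20, 58, 0) — each tested with 4–6 patients against the 107
controls, with raw p below the map's Holm threshold H. The measure with no
planted effect (`te1_total_s`) yields no significant subregions. The same
pipeline is available as a CLI (`anacom simulate`, `anacom run`,
`anacom demo`) for masks and subject tables of your own.

The remaining drivers exercise the pipeline's statistical properties:
`analysis/03_score_behaviour.py` (trial-stream scoring and the negative
inter-press/clock-check correlation), `analysis/04_null_calibration.py`
(family-wise error on 200 null cohorts: 0/200 with any rejection at
α = 0.05) and `analysis/05_planted_recovery.py` (detection of the planted
region in 48/50 seeded cohorts with zero stray voxels).

## Layout

```
src/anacom/        the library: imaging I/O, stats kernel, mapping core,
                   trial-stream scoring, cohort simulation, CLI
analysis/          numbered narrative drivers writing tables to results/
tests/             pytest suite incl. enumeration/brute-force oracles
scripts/           acceptance script
docs/methods.md    models, conventions, parameter choices, limitations
```
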