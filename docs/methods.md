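# Methods

## The mapping procedure

The package implements a voxelwise lesion-symptom mapping in which patients
are compared to **healthy controls** rather than to spared patients. Inputs
are per-patient binary lesion masks drawn on one shared standard-space grid
(MNI-template space; the grid is described by the array shape and a 4×4
affine from 0-based voxel indices to millimetre coordinates) and a subject
table with one behavioural score column per measure.

Per measure, the chain is:

1. **Overlap map.** The binary masks are superimposed; each voxel carries
   the number of lesions covering it.
2. **Coverage-pattern subregions.** Voxels are grouped by the *exact set*
   of patients whose lesion covers them. A subregion is a maximal set of
   voxels sharing one coverage pattern; spatially disconnected voxels with
   the same pattern form a single subregion (the definition is purely by
   coverage; a 26-connected splitter is available for reporting). Only
   subregions covered by at least `min_overlap` lesions (default 3) are
   tested.
3. **Subregion test.** The scores of the subregion's patients are compared
   to the control scores with a two-sided Wilcoxon rank-sum test. Patients
   lacking the measure are excluded (logged); a subregion left with fewer
   than `min_overlap` scored patients is skipped, not silently tested.
   An optional `deficit_direction` switches to a one-sided test; the
   default is two-sided.
4. **Holm correction.** The raw p-values of all tested subregions of one
   map form the family for the Bonferroni–Holm step-down procedure at
   `alpha` (default 0.05). Families are never pooled across measures. The
   report carries `H`, the critical value α/(m−k+1) at the first
   non-rejected rank k — the cutoff a raw p had to fall below when the
   procedure stopped (α itself when everything is rejected) — and, because
   the “threshold” of a step-down procedure is ambiguous, also the largest
   rejected raw p.
5. **Outputs.** A per-voxel p-map (each voxel inherits its subregion's raw
   p; untested voxels are NaN in memory and a documented −1 sentinel on
   disk), a binary significance map, and a region report: one row per
   significant subregion with the voxel-count centroid mapped through the
   affine to integer MNI mm, raw p, patient count and size in mm³. The
   centroid (rather than a peak) is reported because the subregion has one
   p-value everywhere; coordinates use neurological orientation via the
   affine.

A *region-vs-rest* contrast supplements the map: patients whose lesion
shares any voxel with a given region are compared to all other patients
(rank-sum per continuous measure, Pearson chi-square for categorical
covariates, Wilcoxon signed-rank for paired within-group measure pairs).

Score-weighted lesion volumes (every lesioned voxel set to the patient's
score) are supported as an I/O and visualisation representation; the
statistics consume raw score lists directly, which is numerically
equivalent.

Grids are compared by dims and affine (tolerance 1e-4) and mismatches are
rejected, never resampled: masks are expected to be pre-normalised to one
template, so a mismatch signals an upstream error.

## Statistical kernel

- **Rank-sum.** Exact null distribution when the pooled sample is tie-free
  and ≤ 12 (two-sided p = twice the smaller tail, capped at 1); otherwise
  the normal approximation with mid-rank ties, tie-corrected variance and
  continuity correction (on by default, toggleable). The reported `z` is
  always the tie-corrected normal deviate of min(U₁, U₂), so exact and
  approximate results are comparable across a map; both U's are exposed
  because reporting conventions differ. Verified behaviour: exact p equals
  complete enumeration on every tie-free sample with pooled n ≤ 10; in the
  decision-relevant region (exact p ≤ 0.25, groups ≥ 3) the approximation
  is within 0.02 of exact; with continuity correction the p-value is
  conservative, never meaningfully anticonservative. For groups of 1–2 the
  normal approximation is poor (discrepancies up to ~0.13) — irrelevant to
  the mapping, whose minimum tested group is 3.
- **Signed-rank.** Zero differences dropped; exact sign-flip distribution
  for tie-free difference sets ≤ 12, else normal approximation; z is the
  tie-corrected deviate without continuity correction.
- **Chi-square.** Pearson statistic without Yates correction,
  (r−1)(k−1) df; a zero marginal is an error.
- **Spearman.** Mid-rank rho; a constant input yields a missing result
  rather than an arbitrary number.

Holm's step-down uses ≤ comparisons; rejection sets were checked against an
independent brute-force implementation and against
`statsmodels.multipletests` on random p-vectors, and always sit between
Bonferroni's and the unadjusted rule's.

## Behavioural scoring

The battery's core is a two-alternative forced-choice **ongoing task**
(left/right key toward the shorter word or lighter object, self-paced,
3 s cap) with a prospective-memory load added in a later phase.

- **Ongoing blocks**: accuracy (% of analysed trials answered on the
  correct side; a timed-out trial counts as incorrect) and mean RT over
  correct trials. The first 10 trials of a 30-trial block are warm-up and
  discarded, leaving 20 analysed trials.
- **Event-based PM**: 15 target trials embedded in 242 ongoing trials with
  the fixed inter-target schedule (30 24 22 16 14 8 6 2 4 10 12 18 20 26
  28) plus two terminal trials; excluding those terminal trials the target
  rate is 15/255 = 5.9%. A target is credited if a spacebar press falls
  between its onset and the end of the *following* trial — participants
  are explicitly told to respond even when late, and one following trial
  is the narrowest window consistent with the cue having already
  disappeared. PM accuracy is the percentage of credited targets; PM RT is
  press time minus target onset.
- **Time-based PM**: the mean of successive spacebar inter-press intervals
  (instructed interval 30 s), reported missing — never zero — when fewer
  than two presses exist; the press-count ratio 100 × presses /
  ⌊duration / 30 s⌋ (the floor is our choice; no rounding rule is
  standard); and the count of stopwatch-box openings (`clock_open`
  events; closings are retained but unused).
- **Time estimation (TE1/TE2)**: four trials of silent continuation of a
  paced count (TE1: 1 s rhythm, counting on to 20/30/40/50; TE2: 2 s
  rhythm, to 15/20/25/30). Trial duration is press time minus the onset of
  the last paced numeral; the global score sums the four trials, ideal
  100 s in both variants. The real task paces with 100 ms numerals plus an
  inter-stimulus gap; generator and scorer use the idealised numeral
  period (1 s / 2 s), which reproduces the ideal totals exactly and keeps
  the scorer's pacing reference well defined. A trial without a press
  scores missing and marks the total as partial.

Undefined measures propagate as missing values into the subject table,
never as zeros.

## Synthetic cohorts

The generator emulates the cohort the pipeline targets: 45 patients and
107 controls at full scale, lesion volumes log-uniform over 1–100 cm³ on a
79×95×79 grid at 2 mm (an MNI-like bounding box; 2 mm rather than 1 mm
keeps full-scale runs at desk speed), a planted right-frontopolar sphere,
and score anchors taken from the time-based task: controls 32.934 ± 9.6 s
(pictures) / 30.147 ± 6.4 s (words) between presses, deficit carriers
48.084 ± 5.1 s / 47.802 ± 6.0 s, plus a TE2 deficit (65.1 vs 85.9 s
against a 89.1 ± 22.9 control distribution).

Lesions are unions of 1–3 axis-aligned random ellipsoids with mild
anisotropy, satellites hugging the first ellipsoid. A patient *carries*
the planted deficit when their lesion overlaps the planted region by at
least the carrier rule's threshold (default any voxel; the desk-scale
recovery condition uses ≥ 3 voxels). To guarantee a deficit group,
`guaranteed_carriers` lesions (default 8 at desk scale — the size of a
focal deficit group in a cohort like this) are centred on the planted
region, mirroring the fact that real deficit carriers have lesions
covering the region substantially, not grazing it. Scores are
truncated-normal (non-negative); carriers draw from the shifted
distribution. A single seed fans out to per-subject substreams
(`default_rng([seed, group, index])`), so cohorts are bit-reproducible and
stable under subject-count changes.

Trial-stream generation follows the printed schedules exactly (event-PM
targets), presses at Normal(30 + bias, jitter) intervals (time-based), and
pace × ideal counting rhythms (TE), with lognormal ongoing RTs capped at
3 s.

**What the generator does not emulate**: vascular-territory or tumour
lesion geometry, spatial normalisation error, registration artifacts,
score distributions with floor/ceiling effects or skew, and correlations
between measures within subject. Passing recovery tests therefore show
that the machinery is correct and well calibrated under clean conditions,
not that the procedure is robust to real-data pathologies.

## Simulation experiments and problem sizes

- **Null calibration**: 200 cohorts of 30 patients / 50 controls on a 20³
  grid, all scores iid; the fraction of cohorts with any Holm-significant
  subregion is the empirical family-wise error rate. Holm guarantees
  ≤ α under any dependence; in practice the rate is far below 0.05
  because overlapping subregions are heavily positively correlated and
  the smallest achievable p is bounded for 3-patient groups (measured:
  0/200 at both `min_overlap` 3 and 5).
- **Planted recovery**: 50 cohorts at the same scale with the
  study-anchored effect (≈ 15 s shift against sd 9.6). Measured: 48/50
  replicates flag the planted region; zero significant voxels outside the
  planted region ∪ carrier lesions, on the effect measure and on a
  matched null measure.

These sizes were chosen so each experiment completes in tens of seconds
on one CPU while leaving the binomial margins meaningful.

## Numerical choices and edge cases

- Voxel indices are 0-based; all mm coordinates are produced only through
  the affine; round-tripping index→mm→index is identity to 1e-6.
- Binarisation accepts {0, v>0} volumes and rejects anything with more
  than two distinct values; binarisation is idempotent.
- Written p-maps store float64 and round-trip bit-exact; the untested
  sentinel (−1.0) is outside (0, 1] and is documented in the NIfTI header
  description field.
- An empty Holm family returns H = α and no rejections; an all-zero
  difference vector yields the degenerate signed-rank p = 1.
- Two-sided p-values are capped at 1.
- Subregion order is stabilised (descending patient count, then pattern)
  so reports are deterministic; rerunning the CLI with the same config
  yields byte-identical reports.

## Known limitations

- No atlas labelling: report rows carry an empty `label` field as an
  anatomical lookup hook.
- No resampling of mismatched grids, no non-binary lesion probability
  maps, and no covariate-adjusted models.
- The mean inter-press interval cannot distinguish regular from irregular
  pressing (intervals {45, 15} s average 30 s); the press-count ratio
  partially compensates.
- Whether a real cohort's Holm threshold should be read as the stopping
  critical value or the largest rejected p is convention-dependent; both
  are reported.
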