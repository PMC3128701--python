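"""Synthetic lesion-and-behaviour cohorts with known ground truth.

The generator emulates the study conditions the pipeline was built for:
45 patients with focal lesions (volumes spanning roughly 0.8-465 cm^3) and
107 healthy controls, behavioural scores per measure, and optionally a
*planted* deficit region — patients whose lesion overlaps it ("carriers")
draw their scores from a shifted distribution.  The default time-based
inter-press anchors are control mean 32.9 s (sd 9.6) and carrier mean
48.1 s (sd 5.1), i.e. a roughly 15 s deficit.

Lesions are unions of 1-3 randomised axis-aligned ellipsoids: crude
geometry, but enough to produce realistic overlap topology for testing the
coverage-pattern machinery.  A single global seed fans out to per-subject
substreams, so cohorts are reproducible and stable under subject-count
changes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .imaging import LesionMask, VolumeGrid, mni_grid
from .scoring import (EVENT_PM_SCHEDULE, EVENT_PM_TERMINAL_OG,
                      OG_RESPONSE_CAP_MS, TE_DESIGNS, TE_PACED_COUNT,
                      TrialStream)


@dataclass(frozen=True)
class EffectModel:
    """Score distribution for one measure: controls and deficit carriers."""

    control_mean: float
    control_sd: float
    carrier_shift: float = 0.0
    carrier_sd: float | None = None  # defaults to control_sd
    lower: float = 0.0  # truncation bound (scores are times/accuracies >= 0)

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise SpecError("control_sd must be positive")


@dataclass(frozen=True)
class LesionModel:
    """Randomised-ellipsoid lesion geometry."""

    max_ellipsoids: int = 3
    volume_range_cm3: tuple[float, float] = (1.0, 100.0)  # log-uniform
    anisotropy: float = 0.35  # per-axis log stretch of the semi-axes
    margin_voxels: int = 2  # keep ellipsoid centres off the grid edge


@dataclass(frozen=True)
class CarrierRule:
    """When does a lesion carry the planted deficit."""

    min_voxels: int = 1  # overlap with the planted region, in voxels
    min_fraction: float = 0.0  # of the planted region's size


@dataclass
class CohortSpec:
    n_patients: int = 45
    n_controls: int = 107
    grid: VolumeGrid = field(default_factory=mni_grid)
    lesion_model: LesionModel = field(default_factory=LesionModel)
    planted_region: np.ndarray | None = None  # (k, 3) voxel indices
    effect_model: dict[str, EffectModel] = field(default_factory=dict)
    carrier_rule: CarrierRule = field(default_factory=CarrierRule)
    guaranteed_carriers: int = 0  # seed this many lesions inside the region
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise SpecError("cohort needs at least 1 patient and 1 control")
        has_effect = any(e.carrier_shift != 0 for e in self.effect_model.values())
        empty = self.planted_region is None or len(self.planted_region) == 0
        if has_effect and empty:
            raise SpecError("nonzero carrier_shift requires a planted_region")
        if not empty:
            pr = np.asarray(self.planted_region, dtype=int)
            if np.any(pr < 0) or np.any(pr >= np.array(self.grid.dims)):
                raise SpecError("planted_region voxels outside the grid")
            self.planted_region = pr


@dataclass
class GroundTruth:
    carrier_ids: frozenset[str]
    planted_region: np.ndarray | None
    true_effects: dict[str, float]


def sphere_region(grid: VolumeGrid, center_mni, radius_mm: float) -> np.ndarray:
    """Voxel indices within ``radius_mm`` of an MNI-mm centre point."""
    center_vox = grid.mm_to_voxel(np.asarray(center_mni, dtype=float))
    idx = np.indices(grid.dims).reshape(3, -1).T
    mm = grid.voxel_to_mm(idx)
    keep = np.linalg.norm(mm - np.asarray(center_mni, float), axis=1) <= radius_mm
    return idx[keep]


def _ellipsoid_voxels(dims, center, semi_axes) -> np.ndarray | None:
    """Boolean volume of an axis-aligned ellipsoid, clipped to the grid."""
    lo = np.maximum(np.floor(center - semi_axes).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi_axes).astype(int) + 1, dims)
    if np.any(lo >= hi):
        return None
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    dist = sum(((g - c) / max(a, 0.5)) ** 2
               for g, c, a in zip(grids, center, semi_axes))
    inside = dist <= 1.0
    vol = np.zeros(dims, dtype=bool)
    vol[tuple(np.array(g[inside]) for g in grids)] = True
    return vol


def _random_lesion(rng: np.random.Generator, grid: VolumeGrid,
                   model: LesionModel,
                   force_center_vox: np.ndarray | None = None) -> np.ndarray:
    """One patient's lesion as a boolean volume."""
    dims = np.array(grid.dims)
    vx = np.array(grid.voxel_size_mm)
    lo_v, hi_v = model.volume_range_cm3
    total_mm3 = 1000.0 * math.exp(rng.uniform(math.log(lo_v), math.log(hi_v)))
    n_ell = int(rng.integers(1, model.max_ellipsoids + 1))
    shares = rng.dirichlet(np.ones(n_ell))
    data = np.zeros(grid.dims, dtype=bool)
    margin = model.margin_voxels
    first_center = None
    for k in range(n_ell):
        r_mm = (3.0 * shares[k] * total_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        stretch = np.exp(rng.uniform(-model.anisotropy, model.anisotropy, 3))
        semi_vox = np.maximum(r_mm * stretch / vx, 1.0)
        if k == 0:
            if force_center_vox is not None:
                center = np.asarray(force_center_vox, dtype=float)
            else:
                center = np.array([
                    rng.uniform(margin, max(d - margin, margin + 1))
                    for d in dims
                ])
            first_center = center
        else:
            # satellites hug the first ellipsoid so the lesion stays compact
            center = first_center + rng.normal(0.0, semi_vox)
        vol = _ellipsoid_voxels(tuple(dims), center, semi_vox)
        if vol is not None:
            data |= vol
    if not data.any():  # degenerate clip: keep at least the centre voxel
        c = np.clip(np.round(first_center).astype(int), 0, dims - 1)
        data[tuple(c)] = True
    return data


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int | None = None):
    """Normal draw(s) truncated below at ``lower`` by redrawing."""
    n = 1 if size is None else size
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    out = np.maximum(out, lower)
    return float(out[0]) if size is None else out


def _subject_rng(seed: int, group_tag: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), group_tag, index])


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[LesionMask], pd.DataFrame, GroundTruth]:
    """Draw lesion masks, a subject table and the ground truth.

    Control scores are truncated-normal per measure; carrier patients'
    scores are shifted by the measure's ``carrier_shift``; non-carriers are
    drawn from the control distribution.  Carriers are the patients whose
    lesion overlaps the planted region by at least the carrier rule's
    threshold.
    """
    measures = sorted(spec.effect_model)
    planted_vol = None
    if spec.planted_region is not None and len(spec.planted_region):
        planted_vol = np.zeros(spec.grid.dims, dtype=bool)
        planted_vol[tuple(spec.planted_region.T)] = True

    masks: list[LesionMask] = []
    carrier_ids: list[str] = []
    rows = []
    threshold = 1
    if planted_vol is not None:
        threshold = max(spec.carrier_rule.min_voxels,
                        math.ceil(spec.carrier_rule.min_fraction
                                  * len(spec.planted_region)))
    for i in range(spec.n_patients):
        rng = _subject_rng(spec.seed, 0, i)
        sid = f"p{i:03d}"
        force = None
        if planted_vol is not None and i < spec.guaranteed_carriers:
            # seeded lesions are centred on the planted region (small jitter)
            # so they damage it substantially, as deficit-carrying lesions do
            force = (spec.planted_region.mean(axis=0)
                     + rng.uniform(-1.0, 1.0, 3))
        data = _random_lesion(rng, spec.grid, spec.lesion_model,
                              force_center_vox=force)
        mask = LesionMask(subject_id=sid, grid=spec.grid, data=data)
        masks.append(mask)
        is_carrier = bool(
            planted_vol is not None
            and int((data & planted_vol).sum()) >= threshold
        )
        if is_carrier:
            carrier_ids.append(sid)
        row = {"subject_id": sid, "group": "patient"}
        for m in measures:
            eff = spec.effect_model[m]
            if is_carrier and eff.carrier_shift != 0:
                sd = eff.carrier_sd if eff.carrier_sd is not None else eff.control_sd
                row[m] = _truncated_normal(
                    rng, eff.control_mean + eff.carrier_shift, sd, eff.lower)
            else:
                row[m] = _truncated_normal(
                    rng, eff.control_mean, eff.control_sd, eff.lower)
        rows.append(row)

    for i in range(spec.n_controls):
        rng = _subject_rng(spec.seed, 1, i)
        row = {"subject_id": f"c{i:03d}", "group": "control"}
        for m in measures:
            eff = spec.effect_model[m]
            row[m] = _truncated_normal(rng, eff.control_mean, eff.control_sd,
                                       eff.lower)
        rows.append(row)

    subjects = pd.DataFrame(rows)
    truth = GroundTruth(
        carrier_ids=frozenset(carrier_ids),
        planted_region=spec.planted_region,
        true_effects={m: spec.effect_model[m].carrier_shift for m in measures},
    )
    return masks, subjects, truth


# ---------------------------------------------------------------------------
# Ready-made cohort specifications


#: Anchors for the time-based inter-press interval (seconds): control
#: mean/sd for pictures and words, and the carrier (deficit) mean/sd.
TIME_BASED_ANCHORS = {
    "tb_pictures_interpress_s": dict(control_mean=32.934, control_sd=9.6,
                                     carrier_mean=48.084, carrier_sd=5.1),
    "tb_words_interpress_s": dict(control_mean=30.147, control_sd=6.4,
                                  carrier_mean=47.802, carrier_sd=6.0),
}


def study_scale_spec(seed: int = 0) -> CohortSpec:
    """The full-scale study-like cohort: 45 patients, 107 controls.

    2 mm MNI-like grid (downscaled from 1 mm for desk speed), lesion volumes
    log-uniform over 1-100 cm^3, a planted right-frontopolar sphere, and the
    time-based inter-press deficit anchors above plus an (unshifted) TE1 and
    a shifted TE2 measure.
    """
    grid = mni_grid()
    planted = sphere_region(grid, center_mni=(20.0, 58.0, 0.0), radius_mm=8.0)
    effects = {
        name: EffectModel(
            control_mean=a["control_mean"], control_sd=a["control_sd"],
            carrier_shift=a["carrier_mean"] - a["control_mean"],
            carrier_sd=a["carrier_sd"],
        )
        for name, a in TIME_BASED_ANCHORS.items()
    }
    effects["te1_total_s"] = EffectModel(control_mean=96.2, control_sd=17.1)
    effects["te2_total_s"] = EffectModel(control_mean=89.1, control_sd=22.9,
                                         carrier_shift=65.137 - 85.914,
                                         carrier_sd=21.8)
    return CohortSpec(
        n_patients=45, n_controls=107, grid=grid, planted_region=planted,
        effect_model=effects, guaranteed_carriers=6,
        carrier_rule=CarrierRule(min_voxels=3), seed=seed,
    )


def _small_grid(dims: int = 20, voxel_mm: float = 2.0) -> VolumeGrid:
    return mni_grid(dims=(dims, dims, dims), voxel_mm=voxel_mm)


#: Lesion geometry for small test grids (20^3 at 2 mm): volumes scaled so a
#: lesion spans a realistic fraction of the grid, as the study's lesions
#: (up to 465 cm^3) did of the brain.
SMALL_LESION_MODEL = LesionModel(volume_range_cm3=(0.5, 8.0))


def null_cohort_spec(seed: int, n_patients: int = 30, n_controls: int = 50,
                     grid_dims: int = 20) -> CohortSpec:
    """A no-effect cohort: all scores iid from one control distribution."""
    return CohortSpec(
        n_patients=n_patients, n_controls=n_controls,
        grid=_small_grid(grid_dims), lesion_model=SMALL_LESION_MODEL,
        planted_region=None,
        effect_model={"score": EffectModel(control_mean=32.934,
                                           control_sd=9.6)},
        seed=seed,
    )


def recovery_cohort_spec(seed: int, n_patients: int = 30,
                         n_controls: int = 50, grid_dims: int = 20,
                         guaranteed_carriers: int = 8) -> CohortSpec:
    """A planted-deficit cohort at desk scale.

    The deficit measure uses the time-based picture anchors (carriers mean
    48.1 s vs controls 32.9 s, control sd 9.6); a matched ``null_score``
    measure with the same control distribution and no shift rides along.
    Carriers must overlap the planted central sphere by >= 3 voxels, and
    ``guaranteed_carriers`` lesions (default 8, the size of a deficit group
    in a cohort of this kind) are seeded centred on it.
    """
    grid = _small_grid(grid_dims)
    center = grid.voxel_to_mm(np.array(grid.dims) / 2.0)
    planted = sphere_region(grid, center_mni=center, radius_mm=6.0)
    a = TIME_BASED_ANCHORS["tb_pictures_interpress_s"]
    return CohortSpec(
        n_patients=n_patients, n_controls=n_controls, grid=grid,
        lesion_model=SMALL_LESION_MODEL, planted_region=planted,
        effect_model={
            "tb_interpress_s": EffectModel(
                control_mean=a["control_mean"], control_sd=a["control_sd"],
                carrier_shift=a["carrier_mean"] - a["control_mean"],
                carrier_sd=a["carrier_sd"]),
            "null_score": EffectModel(control_mean=a["control_mean"],
                                      control_sd=a["control_sd"]),
        },
        carrier_rule=CarrierRule(min_voxels=3),
        guaranteed_carriers=guaranteed_carriers, seed=seed,
    )


# ---------------------------------------------------------------------------
# Trial-stream generation


@dataclass(frozen=True)
class PerformanceProfile:
    """Parameters of a simulated performer."""

    og_accuracy: float = 0.95
    og_mean_rt_ms: float = 900.0
    og_rt_sigma: float = 0.3  # lognormal shape
    iti_ms: float = 300.0
    pm_hit_rate: float = 0.93  # event-based target crediting probability
    pm_late_rate: float = 0.1  # credited presses landing in the next trial
    press_bias_s: float = 0.0  # time-based: mean interval = 30 + bias
    press_jitter_s: float = 6.0  # time-based interval sd
    clock_check_rate: float = 1.0  # stopwatch openings per press interval
    pace: float = 1.0  # time-estimation rhythm multiplier
    te_respond: bool = True


def _lognormal_rt(rng, profile: PerformanceProfile) -> float:
    mu = math.log(profile.og_mean_rt_ms) - profile.og_rt_sigma**2 / 2
    return float(rng.lognormal(mu, profile.og_rt_sigma))


def _og_trial_events(rng, profile, t: float, is_target: bool = False):
    """One ongoing trial starting at t; returns (events, t_next)."""
    side = "left" if rng.random() < 0.5 else "right"
    events = [(t, "stimulus_on", is_target, side)]
    rt = _lognormal_rt(rng, profile)
    if rt < OG_RESPONSE_CAP_MS:
        resp = side if rng.random() < profile.og_accuracy else (
            "right" if side == "left" else "left")
        events.append((t + rt, resp, False, None))
        t_next = t + rt + profile.iti_ms
    else:  # timed out: no response recorded
        t_next = t + OG_RESPONSE_CAP_MS + profile.iti_ms
    return events, t_next


def generate_trial_stream(profile: PerformanceProfile, task: str, seed: int,
                          session_id: str = "sim",
                          n_trials: int = 30,
                          session_duration_s: float = 300.0) -> TrialStream:
    """Simulate one session's event log.

    Event-based PM sessions follow the fixed printed target schedule exactly
    (15 targets, 242 ongoing trials).  Time-based sessions emit spacebar
    presses with Normal(30 + bias, jitter) intervals over
    ``session_duration_s``.  Time-estimation sessions press at
    ``pace`` x the ideal silent-count rhythm, so an error-free performer
    (pace 1) scores the ideal 100 s total.  Ongoing-style control tasks get
    ``n_trials`` two-alternative trials.
    """
    task_tag = zlib.crc32(task.encode()) % (2**31)
    rng = np.random.default_rng([int(seed), task_tag])
    events: list[tuple] = []
    t = 0.0

    if task == "PM_phase_event":
        for gap in EVENT_PM_SCHEDULE:
            for _ in range(gap):
                ev, t = _og_trial_events(rng, profile, t)
                events.extend(ev)
            target_t = t
            ev, t = _og_trial_events(rng, profile, t, is_target=True)
            events.append(ev[0])  # keep the target stimulus, drop OG response
            t = target_t + _lognormal_rt(rng, profile) + profile.iti_ms
            if rng.random() < profile.pm_hit_rate:
                if rng.random() < profile.pm_late_rate:
                    press_t = t + 0.5 * profile.og_mean_rt_ms  # next trial
                else:
                    press_t = target_t + min(_lognormal_rt(rng, profile),
                                             OG_RESPONSE_CAP_MS - 1)
                events.append((press_t, "spacebar", False, None))
        for _ in range(EVENT_PM_TERMINAL_OG):
            ev, t = _og_trial_events(rng, profile, t)
            events.extend(ev)

    elif task == "PM_phase_time":
        duration_ms = session_duration_s * 1000.0
        while t < duration_ms:
            ev, t = _og_trial_events(rng, profile, t)
            events.extend(ev)
        events = [e for e in events if e[0] < duration_ms]
        press_t = 0.0
        while True:
            interval = 30.0 + profile.press_bias_s
            if profile.press_jitter_s > 0:
                interval = max(rng.normal(interval, profile.press_jitter_s), 1.0)
            press_t = press_t + interval * 1000.0
            if press_t > duration_ms:
                break
            if profile.clock_check_rate > 0 and rng.random() < min(
                    profile.clock_check_rate, 1.0):
                open_t = max(press_t - 5000.0, 0.0)
                events.append((open_t, "clock_open", False, None))
                events.append((open_t + 1500.0, "clock_close", False, None))
            events.append((press_t, "spacebar", False, None))

    elif task in TE_DESIGNS:
        period_s, ends = TE_DESIGNS[task]
        for end_count in ends:
            for k in range(TE_PACED_COUNT):
                events.append((t + k * period_s * 1000.0, "stimulus_on",
                               False, None))
            last_numeral = t + (TE_PACED_COUNT - 1) * period_s * 1000.0
            if profile.te_respond:
                press = last_numeral + (
                    (end_count - TE_PACED_COUNT) * profile.pace
                    * period_s * 1000.0)
                events.append((press, "spacebar", False, None))
                t = press + 3000.0
            else:
                t = last_numeral + end_count * period_s * 1000.0 + 3000.0

    else:  # OGonly and ongoing-style control tasks
        for _ in range(n_trials):
            ev, t = _og_trial_events(rng, profile, t)
            events.extend(ev)

    events.sort(key=lambda e: e[0])
    frame = pd.DataFrame(events, columns=["t_ms", "kind", "is_pm_target",
                                          "correct_side"])
    return TrialStream(session_id=session_id, task=task, events=frame)
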