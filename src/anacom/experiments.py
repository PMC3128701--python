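"""Replicated simulation experiments over the full pipeline.

Two study-level properties are checked by simulation: family-wise error
control of the mapping on null cohorts, and recovery of a planted deficit
region at the study-anchored effect size.  Both run at desk scale
(30 patients / 50 controls on a 20^3 grid at 2 mm) so hundreds of
replicates complete in well under a minute each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import run_anacom
from .simulate import (generate_cohort, null_cohort_spec,
                       recovery_cohort_spec)


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds (< 2^31) fanned out from one base seed."""
    return np.random.SeedSequence(int(base_seed)).generate_state(n) % (2**31)


@dataclass
class FweSummary:
    n_replicates: int
    n_with_rejection: int

    @property
    def fraction(self) -> float:
        return self.n_with_rejection / self.n_replicates


def null_fwe_rate(n_replicates: int = 200, base_seed: int = 0,
                  n_patients: int = 30, n_controls: int = 50,
                  grid_dims: int = 20, min_overlap: int = 3,
                  alpha: float = 0.05) -> FweSummary:
    """Fraction of null cohorts with any Holm-significant subregion.

    Every cohort's scores are iid from one distribution, so any rejection
    is a family-wise error; the Holm procedure should keep the fraction at
    or below alpha.
    """
    n_hit = 0
    for seed in replicate_seeds(base_seed, n_replicates):
        spec = null_cohort_spec(seed=int(seed), n_patients=n_patients,
                                n_controls=n_controls, grid_dims=grid_dims)
        masks, subjects, _ = generate_cohort(spec)
        result = run_anacom(masks, subjects, "score",
                            min_overlap=min_overlap, alpha=alpha)
        n_hit += bool(result.holm.n_rejected)
    return FweSummary(n_replicates=n_replicates, n_with_rejection=n_hit)


@dataclass
class RecoverySummary:
    n_replicates: int
    n_detected: int  # replicates with a significant voxel inside the region
    n_outside_effect: int  # sig voxels outside planted+carriers, effect map
    n_outside_null: int  # same, on the matched no-effect measure
    jaccard: list  # per replicate: sig voxels vs coverable planted voxels

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_replicates


def planted_recovery(n_replicates: int = 50, base_seed: int = 0,
                     min_overlap: int = 3,
                     alpha: float = 0.05) -> RecoverySummary:
    """Recovery of the planted deficit region across seeded cohorts.

    For each replicate the mapping runs on the deficit measure (detection:
    any significant voxel inside the planted region; specificity: none
    outside planted region union carrier lesions) and on the matched null
    measure (no voxel outside that union may ever be flagged).
    """
    n_det = 0
    n_out_eff = 0
    n_out_null = 0
    jacc = []
    for seed in replicate_seeds(base_seed, n_replicates):
        spec = recovery_cohort_spec(seed=int(seed))
        masks, subjects, truth = generate_cohort(spec)
        planted = np.zeros(spec.grid.dims, dtype=bool)
        planted[tuple(truth.planted_region.T)] = True
        carrier_union = np.zeros_like(planted)
        for m in masks:
            if m.subject_id in truth.carrier_ids:
                carrier_union |= m.data
        allowed = planted | carrier_union

        eff = run_anacom(masks, subjects, "tb_interpress_s",
                         min_overlap=min_overlap, alpha=alpha)
        sig = eff.stat_map.significant
        n_det += bool((sig & planted).any())
        n_out_eff += int((sig & ~allowed).sum())
        coverable = planted & carrier_union
        denom = int((sig | coverable).sum())
        jacc.append(int((sig & coverable).sum()) / denom if denom else 0.0)

        null = run_anacom(masks, subjects, "null_score",
                          min_overlap=min_overlap, alpha=alpha)
        n_out_null += int((null.stat_map.significant & ~allowed).sum())
    return RecoverySummary(n_replicates=n_replicates, n_detected=n_det,
                           n_outside_effect=n_out_eff,
                           n_outside_null=n_out_null, jaccard=jacc)
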