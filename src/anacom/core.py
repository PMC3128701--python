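"""The voxelwise lesion-symptom mapping procedure.

The chain, per behavioural measure:

1. superimpose the binary lesion masks into an *overlap map* giving, per
   voxel, the number of lesions covering it;
2. group the covered voxels into *coverage-pattern subregions* — maximal
   voxel sets lesioned in exactly the same set of patients — and keep those
   covered by at least ``min_overlap`` lesions (default 3);
3. for each subregion, compare the scores of the patients whose lesion
   covers it against the healthy-control scores with a Wilcoxon rank-sum
   test;
4. correct the family of subregion p-values of that one map with the
   Bonferroni-Holm step-down procedure;
5. emit a per-voxel statistical map (each voxel inherits its subregion's
   raw p) and a region report with MNI coordinates.

Unlike the classic lesioned-vs-spared patient split, the comparison group
is always the healthy controls, so a subregion needs only a handful of
lesioned patients to be testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .errors import GridMismatchError
from .imaging import LesionMask, StatMap, VolumeGrid
from .subjects import control_scores as _control_scores
from .subjects import patient_scores as _patient_scores
from .subjects import validate_subject_table

logger = logging.getLogger("anacom")

DEFICIT_DIRECTIONS = ("two_sided", "higher_is_worse", "lower_is_worse")


@dataclass
class OverlapMap:
    """Per-voxel count of lesions covering that voxel."""

    grid: VolumeGrid
    count: np.ndarray  # int, shape == grid.dims

    @property
    def max_overlap(self) -> int:
        return int(self.count.max())


@dataclass
class Subregion:
    """Voxels lesioned in exactly the same set of patients.

    Spatially disconnected voxels sharing one coverage pattern form a single
    subregion: the definition is purely by coverage, no connectivity rule.
    """

    pattern: frozenset[str]
    voxels: np.ndarray  # (k, 3) voxel indices
    grid: VolumeGrid

    @property
    def n_patients(self) -> int:
        return len(self.pattern)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def size_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    @property
    def centroid_mni(self) -> np.ndarray:
        """Voxel-count centroid mapped through the affine to mm."""
        return self.grid.voxel_to_mm(self.voxels.mean(axis=0))


@dataclass
class SubregionResult:
    subregion: Subregion
    test: stats.TestResult
    direction: int  # sign of patient-minus-control median difference
    n_scored: int
    significant_after_holm: bool = False

    @property
    def p_raw(self) -> float:
        return self.test.p


@dataclass
class HolmResult:
    """Step-down Holm decision over one family of tests."""

    m: int
    alpha: float
    rejected: np.ndarray  # bool, in input order
    H: float  # critical value alpha/(m-k+1) at the first non-rejected rank k
    largest_rejected_p: float | None

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


@dataclass
class RegionReportRow:
    label: str
    mni_xyz: tuple[int, int, int]
    p_raw: float
    size_mm3: float
    n_patients: int


@dataclass
class AnacomResult:
    """Everything one map run produces."""

    measure: str
    stat_map: StatMap
    regions: list[RegionReportRow]
    holm: HolmResult
    tested: list[SubregionResult]
    subregions: list[Subregion]
    skipped: list[tuple[Subregion, str]]
    warnings: list[str]
    min_overlap: int
    alpha: float


def _require_shared_grid(masks: list[LesionMask]) -> VolumeGrid:
    if not masks:
        raise ValueError("need at least one lesion mask")
    grid = masks[0].grid
    for m in masks[1:]:
        grid.require_match(m.grid, context=f"mask {m.subject_id}")
    return grid


def build_overlap_map(masks: list[LesionMask]) -> OverlapMap:
    """Superimpose binary masks into a per-voxel lesion count."""
    grid = _require_shared_grid(masks)
    count = np.zeros(grid.dims, dtype=np.int32)
    for m in masks:
        count += m.data
    return OverlapMap(grid=grid, count=count)


def partition_subregions(masks: list[LesionMask],
                         min_overlap: int = 3) -> list[Subregion]:
    """Group voxels covered by >= ``min_overlap`` lesions by coverage pattern.

    Returns one :class:`Subregion` per distinct pattern, sorted by
    descending patient count then pattern id for a stable order.  The union
    of returned voxel sets is exactly the set of voxels with overlap count
    >= ``min_overlap``, and the sets are pairwise disjoint.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    grid = _require_shared_grid(masks)
    stack = np.stack([m.data for m in masks])  # (S, X, Y, Z)
    count = stack.sum(axis=0)
    covered = np.argwhere(count >= min_overlap)
    if len(covered) == 0:
        return []
    membership = stack[:, covered[:, 0], covered[:, 1], covered[:, 2]].T  # (V, S)
    patterns, inverse = np.unique(membership, axis=0, return_inverse=True)
    ids = np.array([m.subject_id for m in masks])
    subregions = []
    for j, pat in enumerate(patterns):
        vox = covered[inverse == j]
        subregions.append(
            Subregion(pattern=frozenset(ids[pat]), voxels=vox, grid=grid)
        )
    subregions.sort(key=lambda s: (-s.n_patients, sorted(s.pattern)))
    return subregions


def split_connected_components(sub: Subregion) -> list[np.ndarray]:
    """26-connected components of a subregion's voxels (reporting aid only)."""
    from scipy import ndimage

    vol = np.zeros(sub.grid.dims, dtype=bool)
    vol[tuple(sub.voxels.T)] = True
    labels, n = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    return [np.argwhere(labels == k) for k in range(1, n + 1)]


def test_subregion(sub: Subregion, patient_scores: dict[str, float],
                   control_scores, min_overlap: int = 3,
                   deficit_direction: str = "two_sided",
                   exact_threshold: int = 12) -> SubregionResult | None:
    """Rank-sum test of the subregion's patients against the controls.

    Patients in the coverage pattern lacking a score are excluded (with a
    logged warning); if fewer than ``min_overlap`` scored patients remain
    the subregion is skipped and ``None`` is returned.
    """
    if deficit_direction not in DEFICIT_DIRECTIONS:
        raise ValueError(f"deficit_direction must be one of {DEFICIT_DIRECTIONS}")
    controls = np.asarray(control_scores, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 control scores")
    scored = [patient_scores[s] for s in sorted(sub.pattern) if s in patient_scores
              and np.isfinite(patient_scores[s])]
    missing = sorted(s for s in sub.pattern
                     if s not in patient_scores
                     or not np.isfinite(patient_scores[s]))
    if missing:
        logger.warning("subregion %s: no score for %s",
                       sorted(sub.pattern), missing)
    if len(scored) < min_overlap:
        logger.warning("subregion %s skipped: %d scored patients < min_overlap %d",
                       sorted(sub.pattern), len(scored), min_overlap)
        return None
    alternative = {"two_sided": "two-sided", "higher_is_worse": "greater",
                   "lower_is_worse": "less"}[deficit_direction]
    result = stats.rank_sum(scored, controls, exact_threshold=exact_threshold,
                            alternative=alternative)
    direction = int(np.sign(np.median(scored) - np.median(controls)))
    return SubregionResult(subregion=sub, test=result, direction=direction,
                           n_scored=len(scored))


def holm_correct(p_values, alpha: float = 0.05) -> HolmResult:
    """Bonferroni-Holm step-down over one family of raw p-values.

    The i-th smallest p is rejected iff every j <= i satisfies
    p_(j) <= alpha / (m - j + 1).  ``H`` is the critical value at the rank
    where the procedure stopped (alpha itself when everything is rejected):
    a raw p had to fall below H to be rejected.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return HolmResult(m=0, alpha=alpha, rejected=np.zeros(0, dtype=bool),
                          H=alpha, largest_rejected_p=None)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    rejected = np.zeros(m, dtype=bool)
    stop_rank = m  # 0-based rank of the first non-rejection
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            rejected[idx] = True
        else:
            stop_rank = k
            break
    H = alpha if stop_rank == m else alpha / (m - stop_rank)
    largest = float(p[rejected].max()) if rejected.any() else None
    return HolmResult(m=m, alpha=alpha, rejected=rejected, H=H,
                      largest_rejected_p=largest)


def run_anacom(masks: list[LesionMask], subjects: pd.DataFrame, measure: str,
               min_overlap: int = 3, alpha: float = 0.05,
               deficit_direction: str = "two_sided") -> AnacomResult:
    """Full mapping chain for one behavioural measure.

    Partition -> per-subregion rank-sum vs controls -> Holm across all
    tested subregions of this map -> statistical map plus region report.
    The Holm family is the set of subregions tested within this one map;
    it is never pooled across measures.
    """
    validate_subject_table(subjects)
    if measure not in subjects.columns:
        raise ValueError(f"measure {measure!r} not in subject table")
    grid = _require_shared_grid(masks)
    warnings: list[str] = []

    pscores = _patient_scores(subjects, measure)
    cscores = _control_scores(subjects, measure)
    mask_ids = {m.subject_id for m in masks}
    unscored = sorted(mask_ids - set(pscores))
    if unscored:
        msg = f"patients without {measure!r} score excluded from tests: {unscored}"
        warnings.append(msg)
        logger.warning(msg)

    subregions = partition_subregions(masks, min_overlap=min_overlap)
    if not subregions:
        msg = f"no subregion reaches min_overlap={min_overlap}; empty map"
        warnings.append(msg)
        logger.warning(msg)

    tested: list[SubregionResult] = []
    skipped: list[tuple[Subregion, str]] = []
    for sub in subregions:
        res = test_subregion(sub, pscores, cscores, min_overlap=min_overlap,
                             deficit_direction=deficit_direction)
        if res is None:
            reason = "fewer scored patients than min_overlap"
            skipped.append((sub, reason))
            warnings.append(f"skipped subregion {sorted(sub.pattern)}: {reason}")
        else:
            tested.append(res)

    holm = holm_correct([r.p_raw for r in tested], alpha=alpha)
    for r, rej in zip(tested, holm.rejected):
        r.significant_after_holm = bool(rej)

    p_map = np.full(grid.dims, np.nan)
    sig_map = np.zeros(grid.dims, dtype=bool)
    for r in tested:
        idx = tuple(r.subregion.voxels.T)
        p_map[idx] = r.p_raw
        sig_map[idx] = r.significant_after_holm
    stat_map = StatMap(grid=grid, p_values=p_map, significant=sig_map)

    regions = [
        RegionReportRow(
            label="",
            mni_xyz=tuple(int(round(c)) for c in r.subregion.centroid_mni),
            p_raw=r.p_raw,
            size_mm3=r.subregion.size_mm3,
            n_patients=r.n_scored,
        )
        for r in sorted(
            (r for r in tested if r.significant_after_holm),
            key=lambda r: r.p_raw,
        )
    ]
    return AnacomResult(
        measure=measure, stat_map=stat_map, regions=regions, holm=holm,
        tested=tested, subregions=subregions, skipped=skipped,
        warnings=warnings, min_overlap=min_overlap, alpha=alpha,
    )


def damaged_in_region(region: Subregion, masks: list[LesionMask]) -> set[str]:
    """Patients whose lesion shares at least one voxel with the region."""
    vol = np.zeros(region.grid.dims, dtype=bool)
    vol[tuple(region.voxels.T)] = True
    return {m.subject_id for m in masks if np.any(m.data & vol)}


def region_vs_rest(region: Subregion, masks: list[LesionMask],
                   subjects: pd.DataFrame, measures: list[str],
                   categorical: list[str] = (),
                   paired: list[tuple[str, str]] = ()) -> pd.DataFrame:
    """Contrast patients damaged in ``region`` against all other patients.

    Any lesion sharing a voxel with the region counts as damaged.  Each
    continuous measure gets a Mann-Whitney U/z/p row; categorical covariates
    get chi-square rows; ``paired`` pairs of measures get within-group
    Wilcoxon signed-rank rows (computed within the damaged group).  A group
    smaller than 2 skips the measure with a warning.
    """
    validate_subject_table(subjects)
    damaged = damaged_in_region(region, masks)
    patients = subjects[subjects["group"] == "patient"]
    in_region = patients["subject_id"].isin(damaged)
    rows = []

    def _groups(measure: str):
        g1 = patients.loc[in_region, measure].dropna().to_numpy(float)
        g2 = patients.loc[~in_region, measure].dropna().to_numpy(float)
        return g1, g2

    for measure in measures:
        g1, g2 = _groups(measure)
        if len(g1) < 2 or len(g2) < 2:
            logger.warning("region-vs-rest %s skipped: group too small "
                           "(%d vs %d)", measure, len(g1), len(g2))
            rows.append({"measure": measure, "kind": "rank_sum",
                         "n_region": len(g1), "n_rest": len(g2),
                         "statistic": np.nan, "z": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        t = stats.rank_sum(g1, g2)
        rows.append({"measure": measure, "kind": "rank_sum",
                     "n_region": len(g1), "n_rest": len(g2),
                     "statistic": t.statistic, "z": t.z, "p": t.p,
                     "skipped": False})

    for covariate in categorical:
        tab = pd.crosstab(in_region, patients[covariate])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            logger.warning("chi-square on %s skipped: degenerate table",
                           covariate)
            rows.append({"measure": covariate, "kind": "chi_square",
                         "n_region": int(in_region.sum()),
                         "n_rest": int((~in_region).sum()),
                         "statistic": np.nan, "z": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        t = stats.chi_square_2xk(tab.to_numpy())
        rows.append({"measure": covariate, "kind": "chi_square",
                     "n_region": int(in_region.sum()),
                     "n_rest": int((~in_region).sum()),
                     "statistic": t.statistic, "z": np.nan, "p": t.p,
                     "skipped": False})

    for ma, mb in paired:
        pair = patients.loc[in_region, [ma, mb]].dropna()
        if len(pair) < 2:
            logger.warning("signed-rank %s vs %s skipped: fewer than 2 pairs",
                           ma, mb)
            rows.append({"measure": f"{ma} vs {mb}", "kind": "signed_rank",
                         "n_region": len(pair), "n_rest": 0,
                         "statistic": np.nan, "z": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        t = stats.signed_rank(pair[ma].to_numpy(float), pair[mb].to_numpy(float))
        rows.append({"measure": f"{ma} vs {mb}", "kind": "signed_rank",
                     "n_region": len(pair), "n_rest": 0,
                     "statistic": t.statistic, "z": t.z, "p": t.p,
                     "skipped": False})
    return pd.DataFrame(rows)
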