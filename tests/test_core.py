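"""Overlap map, coverage-pattern partition, Holm, and the full mapping."""

import numpy as np
import pandas as pd
import pytest

from anacom.core import (build_overlap_map, damaged_in_region, holm_correct,
                         partition_subregions, region_vs_rest, run_anacom)
from anacom.core import test_subregion as subregion_test  # avoid collection
from anacom.errors import GridMismatchError
from anacom.imaging import LesionMask, VolumeGrid
from anacom.simulate import generate_cohort, recovery_cohort_spec
from conftest import make_mask, random_masks
from oracles import (count_overlaps_at, group_voxels_by_membership,
                     holm_reject)


class TestOverlapMap:
    def test_identical_masks_double_count(self, small_grid):
        vox = [(1, 1, 1), (2, 3, 4)]
        masks = [make_mask(small_grid, s, vox) for s in ("a", "b")]
        om = build_overlap_map(masks)
        assert om.count[1, 1, 1] == 2 and om.count[2, 3, 4] == 2
        assert om.count.sum() == 4

    def test_disjoint_masks_max_one(self, small_grid):
        m1 = make_mask(small_grid, "a", [(0, 0, 0)])
        m2 = make_mask(small_grid, "b", [(5, 5, 5)])
        assert build_overlap_map([m1, m2]).max_overlap == 1

    def test_counts_match_per_voxel_loop(self, small_grid):
        rng = np.random.default_rng(11)
        masks = random_masks(small_grid, 5, rng)
        om = build_overlap_map(masks)
        pairs = [(m.subject_id, m.data) for m in masks]
        for idx in np.ndindex(small_grid.dims):
            assert om.count[idx] == count_overlaps_at(pairs, idx)

    def test_mixed_grids_rejected(self, small_grid):
        other = VolumeGrid(dims=small_grid.dims, affine=np.eye(4))
        masks = [make_mask(small_grid, "a", [(0, 0, 0)]),
                 LesionMask("b", other, np.zeros(other.dims, bool))]
        with pytest.raises(GridMismatchError):
            build_overlap_map(masks)


class TestPartition:
    def test_three_identical_masks_one_subregion(self, small_grid):
        vox = [(1, 2, 3), (1, 2, 4), (4, 4, 4)]
        masks = [make_mask(small_grid, s, vox) for s in ("a", "b", "c")]
        subs = partition_subregions(masks, min_overlap=3)
        assert len(subs) == 1
        assert subs[0].pattern == frozenset({"a", "b", "c"})
        assert sorted(map(tuple, subs[0].voxels)) == sorted(vox)

    def test_undercovered_voxel_excluded(self, small_grid):
        # a voxel covered by only 2 lesions never enters a tested subregion
        masks = [make_mask(small_grid, "a", [(0, 0, 0), (1, 1, 1)]),
                 make_mask(small_grid, "b", [(0, 0, 0), (1, 1, 1)]),
                 make_mask(small_grid, "c", [(1, 1, 1)])]
        subs = partition_subregions(masks, min_overlap=3)
        covered = {tuple(v) for s in subs for v in s.voxels}
        assert (0, 0, 0) not in covered
        assert covered == {(1, 1, 1)}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_membership_grouping(self, seed):
        grid = VolumeGrid(dims=(6, 6, 6), affine=np.eye(4))
        rng = np.random.default_rng(seed)
        masks = random_masks(grid, 6, rng, p=0.35)
        subs = partition_subregions(masks, min_overlap=3)
        oracle = group_voxels_by_membership(
            [(m.subject_id, m.data) for m in masks], min_overlap=3)
        got = {s.pattern: sorted(map(tuple, s.voxels)) for s in subs}
        assert got == oracle

    def test_partition_covers_exactly_thresholded_voxels(self, small_grid):
        rng = np.random.default_rng(9)
        masks = random_masks(small_grid, 7, rng)
        om = build_overlap_map(masks)
        subs = partition_subregions(masks, min_overlap=3)
        covered = np.zeros(small_grid.dims, bool)
        for s in subs:
            block = tuple(s.voxels.T)
            assert not covered[block].any()  # pairwise disjoint
            covered[block] = True
        np.testing.assert_array_equal(covered, om.count >= 3)

    def test_monotone_in_min_overlap(self, small_grid):
        rng = np.random.default_rng(21)
        masks = random_masks(small_grid, 8, rng)
        counts = [len(partition_subregions(masks, min_overlap=k))
                  for k in (1, 2, 3, 4, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_mask_list_rejected(self):
        with pytest.raises(ValueError):
            partition_subregions([], min_overlap=3)


class TestHolm:
    def test_single_p_reduces_to_plain_alpha(self):
        res = holm_correct([0.01], alpha=0.05)
        assert res.rejected.tolist() == [True]
        assert res.H == pytest.approx(0.05)

    def test_hand_computed_step_down(self):
        # 0.001 <= 0.05/3 rejects; 0.03 > 0.05/2 stops the procedure
        res = holm_correct([0.001, 0.03, 0.04], alpha=0.05)
        assert res.rejected.tolist() == [True, False, False]
        assert res.H == pytest.approx(0.025)
        assert res.largest_rejected_p == pytest.approx(0.001)

    def test_empty_family(self):
        res = holm_correct([], alpha=0.05)
        assert res.m == 0 and res.H == 0.05 and res.n_rejected == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(100)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(1e-6, 1.0, m)
            res = holm_correct(p, alpha=0.05)
            np.testing.assert_array_equal(res.rejected, holm_reject(p, 0.05))

    def test_matches_statsmodels_and_brackets_bonferroni(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(200)
        for _ in range(200):
            m = int(rng.integers(1, 15))
            p = rng.uniform(1e-6, 1.0, m)
            ours = holm_correct(p, alpha=0.05).rejected
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(ours, ref)
            bonf = p <= 0.05 / m
            unadj = p <= 0.05
            assert (bonf <= ours).all() and (ours <= unadj).all()


class TestSubregionTest:
    def _sub(self, grid, pattern):
        masks = [make_mask(grid, s, [(1, 1, 1)]) for s in pattern]
        return partition_subregions(masks, min_overlap=len(pattern))[0]

    def test_exchangeable_scores_give_p_one(self, small_grid):
        sub = self._sub(small_grid, ["a", "b", "c"])
        res = subregion_test(sub, {"a": 1.0, "b": 2.0, "c": 3.0},
                             [3.0, 1.0, 2.0])
        assert res.test.z == pytest.approx(0.0, abs=1e-12)
        assert res.test.p == pytest.approx(1.0)

    def test_extreme_separation_exact(self, small_grid):
        sub = self._sub(small_grid, ["a", "b", "c"])
        res = subregion_test(sub, {"a": 5.0, "b": 6.0, "c": 7.0},
                             [1.0, 2.0, 3.0, 4.0])
        assert res.test.u_first == 12
        assert res.test.p == pytest.approx(2 / 35)
        assert res.direction == 1

    def test_missing_scores_skip_with_warning(self, small_grid, caplog):
        sub = self._sub(small_grid, ["a", "b", "c"])
        res = subregion_test(sub, {"a": 5.0}, [1.0, 2.0, 3.0], min_overlap=3)
        assert res is None
        assert any("skipped" in r.message for r in caplog.records)


@pytest.fixture(scope="module")
def planted():
    spec = recovery_cohort_spec(seed=12)
    masks, subjects, truth = generate_cohort(spec)
    result = run_anacom(masks, subjects, "tb_interpress_s")
    return masks, subjects, truth, result


class TestRunAnacom:
    def test_planted_region_recovered(self, planted):
        masks, _, truth, result = planted
        planted_vol = np.zeros(result.stat_map.grid.dims, bool)
        planted_vol[tuple(truth.planted_region.T)] = True
        assert (result.stat_map.significant & planted_vol).any()
        # and detection agrees with a direct rank-sum on the known carriers
        from anacom.stats import rank_sum
        from anacom.subjects import control_scores, patient_scores
        _, subjects, truth, result = planted
        carriers = [patient_scores(subjects, "tb_interpress_s")[c]
                    for c in sorted(truth.carrier_ids)]
        direct = rank_sum(carriers, control_scores(subjects, "tb_interpress_s"))
        assert direct.p < result.holm.H

    def test_voxels_inherit_their_subregion_p(self, planted):
        _, _, _, result = planted
        for r in result.tested[:20]:
            block = tuple(r.subregion.voxels.T)
            assert (result.stat_map.p_values[block] == r.p_raw).all()

    def test_report_coordinates_are_affine_mapped_centroids(self, planted):
        _, _, _, result = planted
        assert result.regions, "fixture cohort should yield significant regions"
        expected = set()
        for r in result.tested:
            if not r.significant_after_holm:
                continue
            hom = np.append(r.subregion.voxels.mean(axis=0), 1.0)
            mm = (r.subregion.grid.affine @ hom)[:3]  # independent route
            expected.add((round(r.p_raw, 12),
                          tuple(int(round(c)) for c in mm)))
        got = {(round(row.p_raw, 12), row.mni_xyz) for row in result.regions}
        assert got == expected

    def test_region_rows_sorted_by_p(self, planted):
        _, _, _, result = planted
        ps = [r.p_raw for r in result.regions]
        assert ps == sorted(ps)

    def test_unknown_measure_rejected(self, planted):
        masks, subjects, _, _ = planted
        with pytest.raises(ValueError, match="not in subject table"):
            run_anacom(masks, subjects, "nope")


class TestRegionVsRest:
    def _setup(self, grid):
        region_vox = [(1, 1, 1), (1, 1, 2)]
        masks = (
            [make_mask(grid, f"in{i}", region_vox + [(3, 3, i)]) for i in range(3)]
            + [make_mask(grid, f"out{i}", [(5, 5, i)]) for i in range(3)]
        )
        region = partition_subregions(masks[:3], min_overlap=3)[0]
        return masks, region

    def test_membership_by_any_shared_voxel(self, small_grid):
        masks, region = self._setup(small_grid)
        assert damaged_in_region(region, masks) == {"in0", "in1", "in2"}

    def test_identical_multisets_give_p_one(self, small_grid):
        masks, region = self._setup(small_grid)
        subjects = pd.DataFrame({
            "subject_id": [m.subject_id for m in masks],
            "group": ["patient"] * 6,
            "score": [1.0, 2.0, 3.0, 3.0, 1.0, 2.0],
        })
        table = region_vs_rest(region, masks, subjects, ["score"])
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_balanced_categorical_gives_chi_square_zero(self, small_grid):
        masks, region = self._setup(small_grid)
        # gender split identically inside and outside the region -> chi2 = 0
        subjects = pd.DataFrame({
            "subject_id": [m.subject_id for m in masks],
            "group": ["patient"] * 6,
            "gender": ["f", "f", "m", "f", "f", "m"],
        })
        table = region_vs_rest(region, masks, subjects, [],
                               categorical=["gender"])
        row = table.iloc[0]
        assert row["kind"] == "chi_square"
        assert row["statistic"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_paired_contrast_and_small_group_skip(self, small_grid):
        masks, region = self._setup(small_grid)
        subjects = pd.DataFrame({
            "subject_id": [m.subject_id for m in masks],
            "group": ["patient"] * 6,
            "rt_og": [900.0, 950.0, 800.0, 700.0, 820.0, 610.0],
            "rt_ogpm": [910.0, 940.0, 815.0, 705.0, 818.0, 650.0],
            "lonely": [1.0] + [np.nan] * 5,
        })
        table = region_vs_rest(region, masks, subjects, ["lonely"],
                               paired=[("rt_og", "rt_ogpm")])
        lonely = table[table["measure"] == "lonely"].iloc[0]
        assert bool(lonely["skipped"])
        paired = table[table["kind"] == "signed_rank"].iloc[0]
        assert not bool(paired["skipped"])
        assert 0 < paired["p"] <= 1
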