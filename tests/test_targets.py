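"""Surface masking, the three selection pipelines, overlap maps."""

import numpy as np
import pytest

from nibstarget.core import BinaryMask, StatMap, VolumeGrid
from nibstarget.inference import InferenceResult
from nibstarget.rois import ClusterRecord, sphere_mask
from nibstarget.synth import Blob, make_toy_parcellation, simulate_meta_map
from nibstarget.targets import (
    OverlapMap,
    SurfaceMask,
    binarize_map,
    build_surface_mask,
    overlap_sum,
    pipeline1,
    pipeline2,
    pipeline3,
)


def _box(grid, i0, i1, j0, j1, k0, k1):
    data = np.zeros(grid.shape, dtype=bool)
    data[i0:i1, j0:j1, k0:k1] = True
    return BinaryMask(grid, data)


def _full_surface(grid):
    return SurfaceMask(BinaryMask(grid, np.ones(grid.shape, dtype=bool)), ["all"])


def _fake_result(grid, clusters, sign="positive", stat=None):
    """Assemble an InferenceResult directly from given cluster voxel blocks."""
    recs = []
    data = stat if stat is not None else np.zeros(grid.shape)
    for i, idx in enumerate(clusters, start=1):
        idx = np.asarray(idx)
        recs.append(
            ClusterRecord(
                cluster_id=i,
                size_voxels=len(idx),
                voxel_indices=idx,
                cluster_fwe_p=0.01,
            )
        )
    return InferenceResult(
        sign=sign, voxel_p=0.001, alpha=0.05, clusters=recs, n_permutations=200,
        rng_seed=0, t_threshold=4.0, df=11, n_subjects=12, grid=grid,
        stat_map=StatMap(grid, data),
    )


def _block(i0, i1, j0, j1, k0, k1):
    return [(i, j, k) for i in range(i0, i1) for j in range(j0, j1) for k in range(k0, k1)]


class TestBuildSurfaceMask:
    def _parc(self, grid):
        a = _box(grid, 0, 4, 0, 12, 0, 12)
        b = _box(grid, 6, 10, 0, 12, 0, 12)
        return make_toy_parcellation(grid, [("A", a), ("B", b)], ["A", "B"])

    def test_single_region(self, grid12):
        parc = self._parc(grid12)
        sm = build_surface_mask(parc, ["A"])
        assert sm.mask.n_voxels == 4 * 12 * 12
        assert sm.region_names == ["A"]

    def test_duplicates_deduplicated(self, grid12):
        parc = self._parc(grid12)
        assert build_surface_mask(parc, ["A", "A", "B"]).mask.n_voxels == 8 * 12 * 12

    def test_unknown_name_rejected(self, grid12):
        with pytest.raises(ValueError, match="Zed"):
            build_surface_mask(self._parc(grid12), ["A", "Zed"])

    def test_full_list_counts_sum(self, grid12):
        parc = self._parc(grid12)
        total = sum(parc.region_mask(n).n_voxels for n in parc.surface_names)
        assert build_surface_mask(parc, parc.surface_names).mask.n_voxels == total


class TestPipeline1:
    def test_deep_blob_excluded_surface_blob_kept(self, default_grid):
        meta = simulate_meta_map(
            default_grid,
            [Blob((0.0, 0.0, 0.0), 12.0, 12.0), Blob((-24.0, 0.0, 0.0), 9.0, 12.0)],
            floor_z=3.0,
        )
        surf_data = np.zeros(default_grid.shape, dtype=bool)
        surf_data[:5] = True  # x <= -16.5 mm
        surface = SurfaceMask(BinaryMask(default_grid, surf_data), ["L"])
        report = pipeline1(meta, surface, min_cluster=20, strict=False)
        assert len(report.clusters) == 1
        assert report.clusters[0].peak_value == pytest.approx(9.0)

    def test_straddling_blob_counts_only_surface_part(self, default_grid):
        meta = simulate_meta_map(default_grid, [Blob((-18.0, 0.0, 0.0), 9.0, 12.0)], 3.0)
        surf_data = np.zeros(default_grid.shape, dtype=bool)
        surf_data[:5] = True
        surface = SurfaceMask(BinaryMask(default_grid, surf_data), ["L"])
        report = pipeline1(meta, surface, min_cluster=1, strict=False)
        want = int(((meta.data != 0) & surf_data).sum())
        assert report.clusters[0].size_voxels == want
        assert want < int((meta.data != 0).sum())

    def test_nine_blobs_give_nine_ranked_rows(self):
        grid = VolumeGrid.isotropic((34, 34, 10), 3.0)
        centers = [(-40.0 + 20.0 * i, -20.0 + 20.0 * j, 0.0) for i in range(3) for j in range(3)]
        peaks = np.linspace(8.0, 16.0, 9)
        meta = simulate_meta_map(grid, [Blob(c, p, 10.0) for c, p in zip(centers, peaks)], 3.0)
        report = pipeline1(meta, _full_surface(grid), min_cluster=20, strict=False)
        assert len(report.clusters) == 9
        got = [c.peak_value for c in report.clusters]
        assert got == sorted(got, reverse=True)


class TestPipeline2:
    def test_top_k_drops_smallest_peak(self, default_grid):
        stat = np.zeros(default_grid.shape)
        blocks = []
        for n in range(7):
            blk = _block(0, 20, n * 3, n * 3 + 2, 0, 4)  # 160 voxels each
            for v in blk:
                stat[v] = 10.0 + n
            blocks.append(blk)
        res_pos = _fake_result(default_grid, blocks, "positive", stat)
        res_neg = _fake_result(default_grid, [], "negative", stat)
        rp, rn = pipeline2(res_pos, res_neg, _full_surface(default_grid), min_cluster=20)
        assert len(rp.clusters) == 6
        assert min(abs(c.peak_value) for c in rp.clusters) == pytest.approx(11.0)
        assert rn.clusters == []

    def test_cluster_below_20_after_surface_cut_excluded(self, default_grid):
        blk = _block(0, 19, 0, 1, 0, 1)  # 19 voxels
        res_pos = _fake_result(default_grid, [blk], "positive")
        res_neg = _fake_result(default_grid, [], "negative")
        rp, _ = pipeline2(res_pos, res_neg, _full_surface(default_grid))
        assert rp.clusters == []

    def test_warning_below_k_min(self, default_grid, caplog):
        blk = _block(0, 10, 0, 5, 0, 1)  # one 50-voxel cluster
        res = _fake_result(default_grid, [blk], "positive")
        empty = _fake_result(default_grid, [], "negative")
        with caplog.at_level("WARNING"):
            pipeline2(res, empty, _full_surface(default_grid))
        assert "wanted >= 4" in caplog.text


class TestOverlapSum:
    def test_two_masks_overlap_at_one_voxel(self, grid12):
        a = _box(grid12, 0, 3, 0, 1, 0, 1)
        b = _box(grid12, 2, 5, 0, 1, 0, 1)
        om = overlap_sum([a, b])
        assert om.data[2, 0, 0] == 2
        assert om.data[0, 0, 0] == om.data[4, 0, 0] == 1
        assert om.data.max() <= 2

    def test_n_copies_scale_mask(self, grid12):
        m = _box(grid12, 1, 4, 1, 4, 1, 4)
        om = overlap_sum([m] * 5)
        assert np.array_equal(om.data, 5 * m.data.astype(int))

    def test_exhaustive_sum_on_8cubed_random_masks(self):
        grid = VolumeGrid.isotropic((8, 8, 8), 3.0)
        rng = np.random.default_rng(5)
        masks = [BinaryMask(grid, rng.random(grid.shape) < 0.4) for _ in range(6)]
        om = overlap_sum(masks)
        # voxel-by-voxel oracle
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert om.data[i, j, k] == sum(int(m.data[i, j, k]) for m in masks)
        assert om.data.max() <= 6

    def test_grid_mismatch_rejected(self, grid12):
        other = VolumeGrid.isotropic((8, 8, 8), 3.0)
        with pytest.raises(ValueError):
            overlap_sum([
                _box(grid12, 0, 1, 0, 1, 0, 1),
                BinaryMask(other, np.zeros(other.shape, dtype=bool)),
            ])


class TestBinarize:
    def test_no_survivors_gives_empty_mask(self, grid12):
        res = _fake_result(grid12, [])
        assert binarize_map(res).n_voxels == 0

    def test_mask_is_union_of_surviving_clusters(self, grid12):
        blocks = [_block(0, 2, 0, 2, 0, 2), _block(5, 8, 5, 8, 5, 8)]
        res = _fake_result(grid12, blocks)
        m = binarize_map(res)
        assert set(np.unique(m.data.astype(int))) <= {0, 1}
        assert m.n_voxels == sum(len(b) for b in blocks)


class TestPipeline3:
    def test_small_high_level_core_reported_at_first_qualifying_level(self, default_grid):
        counts = np.zeros(default_grid.shape, dtype=int)
        blk = _block(4, 9, 4, 9, 4, 5)  # 25 voxels at level 13
        for v in blk:
            counts[v] = 13
        counts[5, 5, 4] = 15  # a single hotter voxel inside
        op = OverlapMap(default_grid, counts, 15)
        on = OverlapMap(default_grid, np.zeros(default_grid.shape, dtype=int), 15)
        rp, _ = pipeline3(op, on, _full_surface(default_grid), min_cluster=20)
        assert len(rp.clusters) == 1
        rec = rp.clusters[0]
        assert rec.peak_value == 13.0  # level where the cluster first reaches size
        assert rec.size_voxels == 25
        assert rec.peak_mni_mm is None  # flat level set: no peak coordinate

    def test_zero_overlap_everywhere_warns_empty(self, default_grid, caplog):
        zero = OverlapMap(default_grid, np.zeros(default_grid.shape, dtype=int), 3)
        with caplog.at_level("WARNING"):
            rp, rn = pipeline3(zero, zero, _full_surface(default_grid))
        assert rp.clusters == [] and rn.clusters == []
        assert "all zero" in caplog.text

    def test_disjoint_masks_give_level_one_clusters(self, default_grid):
        a = sphere_mask(default_grid, (-15.0, 0.0, 0.0), 7.0)
        b = sphere_mask(default_grid, (15.0, 0.0, 0.0), 7.0)
        om = overlap_sum([a, b])
        on = OverlapMap(default_grid, np.zeros(default_grid.shape, dtype=int), 2)
        rp, _ = pipeline3(om, on, _full_surface(default_grid), min_cluster=20)
        assert len(rp.clusters) == 2
        assert all(c.peak_value == 1.0 for c in rp.clusters)

    def test_report_invariant_to_mask_order(self, default_grid):
        a = sphere_mask(default_grid, (-15.0, 0.0, 0.0), 7.0)
        b = sphere_mask(default_grid, (12.0, 3.0, 0.0), 7.0)
        c = sphere_mask(default_grid, (9.0, -9.0, 0.0), 7.0)
        surface = _full_surface(default_grid)
        zero = OverlapMap(default_grid, np.zeros(default_grid.shape, dtype=int), 3)
        r1, _ = pipeline3(overlap_sum([a, b, c]), zero, surface, min_cluster=20)
        r2, _ = pipeline3(overlap_sum([c, a, b]), zero, surface, min_cluster=20)
        s1 = [(cl.peak_value, cl.size_voxels, cl.centroid_mni_mm) for cl in r1.clusters]
        s2 = [(cl.peak_value, cl.size_voxels, cl.centroid_mni_mm) for cl in r2.clusters]
        assert s1 == s2

    def test_levelset_ranking_prefers_higher_counts(self, default_grid):
        counts = np.zeros(default_grid.shape, dtype=int)
        for v in _block(0, 5, 0, 5, 0, 1):
            counts[v] = 1  # 25 voxels at level 1
        for v in _block(10, 15, 10, 15, 10, 11):
            counts[v] = 3  # 25 voxels at level 3
        op = OverlapMap(default_grid, counts, 3)
        on = OverlapMap(default_grid, np.zeros(default_grid.shape, dtype=int), 3)
        rp, _ = pipeline3(op, on, _full_surface(default_grid), min_cluster=20)
        assert [c.peak_value for c in rp.clusters] == [3.0, 1.0]
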