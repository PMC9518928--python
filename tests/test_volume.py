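"""Binarization, component labeling (vs BFS oracle), midsagittal integration,
illuminated rendering, and patch extraction."""

import numpy as np
import pytest

from cephaloseed.volume import (SegmentationError, VolumeGrid, binarize,
                                extract_patch_2d, extract_patch_3d,
                                integrate_midsagittal, render_depth,
                                render_illuminated, segment_components)


def _dilate26(mask):
    """One 26-connected dilation step via shifted ORs (no scipy)."""
    out = mask.copy()
    p = np.pad(mask, 1)
    n = mask.shape
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            for c in (0, 1, 2):
                out |= p[a:a + n[0], b:b + n[1], c:c + n[2]]
    return out


def bfs_components(data):
    """Independent flood-fill labeling oracle (iterated frontier growth).

    Returns the list of 26-connected components as voxel-index sets.
    """
    remaining = np.asarray(data, dtype=bool).copy()
    comps = []
    while remaining.any():
        seed = tuple(np.argwhere(remaining)[0])
        comp = np.zeros_like(remaining)
        comp[seed] = True
        while True:
            grown = _dilate26(comp) & remaining
            if grown.sum() == comp.sum():
                break
            comp = grown
        comps.append(set(map(tuple, np.argwhere(comp))))
        remaining &= ~comp
    return comps


class TestBinarize:
    def test_threshold_is_inclusive(self):
        v = VolumeGrid(np.array([[[600.0, 500.0, 499.0]]]))
        out = binarize(v, 500.0)
        np.testing.assert_array_equal(out.data[0, 0], [1, 1, 0])

    def test_air_volume_all_zero(self):
        v = VolumeGrid(np.full((4, 4, 4), -1000.0))
        assert binarize(v).data.sum() == 0

    def test_idempotent_on_binary_input(self):
        rng = np.random.default_rng(0)
        v = VolumeGrid((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        once = binarize(v, 1.0)
        twice = binarize(once, 1.0)
        np.testing.assert_array_equal(once.data, twice.data)


class TestSegmentComponents:
    def test_two_blobs_sized_100_and_40(self):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[1:5, 1:6, 1:6] = 1          # 100 voxels
        data[10:14, 10:12, 10:15] = 1    # 40 voxels
        cr, md = segment_components(VolumeGrid(data))
        assert cr.data.sum() == 100
        assert md.data.sum() == 40
        assert not np.any(cr.data & md.data)

    def test_single_blob_raises(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[1:3, 1:3, 1:3] = 1
        with pytest.raises(SegmentationError):
            segment_components(VolumeGrid(data))

    def test_matches_bfs_oracle_on_random_grids(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            shape = tuple(rng.integers(6, 16, size=3))
            data = (rng.random(shape) > 0.82).astype(np.uint8)
            comps = bfs_components(data)
            if len(comps) < 2:
                continue
            cr, md = segment_components(VolumeGrid(data))
            sizes = sorted((len(c) for c in comps), reverse=True)
            assert cr.data.sum() == sizes[0]
            assert md.data.sum() == sizes[1]
            got_cr = set(map(tuple, np.argwhere(cr.data)))
            got_md = set(map(tuple, np.argwhere(md.data)))
            assert got_cr in comps or got_cr in [c for c in comps if len(c) == sizes[0]]
            assert any(got_md == c for c in comps)

    def test_size_tie_broken_by_lower_linear_index(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[8, 8, 8] = 1   # later in linear order
        data[0, 0, 0] = 1   # earlier
        cr, _ = segment_components(VolumeGrid(data))
        assert cr.data[0, 0, 0] == 1


class TestIntegrateMidsagittal:
    def test_single_voxel_slab_equals_slice(self):
        rng = np.random.default_rng(1)
        data = (rng.random((8, 6, 7)) > 0.5).astype(np.uint8)
        v = VolumeGrid(data, spacing=(1, 1, 1))
        img = integrate_midsagittal(v, plane_v1=3.0, half_width_mm=0.4)
        np.testing.assert_array_equal(img, data[3])

    def test_full_slab_of_all_ones_is_constant(self):
        v = VolumeGrid(np.ones((4, 3, 3), dtype=np.uint8), spacing=(1, 1, 1))
        img = integrate_midsagittal(v, plane_v1=1.5, half_width_mm=10.0)
        np.testing.assert_array_equal(img, np.full((3, 3), 4))

    def test_mass_conservation_vs_triple_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            shape = tuple(rng.integers(5, 12, size=3))
            data = (rng.random(shape) > 0.6).astype(np.uint8)
            s1 = float(rng.uniform(0.5, 2.0))
            v = VolumeGrid(data, spacing=(s1, 1, 1),
                           origin=rng.normal(size=3))
            plane = float(v.origin[0] + rng.uniform(0, (shape[0] - 1) * s1))
            hw = float(rng.uniform(0.5, 4.0)) * s1
            img = integrate_midsagittal(v, plane, hw)
            # brute force: sum voxels whose v1 center is inside the slab
            total = 0
            for i in range(shape[0]):
                x = v.origin[0] + i * s1
                if plane - hw - 1e-9 <= x <= plane + hw + 1e-9:
                    total += int(data[i].sum())
            assert img.sum() == total

    def test_slab_outside_grid_raises(self):
        v = VolumeGrid(np.ones((4, 3, 3), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            integrate_midsagittal(v, plane_v1=50.0, half_width_mm=1.0)


class TestRenderIlluminated:
    def test_empty_volume_renders_background(self):
        v = VolumeGrid(np.zeros((5, 5, 5), dtype=np.uint8))
        img = render_illuminated(v, (1, 0, 0), (0, 0, 1))
        assert np.all(img == 0)

    def test_cube_face_lit_head_on_is_uniform(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[3:7, 3:7, 3:7] = 1
        v = VolumeGrid(data, spacing=(1, 1, 1))
        img = render_illuminated(v, (0, 0, 1), (0, 0, 1))
        face = img[4:6, 4:6]  # interior of the face, away from edge gradients
        assert np.allclose(face, face[0, 0])
        assert face[0, 0] > 0

    def test_silhouette_independent_of_light(self):
        rng = np.random.default_rng(4)
        data = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8)
        v = VolumeGrid(data)
        a = render_illuminated(v, (0, 1, 0), (0, 1, 0))
        b = render_illuminated(v, (0, 1, 0), (0.6, 0.6, 0.5))
        np.testing.assert_array_equal(a > 0, b > 0)

    def test_zero_direction_rejected(self):
        v = VolumeGrid(np.ones((3, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            render_illuminated(v, (0, 0, 0), (0, 0, 1))
        with pytest.raises(ValueError):
            render_illuminated(v, (0.5, 0.5, 0.7), (0, 0, 1))

    def test_depth_map_measures_first_hit(self):
        data = np.zeros((6, 4, 4), dtype=np.uint8)
        data[2, :, :] = 1
        v = VolumeGrid(data, spacing=(2.0, 1, 1))
        depth, hit = render_depth(v, (-1, 0, 0))
        assert np.all(hit)
        np.testing.assert_allclose(depth, 4.0)  # 2 voxels * 2 mm from -v1 side


class TestPatchExtraction:
    def test_center_patch_of_ones_volume(self):
        v = VolumeGrid(np.ones((20, 20, 20), dtype=np.uint8), spacing=(1, 1, 1))
        p = extract_patch_3d(v, (10, 10, 10), eta_vox=8)
        assert p.data.shape == (8, 8, 8)
        assert p.data.sum() == 8 ** 3

    def test_corner_patch_zero_fill_matches_overlap(self):
        v = VolumeGrid(np.ones((20, 20, 20), dtype=np.uint8), spacing=(1, 1, 1))
        p = extract_patch_3d(v, (0, 0, 0), eta_vox=8)
        # center at voxel 0: only indices 0..3 of each axis fall inside
        assert p.data.sum() == 4 ** 3

    def test_far_outside_center_raises(self):
        v = VolumeGrid(np.ones((10, 10, 10), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            extract_patch_3d(v, (1000, 0, 0), eta_vox=8)

    def test_translation_by_whole_voxels_gives_identical_patch(self):
        rng = np.random.default_rng(6)
        data = (rng.random((24, 24, 24)) > 0.5).astype(np.uint8)
        v1 = VolumeGrid(data, spacing=(2, 2, 2), origin=np.zeros(3))
        v2 = VolumeGrid(np.roll(data, (3, -2, 1), axis=(0, 1, 2)),
                        spacing=(2, 2, 2), origin=np.zeros(3))
        c = np.array([24.0, 24.0, 24.0])
        shift = np.array([3, -2, 1]) * 2.0
        p1 = extract_patch_3d(v1, c, eta_vox=6)
        p2 = extract_patch_3d(v2, c + shift, eta_vox=6)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_2d_patch_center_and_padding(self):
        grid = VolumeGrid(np.zeros((4, 30, 30)), spacing=(1, 1, 1))
        img = np.arange(900).reshape(30, 30)
        p = extract_patch_2d(img, grid, (15, 15), eta_px=6)
        assert p.data.shape == (6, 6)
        assert p.data[3, 3] == img[15, 15]
        edge = extract_patch_2d(img, grid, (0, 0), eta_px=6)
        assert (edge.data == 0).sum() >= 6 * 6 - 9

    def test_landmark_patch_contains_surface_voxels(self, rasterized_subject):
        from cephaloseed.volume import binarize as _bin
        from cephaloseed.volume import segment_components as _seg

        s = rasterized_subject
        _, md = _seg(_bin(s.volume))
        p = extract_patch_3d(md, s.landmarks_raw["Menton"], eta_vox=16)
        assert p.data.sum() > 0
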