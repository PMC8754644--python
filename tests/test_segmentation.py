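"""Projection, cropping, both segmentation methods, and mask overrides."""

import numpy as np
import pytest
from skimage.draw import disk

from ms2burst import (LabelMask, apply_override, crop_field,
                      default_crop_box, max_project, segment_method1,
                      segment_method2)
from ms2burst.segmentation import Method2Config, max_project as _mp


def synthetic_disks(shape=(120, 120), centers=((40, 40), (40, 90)), r=12,
                    level=1000.0, bg=100.0):
    img = np.full(shape, bg)
    for cy, cx in centers:
        rr, cc = disk((cy, cx), r, shape=shape)
        img[rr, cc] = level
    return img


class TestMaxProject:
    def test_single_plane_stack_is_identity(self):
        a = np.random.default_rng(0).uniform(size=(1, 30, 30))
        assert np.array_equal(max_project(a), a[0])

    def test_single_bright_voxel_survives_projection(self):
        a = np.zeros((10, 20, 20))
        a[5, 7, 9] = 42.0
        proj = max_project(a)
        assert proj[7, 9] == 42.0
        assert proj.sum() == 42.0

    def test_all_zero_stack_projects_to_zero(self):
        assert np.all(max_project(np.zeros((4, 8, 8))) == 0)

    def test_movie_projection_requires_valid_channel(self):
        movie = np.zeros((2, 3, 2, 8, 8), dtype=np.uint16)
        assert max_project(movie, 1).shape == (2, 8, 8)
        with pytest.raises(IndexError):
            max_project(movie, 5)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 8, 8)))


class TestCropField:
    def test_default_square_crop_of_512(self):
        box = default_crop_box((512, 512), "square")
        out = crop_field(np.zeros((512, 512)), box)
        assert out.shape == (430, 430)

    def test_dorsoventral_crop_of_512(self):
        box = default_crop_box((512, 512), "dorsoventral")
        out = crop_field(np.zeros((512, 512)), box)
        assert out.shape == (300, 430)

    def test_identity_box_preserves_raster(self):
        a = np.arange(64.0).reshape(8, 8)
        assert np.array_equal(crop_field(a, (0, 8, 0, 8)), a)

    def test_out_of_bounds_box_rejected(self):
        with pytest.raises(ValueError):
            crop_field(np.zeros((8, 8)), (0, 9, 0, 8))


class TestMethod1:
    def test_well_separated_disks_give_two_labels(self):
        mask = segment_method1(synthetic_disks())
        assert mask.n_labels == 2

    def test_tangent_disks_split_by_watershed(self):
        # two disks touching at one point: distance transform has two maxima
        img = synthetic_disks(centers=((60, 48), (60, 72)), r=12)
        mask = segment_method1(img)
        assert mask.n_labels == 2

    def test_blank_raster_yields_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            mask = segment_method1(np.zeros((60, 60)))
        assert mask.n_labels == 0

    def test_recovers_rendered_nuclei(self, small_field):
        fp, _, movie, truth = small_field
        his = max_project(movie, 0)
        mask = segment_method1(his[0])
        assert mask.n_labels == fp.n_nuclei
        ious = _iou_per_nucleus(mask.labels, truth.masks[0], fp.n_nuclei)
        assert (ious >= 0.7).mean() >= 0.95


def _iou_per_nucleus(seg, true, n):
    out = []
    for nid in range(1, n + 1):
        tm = true == nid
        labs, counts = np.unique(seg[tm], return_counts=True)
        fg = labs > 0
        if not fg.any():
            out.append(0.0)
            continue
        best = labs[fg][np.argmax(counts[fg])]
        sm = seg == best
        out.append((tm & sm).sum() / (tm | sm).sum())
    return np.asarray(out)


class TestMethod2:
    def test_recovers_rendered_nuclei_and_centroids(self, small_field):
        from scipy import ndimage as ndi
        fp, _, movie, truth = small_field
        his = max_project(movie, 0)
        ms2 = max_project(movie, 1)
        mask = segment_method2(his[0], ms2[0])
        assert mask.n_labels == fp.n_nuclei
        ious = _iou_per_nucleus(mask.labels, truth.masks[0], fp.n_nuclei)
        assert (ious >= 0.7).mean() >= 0.95
        # centroid agreement with ground truth within 1 px
        ids = np.unique(mask.labels)[1:]
        segc = np.asarray(ndi.center_of_mass(mask.labels > 0, mask.labels, ids))
        for tr in truth.tracks:
            gy, gx = tr.centroids[0]
            d = np.hypot(segc[:, 0] - gy, segc[:, 1] - gx).min()
            assert d <= 1.0

    def test_spot_outside_boundary_pulled_into_nearest_nucleus(self):
        img = synthetic_disks(centers=((60, 40), (60, 90)), r=10)
        ms2 = np.zeros((120, 120))
        ms2[60:63, 53:56] = 100.0   # dot 3 px outside the first nucleus
        mask = segment_method2(img, ms2)
        lab_at_spot = mask.labels[61, 54]
        assert lab_at_spot > 0
        # it must be the nucleus whose boundary is nearest (the left one)
        assert lab_at_spot == mask.labels[60, 40]
        # refinement guarantee: every dot pixel is inside some label
        assert np.all(mask.labels[ms2 > 2 * ms2.mean()] > 0)

    def test_subthreshold_ms2_noise_is_a_noop(self):
        img = synthetic_disks()
        rng = np.random.default_rng(4)
        ms2 = rng.uniform(0, 10, img.shape)  # nothing exceeds 2x mean by area
        with_spots = segment_method2(img, ms2)
        without = segment_method2(img, None)
        assert np.array_equal(with_spots.labels, without.labels)

    def test_voronoi_labels_are_disjoint_single_components(self, small_field):
        from scipy import ndimage as ndi
        _, _, movie, _ = small_field
        mask = segment_method2(max_project(movie, 0)[0],
                               max_project(movie, 1)[0])
        for lab in mask.label_ids():
            _, n = ndi.label(mask.labels == lab)
            assert n == 1

    def test_flat_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = segment_method2(np.zeros((50, 50)), None)
        assert mask.n_labels == 0


class TestApplyOverride:
    def test_zero_override_is_identity(self):
        m = LabelMask(0, np.ones((10, 10), np.uint16))
        out = apply_override(m, np.zeros((10, 10), np.uint16))
        assert np.array_equal(out.labels, m.labels)

    def test_full_override_returned_verbatim(self):
        m = LabelMask(0, np.ones((10, 10), np.uint16))
        ov = np.full((10, 10), 7, np.uint16)
        out = apply_override(m, ov)
        assert np.array_equal(out.labels, ov)
        assert out.method == "override"

    def test_partial_override_changes_only_its_region(self):
        m = LabelMask(0, np.ones((10, 10), np.uint16))
        ov = np.zeros((10, 10), np.uint16)
        ov[:3, :3] = 9
        out = apply_override(m, ov)
        assert np.all(out.labels[:3, :3] == 9)
        assert np.all(out.labels[3:, :] == 1)

    def test_shape_mismatch_rejected(self):
        m = LabelMask(0, np.ones((10, 10), np.uint16))
        with pytest.raises(ValueError, match="shape"):
            apply_override(m, np.zeros((5, 5), np.uint16))
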