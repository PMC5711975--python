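"""Segmentation stage: background, thresholding, nuclei, group labeling."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from ciquant import segmentation
from ciquant.datatypes import INDIVIDUAL, RegionMasks
from ciquant.errors import DegenerateInputError


def _render_blobs(shape, centers, radius, amplitude, offset=0.0):
    img = np.full(shape, float(offset))
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = amplitude + offset
    return img


class TestBackgroundCorrection:
    @pytest.mark.parametrize("method", ["rolling_ball", "mode_subtract"])
    def test_constant_image_maps_to_zero(self, method):
        out = segmentation.correct_background(np.full((64, 64), 37.0), method)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_all_zero_unchanged(self):
        out = segmentation.correct_background(np.zeros((32, 32)))
        assert (out == 0).all()

    @pytest.mark.parametrize("method", ["rolling_ball", "mode_subtract"])
    def test_offset_invariance_of_foreground_means(self, method):
        """Adding a constant offset changes foreground means by < 1%."""
        centers = [(30, 30), (70, 80), (100, 40)]
        base = _render_blobs((128, 128), centers, 6, 150.0)
        shifted = _render_blobs((128, 128), centers, 6, 150.0, offset=50.0)
        fg = base > 0
        m0 = segmentation.correct_background(base, method)[fg].mean()
        m50 = segmentation.correct_background(shifted, method)[fg].mean()
        assert m50 == pytest.approx(m0, rel=0.01)

    def test_smooth_gradient_background_removed(self, noisy_slide):
        """Foreground keratin means on a noisy slide come back within a few
        percent of the rendered amplitude after correction."""
        params, image, truth = noisy_slide
        corrected = segmentation.correct_background(image["keratin"],
                                                    "mode_subtract")
        from scipy import ndimage
        interior = ndimage.binary_erosion(truth.tumor_mask, iterations=4)
        mean = corrected[interior].mean()
        assert mean == pytest.approx(truth.amplitudes["keratin"], rel=0.07)

    def test_output_nonnegative(self, noisy_slide):
        _, image, _ = noisy_slide
        out = segmentation.correct_background(image["vimentin"],
                                              "mode_subtract")
        assert (out >= 0).all()


class TestThreshold:
    def test_bimodal_otsu_exact(self):
        img = _render_blobs((96, 96), [(48, 48)], 10, 190.0, offset=10.0)
        mask = segmentation.threshold_channel(img, "otsu")
        np.testing.assert_array_equal(mask, img == 200.0)

    def test_fixed_zero_on_positive_image(self):
        img = np.full((16, 16), 3.0)
        assert segmentation.threshold_channel(img, "fixed:0").all()

    def test_fixed_cut_is_strict(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = segmentation.threshold_channel(img, "fixed:2")
        np.testing.assert_array_equal(mask, img > 2)

    def test_constant_channel_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segmentation.threshold_channel(np.full((8, 8), 5.0), "otsu")

    def test_otsu_recovers_tumor_mask_on_noisefree_slide(self, noisefree_slide):
        """Pixelwise agreement with ground truth >= 99% on clean renders."""
        _, image, truth = noisefree_slide
        mask = segmentation.threshold_channel(image["keratin"], "otsu")
        agreement = (mask == truth.tumor_mask).mean()
        assert agreement >= 0.99


class TestExclusions:
    def test_empty_exclusion_identity(self, rng):
        tumor = rng.random((32, 32)) > 0.5
        out = segmentation.apply_exclusions(tumor, np.zeros((32, 32), bool))
        np.testing.assert_array_equal(out, tumor)

    def test_total_exclusion_empties_mask(self, rng):
        tumor = rng.random((32, 32)) > 0.5
        out = segmentation.apply_exclusions(tumor, np.ones((32, 32), bool))
        assert not out.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation.apply_exclusions(np.zeros((8, 8), bool),
                                          np.zeros((9, 8), bool))

    def test_duct_exclusion_recovers_true_tumor_area(self):
        """A keratin-positive normal duct inflates the thresholded area;
        the supplied exclusion mask brings it back to the true value."""
        from tests.conftest import small_slide_params
        from ciquant import synthetic
        params = small_slide_params(n_ducts=2, seed=11)
        image, truth = synthetic.generate_slide(params)
        mask = segmentation.threshold_channel(image["keratin"], "otsu")
        with_ducts = mask.sum()
        cleaned = segmentation.apply_exclusions(mask, truth.exclusion_mask)
        true_area = truth.tumor_mask.sum()
        assert with_ducts > 1.05 * true_area
        assert cleaned.sum() == pytest.approx(true_area, rel=0.02)


class TestNucleusDetection:
    def test_single_nucleus(self):
        img = _render_blobs((64, 64), [(30.0, 33.0)], 4, 255.0)
        coords = segmentation.detect_nuclei(img, pixel_size=0.5)
        assert len(coords) == 1
        assert np.hypot(*(coords[0] - (30, 33))) <= 2.0

    def test_two_separated_nuclei(self):
        # 20 um apart at 0.5 um/px = 40 px
        img = _render_blobs((96, 96), [(30, 30), (30, 70)], 4, 255.0)
        coords = segmentation.detect_nuclei(img, pixel_size=0.5)
        assert len(coords) == 2

    def test_empty_image(self):
        assert len(segmentation.detect_nuclei(np.zeros((32, 32)))) == 0

    def test_count_on_noisy_slide_within_2pct(self, noisy_slide):
        params, image, truth = noisy_slide
        corrected = segmentation.correct_background(image["nuclear"],
                                                    "mode_subtract")
        coords = segmentation.detect_nuclei(corrected,
                                            pixel_size=params.pixel_size)
        expected = len(truth.cell_table) + params.n_stromal_cells
        assert len(coords) == pytest.approx(expected, rel=0.02)


class TestGroupLabeling:
    def test_one_blob_five_nuclei(self):
        mask = np.zeros((64, 64), bool)
        mask[20:44, 10:54] = True
        nuclei = np.array([[30, 15], [30, 25], [30, 35], [30, 45], [30, 50]])
        groups, cells = segmentation.label_groups(mask, nuclei)
        assert len(groups) == 1
        assert groups[0].cell_count == 5
        assert {c.group_id for c in cells} == {groups[0].group_id}

    def test_three_isolated_singles(self):
        mask = np.zeros((64, 64), bool)
        for cy, cx in [(10, 10), (30, 40), (55, 20)]:
            mask[cy - 2:cy + 3, cx - 2:cx + 3] = True
        nuclei = np.array([[10, 10], [30, 40], [55, 20]])
        groups, cells = segmentation.label_groups(mask, nuclei)
        assert groups == []
        assert all(c.group_id == INDIVIDUAL for c in cells)
        assert all(c.keratin_positive for c in cells)

    def test_single_nucleus_near_group_is_merged(self):
        """A 1-nucleus blob within the neighbor radius of a group is not
        individual: it joins that group."""
        mask = np.zeros((64, 64), bool)
        mask[20:30, 10:40] = True          # group blob, 2 nuclei
        mask[20:26, 44:50] = True          # satellite 4 px away (2 um)
        nuclei = np.array([[24.0, 15.0], [24.0, 35.0], [23.0, 47.0]])
        groups, cells = segmentation.label_groups(mask, nuclei, pixel_size=0.5)
        assert len(groups) == 1
        assert groups[0].cell_count == 3
        assert all(c.group_id == groups[0].group_id for c in cells)

    def test_empty_mask_yields_empty_lists(self):
        groups, cells = segmentation.label_groups(
            np.zeros((16, 16), bool), np.empty((0, 2)))
        assert groups == [] and cells == []

    def test_cell_conservation(self, noisefree_slide):
        """grouped + individual keratin-positive cells = all keratin-positive
        nuclei (nothing lost or double-counted)."""
        params, image, truth = noisefree_slide
        mask = segmentation.threshold_channel(image["keratin"], "otsu")
        coords = segmentation.detect_nuclei(image["nuclear"],
                                            pixel_size=params.pixel_size)
        groups, cells = segmentation.label_groups(mask, coords,
                                                  pixel_size=params.pixel_size)
        kpos = [c for c in cells if c.keratin_positive]
        n_grouped = sum(1 for c in kpos if c.group_id != INDIVIDUAL)
        n_ind = sum(1 for c in kpos if c.group_id == INDIVIDUAL)
        assert n_grouped + n_ind == len(kpos)
        assert sum(g.cell_count for g in groups) == n_grouped

    def test_labels_match_ground_truth(self, noisefree_slide):
        """Per-cell grouped/individual calls agree with generator truth."""
        params, image, truth = noisefree_slide
        mask = segmentation.threshold_channel(image["keratin"], "otsu")
        coords = segmentation.detect_nuclei(image["nuclear"],
                                            pixel_size=params.pixel_size)
        _, cells = segmentation.label_groups(mask, coords,
                                             pixel_size=params.pixel_size)
        kpos = [c for c in cells if c.keratin_positive]
        pts = np.array([c.centroid for c in kpos])
        is_ind = np.array([c.group_id == INDIVIDUAL for c in kpos])
        ct = truth.cell_table
        d, idx = cKDTree(pts).query(ct[["row", "col"]].to_numpy())
        matched = d < 4
        agree = matched & (is_ind[idx] == (ct.group_id == 0).to_numpy())
        assert agree.mean() >= 0.99


class TestCompartments:
    def test_adipose_core_fibrous_assignment(self):
        tissue = np.ones((20, 20), bool)
        adipose = np.zeros((20, 20), bool)
        adipose[:, 12:] = True
        core = np.zeros((20, 20), bool)
        core[:, :5] = True
        masks = RegionMasks(tissue=tissue, adipose=adipose,
                            tumor=np.zeros((20, 20), bool), core=core)
        from ciquant.datatypes import CellRecord
        cells = [CellRecord((10.0, 15.0), 1, True),
                 CellRecord((10.0, 2.0), 1, True),
                 CellRecord((10.0, 8.0), 1, True)]
        out = segmentation.assign_compartments(cells, masks)
        assert [c.compartment for c in out] == ["adipose", "core", "fibrous"]

    def test_all_false_adipose_mask(self):
        tissue = np.ones((10, 10), bool)
        masks = RegionMasks(tissue=tissue, adipose=np.zeros((10, 10), bool),
                            tumor=np.zeros((10, 10), bool))
        from ciquant.datatypes import CellRecord
        cells = [CellRecord((5.0, 5.0), 1, True)]
        out = segmentation.assign_compartments(cells, masks)
        assert out[0].compartment == "fibrous"

    def test_compartments_match_ground_truth(self, noisefree_slide,
                                             truth_masks):
        """Compartment labels at true centroids equal the generator's."""
        from ciquant.datatypes import CellRecord
        _, _, truth = noisefree_slide
        ct = truth.cell_table
        cells = [CellRecord((r.row, r.col), int(r.group_id), True)
                 for r in ct.itertuples()]
        out = segmentation.assign_compartments(cells, truth_masks)
        got = [c.compartment for c in out]
        assert (np.array(got) == ct.compartment.to_numpy()).mean() > 0.97


class TestSceneInvariance:
    def test_translation_leaves_areas_unchanged(self, noisefree_slide):
        """Rolling the whole scene does not change measured areas."""
        _, image, truth = noisefree_slide
        mask = segmentation.threshold_channel(image["keratin"], "otsu")
        shifted = np.roll(image["keratin"], (7, -11), axis=(0, 1))
        mask2 = segmentation.threshold_channel(shifted, "otsu")
        assert mask2.sum() == mask.sum()
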