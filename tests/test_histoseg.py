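import numpy as np
import pytest

import gelquant as gq
from gelquant import histoseg as hs
from gelquant import morphometry as mm
from gelquant import synthgen


def _image_from_od(hema, second, pair="HE"):
    """Render OD fields through the forward stain model, as the generator does."""
    names = hs.STAIN_PAIRS[pair]
    od_rgb = (
        np.asarray(hema)[..., None] * hs.STAIN_VECTORS[names[0]]
        + np.asarray(second)[..., None] * hs.STAIN_VECTORS[names[1]]
    )
    return hs.SectionImage(hs.od_to_rgb(od_rgb), um_per_px=0.5)


class TestDeconvolution:
    def test_white_image_has_zero_od(self):
        image = hs.SectionImage(np.full((8, 8, 3), 255, dtype=np.uint8), 0.5)
        od = hs.deconvolve_stains(image, "HE")
        assert np.allclose(od.hematoxylin_od, 0.0)
        assert np.allclose(od.second_stain_od, 0.0)

    @pytest.mark.parametrize("pair", ["HE", "H-DAB"])
    def test_single_stain_goes_to_its_own_channel(self, pair):
        hema = np.full((6, 6), 0.5)
        image = _image_from_od(hema, np.zeros((6, 6)), pair)
        od = hs.deconvolve_stains(image, pair)
        assert od.hematoxylin_od.mean() == pytest.approx(0.5, abs=0.02)
        assert od.second_stain_od.mean() == pytest.approx(0.0, abs=0.02)
        # and symmetrically for the second stain
        image2 = _image_from_od(np.zeros((6, 6)), hema, pair)
        od2 = hs.deconvolve_stains(image2, pair)
        assert od2.second_stain_od.mean() == pytest.approx(0.5, abs=0.02)
        assert od2.hematoxylin_od.mean() == pytest.approx(0.0, abs=0.02)

    def test_render_unmix_roundtrip_within_tolerance(self, rng):
        hema = rng.uniform(0, 1.0, (32, 32))
        dab = rng.uniform(0, 1.0, (32, 32))
        od = hs.deconvolve_stains(_image_from_od(hema, dab, "H-DAB"), "H-DAB")
        assert np.mean(np.abs(od.hematoxylin_od - hema)) <= 0.05
        assert np.mean(np.abs(od.second_stain_od - dab)) <= 0.05

    def test_dab_od_recovered_for_rendered_positive(self):
        dab = np.full((8, 8), 0.8)
        od = hs.deconvolve_stains(_image_from_od(np.zeros((8, 8)), dab, "H-DAB"), "H-DAB")
        assert od.second_stain_od.mean() == pytest.approx(0.8, abs=0.05)

    def test_unknown_pair_rejected(self):
        image = hs.SectionImage(np.full((4, 4, 3), 255, dtype=np.uint8), 0.5)
        with pytest.raises(ValueError):
            hs.deconvolve_stains(image, "Masson")


class TestSegmentSolid:
    def test_all_white_image_is_all_hollow_with_warning(self):
        image = hs.SectionImage(np.full((32, 32, 3), 255, dtype=np.uint8), 0.5)
        with pytest.warns(hs.EmptySectionWarning):
            solid = hs.segment_solid(image)
        assert solid.sum() == 0

    def test_uniformly_stained_image_is_all_solid(self):
        image = _image_from_od(np.full((32, 32), 0.02), np.full((32, 32), 0.25))
        assert hs.segment_solid(image).all()

    def test_porosity_recovered_on_synthetic_section(self, he_section, he_analysis):
        _image, truth = he_section
        row, _ = he_analysis
        assert abs(row["porosity_pct"] - 100.0 * truth.true_porosity) <= 1.0


def _nucleus_od(disks, shape=(96, 96), od=0.8, um_per_px=0.5):
    """ODChannels with hematoxylin disks at (cy, cx, r)."""
    hema = np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for cy, cx, r in disks:
        hema[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = od
    return hs.ODChannels(hema, np.zeros(shape), "eosin", um_per_px)


class TestSegmentNuclei:
    def test_two_overlapping_disks_split_into_two(self):
        # r=5 disks with centres 8 px apart overlap by ~10% of each disk's area
        od = _nucleus_od([(40, 40, 5), (40, 48, 5)])
        labels = hs.segment_nuclei(od)
        assert labels.max() == 2

    def test_well_separated_grid_counted_exactly(self):
        disks = [(12 + 18 * i, 12 + 18 * j, 4) for i in range(10) for j in range(10)]
        od = _nucleus_od(disks, shape=(200, 200))
        labels = hs.segment_nuclei(od)
        assert abs(labels.max() - 100) <= 2

    def test_blank_od_gives_zero_labels(self):
        od = hs.ODChannels(np.zeros((32, 32)), np.zeros((32, 32)), "eosin", 0.5)
        assert hs.segment_nuclei(od).max() == 0

    def test_labels_contiguous_from_one(self, ihc_analysis):
        _row, inter = ihc_analysis
        labels = inter["nucleus_labels"]
        ids = np.unique(labels)
        assert ids[0] == 0
        np.testing.assert_array_equal(ids[1:], np.arange(1, labels.max() + 1))


class TestLabelClusters:
    def test_single_isolated_nucleus_forms_one_cluster(self):
        od = _nucleus_od([(48, 48, 4.2)])  # ~14 um^2 at 0.5 um/px
        labels = hs.segment_nuclei(od)
        solid = np.ones(labels.shape, dtype=bool)
        cluster_labels, records = hs.label_clusters(solid, labels, 0.5)
        assert len(records) == 1
        assert records[0].area_um2 >= 14.0

    def test_no_nuclei_no_clusters(self):
        solid = np.ones((64, 64), dtype=bool)
        cluster_labels, records = hs.label_clusters(solid, np.zeros((64, 64), dtype=int), 0.5)
        assert records == []
        assert cluster_labels.max() == 0

    def test_cluster_pixels_contained_in_solid(self, he_analysis):
        _row, inter = he_analysis
        assert not (inter["cluster_labels"][~inter["solid_mask"]] > 0).any()

    def test_requested_cluster_count_recovered(self, he_section, he_analysis):
        _image, truth = he_section
        row, _ = he_analysis
        assert abs(row["n_clusters"] - len(truth.clusters)) <= 1


class TestPoreAreaStats:
    def _mask_with_pore_areas_px(self, areas_px):
        mask = np.zeros((80, 200), dtype=bool)
        x = 5
        for a in areas_px:
            side = int(np.ceil(np.sqrt(a)))
            block = np.zeros((side, side), dtype=bool)
            block.flat[:a] = True
            mask[5 : 5 + side, x : x + side] = block
            x += side + 5
        return mask

    def test_known_areas_median_and_iqr(self):
        # pores of 1, 2, 3, 10 um^2 at 0.5 um/px (4, 8, 12, 40 px)
        mask = self._mask_with_pore_areas_px([4, 8, 12, 40])
        stats = hs.pore_area_stats(mask, 0.5)
        assert stats.n_pores == 4
        assert stats.median_um2 == pytest.approx(2.5)
        expected_iqr = np.percentile([1, 2, 3, 10], 75) - np.percentile([1, 2, 3, 10], 25)
        assert stats.iqr_um2 == pytest.approx(expected_iqr)

    def test_single_pore_degenerate_stats(self):
        mask = self._mask_with_pore_areas_px([16])
        stats = hs.pore_area_stats(mask, 0.5)
        assert stats.n_pores == 1
        assert stats.iqr_um2 == 0.0
        assert stats.skewness == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(hs.NoPoresError):
            hs.pore_area_stats(np.zeros((10, 10), dtype=bool), 0.5)

    def test_lognormal_mask_right_skewed(self):
        mask, _truth = synthgen.generate_pore_mask(500, (3.0, 0.9), 400.0 * 400.0, seed=2)
        stats = hs.pore_area_stats(mask, 0.5)
        assert stats.n_pores == 500
        assert stats.skewness > 0.0


class TestSectionImageIO:
    def test_png_roundtrip(self, tmp_path, he_section):
        image, _ = he_section
        path = tmp_path / "section.png"
        image.save(path)
        back = hs.SectionImage.load(path, image.um_per_px)
        np.testing.assert_array_equal(back.pixels, image.pixels)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            hs.SectionImage(np.zeros((4, 4), dtype=np.uint8), 0.5)
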