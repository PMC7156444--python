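import json

import numpy as np
import pandas as pd
import pytest

import gelquant as gq
from gelquant import histoseg, morphometry, synthgen


class TestSectionGenerator:
    def test_identical_seed_bit_identical_output(self):
        a, _ = gq.generate_section(gq.SectionParams(seed=42))
        b, _ = gq.generate_section(gq.SectionParams(seed=42))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self):
        a, _ = gq.generate_section(gq.SectionParams(seed=1))
        b, _ = gq.generate_section(gq.SectionParams(seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_degenerate_all_solid_section(self):
        params = gq.SectionParams(
            seed=0, target_porosity=0.0, clusters_per_class=(0, 0, 0)
        )
        _image, truth = gq.generate_section(params)
        assert truth.true_porosity == 0.0
        assert truth.hollow_mask.sum() == 0
        assert len(truth.clusters) == 0

    def test_requested_class_counts_exact(self, he_section):
        _image, truth = he_section  # clusters_per_class defaults to (5, 3, 2)
        counts = truth.clusters["size_class"].value_counts()
        assert counts.get("small", 0) == 5
        assert counts.get("medium", 0) == 3
        assert counts.get("large", 0) == 2

    def test_truth_areas_roundtrip_through_classifier(self, he_section):
        _image, truth = he_section
        for row in truth.clusters.itertuples():
            assert morphometry.classify_cluster_size(row.area_um2) == row.size_class

    def test_target_porosity_hit_within_half_point(self):
        _image, truth = gq.generate_section(gq.SectionParams(seed=5, target_porosity=0.149))
        measured = morphometry.porosity(~truth.hollow_mask)
        assert abs(measured - 14.9) <= 0.5

    def test_every_nucleus_references_a_cluster(self, he_section):
        _image, truth = he_section
        assert set(truth.nuclei["cluster_id"]) <= set(truth.clusters["id"])
        assert (truth.nuclei["area_um2"] > 0).all()

    def test_stain_separability_strictly_ordered(self, ihc_section):
        image, truth = ihc_section
        od = histoseg.deconvolve_stains(image, "H-DAB")
        means = {}
        for cls in ("negative", "weak", "moderate", "strong"):
            sub = truth.nuclei[truth.nuclei.intensity_class == cls]
            ys = sub["cy_px"].round().astype(int)
            xs = sub["cx_px"].round().astype(int)
            means[cls] = float(od.second_stain_od[ys, xs].mean())
        assert means["strong"] > means["moderate"] > means["weak"] > means["negative"]

    def test_infeasible_layout_rejected(self):
        with pytest.raises(synthgen.InfeasibleLayoutError):
            gq.SectionParams(
                width_px=128, height_px=128, clusters_per_class=(0, 0, 8), seed=0
            )

    def test_invalid_intensity_mix_rejected(self):
        with pytest.raises(ValueError, match="intensity_mix"):
            gq.SectionParams(intensity_mix=(0.5, 0.5, 0.5))

    def test_phase_rates_must_sum_below_one(self):
        with pytest.raises(ValueError, match="phase_rates"):
            gq.SectionParams(phase_rates=(0.6, 0.6))


class TestPoreMaskGenerator:
    def test_single_pore_single_component(self):
        mask, truth = gq.generate_pore_mask(1, (3.0, 0.5), 100.0 * 100.0, seed=0)
        from skimage import measure

        assert measure.label(mask).max() == 1
        assert len(truth.pore_areas_um2) == 1

    def test_component_count_matches_requested(self):
        mask, truth = gq.generate_pore_mask(200, (3.0, 0.8), 300.0 * 300.0, seed=1)
        from skimage import measure

        assert measure.label(mask, connectivity=2).max() == 200

    def test_lower_mu_gives_lower_sample_median(self):
        _m1, t_hi = gq.generate_pore_mask(500, (3.0, 0.9), 400.0 * 400.0, seed=3)
        _m2, t_lo = gq.generate_pore_mask(500, (2.6, 0.9), 400.0 * 400.0, seed=3)
        assert np.median(t_lo.pore_areas_um2) < np.median(t_hi.pore_areas_um2)

    def test_deterministic(self):
        m1, _ = gq.generate_pore_mask(50, (3.0, 0.8), 200.0 * 200.0, seed=9)
        m2, _ = gq.generate_pore_mask(50, (3.0, 0.8), 200.0 * 200.0, seed=9)
        np.testing.assert_array_equal(m1, m2)

    def test_overfilled_frame_rejected(self):
        with pytest.raises(synthgen.InfeasibleLayoutError):
            gq.generate_pore_mask(500, (6.0, 0.5), 100.0 * 100.0, seed=0)


class TestCurveGenerator:
    def test_noise_free_curve_is_exactly_linear(self):
        params = gq.CurveParams(E_true_kpa=1.11, toe_coeff=0.0, noise_sd_kpa=0.0, seed=0)
        curve, truth = gq.generate_stress_strain(params)
        np.testing.assert_allclose(curve.stress_kpa, 1.11 * curve.strain)
        assert truth.E_true_kpa == 1.11

    def test_two_point_line_value(self):
        params = gq.CurveParams(
            E_true_kpa=0.28, max_strain=0.1, n_points=21, toe_coeff=0.0, noise_sd_kpa=0.0
        )
        curve, _ = gq.generate_stress_strain(params)
        assert curve.strain[0] == 0.0
        assert curve.stress_kpa[0] == 0.0
        assert curve.stress_kpa[-1] == pytest.approx(0.028)

    def test_deterministic(self):
        c1, _ = gq.generate_stress_strain(gq.CurveParams(seed=4))
        c2, _ = gq.generate_stress_strain(gq.CurveParams(seed=4))
        np.testing.assert_array_equal(c1.stress_kpa, c2.stress_kpa)

    def test_toe_term_is_cubic(self):
        params = gq.CurveParams(E_true_kpa=1.0, toe_coeff=0.5, noise_sd_kpa=0.0)
        curve, _ = gq.generate_stress_strain(params)
        np.testing.assert_allclose(curve.stress_kpa, curve.strain + 0.5 * curve.strain**3)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gq.CurveParams(E_true_kpa=-1.0)
        with pytest.raises(ValueError):
            gq.CurveParams(max_strain=0.6)
        with pytest.raises(ValueError):
            gq.CurveParams(n_points=10)


class TestTruthBundle:
    def test_orphan_nucleus_rejected(self):
        clusters = pd.DataFrame({"id": [1], "area_um2": [100.0]})
        nuclei = pd.DataFrame({"id": [1], "cluster_id": [2], "area_um2": [10.0]})
        with pytest.raises(ValueError, match="cluster id"):
            synthgen.TruthBundle(clusters=clusters, nuclei=nuclei)

    def test_json_and_csv_serialisation(self, tmp_path, he_section):
        _image, truth = he_section
        truth.write(tmp_path, "sec")
        payload = json.loads((tmp_path / "sec_truth.json").read_text())
        assert payload["true_porosity"] == pytest.approx(truth.true_porosity)
        clusters = pd.read_csv(tmp_path / "sec_clusters.csv")
        assert len(clusters) == len(truth.clusters)


class TestConditionPresets:
    def test_intensity_mix_mean_weight_roundtrip(self):
        for mu in (1.0, 1.6, 2.0, 2.8, 3.0):
            w, m, s = synthgen.intensity_mix_for_mean_weight(mu)
            assert w + m + s == pytest.approx(1.0)
            assert w * 1 + m * 2 + s * 3 == pytest.approx(mu)

    def test_presets_build_valid_generator_params(self):
        for (label, weeks) in synthgen.CONDITION_PRESETS:
            params = synthgen.section_params_for_condition(label, weeks, seed=0)
            assert 0.0 < params.positive_fraction < 1.0
            assert 0.0 < params.target_porosity < 0.3
            assert sum(params.phase_rates) <= 1.0
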