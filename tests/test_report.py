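import json

import numpy as np
import pytest

from gelquant import report
from gelquant.report import AggregateRow, ConditionKey


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.2, "ns"),
            (0.05, "ns"),  # strict inequality at the 0.05 boundary
            (0.049, "*"),
            (0.01, "*"),
            (0.009, "**"),
            (0.001, "**"),
            (0.0005, "***"),
            (1.0, "ns"),
        ],
    )
    def test_caption_convention(self, p, expected):
        assert report.significance_stars(p) == expected

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            report.significance_stars(bad)


class TestAggregate:
    def test_two_values_mean_and_sd(self):
        (row,) = report.aggregate([2.0, 4.0])
        assert row.mean == 3.0
        assert row.dispersion == pytest.approx(np.sqrt(2.0))
        assert row.n_replicates == 2

    def test_single_replicate_flagged_with_zero_dispersion(self):
        (row,) = report.aggregate([14.9])
        assert row.mean == 14.9
        assert row.dispersion == 0.0
        assert row.single_replicate

    def test_sem_is_sd_over_sqrt_n(self):
        (sd_row,) = report.aggregate([1.0, 2.0, 3.0, 4.0], dispersion="sd")
        (sem_row,) = report.aggregate([1.0, 2.0, 3.0, 4.0], dispersion="sem")
        assert sem_row.dispersion == pytest.approx(sd_row.dispersion / 2.0)

    def test_mapping_input_keeps_condition_and_metric(self):
        key = (ConditionKey("0% AlgMA", 2), "porosity_pct")
        rows = report.aggregate({key: [10.0, 20.0]})
        assert rows[0].condition == key[0]
        assert rows[0].metric == "porosity_pct"

    def test_order_invariant(self):
        a = report.aggregate([5.0, 1.0, 3.0])[0]
        b = report.aggregate([3.0, 5.0, 1.0])[0]
        assert a.mean == b.mean and a.dispersion == b.dispersion


class TestDeltaOverTime:
    def _row(self, mean, weeks, metric="porosity_pct", label="0% AlgMA"):
        return AggregateRow(ConditionKey(label, weeks), metric, mean, 0.0, "sd", 3)

    def test_signed_difference(self):
        assert report.delta_over_time(self._row(14.9, 2), self._row(23.8, 4)) == pytest.approx(8.9)

    def test_antisymmetric(self):
        a, b = self._row(10.0, 2), self._row(16.0, 4)
        assert report.delta_over_time(a, b) == -report.delta_over_time(b, a)

    def test_metric_mismatch_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            report.delta_over_time(self._row(1.0, 2), self._row(2.0, 4, metric="h_score"))

    def test_stiffness_mismatch_rejected(self):
        with pytest.raises(ValueError, match="stiffness"):
            report.delta_over_time(self._row(1.0, 2), self._row(2.0, 4, label="2% AlgMA"))


class TestChiSquare:
    def test_identical_tables_no_association(self):
        chi2, p, stars = report.chi_square_positivity(50, 50, 50, 50)
        assert chi2 == 0.0
        assert p == 1.0
        assert stars == "ns"

    def test_hand_computed_pearson_value(self):
        # (90,10) vs (10,90): all expected counts are 50, sum (O-E)^2/E = 4*32 = 128
        chi2, p, stars = report.chi_square_positivity(90, 10, 10, 90)
        assert chi2 == pytest.approx(128.0)
        assert stars == "***"

    def test_doubling_counts_doubles_statistic(self):
        chi2, _, _ = report.chi_square_positivity(30, 20, 15, 35)
        chi2x2, _, _ = report.chi_square_positivity(60, 40, 30, 70)
        assert chi2x2 == pytest.approx(2 * chi2)

    def test_yates_correction_shrinks_statistic(self):
        plain, _, _ = report.chi_square_positivity(30, 20, 15, 35)
        corrected, _, _ = report.chi_square_positivity(30, 20, 15, 35, correction=True)
        assert corrected < plain

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            report.chi_square_positivity(0, 50, 0, 50)


def _tiny_config(tmp_path=None):
    return dict(
        um_per_px=0.5,
        dispersion="sem",
        conditions=[
            dict(
                stiffness_label="0% AlgMA",
                timepoint_weeks=2,
                sections=[
                    dict(
                        synth=dict(
                            width_px=256,
                            height_px=256,
                            target_porosity=0.15,
                            clusters_per_class=(3, 2, 0),
                            stain_mode="IHC",
                            positive_fraction=0.5,
                            seed=21,
                        )
                    )
                ],
                curves=[
                    dict(synth=dict(E_true_kpa=0.33, seed=1)),
                    dict(synth=dict(E_true_kpa=0.33, seed=2)),
                ],
            ),
            dict(
                stiffness_label="2% AlgMA",
                timepoint_weeks=2,
                sections=[],
                curves=[
                    dict(synth=dict(E_true_kpa=1.75, seed=3)),
                    dict(synth=dict(E_true_kpa=1.75, seed=4)),
                ],
            ),
        ],
    )


class TestRunPipeline:
    def test_missing_inputs_fail_fast_listing_all(self, tmp_path):
        config = dict(
            conditions=[
                dict(
                    stiffness_label="0% AlgMA",
                    timepoint_weeks=2,
                    sections=[dict(image=str(tmp_path / "absent_a.png"))],
                    curves=[dict(csv=str(tmp_path / "absent_b.csv"))],
                )
            ]
        )
        with pytest.raises(FileNotFoundError) as err:
            report.run_pipeline(config)
        assert "absent_a.png" in str(err.value)
        assert "absent_b.csv" in str(err.value)

    def test_mechanics_only_config(self):
        config = _tiny_config()
        config["conditions"] = [c for c in config["conditions"] if not c["sections"]]
        result = report.run_pipeline(config)
        assert result["sections"] == []
        assert len(result["moduli"]) == 2
        assert result["moduli"][0]["E_kpa"] == pytest.approx(1.75, rel=0.05)

    def test_full_run_outputs_and_determinism(self, tmp_path):
        config = _tiny_config()
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        result = report.run_pipeline(config, out_a)
        report.run_pipeline(config, out_b)
        for name in ("sections.csv", "moduli.csv", "aggregates.csv", "comparisons.csv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()
        payload = json.loads((out_a / "report.json").read_text())
        assert payload["sections"][0]["porosity_pct"] == pytest.approx(15.0, abs=1.5)
        # moduli t-test between the two stiffness conditions is reported
        tests = [c for c in payload["comparisons"] if c["test"] == "t_welch"]
        assert tests and tests[0]["p_value"] < 0.05

    def test_demo_config_covers_all_conditions(self):
        cfg = report.demo_config(seed=0, n_replicates=1, n_curves=2, size_px=256)
        assert len(cfg["conditions"]) == 6
        labels = {(c["stiffness_label"], c["timepoint_weeks"]) for c in cfg["conditions"]}
        assert ("2% AlgMA", 4) in labels
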