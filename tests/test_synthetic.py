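"""Generator contracts: determinism, ground-truth conservation, cohort model."""

import numpy as np
import pytest

import invasivefront as iv
from invasivefront.synthetic import (
    CohortSpec,
    FeatureEffect,
    FieldTooCrowdedError,
    cohort_to_frame,
    default_section_specs,
    generate_cohort,
)


class TestFieldGeneration:
    def test_planted_counts_by_construction(self, rich_field):
        _, truth = rich_field
        assert truth.counts == {
            "tumor_bud": 3, "pdc": 2, "lvi": 1, "minimal_lvi": 1, "vessel": 2
        }

    def test_empty_field_has_only_rois(self, small_empty_field):
        _, truth = small_empty_field
        assert truth.counts == {
            "tumor_bud": 0, "pdc": 0, "lvi": 0, "minimal_lvi": 0, "vessel": 0
        }
        assert truth.area_pdc_um2 == 0.0
        assert set(np.unique(truth.roi)) <= {0, 1, 2, 3}

    def test_pdc_area_equals_pixel_count_oracle(self):
        spec = iv.FieldSpec(n_pdc=2, pdc_nucleus_counts=[5, 7],
                            pixel_size_um=0.5, seed=3)
        _, truth = iv.generate_field(spec)
        pdc_ids = [r.id for r in truth.objects if r.cls == "pdc"]
        # independent oracle: count labelled pixels in the emitted raster
        oracle_px = sum(int((truth.epithelial_labels == i).sum()) for i in pdc_ids)
        assert truth.area_pdc_um2 == pytest.approx(oracle_px * 0.25)

    def test_determinism_bit_identical(self, rich_field_spec):
        f1, t1 = iv.generate_field(rich_field_spec)
        f2, t2 = iv.generate_field(rich_field_spec)
        assert np.array_equal(f1.dapi, f2.dapi)
        assert np.array_equal(f1.panck, f2.panck)
        assert np.array_equal(f1.d240, f2.d240)
        assert np.array_equal(t1.nucleus_labels, t2.nucleus_labels)

    @pytest.mark.parametrize("seed", range(5))
    def test_label_raster_conservation(self, seed):
        """Planted records equal recounts from the emitted label rasters."""
        spec = iv.default_field_spec(seed)
        _, truth = iv.generate_field(spec)
        for rec in truth.objects:
            raster = (truth.vessel_labels if rec.cls == "vessel"
                      else truth.epithelial_labels)
            assert int((raster == rec.id).sum()) == rec.area_px
        n_label_nuclei = len(np.unique(truth.nucleus_labels)) - 1
        assert n_label_nuclei == truth.n_nuclei

    def test_crowded_field_raises(self):
        spec = iv.FieldSpec(
            image_size_px=(128, 128),
            n_pdc=30,
            pdc_nucleus_counts=[9] * 30,
            tumor_fraction=0.6,
            seed=0,
        )
        with pytest.raises(FieldTooCrowdedError):
            iv.generate_field(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            iv.FieldSpec(n_buds=1, bud_nucleus_counts=[5])  # buds are <=4 nuclei
        with pytest.raises(ValueError):
            iv.FieldSpec(n_pdc=1, pdc_nucleus_counts=[4])   # PDCs are >=5
        with pytest.raises(ValueError):
            iv.FieldSpec(n_vessels=1, lvi_events=[(2, 3)])  # vessel index range


class TestSections:
    def test_default_section_has_15_fields(self):
        specs = default_section_specs(seed=1)
        assert len(specs) == 15
        section = iv.generate_section(specs[:3])
        assert len(section) == 3

    def test_section_totals_equal_per_field_sums(self):
        specs = default_section_specs(seed=5, n_fields=4)
        section = iv.generate_section(specs)
        total_buds = sum(t.counts["tumor_bud"] for _, t in section)
        oracle = sum(s.n_buds for s in specs)
        assert total_buds == oracle

    def test_same_recipe_different_subseeds(self):
        base = dict(image_size_px=(256, 256), n_buds=2, bud_nucleus_counts=[2, 3])
        s1 = iv.FieldSpec(**base, seed=1)
        s2 = iv.FieldSpec(**base, seed=2)
        (f1, t1), (f2, t2) = iv.generate_field(s1), iv.generate_field(s2)
        assert t1.counts == t2.counts
        assert not np.array_equal(f1.dapi, f2.dapi)  # noise/placement differ


class TestCohorts:
    def test_empty_cohort(self):
        assert generate_cohort(CohortSpec(n_patients=0)) == []

    def test_event_fraction_matches_analytic_value(self):
        # single-arm exponential: P(event) = 1 - exp(-lambda * censor_time)
        spec = CohortSpec(n_patients=2000, baseline_hazard=0.01,
                          censor_time_months=60.0, seed=42)
        df = cohort_to_frame(generate_cohort(spec))
        expect = 1 - np.exp(-0.01 * 60)
        se = np.sqrt(expect * (1 - expect) / 2000)
        assert abs(df["event"].mean() - expect) < 3 * se

    def test_null_covariate_does_not_separate_survival(self):
        spec = CohortSpec(
            n_patients=2000, baseline_hazard=0.01,
            hr_map={"x": 1.0}, covariate_prevalence={"x": 0.5}, seed=7,
        )
        df = cohort_to_frame(generate_cohort(spec))
        res = iv.km_logrank(df["x"], df["time_months"], df["event"])
        assert res.p > 0.01  # no planted effect

    def test_planted_hr_recovered_by_cox(self):
        covered = 0
        for seed in range(10):
            spec = CohortSpec(
                n_patients=500, baseline_hazard=0.01,
                hr_map={"x": 4.0}, covariate_prevalence={"x": 0.5}, seed=seed,
            )
            df = cohort_to_frame(generate_cohort(spec))
            res = iv.cox_univariate(df["x"], df["time_months"], df["event"], "x")
            lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
            covered += lo <= 4.0 <= hi
        assert covered >= 8

    def test_feature_effect_means(self):
        spec = CohortSpec(
            n_patients=1000, covariate_prevalence={"g": 0.5},
            feature_effects={"f": FeatureEffect("g", 10.0, 50.0, 1.0)}, seed=1,
        )
        df = cohort_to_frame(generate_cohort(spec))
        assert df.loc[df["g"] == 1, "f"].mean() == pytest.approx(50.0, abs=0.5)
        assert df.loc[df["g"] == 0, "f"].mean() == pytest.approx(10.0, abs=0.5)

    def test_invalid_cohort_specs(self):
        with pytest.raises(ValueError):
            CohortSpec(hr_map={"x": -1.0})
        with pytest.raises(ValueError):
            CohortSpec(covariate_prevalence={"x": 1.5})
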