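"""Manifest structure, per-field extraction and per-patient collation."""

import numpy as np
import pytest

import invasivefront as iv
from invasivefront.features import (
    FeatureManifest,
    build_default_manifest,
    collate_patient,
    extract_field_features,
    manifest_default,
    masked_glcm_stats,
)
from invasivefront.segmentation import FieldImage


class TestManifest:
    def test_has_123_unique_entries_with_collation(self):
        m = manifest_default()
        assert len(m) == 123
        assert len(set(m.names)) == 123
        assert set(m.collations()) == {"sum", "mean"}

    def test_extensive_features_are_summed(self):
        m = manifest_default()
        by_name = {e.name: e for e in m.entries}
        for name in ("n_buds", "n_pdc", "n_lvi", "n_minimal_lvi",
                     "area_pdc_um2", "tumor_area_um2"):
            assert by_name[name].collation == "sum"
        for name in ("tumor_stroma_pct", "lvd_per_mm2", "pdc_mean_roundness",
                     "tumor_mean_intensity_dapi"):
            assert by_name[name].collation == "mean"

    def test_roundtrip_through_frame(self):
        m = build_default_manifest()
        again = FeatureManifest.from_frame(m.to_frame())
        assert again.names == m.names

    def test_packaged_csv_matches_builder(self):
        from importlib import resources

        import pandas as pd

        with resources.files("invasivefront").joinpath(
            "data/feature_manifest.csv"
        ).open() as fh:
            packaged = FeatureManifest.from_frame(pd.read_csv(fh))
        assert packaged.names == build_default_manifest().names

    def test_duplicate_names_rejected(self):
        e = manifest_default().entries
        with pytest.raises(ValueError):
            FeatureManifest([e[0], e[0]])


@pytest.fixture(scope="module")
def field_values(rich_field, rich_hierarchy, rich_classified):
    field, truth = rich_field
    vals = extract_field_features(field, rich_hierarchy, rich_classified)
    return dict(zip(manifest_default().names, vals)), truth


class TestExtraction:

    def test_headline_scalars_match_ground_truth(self, field_values):
        vals, truth = field_values
        assert vals["n_buds"] == truth.counts["tumor_bud"]
        assert vals["n_pdc"] == truth.counts["pdc"]
        assert vals["n_vessels"] == truth.counts["vessel"]
        assert vals["area_pdc_um2"] == pytest.approx(truth.area_pdc_um2, rel=0.05)

    def test_empty_class_policy(self, small_empty_field):
        field, _ = small_empty_field
        h = iv.segment_field(field)
        cf = iv.classify_objects(h)
        vals = dict(zip(manifest_default().names,
                        extract_field_features(field, h, cf)))
        assert vals["n_pdc"] == 0
        assert vals["pdc_sum_area_um2"] == 0.0
        assert np.isnan(vals["pdc_mean_roundness"])  # intensive + absent = missing

    def test_nucleus_tallies_conserved(self, field_values, rich_hierarchy):
        vals, _ = field_values
        tallied = (vals["n_nuclei_tumor"] + vals["n_nuclei_stroma"]
                   + vals["n_nuclei_tumor_bud"] + vals["n_nuclei_pdc"]
                   + vals["n_nuclei_intravascular"])
        assert tallied == len(rich_hierarchy.nuclei)

    def test_circular_object_roundness(self):
        # analytic oracle: a rasterized disc has roundness near 1
        img = np.zeros((64, 64), dtype=np.float32)
        yy, xx = np.mgrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2
        img[disc] = 200.0
        from invasivefront.features import _shape_props

        roundness, elong = _shape_props(disc)
        assert 0.9 <= roundness <= 1.0
        assert elong == pytest.approx(1.0, abs=0.05)

    def test_glcm_uniform_region_has_zero_contrast(self):
        img = np.full((32, 32), 7.0)
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        stats = masked_glcm_stats(img, mask)
        assert stats["contrast"] == 0.0
        assert stats["entropy"] == 0.0

    def test_glcm_noise_has_positive_entropy(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 30, size=(64, 64))
        mask = np.ones((64, 64), dtype=bool)
        stats = masked_glcm_stats(img, mask)
        assert stats["entropy"] > 2.0
        assert stats["contrast"] > 0.0


class TestCollation:
    def test_single_field_idempotence(self, rich_field, rich_hierarchy, rich_classified):
        field, _ = rich_field
        v = extract_field_features(field, rich_hierarchy, rich_classified)
        out = collate_patient([v], patient_id="p")
        finite = np.isfinite(v)
        assert np.allclose(out.values[finite], v[finite])

    def test_sum_and_mean_rules(self):
        m = manifest_default()
        base = np.zeros(len(m))
        i_buds = m.names.index("n_buds")
        i_ts = m.names.index("tumor_stroma_pct")
        vecs = []
        for buds in (1, 2, 0):
            v = base.copy()
            v[i_buds] = buds
            v[i_ts] = 40.0
            vecs.append(v)
        out = collate_patient(vecs)
        assert out["n_buds"] == 3.0       # extensive: summed across fields
        assert out["tumor_stroma_pct"] == 40.0  # intensive: averaged

    def test_mean_skips_missing_fields(self):
        m = manifest_default()
        i = m.names.index("pdc_mean_roundness")
        v1 = np.zeros(len(m)); v1[i] = 0.8
        v2 = np.zeros(len(m)); v2[i] = np.nan
        out = collate_patient([v1, v2])
        assert out["pdc_mean_roundness"] == pytest.approx(0.8)

    def test_all_missing_intensive_flagged_zero(self):
        m = manifest_default()
        i = m.names.index("pdc_mean_roundness")
        v = np.zeros(len(m)); v[i] = np.nan
        out = collate_patient([v, v])
        assert out["pdc_mean_roundness"] == 0.0
        assert "pdc_mean_roundness" in out.qc_flags

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            collate_patient([np.zeros(5)])
        with pytest.raises(ValueError):
            collate_patient([])

    def test_section_area_pdc_matches_concatenated_truth(self):
        specs = iv.default_section_specs(seed=9, n_fields=3)
        m = manifest_default()
        vecs, truths = [], []
        for spec in specs:
            field, truth = iv.generate_field(spec)
            h = iv.segment_field(field)
            cf = iv.classify_objects(h)
            vecs.append(extract_field_features(field, h, cf, m))
            truths.append(truth)
        out = collate_patient(vecs)
        oracle = sum(t.area_pdc_um2 for t in truths)
        if oracle > 0:
            assert out["area_pdc_um2"] == pytest.approx(oracle, rel=0.05)
        assert out["n_buds"] == sum(t.counts["tumor_bud"] for t in truths)
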