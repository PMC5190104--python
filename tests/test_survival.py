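"""Cut-point search, dichotomization, KM/log-rank, BH-FDR, Cox and the NPI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import invasivefront as iv
from invasivefront.survival import (
    CutoffConfig,
    PatientRecord,
    _logrank_chi2_scan,
    cox_backward_aic,
)
from invasivefront.synthetic import CohortSpec, cohort_to_frame, generate_cohort


def _cohort(seed, n=300, hr=4.0, prevalence=0.5, baseline=0.01):
    spec = CohortSpec(
        n_patients=n, baseline_hazard=baseline,
        hr_map={"x": hr}, covariate_prevalence={"x": prevalence}, seed=seed,
    )
    return cohort_to_frame(generate_cohort(spec))


class TestLogrankScan:
    def test_matches_lifelines_single_threshold(self):
        from lifelines.statistics import logrank_test

        df = _cohort(seed=0, n=120)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=len(df))
        thr = np.array([0.0])
        chi2 = _logrank_chi2_scan(vals, df["time_months"].to_numpy(),
                                  df["event"].to_numpy(), thr)[0]
        g = vals > 0
        ref = logrank_test(df["time_months"][g], df["time_months"][~g],
                           df["event"][g], df["event"][~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)


class TestOptimalCutpoint:
    def test_planted_step_hazard_recovered(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(
                n_patients=300, baseline_hazard=0.01,
                hr_map={"g": 4.0}, covariate_prevalence={"g": 0.5}, seed=seed,
            )
            df = cohort_to_frame(generate_cohort(spec))
            rng = np.random.default_rng(seed + 1000)
            # continuous marker: separated group means, planted gap around 30
            vals = np.where(df["g"] == 1, rng.normal(40, 3, len(df)),
                            rng.normal(20, 3, len(df)))
            res = iv.optimal_cutpoint(vals, df["time_months"], df["event"],
                                      n_sim=50, seed=seed)
            hits += 25.0 <= res.threshold <= 35.0
        assert hits >= 8

    def test_corrected_p_at_least_naive(self):
        for seed in range(5):
            df = _cohort(seed=seed, n=80, hr=1.0)
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=len(df))
            res = iv.optimal_cutpoint(vals, df["time_months"], df["event"],
                                      n_sim=100, seed=seed)
            assert res.p_corrected >= res.p_naive

    def test_threshold_inside_observed_range(self):
        df = _cohort(seed=3, n=100)
        rng = np.random.default_rng(3)
        vals = rng.normal(size=len(df))
        res = iv.optimal_cutpoint(vals, df["time_months"], df["event"],
                                  n_sim=20, seed=0)
        assert vals.min() < res.threshold < vals.max()

    def test_degenerate_inputs_rejected(self):
        df = _cohort(seed=4, n=50)
        with pytest.raises(ValueError):
            iv.optimal_cutpoint(np.ones(len(df)), df["time_months"], df["event"])
        with pytest.raises(ValueError):
            iv.optimal_cutpoint(np.arange(10.0), np.arange(10.0), np.zeros(10))


class TestDichotomize:
    @pytest.mark.parametrize("feature,at,above", [
        ("n_buds", 287, 288),
        ("n_minimal_lvi", 16, 17),
        ("n_pdc", 35, 36),
        ("tumor_stroma_pct", 21.0, 21.5),
        ("area_pdc_um2", 35_647.0, 35_648.0),
    ])
    def test_published_cutoff_boundaries(self, feature, at, above):
        df = pd.DataFrame({feature: [at, above]})
        groups = iv.dichotomize(df)
        assert groups[feature].tolist() == [1, 2]  # exact value stays group 1

    def test_all_zero_feature_all_group1(self):
        df = pd.DataFrame({"n_buds": np.zeros(5)})
        assert (iv.dichotomize(df)["n_buds"] == 1).all()

    def test_missing_values_excluded(self):
        df = pd.DataFrame({"n_buds": [100.0, np.nan, 400.0]})
        g = iv.dichotomize(df)["n_buds"]
        assert g[0] == 1 and g[2] == 2 and pd.isna(g[1])


class TestKMAndBH:
    def test_identical_groups_null_test(self):
        df = _cohort(seed=5, n=60, hr=1.0)
        dup = pd.concat([df, df], ignore_index=True)
        groups = np.repeat([1, 2], len(df))
        res = iv.km_logrank(groups, dup["time_months"], dup["event"])
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_km_steps_at_event_times(self):
        time = np.array([5.0, 10.0, 15.0, 20.0])
        event = np.array([1, 0, 1, 1])
        res = iv.km_logrank(np.ones(4, dtype=int), time, event)
        curve = res.curves[1]
        drops = curve.index[curve.iloc[:, 0].diff().fillna(0) < 0]
        assert set(drops) == {5.0, 15.0, 20.0}

    def test_planted_hr_power(self):
        low_p = 0
        for seed in range(10):
            df = _cohort(seed=seed, n=500)
            res = iv.km_logrank(df["x"], df["time_months"], df["event"])
            low_p += res.p < 0.01
        assert low_p >= 9

    def test_bh_hand_computed_example(self):
        adj = iv.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged(self):
        assert iv.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_bh_range_validation(self):
        with pytest.raises(ValueError):
            iv.bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_bh_equals_stepup_oracle(self, pvals):
        # independent hand-coded step-up oracle
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(ranked, 1.0)
        assert np.allclose(iv.bh_adjust(p), oracle)


class TestCox:
    def test_planted_hr_ci_coverage(self):
        covered = 0
        for seed in range(20):
            df = _cohort(seed=seed, n=500)
            res = iv.cox_univariate(df["x"], df["time_months"], df["event"], "x")
            lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
            covered += lo <= 4.0 <= hi
        assert covered >= 18

    def test_log_hr_bias_small_at_large_n(self):
        for hr in (1.0, 2.0, 4.0):
            log_hrs = []
            for seed in range(5):
                df = _cohort(seed=seed + int(hr * 100), n=1000, hr=hr)
                res = iv.cox_univariate(df["x"], df["time_months"], df["event"], "x")
                log_hrs.append(np.log(res.hr("x")))
            assert abs(np.mean(log_hrs) - np.log(hr)) < 0.1

    def test_null_covariate_hr_near_one(self):
        df = _cohort(seed=9, n=2000, hr=1.0)
        res = iv.cox_univariate(df["x"], df["time_months"], df["event"], "x")
        lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
        assert lo <= 1.0 <= hi

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            iv.cox_univariate(np.ones(10), np.arange(10.0) + 1, np.ones(10, dtype=int))


class TestBackwardElimination:
    def test_informative_covariate_retained(self):
        kept = 0
        for seed in range(5):
            df = _cohort(seed=seed, n=400)
            rng = np.random.default_rng(seed)
            cov = pd.DataFrame({"x": df["x"].astype(float)})
            for i in range(5):
                cov[f"noise_{i}"] = rng.integers(0, 2, len(df)).astype(float)
            res = cox_backward_aic(cov, df["time_months"], df["event"])
            kept += "x" in res.covariates
        assert kept >= 5 * 0.9 - 1  # >=4/5 seeds

    def test_all_noise_mostly_eliminated(self):
        small = 0
        for seed in range(5):
            df = _cohort(seed=seed + 50, n=300, hr=1.0)
            rng = np.random.default_rng(seed)
            cov = pd.DataFrame(
                {f"noise_{i}": rng.integers(0, 2, len(df)).astype(float)
                 for i in range(4)}
            )
            res = cox_backward_aic(cov, df["time_months"], df["event"])
            small += len(res.covariates) <= 1
        assert small >= 3

    def test_aic_trace_nonincreasing(self):
        df = _cohort(seed=13, n=300)
        rng = np.random.default_rng(13)
        cov = pd.DataFrame({
            "x": df["x"].astype(float),
            "n1": rng.integers(0, 2, len(df)).astype(float),
            "n2": rng.integers(0, 2, len(df)).astype(float),
        })
        res = cox_backward_aic(cov, df["time_months"], df["event"])
        aics = [a for _, a in res.elimination_trace]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))

    def test_collinear_covariate_dropped(self):
        df = _cohort(seed=14, n=200)
        cov = pd.DataFrame({"x": df["x"].astype(float)})
        cov["x_copy"] = cov["x"]
        with pytest.warns(UserWarning, match="collinear"):
            res = cox_backward_aic(cov, df["time_months"], df["event"])
        assert "x_copy" not in res.covariates


class TestNPI:
    def test_rule_examples(self):
        cfg = CutoffConfig()
        hi = iv.build_npi({"area_pdc_um2": 40_000, "pt_stage": "pT4",
                           "differentiation": "moderate"}, cfg)
        assert hi.score == 2 and hi.group == "high"
        lo = iv.build_npi({"area_pdc_um2": 10_000, "pt_stage": "pT3",
                           "differentiation": "poor"}, cfg)
        assert lo.score == 1 and lo.group == "low"

    def test_truth_table_matches_enumeration_oracle(self):
        cfg = CutoffConfig()
        for area_high, stage, diff in itertools.product(
            (False, True), ("pT3", "pT4"), ("well", "moderate", "poor")
        ):
            area = 50_000.0 if area_high else 1_000.0
            npi = iv.build_npi(
                {"area_pdc_um2": area, "pt_stage": stage, "differentiation": diff},
                cfg,
            )
            oracle_flags = [area > 35_647.0, stage == "pT4", diff == "poor"]
            assert npi.score == sum(oracle_flags)
            assert npi.group == ("high" if sum(oracle_flags) >= 2 else "low")

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            iv.build_npi({"pt_stage": "pT3", "differentiation": "well"})
        with pytest.raises(ValueError):
            iv.build_npi({"area_pdc_um2": 1.0, "pt_stage": "pT2",
                          "differentiation": "well"})

    def test_patient_record_interface(self):
        rec = PatientRecord(id="p", time_months=10.0, event=1, pt_stage="pT4",
                            differentiation="poor",
                            features={"area_pdc_um2": 99_999.0})
        npi = iv.build_npi(rec)
        assert npi.score == 3 and npi.group == "high"
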