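"""Agreement statistics: ICC(A,1), Bland–Altman, proportional bias,
covariate regressions, cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from kinemark import (
    PairedMeasurements,
    bland_altman,
    error_vs_covariate,
    icc_a1,
    load_cohort,
    proportional_bias,
    simulate_two_way_table,
    summarize_cohort,
)
from kinemark.agreement import icc_c1, parse_surgery_type


def pairs_of(clinical, algorithm, **cov):
    return PairedMeasurements(
        subjects=[f"S{i}" for i in range(len(clinical))],
        clinical_deg=np.asarray(clinical, float),
        algorithm_deg=np.asarray(algorithm, float),
        covariates={k: np.asarray(v, float) for k, v in cov.items()},
    )


class TestICC:
    def test_perfect_agreement_is_one(self):
        p = pairs_of([80, 90, 100, 110], [80, 90, 100, 110])
        r = icc_a1(p)
        assert r.estimate == pytest.approx(1.0, abs=1e-12)
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_constant_offset_penalized_vs_consistency(self):
        clinical = [70.0, 85.0, 95.0, 110.0, 120.0]
        p = pairs_of(clinical, [c + 50.0 for c in clinical])
        assert icc_a1(p).estimate < icc_c1(p)

    def test_monte_carlo_recovery_large_n(self):
        # true ~ N(90, 9^2), both raters add N(0, 3^2): pop ICC = 81/90 = 0.90
        p = simulate_two_way_table(200, subject_sd=9, error_sd=3, seed=42)
        r = icc_a1(p)
        assert r.estimate == pytest.approx(0.90, abs=0.05)
        assert r.ci_low <= 0.90 <= r.ci_high

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            pairs_of([1, 2], [1, 2])

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            icc_a1(pairs_of([90, 90, 90], [90, 90, 90]))

    def test_affine_invariance_both_raters(self):
        p = simulate_two_way_table(20, subject_sd=8, rater_offset=2, error_sd=2, seed=3)
        r0 = icc_a1(p)
        q = pairs_of(1.7 * p.clinical_deg - 12.0, 1.7 * p.algorithm_deg - 12.0)
        assert icc_a1(q).estimate == pytest.approx(r0.estimate, abs=1e-9)

    def test_offset_to_one_rater_decreases_estimate(self):
        p = simulate_two_way_table(20, subject_sd=8, error_sd=2, seed=4)
        r0 = icc_a1(p).estimate
        q = pairs_of(p.clinical_deg, p.algorithm_deg + 15.0)
        assert icc_a1(q).estimate < r0

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            p = simulate_two_way_table(
                n,
                subject_sd=float(rng.uniform(1, 12)),
                rater_offset=float(rng.uniform(0, 6)),
                error_sd=float(rng.uniform(0.3, 6)),
                seed=int(rng.integers(2**31)),
            )
            mine = icc_a1(p)
            df = pd.DataFrame({
                "targets": np.repeat(p.subjects, 2),
                "raters": ["c", "a"] * p.n,
                "ratings": np.column_stack(
                    [p.clinical_deg, p.algorithm_deg]
                ).ravel(),
            })
            row = (
                pg.intraclass_corr(df, "targets", "raters", "ratings")
                .set_index("Type")
                .loc["ICC(A,1)"]
            )
            assert mine.estimate == pytest.approx(row.ICC, abs=1e-9)
            # pingouin rounds CI bounds to 2 dp and does not clip to [-1, 1]
            assert mine.ci_low == pytest.approx(
                float(np.clip(row.CI95[0], -1, 1)), abs=0.006
            )
            assert mine.ci_high == pytest.approx(
                float(np.clip(row.CI95[1], -1, 1)), abs=0.006
            )

    def test_small_n_parameter_recovery_and_coverage(self):
        # study-sized tables: n=14, population ICC 0.90
        est, covered = [], 0
        n_sim = 500
        for s in range(n_sim):
            p = simulate_two_way_table(14, subject_sd=9, error_sd=3, seed=s)
            r = icc_a1(p)
            est.append(r.estimate)
            covered += r.ci_low <= 0.90 <= r.ci_high
        assert np.mean(est) == pytest.approx(0.90, abs=0.03)
        assert 0.90 <= covered / n_sim <= 0.98


class TestBlandAltman:
    def test_identical_pairs(self):
        r = bland_altman(pairs_of([10, 20, 30], [10, 20, 30]))
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_difference(self):
        r = bland_altman(pairs_of([10, 20, 30], [12, 22, 32]))
        assert r.bias == pytest.approx(2.0)
        assert r.sd_diff == 0.0
        assert (r.loa_low, r.loa_high) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_bias_equals_mean_difference_and_swap_mirrors(self):
        p = simulate_two_way_table(30, subject_sd=10, rater_offset=3, error_sd=4, seed=8)
        r = bland_altman(p)
        assert r.bias == pytest.approx(
            p.algorithm_deg.mean() - p.clinical_deg.mean(), abs=1e-12
        )
        swapped = pairs_of(p.algorithm_deg, p.clinical_deg)
        rs = bland_altman(swapped)
        assert rs.bias == pytest.approx(-r.bias, abs=1e-12)
        assert rs.loa_low == pytest.approx(-r.loa_high, abs=1e-12)
        assert rs.loa_high == pytest.approx(-r.loa_low, abs=1e-12)

    def test_monte_carlo_normal_differences(self):
        # differences ~ N(-2, 5^2), n = 10^4: LoA width -> 2*1.96*5 = 19.6
        rng = np.random.default_rng(123)
        clinical = rng.uniform(60, 120, size=10_000)
        algorithm = clinical + rng.normal(-2.0, 5.0, size=10_000)
        r = bland_altman(pairs_of(clinical, algorithm))
        assert r.bias == pytest.approx(-2.0, abs=0.15)
        assert (r.loa_high - r.loa_low) == pytest.approx(19.6, abs=0.5)


class TestProportionalBias:
    def test_perfect_linear_dependence(self):
        clinical = np.array([60.0, 80.0, 100.0, 120.0, 140.0])
        # choose algorithm so difference = 0.5 * mean exactly:
        # a - c = 0.5 (a + c)/2 => a = c * 1.25 / 0.75
        algorithm = clinical * (1.25 / 0.75)
        slope, p = proportional_bias(pairs_of(clinical, algorithm))
        assert slope == pytest.approx(0.5, abs=1e-9)
        assert p < 1e-12

    def test_constant_difference_zero_slope(self):
        clinical = np.array([60.0, 80.0, 100.0, 120.0])
        slope, _ = proportional_bias(pairs_of(clinical, clinical + 2.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_means_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            proportional_bias(pairs_of([90, 88, 92, 91], [90, 92, 88, 89]))

    def test_null_type_one_error_rate(self):
        # independent noise: rejection rate at alpha=.05 should be ~5%
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            clinical = rng.uniform(60, 120, size=14)
            algorithm = clinical + rng.normal(0, 4, size=14)
            d_indep = rng.normal(0, 4, size=14)  # difference independent of mean
            p = pairs_of(clinical - d_indep / 2, clinical + d_indep / 2)
            _, pval = proportional_bias(p)
            rejections += pval < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestErrorVsCovariate:
    def test_exact_linear_absolute_error(self):
        months = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        clinical = np.full(5, 90.0)
        algorithm = clinical + 2.0 * months  # absolute error = 2 * months
        r = error_vs_covariate(
            pairs_of(clinical, algorithm, months_since_surgery=months),
            "months_since_surgery",
        )
        assert r.beta == pytest.approx(2.0, abs=1e-9)
        assert r.r_squared == pytest.approx(1.0, abs=1e-9)
        assert r.rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(11)
        n = 500
        months = rng.uniform(1, 24, size=n)
        clinical = rng.uniform(60, 120, size=n)
        algorithm = clinical + rng.normal(0, 3, size=n)
        r = error_vs_covariate(
            pairs_of(clinical, algorithm, months_since_surgery=months),
            "months_since_surgery",
            error_kind="signed",
        )
        assert abs(r.beta) < 0.05
        assert abs(r.rho) < 0.1

    def test_exact_spearman_with_ties(self):
        # two distinct covariate values: midranks, permutation p enumerable
        months = np.array([1.0, 1.0, 2.0, 2.0, 2.0])
        clinical = np.full(5, 90.0)
        algorithm = np.array([91.0, 92.0, 95.0, 96.0, 97.0])
        r = error_vs_covariate(
            pairs_of(clinical, algorithm, m=months), "m", spearman_method="exact"
        )
        assert 0 < r.rho_p <= 1.0
        # midranks with ties: rho = sqrt(3)/2 for this configuration
        assert r.rho == pytest.approx(0.8660254, abs=1e-6)

    def test_missing_covariate_values_listed(self):
        months = np.array([1.0, np.nan, 3.0, 4.0])
        p = pairs_of([90, 91, 92, 93], [91, 92, 93, 94], m=months)
        with pytest.raises(ValueError, match="S1"):
            error_vs_covariate(p, "m")


class TestCohort:
    def test_reference_cohort_summary(self):
        s = summarize_cohort(load_cohort())
        assert s.n == 14
        months = s.numeric["months_since_surgery"]
        assert months["mean"] == 7.14
        assert (months["min"], months["max"]) == (1.0, 60.0)
        assert s.procedure_counts == {"THA": 9, "TKA": 5}

    def test_single_row(self):
        df = pd.DataFrame(
            [{"age_years": 61, "weight_kg": 78, "height_m": 1.63,
              "surgery_type": "Left THA", "months_since_surgery": 60}]
        )
        s = summarize_cohort(df)
        col = s.numeric["age_years"]
        assert col["mean"] == col["min"] == col["max"] == 61.0

    def test_bilateral_counts_once(self):
        assert parse_surgery_type("Left and Right THA") == ("THA", True)
        assert parse_surgery_type("Right TKA") == ("TKA", False)

    def test_unparseable_surgery_type_quoted(self):
        df = load_cohort().copy()
        df.loc[0, "surgery_type"] = "Left Shoulder"
        with pytest.raises(ValueError, match="Left Shoulder"):
            summarize_cohort(df)
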