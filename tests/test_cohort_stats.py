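"""Cohort statistics: descriptive tables, correlations, adjustments, models."""

import numpy as np
import pandas as pd
import pytest

from muscleidp.cohort_stats import (
    AgeBinScheme,
    adjust_mass,
    correlate_with_age,
    decline_rate,
    density_error_analysis,
    descriptive_by_age_sex,
    fit_interaction_model,
)
from muscleidp.phantom import CohortSimSpec, generate_cohort


def _mini_cohort(masses, ages, sexes, heights=None, bmis=None):
    n = len(masses)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age_years": ages,
            "sex": sexes,
            "height_m": heights if heights is not None else [1.7] * n,
            "bmi": bmis if bmis is not None else [25.0] * n,
            "total_mass_g": masses,
        }
    )


class TestDescriptiveTable:
    def test_identical_subjects_have_zero_sd(self):
        df = _mini_cohort([2000.0, 2000.0], [45, 45], ["female", "female"])
        out = descriptive_by_age_sex(df)
        row = out[(out.sex == "female") & (out.age_bin == "41-50")].iloc[0]
        assert row["n"] == 2
        assert row["total_sd"] == 0.0

    def test_bin_counts_sum_to_cohort_size(self, small_cohort):
        out = descriptive_by_age_sex(small_cohort)
        binned = out[out.age_bin != "all"]
        assert binned["n"].sum() == len(small_cohort)

    def test_female_mean_matches_generator_within_2se(self):
        """The default generator is calibrated so the age-60 female mean is
        2041 g; over a uniform 18-95 age range the population mean shifts by
        slope x (mean age - 60)."""
        spec = CohortSimSpec(n_subjects=3000, sex_fraction_male=0.0, seed=21)
        df = generate_cohort(spec)
        mean_age = np.mean(spec.age_range_years)
        expected = spec.intercept_g["female"] + spec.slope_g_per_year["female"] * mean_age
        se = df["total_mass_g"].std(ddof=1) / np.sqrt(len(df))
        out = descriptive_by_age_sex(df)
        female_all = out[(out.sex == "female") & (out.age_bin == "all")].iloc[0]
        assert abs(female_all["total_mean"] - expected) < 2 * se

    def test_subject_outside_bins_is_an_error(self):
        df = _mini_cohort([2000.0] * 3, [30, 50, 130], ["female"] * 3)
        with pytest.raises(ValueError, match="outside all age bins"):
            descriptive_by_age_sex(df)

    def test_age_exactly_40_falls_in_youngest_bin(self):
        scheme = AgeBinScheme()
        bins = scheme.assign(pd.Series([40.0, 40.001, 80.0, 80.001]))
        assert list(bins) == ["<40", "41-50", "71-80", "81-100"]

    def test_group_means_reconcile_with_total(self, small_cohort):
        out = descriptive_by_age_sex(small_cohort)
        groups = (
            "psoas", "quadratus_lumborum", "erector_spinae",
            "gluteus_medius", "rectus_abdominis", "lateral_abdominals",
        )
        for _, row in out[out.age_bin == "all"].iterrows():
            total_from_groups = sum(row[f"{g}_mean"] for g in groups)
            assert total_from_groups == pytest.approx(row["total_mean"], rel=1e-9)


class TestCorrelateWithAge:
    def test_perfect_linear_increase_gives_r_one(self):
        ages = [30.0, 40, 50, 60, 70]
        df = _mini_cohort([100 + 2 * a for a in ages], ages, ["male"] * 5)
        r, p = correlate_with_age(df, "total_mass_g", "male")
        assert r == pytest.approx(1.0)

    def test_null_correlation_small_at_n2000(self, rng):
        df = _mini_cohort(
            rng.normal(2000, 300, 2000), rng.uniform(18, 95, 2000), ["female"] * 2000
        )
        r, _ = correlate_with_age(df, "total_mass_g", "female")
        assert abs(r) < 0.06

    def test_matches_definitional_formula_on_hand_table(self):
        ages = np.array([30.0, 40, 50, 60, 70])
        mass = np.array([10.0, 12, 9, 7, 8])
        df = _mini_cohort(mass, ages, ["female"] * 5)
        r, _ = correlate_with_age(df, "total_mass_g", "female")
        cov = ((ages - ages.mean()) * (mass - mass.mean())).mean()
        oracle = cov / (ages.std() * mass.std())
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_constant_series_rejected(self):
        df = _mini_cohort([5.0, 5.0, 5.0], [30, 40, 50], ["male"] * 3)
        with pytest.raises(ValueError, match="constant"):
            correlate_with_age(df, "total_mass_g", "male")


class TestAdjustMass:
    def test_height_squared_division(self):
        df = _mini_cohort([2000.0], [50], ["female"], heights=[1.6])
        assert adjust_mass(df, "height").iloc[0] == pytest.approx(781.25)

    def test_equal_heights_preserve_age_correlation(self, rng):
        ages = rng.uniform(20, 90, 200)
        mass = 3000 - 5 * ages + rng.normal(0, 100, 200)
        df = _mini_cohort(mass, ages, ["male"] * 200, heights=[1.8] * 200)
        r_raw, _ = correlate_with_age(df, "total_mass_g", "male")
        df["adj"] = adjust_mass(df, "height")
        r_adj, _ = correlate_with_age(df, "adj", "male")
        assert r_adj == pytest.approx(r_raw, rel=1e-9)

    def test_mass_proportional_to_height_squared_becomes_constant(self, rng):
        heights = rng.uniform(1.5, 1.9, 50)
        df = _mini_cohort(1000 * heights**2, rng.uniform(20, 80, 50), ["female"] * 50, heights=heights)
        adj = adjust_mass(df, "height")
        np.testing.assert_allclose(adj, 1000.0, rtol=1e-12)

    def test_height_adjustment_attenuates_height_correlation(self):
        """On a single-sex cohort generated with mass proportional to height
        squared, the adjusted mass correlates far less with height than raw
        mass does (a mixed cohort would retain a sex-confounded residual)."""
        df = generate_cohort(
            CohortSimSpec(
                n_subjects=1500, height_coupling_exp=2.0, sex_fraction_male=0.0, seed=13
            )
        )
        r_raw = np.corrcoef(df["total_mass_g"], df["height_m"])[0, 1]
        r_adj = np.corrcoef(adjust_mass(df, "height"), df["height_m"])[0, 1]
        assert abs(r_adj) < abs(r_raw)
        assert abs(r_adj) < 0.1

    def test_bmi_z_mode_removes_bmi_correlation(self, rng):
        bmis = rng.uniform(18, 40, 300)
        mass = 50 * bmis + rng.normal(0, 50, 300)
        df = _mini_cohort(mass, rng.uniform(20, 80, 300), ["male"] * 300, bmis=bmis)
        z = adjust_mass(df, "bmi_z_of_height_adjusted")
        assert abs(np.corrcoef(z, bmis)[0, 1]) < 1e-8
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_nonpositive_covariate_reports_rows(self):
        df = _mini_cohort([1.0, 2.0], [30, 40], ["male"] * 2, heights=[1.7, -1.0])
        with pytest.raises(ValueError, match="height_m.*1"):
            adjust_mass(df, "height")


class TestInteractionModel:
    @staticmethod
    def _simulate(n, beta, noise, seed):
        rng = np.random.default_rng(seed)
        sex = rng.random(n) < 0.5
        bmi = rng.uniform(18, 40, n)
        heights = rng.uniform(1.5, 1.95, n)
        smm_ha = (
            beta[0] + beta[1] * bmi + beta[2] * sex + beta[3] * sex * bmi
            + rng.normal(0, noise, n)
        )
        return _mini_cohort(
            smm_ha * heights**2,
            rng.uniform(20, 90, n),
            np.where(sex, "male", "female"),
            heights=heights,
            bmis=bmi,
        )

    def test_noiseless_cohort_recovers_coefficients_exactly(self):
        beta = (300.0, 12.0, 150.0, 6.0)
        df = self._simulate(200, beta, 0.0, seed=3)
        fit = fit_interaction_model(df)
        for name, b in zip(("const", "bmi", "sex", "sex_bmi"), beta):
            assert fit["params"][name] == pytest.approx(b, abs=1e-8)

    def test_noisy_cohort_cis_cover_generating_coefficients(self):
        beta = (300.0, 12.0, 150.0, 6.0)
        df = self._simulate(2000, beta, 40.0, seed=7)
        fit = fit_interaction_model(df)
        for name, b in zip(("const", "bmi", "sex", "sex_bmi"), beta):
            lo, hi = fit["conf_int"][name]
            assert lo <= b <= hi

    def test_null_interaction_rarely_significant(self):
        hits = 0
        for seed in range(20):
            df = self._simulate(300, (300.0, 12.0, 150.0, 0.0), 40.0, seed=seed)
            if fit_interaction_model(df)["pvalues"]["sex_bmi"] < 0.05:
                hits += 1
        assert hits <= 2  # expect ~1 of 20 at the 5% level

    def test_single_sex_cohort_rejected(self):
        df = _mini_cohort(np.arange(1, 13.0) * 100, np.linspace(20, 80, 12), ["male"] * 12)
        with pytest.raises(ValueError, match="both sexes"):
            fit_interaction_model(df)


class TestDeclineRate:
    def test_collinear_points_give_exact_slope(self):
        """Masses falling on a -1.73 g/year line recover that slope exactly
        (the two-point case 3000 g at 50 vs 2982.7 g at 60, plus a midpoint)."""
        df = _mini_cohort(
            [3000.0, 2982.7, 2991.35], [50.0, 60.0, 55.0], ["male"] * 3
        )
        out = decline_rate(df, "male")
        assert out["slope_g_per_year"] == pytest.approx(-1.73)

    def test_ci_covers_simulated_female_decline(self):
        df = generate_cohort(CohortSimSpec(n_subjects=2000, sex_fraction_male=0.0, seed=17))
        out = decline_rate(df, "female")
        lo, hi = out["ci95"]
        assert lo <= -0.96 <= hi

    def test_ci_covers_simulated_male_decline(self):
        df = generate_cohort(CohortSimSpec(n_subjects=2000, sex_fraction_male=1.0, seed=18))
        out = decline_rate(df, "male")
        lo, hi = out["ci95"]
        assert lo <= -1.73 <= hi

    def test_age_independent_cohort_ci_contains_zero(self, rng):
        df = _mini_cohort(
            rng.normal(2500, 200, 500), rng.uniform(20, 90, 500), ["male"] * 500
        )
        lo, hi = decline_rate(df, "male")["ci95"]
        assert lo <= 0 <= hi

    def test_constant_age_rejected(self):
        df = _mini_cohort([1.0, 2.0, 3.0], [50, 50, 50], ["male"] * 3)
        with pytest.raises(ValueError, match="constant age"):
            decline_rate(df, "male")

    def test_over40_subset_preserves_correlation_signs(self):
        df = generate_cohort(CohortSimSpec(n_subjects=3000, seed=23))
        for sex in ("female", "male"):
            r_all, _ = correlate_with_age(df, "total_mass_g", sex)
            over40 = df[df.age_years > 40]
            r_old, _ = correlate_with_age(over40, "total_mass_g", sex)
            assert np.sign(r_all) == np.sign(r_old)


class TestDensityErrorAnalysis:
    def test_reference_densities_give_17pct_excess_and_8pct_error(self):
        excess, err = density_error_analysis(0.9, 1.06, 0.5)
        assert int(excess) == 17  # 17.78 truncates to 17
        assert round(err) == 8  # 8.16 rounds to 8

    def test_zero_fat_fraction_is_zero_error(self):
        _, err = density_error_analysis(0.9, 1.06, 0.0)
        assert err == 0.0

    def test_exact_values(self):
        excess, err = density_error_analysis(0.9, 1.06, 0.5)
        assert excess == pytest.approx(100 * 0.16 / 0.9)
        assert err == pytest.approx(100 * (1.06 - 0.98) / 0.98)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            density_error_analysis(0.0, 1.06, 0.5)
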