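import numpy as np
import pytest
from scipy import stats

from targetheight import (
    CDC_DERIVED,
    DEFAULT_SHRINKAGE,
    MidparentModel,
    RegressionToMeanParams,
    Sex,
    SimulationParams,
    estimate_reference_from_cohort,
    family_level_rtm,
    ideal_cohort,
    residual_spread_vs_midparent,
    scheme_comparison_table,
    simulate_cohort,
    within_family_residuals,
)
from targetheight.analysis import TABLE_ROW_ORDER
from targetheight.cohort import Cohort

from conftest import make_family


def ols_oracle(x, y):
    """Closed-form least squares from sums, independent of statsmodels."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy, syy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r2 = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r2


class TestMidparentRegression:
    def test_matches_sums_oracle(self, stochastic_cohort):
        res = MidparentModel(stochastic_cohort, scheme="mult1.08").fit()
        slope, intercept, r2 = ols_oracle(res.model.midparent, res.model.child_common)
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.intercept == pytest.approx(intercept, abs=1e-9)
        assert res.rsquared == pytest.approx(r2, abs=1e-9)

    def test_identity_cohort(self):
        """Children exactly at midparent: slope 1, R² 1, zero systematic error."""
        cohort = ideal_cohort(SimulationParams(midparent_slope=1.0, seed=3))
        res = MidparentModel(cohort, scheme="zscore-cdc", shrinkage=None).fit()
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-9)
        assert res.systematic_error == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("b", [0.6, 0.79, 1.0])
    def test_ideal_cohort_recovers_generative_slope(self, b):
        cohort = ideal_cohort(SimulationParams(midparent_slope=b, seed=11))
        res = MidparentModel(cohort, scheme="zscore-cdc").fit()
        assert res.slope == pytest.approx(b, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_stochastic_recovery_within_three_se(self, stochastic_cohort):
        res = MidparentModel(stochastic_cohort, scheme="zscore-cdc").fit()
        assert abs(res.slope - 0.79) < 3 * res.slope_se

    def test_heritability_equals_slope(self, stochastic_cohort):
        res = MidparentModel(stochastic_cohort).fit()
        assert res.heritability == res.slope

    def test_zero_midparent_variance_rejected(self):
        fams = tuple(
            make_family(f"f{i}", 176.0, 163.0, [("M", 170.0 + i)]) for i in range(4)
        )
        with pytest.raises(ValueError, match="variance"):
            MidparentModel(Cohort(fams)).fit()

    def test_summary_mentions_key_quantities(self, stochastic_cohort):
        text = MidparentModel(stochastic_cohort).fit().summary()
        for token in ("slope", "R-squared", "heritability", "systematic error"):
            assert token in text


class TestSystematicError:
    def test_age_correction_removes_shrinkage_bias(self):
        """Uncorrected analysis is biased by parental shrinkage; corrected ≈ 0."""
        cohort = simulate_cohort(SimulationParams(n_families=1000, seed=5))
        corrected = MidparentModel(cohort, scheme="tanner13").fit()
        uncorrected = MidparentModel(cohort, scheme="tanner13", shrinkage=None).fit()

        parental_shrink = np.mean([
            (DEFAULT_SHRINKAGE.shrinkage(f.father.age, Sex.MALE)
             + DEFAULT_SHRINKAGE.shrinkage(f.mother.age, Sex.FEMALE)) / 2
            for f in cohort
        ])
        child_shrink = np.mean([
            DEFAULT_SHRINKAGE.shrinkage(c.age, c.sex)
            for f in cohort for c in f.children
        ])
        assert corrected.systematic_error == pytest.approx(0.0, abs=0.2)
        assert uncorrected.systematic_error == pytest.approx(
            parental_shrink - child_shrink, abs=0.25
        )
        # parents at 62 ± 5 have shrunk by roughly 2.7 cm
        assert uncorrected.systematic_error > 2.0


class TestSchemeComparison:
    def test_default_table_layout(self, stochastic_cohort):
        table = scheme_comparison_table(stochastic_cohort)
        assert len(table) == 7
        assert list(table["scheme"]) == [name for _, name in TABLE_ROW_ORDER]
        assert list(table["age_corrected"]) == [on for on, _ in TABLE_ROW_ORDER]
        assert (table["heritability"] == table["slope"]).all()
        assert table.loc[table["scheme"] == "zscore-cdc", "units"].item() == "SD"
        assert table.loc[0, "units"] == "cm"

    def test_single_scheme_identity(self):
        cohort = ideal_cohort(SimulationParams(midparent_slope=1.0, seed=2))
        table = scheme_comparison_table(cohort, schemes=[(True, "zscore-cdc")])
        assert len(table) == 1
        assert table.loc[0, "slope"] == pytest.approx(1.0, abs=1e-9)

    def test_sample_zscore_estimates_reference(self, stochastic_cohort):
        ref = estimate_reference_from_cohort(stochastic_cohort)
        assert 165 < ref.mean_male < 185
        assert 155 < ref.mean_female < 172
        table = scheme_comparison_table(stochastic_cohort)
        row = table[table["scheme"] == "zscore-sample"].iloc[0]
        assert abs(row["systematic_error"]) < 0.2  # standardized units


class TestWithinFamilyResiduals:
    def test_noise_free_cohort_has_zero_scatter(self):
        cohort = ideal_cohort(SimulationParams(midparent_slope=0.79, seed=9))
        res = within_family_residuals(
            cohort, scheme="zscore-cdc", shrinkage=None,
            rtm=RegressionToMeanParams(slope=0.79, intercept=0.0),
        )
        for sex in Sex:
            assert res.mean_within[sex] == pytest.approx(0.0, abs=1e-9)
            assert res.pooled_sd[sex] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generative_residual_sd(self):
        """Pooled per-sex SDs land inside the χ² 99% interval around 4.5/4.2."""
        cohort = simulate_cohort(SimulationParams(n_families=200, seed=13))
        res = within_family_residuals(
            cohort, scheme="zscore-cdc",
            rtm=RegressionToMeanParams(slope=0.79, intercept=0.0),
        )
        for sex, sd_true in ((Sex.MALE, 4.5), (Sex.FEMALE, 4.2)):
            n = res.n_children[sex]
            lo = sd_true * np.sqrt(stats.chi2.ppf(0.005, n - 1) / (n - 1))
            hi = sd_true * np.sqrt(stats.chi2.ppf(0.995, n - 1) / (n - 1))
            assert lo < res.pooled_sd[sex] < hi

    def test_within_family_mean_close_to_pooled(self):
        cohort = simulate_cohort(SimulationParams(n_families=300, seed=21))
        res = within_family_residuals(
            cohort, scheme="zscore-cdc",
            rtm=RegressionToMeanParams(slope=0.79, intercept=0.0),
        )
        for sex in Sex:
            # within-family SDs average slightly below the pooled SD
            assert res.mean_within[sex] <= res.pooled_sd[sex] + 0.1
            assert res.mean_within[sex] > 0.8 * res.pooled_sd[sex]

    def test_singleton_sex_excluded_from_within_family(self):
        fam = make_family("f1", 176.0, 163.0, [("M", 178.0), ("F", 160.0), ("F", 166.0)])
        fam2 = make_family("f2", 180.0, 166.0, [("M", 181.0), ("M", 185.0)])
        res = within_family_residuals(Cohort((fam, fam2)), scheme="zscore-cdc")
        assert set(res.family_sds[Sex.MALE]) == {"f2"}
        assert set(res.family_sds[Sex.FEMALE]) == {"f1"}


class TestFamilyLevelRegressionToMean:
    def test_noise_free_slope_one_is_degenerate(self):
        cohort = ideal_cohort(SimulationParams(midparent_slope=1.0, seed=4))
        out = family_level_rtm(cohort, scheme="zscore-cdc", shrinkage=None)
        assert np.allclose(out.frame["mean_child_diff"], 0.0, atol=1e-12)
        assert not out.defined

    def test_regression_to_mean_gives_negative_correlation(self):
        cohort = simulate_cohort(SimulationParams(n_families=100, seed=17))
        out = family_level_rtm(cohort, scheme="mult1.08")
        assert out.r < 0
        assert out.p_value < 0.05

    def test_pvalue_matches_t_distribution(self):
        cohort = simulate_cohort(SimulationParams(n_families=40, seed=23))
        out = family_level_rtm(cohort, scheme="mult1.08")
        n = len(out.frame)
        t = out.r * np.sqrt((n - 2) / (1 - out.r**2))
        assert out.p_value == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-9)

    def test_too_few_families_rejected(self):
        fams = tuple(
            make_family(f"f{i}", 170.0 + i, 160.0, [("M", 175.0)]) for i in range(2)
        )
        with pytest.raises(ValueError, match="three families"):
            family_level_rtm(Cohort(fams))


class TestResidualSpread:
    def test_homoscedastic_cohort_not_significant(self):
        cohort = simulate_cohort(SimulationParams(n_families=150, seed=29))
        out = residual_spread_vs_midparent(
            cohort, scheme="zscore-cdc",
            rtm=RegressionToMeanParams(slope=0.79, intercept=0.0),
        )
        assert abs(out.r) < 0.25

    def test_constructed_heteroscedasticity_detected(self):
        """Families whose scatter grows with midparent height give r > 0."""
        rng = np.random.default_rng(31)
        fams = []
        for i in range(40):
            fh = 165.0 + i * 0.6
            mh = 152.0 + i * 0.6
            spread = 1.0 + 0.15 * i
            kids = [("M", fh + float(rng.normal(0, spread))) for _ in range(6)]
            fams.append(make_family(f"f{i}", fh, mh, kids))
        out = residual_spread_vs_midparent(Cohort(tuple(fams)), scheme="mult1.08")
        assert out.r > 0.5

    def test_constant_spread_gives_zero_correlation(self):
        fams = []
        for i in range(5):
            fh, mh = 168.0 + 3 * i, 155.0 + 3 * i
            kids = [("M", fh - 2.0), ("M", fh + 2.0)]
            fams.append(make_family(f"f{i}", fh, mh, kids))
        out = residual_spread_vs_midparent(Cohort(tuple(fams)), scheme="mult1.08")
        assert out.r == 0.0
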