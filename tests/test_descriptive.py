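"""Descriptive battery: chi-square, proportions, log-scale comparisons."""

import numpy as np
import pandas as pd
import pytest

import leadlasso as ll


def _survey_from_values(bll, sex=None, area="exposed", extra=None):
    n = len(bll)
    df = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "area": area if isinstance(area, (list, np.ndarray)) else [area] * n,
            "bll": np.asarray(bll, dtype=float),
        }
    )
    df["sex"] = sex if sex is not None else "boy"
    if extra:
        for k, v in extra.items():
            df[k] = v
    return ll.SurveyDataset(df, ll.default_codebook())


class TestChiSquare:
    def test_sex_by_stratum_printed_p(self):
        res = ll.chi_square_test(np.array([[351, 109], [307, 56]]))
        assert res.degrees_of_freedom == 1
        assert round(res.p_value, 3) == 0.003

    def test_income_by_stratum_printed_p(self):
        res = ll.chi_square_test(np.array([[18, 5], [49, 14], [84, 21], [463, 120]]))
        assert res.degrees_of_freedom == 3
        assert round(res.p_value, 3) == 0.987

    def test_proportional_rows_null(self):
        res = ll.chi_square_test(np.array([[10, 20], [30, 60]]))
        assert np.isclose(res.statistic, 0.0, atol=1e-12)
        assert np.isclose(res.p_value, 1.0)

    def test_agrees_with_brute_force_expected_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 60, size=(r, c)).astype(float)
            res = ll.chi_square_test(counts)
            # brute force: expected = row_sum * col_sum / total
            total = counts.sum()
            exp = np.outer(counts.sum(1), counts.sum(0)) / total
            stat = ((counts - exp) ** 2 / exp).sum()
            assert abs(stat - res.statistic) < 1e-10

    def test_zero_marginal_degenerate(self):
        with pytest.raises(ll.descriptive.DegenerateTableError):
            ll.chi_square_test(np.array([[0, 0], [5, 6]]))


class TestProportions:
    def test_printed_elevated_percentages(self):
        bll = [12.0] * 123 + [5.0] * 373 + [12.0] * 42 + [5.0] * 285
        area = ["exposed"] * 496 + ["reference"] * 327
        ds = _survey_from_values(bll, area=np.array(area))
        tab = ll.proportion_elevated(ds, ["area"]).set_index("area")
        assert round(float(tab.loc["exposed", "percent"]), 2) == 24.80
        assert round(float(tab.loc["reference", "percent"]), 2) == 12.84
        assert int(tab.loc["exposed", "denominator"]) == 496

    def test_zero_elevated_stratum(self):
        ds = _survey_from_values([3.0, 4.0, 5.0])
        tab = ll.proportion_elevated(ds)
        assert tab["percent"].iloc[0] == 0.0

    def test_reconciles_with_classifier(self, default_survey):
        tab = ll.proportion_elevated(default_survey, ["area", "sex"])
        hi = ll.classify_bll(default_survey.data["bll"].to_numpy())
        for _, row in tab.iterrows():
            m = (default_survey.data["area"] == row["area"]) & (
                default_survey.data["sex"] == row["sex"]
            )
            assert row["numerator"] == int(hi[m.to_numpy()].sum())
            assert row["denominator"] == int(m.sum())

    def test_nonmissing_denominators_in_category_summary(self):
        # counts mimic a column whose sum falls short of the stratum size
        vals = ["always"] * 173 + ["often"] * 242 + ["occasional"] * 175 + ["no"] * 37
        vals += [None] * 31
        bll = [5.0] * len(vals)
        ds = _survey_from_values(bll, extra={"eat_dairy_products": vals})
        tab = ll.categorical_summary(ds, "eat_dairy_products")
        low = tab[tab["stratum"] == "low"].set_index("category")
        assert int(low.loc["always", "denominator"]) == 627
        assert round(float(low.loc["always", "percent"]), 1) == 27.6


class TestCompareLogBll:
    def test_self_comparison_null(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(1.9, 0.5, 50)
        ds = _survey_from_values(
            np.r_[vals, vals], area=np.array(["exposed"] * 50 + ["reference"] * 50)
        )
        res = ll.compare_log_bll(ds, "area")
        assert np.isclose(res.statistic, 0.0, atol=1e-12)
        assert np.isclose(res.p_value, 1.0)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep, n = 400, 200
        for _ in range(n_rep):
            vals = rng.lognormal(1.8, 0.49, 2 * n)
            ds = _survey_from_values(
                vals, area=np.array(["exposed"] * n + ["reference"] * n)
            )
            rejections += ll.compare_log_bll(ds, "area").p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se

    def test_power_at_study_margins(self):
        # log-means differing by ln(7.06)-ln(5.89)=0.18, sd 0.49, n=496 vs 327
        rng = np.random.default_rng(3)
        rejected = 0
        for _ in range(40):
            a = rng.lognormal(1.9544, 0.49, 496)
            b = rng.lognormal(1.7733, 0.49, 327)
            ds = _survey_from_values(
                np.r_[a, b], area=np.array(["exposed"] * 496 + ["reference"] * 327)
            )
            rejected += ll.compare_log_bll(ds, "area").p_value < 0.05
        assert rejected >= 40 * 0.99

    def test_insufficient_group(self):
        ds = _survey_from_values(
            [5.0, 6.0, 7.0], area=np.array(["exposed", "reference", "reference"])
        )
        with pytest.raises(ll.descriptive.InsufficientDataError):
            ll.compare_log_bll(ds, "area")


class TestMannWhitney:
    def test_identical_distributions(self):
        vals = np.r_[np.arange(1, 21), np.arange(1, 21)].astype(float)
        sex = ["boy"] * 20 + ["girl"] * 20
        ds = _survey_from_values(vals, sex=sex)
        res = ll.mann_whitney_by_sex(ds)
        assert np.isclose(res.statistic, 200.0)  # n1*n2/2
        assert np.isclose(res.p_value, 1.0)

    def test_single_pair_exact(self):
        ds = _survey_from_values([2.0, 1.0], sex=["boy", "girl"])
        res = ll.mann_whitney_by_sex(ds)
        assert res.statistic == 1.0
        assert np.isclose(res.p_value, 1.0)

    def test_location_shift_detected(self):
        rng = np.random.default_rng(4)
        detected = 0
        for _ in range(30):
            boys = rng.lognormal(2.0, 0.5, 300)
            girls = rng.lognormal(1.8, 0.5, 300)
            ds = _survey_from_values(np.r_[boys, girls], sex=["boy"] * 300 + ["girl"] * 300)
            detected += ll.mann_whitney_by_sex(ds).p_value < 0.05
        assert detected >= 25  # majority rejection under a +0.2 log shift

    def test_one_sex_absent(self):
        ds = _survey_from_values([5.0, 6.0], sex=["boy", "boy"])
        with pytest.raises(ll.descriptive.InsufficientDataError):
            ll.mann_whitney_by_sex(ds)


class TestAncova:
    @staticmethod
    def _with_covariates(bll, area, age, height, weight):
        ds = _survey_from_values(bll, area=area)
        ds.data["age_years"] = age
        ds.data["height_cm"] = height
        ds.data["weight_kg"] = weight
        return ds

    def test_inert_adjustment_matches_t_test(self):
        rng = np.random.default_rng(5)
        n = 4000
        area = np.array(["exposed"] * n + ["reference"] * n)
        bll = np.r_[rng.lognormal(1.95, 0.49, n), rng.lognormal(1.77, 0.44, n)]
        ds = self._with_covariates(
            bll, area, rng.normal(4.5, 1, 2 * n), rng.normal(105, 8, 2 * n),
            rng.normal(17, 3, 2 * n),
        )
        t_res = ll.compare_log_bll(ds, "area")
        a_res = ll.adjusted_area_comparison(ds)
        assert abs(a_res.estimate - t_res.estimate) < 0.02
        assert a_res.p_value < 0.001 and t_res.p_value < 0.001

    def test_fully_mediated_effect_vanishes(self):
        rng = np.random.default_rng(6)
        n = 5000
        area = np.array(["exposed"] * n + ["reference"] * n)
        height = np.r_[rng.normal(108, 5, n), rng.normal(102, 5, n)]
        bll = np.exp(1.0 + 0.05 * height + rng.normal(0, 0.3, 2 * n))
        ds = self._with_covariates(
            bll, area, rng.normal(4.5, 1, 2 * n), height, rng.normal(17, 3, 2 * n)
        )
        res = ll.adjusted_area_comparison(ds)
        assert abs(res.estimate) < 0.03  # area effect is height in disguise

    def test_recovers_true_adjusted_effect(self):
        rng = np.random.default_rng(7)
        n = 5000
        area = np.array(["exposed"] * n + ["reference"] * n)
        height = rng.normal(105, 8, 2 * n)
        eta = 1.6 + 0.18 * (area == "exposed") + 0.01 * height
        bll = np.exp(eta + rng.normal(0, 0.45, 2 * n))
        ds = self._with_covariates(
            bll, area, rng.normal(4.5, 1, 2 * n), height, rng.normal(17, 3, 2 * n)
        )
        res = ll.adjusted_area_comparison(ds)
        se = (res.conf_high - res.conf_low) / 3.92
        assert abs(res.estimate - 0.18) < 3 * se

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(8)
        n = 100
        area = np.array(["exposed"] * 50 + ["reference"] * 50)
        height = rng.normal(105, 8, n)
        ds = self._with_covariates(
            rng.lognormal(1.9, 0.5, n), area, rng.normal(4.5, 1, n), height, 2 * height
        )
        with pytest.raises(ValueError, match="rank"):
            ll.adjusted_area_comparison(ds, covariates=("height_cm", "weight_kg"))

    def test_area_test_on_study_conditions(self, default_survey):
        res = ll.adjusted_area_comparison(default_survey)
        assert res.p_value < 0.05
        assert res.estimate > 0  # exposed area higher after adjustment
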