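"""Descriptive group comparisons of characteristics and blood lead levels.

The machinery behind the classic two-table presentation of an exposure
study: cross-tabulations of characteristics against the elevated-BLL
stratum with Pearson chi-square tests, elevated proportions by stratum,
t-tests on log-transformed BLL, Mann-Whitney comparisons of boys and girls,
and a covariance-adjusted (ANCOVA) area comparison on the log scale.

BLL distributions are right-skewed, so location summaries are medians with
interquartile ranges and all parametric comparisons act on ln(BLL); the
natural log is used throughout (the test statistics are invariant to the
base).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encode import classify_bll
from .simulate import BLL_THRESHOLD, SurveyDataset


class InsufficientDataError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    degrees_of_freedom: float | None = None
    estimate: float | None = None
    conf_low: float | None = None
    conf_high: float | None = None
    detail: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.degrees_of_freedom is not None:
            d["df"] = self.degrees_of_freedom
        if self.estimate is not None:
            d["estimate"] = self.estimate
            d["ci95"] = [self.conf_low, self.conf_high]
        return d


def chi_square_test(table: ContingencyTable | np.ndarray) -> TestResult:
    """Pearson chi-square on an r x c table, no continuity correction."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("a zero marginal makes expected counts undefined")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(
        method="pearson-chi-square", statistic=float(stat), p_value=float(p),
        degrees_of_freedom=float(dof),
    )


def crosstab(dataset: SurveyDataset, field: str, threshold: float = BLL_THRESHOLD) -> ContingencyTable:
    """field categories x (low, high) BLL stratum counts, non-missing only."""
    df = dataset.data
    ok = df[field].notna() & df["bll"].notna()
    sub = df.loc[ok]
    hi = classify_bll(sub["bll"].to_numpy(dtype=float), threshold)
    cats = list(dataset.codebook[field].categories) if field in dataset.codebook else sorted(sub[field].unique())
    counts = np.array(
        [[int(((sub[field] == c) & (hi == s)).sum()) for s in (0, 1)] for c in cats]
    )
    return ContingencyTable(row_labels=cats, col_labels=["low", "high"], counts=counts)


def proportion_elevated(
    dataset: SurveyDataset, stratify_by: list | None = None, threshold: float = BLL_THRESHOLD
) -> pd.DataFrame:
    """(numerator, denominator, percent) of elevated BLL per stratum.

    Denominators count records with an observed BLL; an empty stratum is
    reported with denominator 0 and NaN percent.
    """
    df = dataset.data
    obs = df["bll"].notna()
    hi = pd.Series(np.zeros(len(df), dtype=int), index=df.index)
    hi.loc[obs] = classify_bll(df.loc[obs, "bll"].to_numpy(dtype=float), threshold)

    if not stratify_by:
        num = int(hi[obs].sum())
        den = int(obs.sum())
        return pd.DataFrame(
            [{"numerator": num, "denominator": den,
              "percent": 100.0 * num / den if den else np.nan}]
        )
    rows = []
    for key, grp in df.groupby(stratify_by, dropna=False, observed=False):
        key = key if isinstance(key, tuple) else (key,)
        gobs = grp["bll"].notna()
        den = int(gobs.sum())
        num = int(hi[grp.index][gobs].sum())
        rows.append(
            dict(zip(stratify_by, key))
            | {"numerator": num, "denominator": den,
               "percent": 100.0 * num / den if den else np.nan}
        )
    return pd.DataFrame(rows)


def categorical_summary(
    dataset: SurveyDataset, field: str, threshold: float = BLL_THRESHOLD
) -> pd.DataFrame:
    """Per-stratum category counts and percents over non-missing denominators."""
    tab = crosstab(dataset, field, threshold)
    out = []
    for s, stratum in enumerate(tab.col_labels):
        col = tab.counts[:, s]
        den = int(col.sum())
        for cat, c in zip(tab.row_labels, col):
            out.append(
                {"stratum": stratum, "category": cat, "count": int(c),
                 "denominator": den,
                 "percent": 100.0 * c / den if den else np.nan}
            )
    return pd.DataFrame(out)


def _log_bll_groups(dataset: SurveyDataset, grouping: str) -> dict:
    df = dataset.data
    ok = df["bll"].notna() & df[grouping].notna()
    sub = df.loc[ok]
    return {
        level: np.log(grp["bll"].to_numpy(dtype=float))
        for level, grp in sub.groupby(grouping, observed=False)
    }


def compare_log_bll(dataset: SurveyDataset, grouping: str = "area") -> TestResult:
    """Two-sided pooled-variance t-test on ln(BLL) between two groups.

    The estimate is the difference in log means (first minus second level);
    geometric means per group are reported in ``detail``.
    """
    groups = _log_bll_groups(dataset, grouping)
    if len(groups) != 2:
        raise InsufficientDataError(f"{grouping!r} must define exactly 2 groups")
    (la, xa), (lb, xb) = sorted(groups.items())
    if len(xa) < 2 or len(xb) < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    dof = len(xa) + len(xb) - 2
    diff = float(xa.mean() - xb.mean())
    sp = np.sqrt(
        ((len(xa) - 1) * xa.var(ddof=1) + (len(xb) - 1) * xb.var(ddof=1)) / dof
    )
    se = sp * np.sqrt(1 / len(xa) + 1 / len(xb))
    tcrit = stats.t.ppf(0.975, dof)
    return TestResult(
        method="t-test-log-bll",
        statistic=float(t),
        p_value=float(p),
        degrees_of_freedom=float(dof),
        estimate=diff,
        conf_low=diff - tcrit * se,
        conf_high=diff + tcrit * se,
        detail={
            "groups": [la, lb],
            "log_means": [float(xa.mean()), float(xb.mean())],
            "geometric_means": [float(np.exp(xa.mean())), float(np.exp(xb.mean()))],
        },
    )


def mann_whitney_by_sex(dataset: SurveyDataset, within_area: str | None = None) -> TestResult:
    """Two-sided Mann-Whitney U comparing BLL of boys and girls.

    Exact null distribution for small untied samples, tie-corrected normal
    approximation otherwise (scipy's ``method='auto'``).
    """
    df = dataset.data
    if within_area is not None:
        df = df[df["area"] == within_area]
    ok = df["bll"].notna() & df["sex"].notna()
    sub = df.loc[ok]
    boys = sub.loc[sub["sex"] == "boy", "bll"].to_numpy(dtype=float)
    girls = sub.loc[sub["sex"] == "girl", "bll"].to_numpy(dtype=float)
    if len(boys) == 0 or len(girls) == 0:
        raise InsufficientDataError("both sexes must be present")
    res = stats.mannwhitneyu(boys, girls, alternative="two-sided", method="auto")
    return TestResult(
        method="mann-whitney-u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        detail={
            "n_boys": int(len(boys)),
            "n_girls": int(len(girls)),
            "median_boys": float(np.median(boys)),
            "median_girls": float(np.median(girls)),
        },
    )


def adjusted_area_comparison(
    dataset: SurveyDataset,
    covariates: tuple = ("age_years", "height_cm", "weight_kg"),
) -> TestResult:
    """ANCOVA: ln(BLL) ~ area + covariates; reports the area contrast.

    The estimate is the exposed-minus-reference difference in adjusted log
    means; ``detail`` carries adjusted (geometric-scale) means at the
    covariate grand means.
    """
    import statsmodels.api as sm

    df = dataset.data
    cols = ["bll", "area", *covariates]
    sub = df[cols].dropna()
    if sub["area"].nunique() != 2:
        raise InsufficientDataError("need both areas present")
    y = np.log(sub["bll"].to_numpy(dtype=float))
    exposed = (sub["area"] == "exposed").astype(float).to_numpy()
    Z = sub[list(covariates)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), exposed, Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates: design is rank-deficient")
    res = sm.OLS(y, X).fit()
    est = float(res.params[1])
    ci = res.conf_int()[1]
    zbar = Z.mean(axis=0)
    adj_ref = float(res.params[0] + zbar @ res.params[2:])
    return TestResult(
        method="ancova-log-bll",
        statistic=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        degrees_of_freedom=float(res.df_resid),
        estimate=est,
        conf_low=float(ci[0]),
        conf_high=float(ci[1]),
        detail={
            "adjusted_log_mean_reference": adj_ref,
            "adjusted_log_mean_exposed": adj_ref + est,
            "adjusted_geometric_means": [float(np.exp(adj_ref + est)), float(np.exp(adj_ref))],
            "covariates": list(covariates),
        },
    )


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range, quartiles by linear interpolation."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


def bll_summary_table(dataset: SurveyDataset, threshold: float = BLL_THRESHOLD) -> pd.DataFrame:
    """Median (IQR) BLL and elevated counts by area and sex."""
    rows = []
    df = dataset.data
    for area in ("exposed", "reference"):
        for sex in (None, "boy", "girl"):
            m = (df["area"] == area) & df["bll"].notna()
            if sex is not None:
                m &= df["sex"] == sex
            vals = df.loc[m, "bll"].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            med, iqr = median_iqr(vals)
            n_hi = int((vals >= threshold).sum())
            rows.append(
                {
                    "area": area,
                    "sex": sex or "all",
                    "n": len(vals),
                    "median": med,
                    "iqr": iqr,
                    "n_elevated": n_hi,
                    "pct_elevated": 100.0 * n_hi / len(vals),
                }
            )
    return pd.DataFrame(rows)
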