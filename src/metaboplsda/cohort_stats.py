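"""Descriptive two-group comparisons for clinical cohort tables.

Continuous covariates are compared with a pooled-variance two-sample
t-test when both groups look normal under a Kolmogorov–Smirnov check
(parameters estimated from the sample — the Lilliefors caveat applies, so
the gate is mildly anti-conservative), and with a Mann–Whitney U test
otherwise.  Categorical covariates use a chi-squared test, with the Yates
continuity correction on 2×2 tables.  Which test ran is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_NORMALITY = 0.05


@dataclass
class GroupComparison:
    """One row of a cohort-characteristics table."""

    variable: str
    case_summary: str
    control_summary: str
    test: str  # "pooled t" | "Mann-Whitney U" | "chi-squared (Yates)" | "chi-squared"
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "case": self.case_summary,
            "control": self.control_summary,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroupComparison":
        return cls(
            variable=payload["variable"],
            case_summary=payload["case"],
            control_summary=payload["control"],
            test=payload["test"],
            statistic=float(payload["statistic"]),
            p_value=float(payload["p_value"]),
        )


def ks_normality(values: np.ndarray) -> float:
    """Two-sided KS p-value against a normal with the sample's own moments."""
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("normality check needs at least 5 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    return float(stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue)


def _mean_sd_summary(v: np.ndarray) -> str:
    return f"{np.mean(v):.1f} ± {np.std(v, ddof=1):.1f}"


def compare_continuous(
    case_values: np.ndarray,
    control_values: np.ndarray,
    variable: str = "",
    force_test: str = "auto",
) -> GroupComparison:
    """Two-group comparison of a continuous covariate.

    ``force_test``: "auto" (KS-gated), "t" (pooled t) or "mwu"
    (Mann–Whitney U with mid-rank ties).
    """
    case_v = np.asarray(case_values, dtype=float)
    ctrl_v = np.asarray(control_values, dtype=float)
    if len(case_v) < 2 or len(ctrl_v) < 2:
        raise ValueError("each group needs at least 2 observations")
    if force_test == "auto":
        normal = (
            ks_normality(case_v) > ALPHA_NORMALITY
            and ks_normality(ctrl_v) > ALPHA_NORMALITY
        )
        force_test = "t" if normal else "mwu"
    if force_test == "t":
        res = stats.ttest_ind(case_v, ctrl_v, equal_var=True)
        test_name = "pooled t"
    elif force_test == "mwu":
        res = stats.mannwhitneyu(case_v, ctrl_v, alternative="two-sided")
        test_name = "Mann-Whitney U"
    else:
        raise ValueError(f"unknown test {force_test!r}")
    return GroupComparison(
        variable=variable,
        case_summary=_mean_sd_summary(case_v),
        control_summary=_mean_sd_summary(ctrl_v),
        test=test_name,
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
    )


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean0: float, sd0: float, n0: int
) -> tuple[float, int, float]:
    """Pooled-variance t-test from published summary statistics.

    Returns (t, df, two-sided p).  Lets a printed "mean ± SD, n" table row
    be re-tested without the underlying raw data.
    """
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n0 - 1) * sd0**2) / df
    t = (mean1 - mean0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def compare_categorical(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    variable: str = "",
) -> GroupComparison:
    """Chi-squared comparison of category counts between groups.

    2×2 tables get the Yates continuity correction; larger tables use the
    plain statistic.  The summaries report the first category as "n (%)".
    """
    case_c = np.asarray(case_counts, dtype=int)
    ctrl_c = np.asarray(control_counts, dtype=int)
    if case_c.shape != ctrl_c.shape or case_c.ndim != 1 or len(case_c) < 2:
        raise ValueError("need matching count vectors over >= 2 categories")
    if (case_c < 0).any() or (ctrl_c < 0).any():
        raise ValueError("counts must be non-negative")
    table = np.column_stack([case_c, ctrl_c])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin: test undefined")
    is_2x2 = table.shape == (2, 2)
    res = stats.chi2_contingency(table, correction=is_2x2)
    return GroupComparison(
        variable=variable,
        case_summary=f"{case_c[0]} ({100 * case_c[0] / case_c.sum():.0f})",
        control_summary=f"{ctrl_c[0]} ({100 * ctrl_c[0] / ctrl_c.sum():.0f})",
        test="chi-squared (Yates)" if is_2x2 else "chi-squared",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


_CONTINUOUS_COVARIATES = ("age", "bmi", "sppb", "disease_count")


def build_table1(clinical: pd.DataFrame) -> list[GroupComparison]:
    """Cohort-characteristics table from a clinical covariate frame.

    Expects columns ``class`` (case/control), ``sex`` and the continuous
    covariates age, bmi, sppb and disease_count; returns one comparison
    per covariate with the test used recorded.
    """
    if "class" not in clinical.columns:
        raise ValueError("clinical table needs a 'class' column")
    is_case = clinical["class"] == "case"
    if is_case.all() or (~is_case).all():
        raise ValueError("both classes must be present")
    rows: list[GroupComparison] = []
    if "age" in clinical.columns:
        rows.append(
            compare_continuous(
                clinical.loc[is_case, "age"],
                clinical.loc[~is_case, "age"],
                variable="age",
            )
        )
    if "sex" in clinical.columns:
        case_counts = [
            (clinical.loc[is_case, "sex"] == "female").sum(),
            (clinical.loc[is_case, "sex"] == "male").sum(),
        ]
        ctrl_counts = [
            (clinical.loc[~is_case, "sex"] == "female").sum(),
            (clinical.loc[~is_case, "sex"] == "male").sum(),
        ]
        rows.append(
            compare_categorical(case_counts, ctrl_counts, variable="sex (female)")
        )
    for covariate in ("bmi", "sppb", "disease_count"):
        if covariate in clinical.columns:
            rows.append(
                compare_continuous(
                    clinical.loc[is_case, covariate],
                    clinical.loc[~is_case, covariate],
                    variable=covariate,
                )
            )
    return rows
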