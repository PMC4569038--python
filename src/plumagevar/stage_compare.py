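"""Nestling vs. adult color statistics.

Covers the longitudinal and cross-sectional comparisons: two-way ANOVA
(sex x developmental stage) with Tukey HSD contrasts per color metric,
Welch two-sample t-tests for recruitment comparisons, the
nestling -> adult ANCOVA (adult color regressed on nestling color with a
sex covariate on mean-standardized values), and a Spearman rank check
that arbitrary band-color labels carry no fitness signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.libqsturng import qsturng

__all__ = [
    "anova_stage_sex",
    "welch_test",
    "ancova_nestling_adult",
    "spearman_check",
]

METRICS = ("theta", "phi", "r_A", "brightness")


def _tukey_cellwise(values: np.ndarray, cells: np.ndarray, pairs: list[tuple[str, str]]) -> list[dict]:
    """Tukey HSD on the sex-x-stage interaction cell means for the selected
    pairs, using the studentized-range distribution with the pooled
    within-cell error."""
    labels, counts, means = [], [], []
    for lab in np.unique(cells):
        sub = values[cells == lab]
        labels.append(lab)
        counts.append(len(sub))
        means.append(sub.mean())
    k = len(labels)
    n = len(values)
    df_w = n - k
    sse = sum(
        ((values[cells == lab] - mu) ** 2).sum() for lab, mu in zip(labels, means)
    )
    mse = sse / df_w
    q_crit = qsturng(0.95, k, df_w)
    idx = {lab: i for i, lab in enumerate(labels)}
    out = []
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        diff = means[ia] - means[ib]
        se = np.sqrt(mse / 2.0 * (1.0 / counts[ia] + 1.0 / counts[ib]))
        half = q_crit * se
        out.append(
            {
                "contrast": f"{a} - {b}",
                "difference": diff,
                "lower": diff - half,
                "upper": diff + half,
                "significant": bool(diff - half > 0 or diff + half < 0),
            }
        )
    return out


def anova_stage_sex(records: pd.DataFrame, metrics: tuple[str, ...] = METRICS) -> dict[str, dict]:
    """Two-way ANOVA (sex, stage, interaction) plus Tukey contrasts per metric.

    ``records`` needs columns stage ('nestling'/'adult'), sex ('M'/'F') and
    the metric columns. Returns, per metric, the F and p for each effect
    and the male-female contrast within each stage and the nestling-adult
    contrast within each sex.
    """
    for col in ("stage", "sex"):
        if records[col].nunique() < 2:
            raise ValueError(f"need both levels of {col}")
    counts = records.groupby(["stage", "sex"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("every sex x stage cell needs >= 2 observations")
    out: dict[str, dict] = {}
    for metric in metrics:
        df = records[["stage", "sex", metric]].rename(columns={metric: "y"})
        fit = smf.ols("y ~ C(sex) * C(stage)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        effects = {
            "sex": {"F": float(table.loc["C(sex)", "F"]), "p": float(table.loc["C(sex)", "PR(>F)"])},
            "stage": {"F": float(table.loc["C(stage)", "F"]), "p": float(table.loc["C(stage)", "PR(>F)"])},
            "interaction": {
                "F": float(table.loc["C(sex):C(stage)", "F"]),
                "p": float(table.loc["C(sex):C(stage)", "PR(>F)"]),
            },
        }
        cells = (df["sex"].astype(str) + ":" + df["stage"].astype(str)).to_numpy()
        pairs = [
            ("M:nestling", "F:nestling"),
            ("M:adult", "F:adult"),
            ("M:nestling", "M:adult"),
            ("F:nestling", "F:adult"),
        ]
        out[metric] = {
            "anova": effects,
            "tukey": _tukey_cellwise(df["y"].to_numpy(dtype=float), cells, pairs),
        }
    return out


def welch_test(group_a, group_b) -> dict[str, float]:
    """Welch's two-sample t-test (unequal variances) with Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def ancova_nestling_adult(
    paired: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    standardize_within_stage: bool = True,
) -> pd.DataFrame:
    """Regress adult color on nestling color within individuals.

    ``paired`` has one row per individual with columns sex and, per metric,
    ``<metric>_nestling`` and ``<metric>_adult``. Values are z-scored
    within stage before fitting. Both the with-sex and without-sex fits
    are computed; the reported model keeps the sex intercept offset when
    it is significant at 0.05 (hue metrics typically retain it, saturation
    and brightness do not). Returns one row per metric with slope b, its
    t statistic and p, model F, R^2, and the sex offset diagnostics.
    """
    if len(paired) < 3:
        raise ValueError("need at least three paired individuals")
    rows = []
    for metric in metrics:
        x = paired[f"{metric}_nestling"].to_numpy(dtype=float)
        y = paired[f"{metric}_adult"].to_numpy(dtype=float)
        if standardize_within_stage:
            x = (x - x.mean()) / x.std(ddof=1)
            y = (y - y.mean()) / y.std(ddof=1)
        df = pd.DataFrame({"x": x, "y": y, "sex": paired["sex"].to_numpy()})
        if df["sex"].nunique() < 2:
            raise ValueError("both sexes required for the sex covariate")
        fit_sex = smf.ols("y ~ x + C(sex)", data=df).fit()
        fit_plain = smf.ols("y ~ x", data=df).fit()
        sex_term = [c for c in fit_sex.params.index if c.startswith("C(sex)")][0]
        sex_p = float(fit_sex.pvalues[sex_term])
        keep_sex = sex_p < 0.05
        fit = fit_sex if keep_sex else fit_plain
        rows.append(
            {
                "metric": metric,
                "slope": float(fit.params["x"]),
                "slope_t": float(fit.tvalues["x"]),
                "slope_p": float(fit.pvalues["x"]),
                "model_F": float(fit.fvalue),
                "model_p": float(fit.f_pvalue),
                "r_squared": float(fit.rsquared),
                "sex_offset": float(fit_sex.params[sex_term]),
                "sex_offset_p": sex_p,
                "sex_term_retained": keep_sex,
                "df_resid": float(fit.df_resid),
            }
        )
    return pd.DataFrame(rows)


def spearman_check(fitness, labels) -> dict[str, float]:
    """Spearman rank correlation (midrank ties) between a fitness measure
    and arbitrary categorical band labels coded as integers."""
    f = np.asarray(fitness, dtype=float)
    lab = pd.Series(labels)
    codes = lab.astype("category").cat.codes.to_numpy(dtype=float) if lab.dtype == object else lab.to_numpy(dtype=float)
    if f.size < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(f) == 0 or np.ptp(codes) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(f, codes)
    return {"rho": float(rho), "p": float(p)}
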