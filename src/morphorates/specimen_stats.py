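"""Specimen-level statistics: repeatability, shape~species models, F test.

Three analyses operate on specimen-level shape descriptors (typically PC
scores of the Fourier coefficients):

* among-species repeatability (intraclass correlation) from a one-way
  ANOVA with the unbalanced-design group-size correction, with a
  parametric-bootstrap standard error / confidence interval and a
  permutation p-value;
* linear models of a PC score on species (+ sex) + trait size with
  sequential (type-I) sums of squares, reported as an ANOVA table;
* a two-sided variance-ratio F test between two samples of species
  values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatabilityResult",
    "AnovaTable",
    "VarianceRatioResult",
    "repeatability",
    "shape_effects_model",
    "variance_ratio_test",
    "f_two_sided_pvalue",
]


# ---------------------------------------------------------------------------
# Repeatability (ICC)


@dataclass(frozen=True)
class RepeatabilityResult:
    """One-way ANOVA intraclass correlation with uncertainty."""

    icc: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_groups: int
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "icc": [self.icc],
                "se": [self.se],
                "ci_lower": [self.ci_lower],
                "ci_upper": [self.ci_upper],
                "p_value": [self.p_value],
                "n_groups": [self.n_groups],
                "n_total": [self.n_total],
            }
        )


def _icc_oneway(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Clamped one-way ICC for integer-coded groups."""
    n_total = len(values)
    counts = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=values, minlength=k)
    group_means = sums / counts
    grand = values.mean()
    ss_between = float(np.sum(counts * (group_means[: len(counts)] - grand) ** 2))
    ss_within = float(np.sum((values - group_means[codes]) ** 2))
    df_between = k - 1
    df_within = n_total - k
    ms_a = ss_between / df_between
    ms_w = ss_within / df_within
    n0 = (n_total - np.sum(counts**2) / n_total) / (k - 1)
    denom = ms_a + (n0 - 1.0) * ms_w
    if denom <= 0:
        return 0.0
    return float(np.clip((ms_a - ms_w) / denom, 0.0, 1.0))


def repeatability(
    values,
    groups,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int | None = None,
) -> RepeatabilityResult:
    """Among-group repeatability of a specimen-level descriptor.

    ICC = (MS_A - MS_W) / (MS_A + (n0 - 1) MS_W) with the unbalanced
    group-size constant n0 = (sum n_i - sum n_i^2 / sum n_i) / (k - 1).
    Negative estimates are clamped to zero (repeatability is reported on
    [0, 1]).  The SE and percentile CI come from a parametric bootstrap
    of the fitted variance components; the p-value from permuting values
    across groups with the (b + 1) / (m + 1) convention.
    """
    values = np.asarray(values, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    k = len(labels)
    n_total = len(values)
    if len(codes) != n_total:
        raise DataError("values and groups must have the same length")
    if k < 2:
        raise DataError("repeatability needs at least 2 groups")
    counts = np.bincount(codes)
    if n_total - k < 1:
        raise DataError(
            "repeatability undefined: no within-group replication "
            "(all groups are singletons)"
        )
    icc = _icc_oneway(values, codes, k)

    # parametric bootstrap from the fitted variance components
    group_means = np.bincount(codes, weights=values) / counts
    grand = values.mean()
    ms_a = float(np.sum(counts * (group_means - grand) ** 2) / (k - 1))
    ms_w = float(np.sum((values - group_means[codes]) ** 2) / (n_total - k))
    n0 = (n_total - np.sum(counts.astype(float) ** 2) / n_total) / (k - 1)
    var_a = max((ms_a - ms_w) / n0, 0.0)
    var_w = ms_w
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        effects = rng.normal(0.0, np.sqrt(var_a), size=k)
        sim = effects[codes] + rng.normal(0.0, np.sqrt(var_w), size=n_total)
        boots[b] = _icc_oneway(sim, codes, k)
    se = float(boots.std(ddof=1))
    ci_lower = float(np.clip(np.quantile(boots, 0.025), 0.0, 1.0))
    ci_upper = float(np.clip(np.quantile(boots, 0.975), 0.0, 1.0))

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if _icc_oneway(perm, codes, k) >= icc:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return RepeatabilityResult(icc, se, ci_lower, ci_upper, p, k, n_total)


# ---------------------------------------------------------------------------
# Shape ~ species (+ sex) + size models


@dataclass(frozen=True)
class AnovaTable:
    """Sequential (type-I) ANOVA rows: effect, F, df_num, df_den, p."""

    frame: pd.DataFrame
    n_used: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def shape_effects_model(pc_scores, species, size, sex=None) -> AnovaTable:
    """Linear model of a shape PC on species (+ sex) and trait size.

    Effects enter in the order species, sex (when provided), size, with
    sequential sums of squares.  Rows with missing score, size or sex are
    excluded (complete-case analysis) and the exclusion count is logged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = pd.DataFrame(
        {
            "score": np.asarray(pc_scores, dtype=float),
            "species": np.asarray(species).astype(str),
            "size": np.asarray(size, dtype=float),
        }
    )
    terms = ["C(species)"]
    if sex is not None:
        data["sex"] = np.asarray(sex).astype(str)
        terms.append("C(sex)")
    terms.append("size")
    complete = data.dropna()
    n_excluded = len(data) - len(complete)
    if n_excluded:
        logger.info("shape_effects_model: excluded %d incomplete rows", n_excluded)
    if complete["species"].nunique() < 2:
        raise DataError("model needs at least 2 species with complete data")
    if (complete["size"] <= 0).any():
        raise DataError("trait sizes must be positive")
    if sex is not None and complete["sex"].nunique() < 2:
        raise DataError("sex term is constant; drop it or supply both sexes")

    formula = "score ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=complete).fit()
    if fit.df_resid < 1:
        raise DataError("model is saturated; no residual degrees of freedom")
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise DataError("rank-deficient design: an effect is aliased")
    table = sm.stats.anova_lm(fit, typ=1)
    rows = []
    pretty = {"C(species)": "species", "C(sex)": "sex", "size": "size"}
    for term in table.index:
        if term == "Residual":
            continue
        rows.append(
            {
                "effect": pretty.get(term, term),
                "F": float(table.loc[term, "F"]),
                "df_num": int(table.loc[term, "df"]),
                "df_den": int(table.loc["Residual", "df"]),
                "p_value": float(table.loc[term, "PR(>F)"]),
            }
        )
    return AnovaTable(pd.DataFrame(rows), len(complete), n_excluded)


# ---------------------------------------------------------------------------
# Variance-ratio F test


@dataclass(frozen=True)
class VarianceRatioResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    two_sided: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f_stat": [self.f_stat],
                "df1": [self.df1],
                "df2": [self.df2],
                "p_value": [self.p_value],
                "two_sided": [self.two_sided],
            }
        )


def f_two_sided_pvalue(f: float, df1: int, df2: int) -> float:
    """Two-sided p for an observed variance ratio: 2 * min(tails), capped at 1."""
    dist = stats.f(df1, df2)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def variance_ratio_test(x, y, two_sided: bool = True) -> VarianceRatioResult:
    """F test comparing the variances of two samples.

    F = s_x^2 / s_y^2 with df (n_x - 1, n_y - 1).  The default two-sided
    p doubles the smaller tail probability (so equal variances give
    p = 1 exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("both samples need at least 2 values")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise DataError("zero variance in the denominator sample")
    f = vx / vy
    df1, df2 = len(x) - 1, len(y) - 1
    if two_sided:
        p = f_two_sided_pvalue(f, df1, df2)
    else:
        p = float(stats.f(df1, df2).sf(f))
    return VarianceRatioResult(f, df1, df2, p, two_sided)
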