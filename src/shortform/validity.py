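"""Convergent and discriminant (known-groups) validity statistics.

Convergent validity correlates the questionnaire total with external
measures.  The correlation method is gated on normality: Shapiro-Wilk is
applied to each variable and Pearson's r is used only when both pass
(p > alpha_level); otherwise Spearman's rho.  Both coefficients are kept
in the result for transparency, along with the normality tests and which
variable triggered the choice.

Discriminant validity compares group means with an independent two-sample
t-test (Student's pooled-variance by default; Welch by flag), reporting
the mean difference with its 95% CI and Cohen's d from the pooled SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "ValidityReport",
    "normality_gated_correlation",
    "known_groups_test",
    "validity_battery",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int
    pearson_r: float
    spearman_rho: float
    shapiro: dict  # per-variable (W, p)
    rationale: str

    def __post_init__(self) -> None:
        assert abs(self.coefficient) <= 1 + 1e-12


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    mean_difference: float
    ci: tuple[float, float]
    t_statistic: float
    p_value: float
    cohens_d: float
    variant: str  # "pooled" or "welch"


@dataclass(frozen=True)
class ValidityReport:
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    group_comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in self.correlations.items():
            rows.append(
                dict(measure=name, kind="correlation", method=c.method,
                     estimate=c.coefficient, n=c.n, p_value=c.p_value)
            )
        for name, g in self.group_comparisons.items():
            rows.append(
                dict(measure=name, kind="known-groups", method=f"t-test ({g.variant})",
                     estimate=g.mean_difference, n=sum(g.group_sizes),
                     p_value=g.p_value, cohens_d=g.cohens_d,
                     ci_lower=g.ci[0], ci_upper=g.ci[1])
            )
        return pd.DataFrame(rows)


def normality_gated_correlation(
    x, y, alpha_level: float = 0.05
) -> CorrelationResult:
    """Correlate two paired vectors, choosing Pearson vs Spearman by
    Shapiro-Wilk normality of both variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw_x = stats.shapiro(x)
        sw_y = stats.shapiro(y)
    both_normal = sw_x.pvalue > alpha_level and sw_y.pvalue > alpha_level
    pear = stats.pearsonr(x, y)
    spear = stats.spearmanr(x, y)
    if both_normal:
        method, coef, p = "pearson", pear.statistic, pear.pvalue
        rationale = "both variables passed Shapiro-Wilk"
    else:
        failed = [name for name, sw in (("x", sw_x), ("y", sw_y))
                  if sw.pvalue <= alpha_level]
        method, coef, p = "spearman", spear.statistic, spear.pvalue
        rationale = f"Shapiro-Wilk rejected normality for: {', '.join(failed)}"
    return CorrelationResult(
        method=method, coefficient=float(coef), p_value=float(p), n=int(x.size),
        pearson_r=float(pear.statistic), spearman_rho=float(spear.statistic),
        shapiro={"x": (float(sw_x.statistic), float(sw_x.pvalue)),
                 "y": (float(sw_y.statistic), float(sw_y.pvalue))},
        rationale=rationale,
    )


def known_groups_test(
    scores, groups, level: float = 0.95, variant: str = "pooled"
) -> GroupComparison:
    """Independent two-sample t-test between the two groups in ``groups``.

    The mean difference is group1 minus group0 (labels sorted), with a CI
    at ``level`` and Cohen's d from the pooled SD (n-2 denominator).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(scores)
    if groups.dtype.kind == "f":
        ok &= ~np.isnan(groups)
    scores, groups = scores[ok], groups[ok]
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    a = scores[groups == labels[1]]
    b = scores[groups == labels[0]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = a.mean() - b.mean()
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    sp = np.sqrt(sp2)
    d = diff / sp if sp > 0 else 0.0
    if variant == "pooled":
        t_res = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
        se = sp * np.sqrt(1 / a.size + 1 / b.size)
    elif variant == "welch":
        t_res = stats.ttest_ind(a, b, equal_var=False)
        df = t_res.df
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    return GroupComparison(
        group_labels=(str(labels[1]), str(labels[0])),
        group_sizes=(int(a.size), int(b.size)),
        mean_difference=float(diff),
        ci=(float(diff - tcrit * se), float(diff + tcrit * se)),
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        cohens_d=float(d),
        variant=variant,
    )


def validity_battery(
    scores: pd.Series,
    covariates: pd.DataFrame | None = None,
    groupings: pd.DataFrame | None = None,
    alpha_level: float = 0.05,
    t_variant: str = "pooled",
) -> ValidityReport:
    """One gated correlation per covariate column and one known-groups test
    per grouping column, each on its pairwise-complete cases.

    Covariates with fewer than 4 complete pairs are skipped with a warning.
    Misaligned columns (length differing from the score vector) raise an
    error naming the column.
    """
    scores = pd.Series(scores)
    correlations: dict[str, CorrelationResult] = {}
    comparisons: dict[str, GroupComparison] = {}
    skipped: list[str] = []
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if len(col) != len(scores):
                raise ValueError(
                    f"covariate {name!r} has {len(col)} rows, scores have {len(scores)}"
                )
            ok = ~(scores.isna() | col.isna())
            if ok.sum() < 4:
                warnings.warn(f"covariate {name!r}: fewer than 4 complete pairs; skipped")
                skipped.append(name)
                continue
            correlations[name] = normality_gated_correlation(
                scores[ok], col[ok], alpha_level=alpha_level
            )
    if groupings is not None:
        for name in groupings.columns:
            col = groupings[name]
            if len(col) != len(scores):
                raise ValueError(
                    f"grouping {name!r} has {len(col)} rows, scores have {len(scores)}"
                )
            ok = ~(scores.isna() | col.isna())
            comparisons[name] = known_groups_test(
                scores[ok], col[ok], variant=t_variant
            )
    return ValidityReport(
        correlations=correlations, group_comparisons=comparisons, skipped=skipped
    )
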