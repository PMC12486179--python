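"""Two-group comparison statistics with the cohort-study decision tree.

Continuous variables are routed by a normality pre-test (Lilliefors-
corrected one-sample Kolmogorov-Smirnov, parameters estimated from the
sample) to either a pooled-variance independent-samples t-test (both
groups normal) or a two-sided Mann-Whitney U test.  Categorical variables
default to the uncorrected Pearson chi-squared test, with Yates-corrected
chi-squared and Fisher's exact test available explicitly; Fisher is used
automatically when any expected cell count falls below 1.

Continuous summaries are displayed as mean (SD), categorical as n (%);
significance is two-tailed at 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "normality",
    "compare_continuous",
    "compare_categorical",
    "build_table",
    "table_to_dataframe",
]

ALPHA = 0.05


@dataclass
class NormalityResult:
    statistic: float
    p: float
    is_normal: bool


@dataclass
class ComparisonResult:
    """One row of a baseline-characteristics comparison table."""

    variable: str
    test: str  # t, mann_whitney, chi2, chi2_yates, fisher
    statistic: float
    p: float
    summary_a: str
    summary_b: str
    n_a: int
    n_b: int
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def normality(
    sample, alpha: float = ALPHA, method: str = "lilliefors"
) -> NormalityResult:
    """One-sample KS normality test with estimated mean/SD.

    ``lilliefors`` (default) corrects the KS null distribution for the
    estimated parameters; ``ks`` is the uncorrected one-sample KS as
    historically reported by some statistics packages.
    """
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError(f"normality test needs n >= 4, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
    elif method == "ks":
        stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return NormalityResult(float(stat), float(p), bool(p > alpha))


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"


def compare_continuous(
    a,
    b,
    variable: str = "value",
    alpha: float = ALPHA,
    welch: bool = False,
    normality_method: str = "lilliefors",
) -> ComparisonResult:
    """Two-sided two-group comparison of a continuous variable.

    Pooled-variance t-test when both samples pass the normality pre-test
    (Welch behind the ``welch`` flag), otherwise Mann-Whitney U with the
    normal approximation and tie correction.  Samples too small or too
    degenerate for the pre-test (n < 4 or constant) route to Mann-Whitney.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    try:
        both_normal = (
            normality(a, alpha, normality_method).is_normal
            and normality(b, alpha, normality_method).is_normal
        )
    except ValueError:
        both_normal = False
    if both_normal:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        test = "t_welch" if welch else "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
        test = "mann_whitney"
    return ComparisonResult(
        variable=variable, test=test, statistic=float(stat),
        p=float(min(p, 1.0)), summary_a=_mean_sd(a), summary_b=_mean_sd(b),
        n_a=int(a.size), n_b=int(b.size), significant=bool(p < alpha),
    )


def compare_categorical(
    table, variable: str = "value", method: str = "auto", alpha: float = ALPHA
) -> ComparisonResult:
    """Two-group categorical comparison on a 2xk count table.

    ``auto`` uses the uncorrected Pearson chi-squared, switching to
    Fisher's exact test (2x2 only) when any expected count is below 1;
    ``chi2``, ``chi2_yates`` and ``fisher`` force a route.  A level absent
    in both groups is dropped with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError(f"expected a 2xk table, got shape {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=1) == 0).any():
        raise ValueError("both groups must have at least one observation")
    empty_cols = t.sum(axis=0) == 0
    if empty_cols.any():
        logger.warning(
            "compare_categorical %s: dropping %d all-zero level(s)",
            variable, int(empty_cols.sum()),
        )
        t = t[:, ~empty_cols]
        if t.shape[1] < 2:
            raise ValueError("fewer than two non-empty levels remain")

    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    if method == "auto":
        method = "fisher" if (expected < 1).any() and t.shape == (2, 2) else "chi2"

    if method == "chi2":
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    elif method == "chi2_yates":
        stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    elif method == "fisher":
        if t.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        stat, p = sps.fisher_exact(t)
    else:
        raise ValueError(f"unknown method {method!r}")

    na, nb = int(t[0].sum()), int(t[1].sum())
    if t.shape[1] == 2:
        # binary variable: report the event (last) level as n (%)
        summary_a = format_n_pct(int(t[0, -1]), na)
        summary_b = format_n_pct(int(t[1, -1]), nb)
    else:
        summary_a = "/".join(str(int(c)) for c in t[0])
        summary_b = "/".join(str(int(c)) for c in t[1])
    return ComparisonResult(
        variable=variable, test=method, statistic=float(stat),
        p=float(min(p, 1.0)), summary_a=summary_a, summary_b=summary_b,
        n_a=na, n_b=nb, significant=bool(p < alpha),
    )


def format_n_pct(k: int, n: int) -> str:
    """Count with percentage, e.g. 5 of 45 -> '5 (11.11)'."""
    return f"{k} ({100.0 * k / n:.2f})" if n else f"{k} (-)"


def build_table(
    subjects,
    variables: dict[str, str] | list[str] | None = None,
    group_col: str = "group",
    alpha: float = ALPHA,
    **kwargs,
) -> list[ComparisonResult]:
    """One ComparisonResult per variable of a two-group subject table.

    ``variables`` maps column name to 'continuous' or 'categorical'; a bare
    list (or None = all non-id columns) infers the type — non-numeric,
    boolean, or integer columns with at most 3 distinct values are treated
    as categorical.  Missing values are dropped pairwise per variable.
    """
    import pandas as pd

    groups = subjects[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two group levels, got {list(groups)}")
    ga, gb = groups
    if variables is None:
        variables = [c for c in subjects.columns
                     if c not in (group_col, "subject_id")]
    if not isinstance(variables, dict):
        inferred = {}
        for name in variables:
            col = subjects[name]
            vals = col.dropna()
            categorical = (
                not pd.api.types.is_numeric_dtype(col)
                or pd.api.types.is_bool_dtype(col)
                or (pd.api.types.is_integer_dtype(col) and vals.nunique() <= 3)
            )
            inferred[name] = "categorical" if categorical else "continuous"
        variables = inferred

    results = []
    for name, kind in variables.items():
        if name not in subjects.columns:
            raise KeyError(f"variable {name!r} not in the subject table")
        sub = subjects[[group_col, name]].dropna()
        a = sub.loc[sub[group_col] == ga, name]
        b = sub.loc[sub[group_col] == gb, name]
        if kind == "continuous":
            results.append(compare_continuous(a.to_numpy(float), b.to_numpy(float),
                                              variable=name, alpha=alpha, **kwargs))
        else:
            levels = sorted(sub[name].unique())
            counts = [[int((g == lv).sum()) for lv in levels] for g in (a, b)]
            results.append(compare_categorical(counts, variable=name, alpha=alpha))
    return results


def table_to_dataframe(results: list[ComparisonResult]):
    """Comparison rows as a tidy DataFrame (for CSV/markdown export)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "variable": r.variable, "group_a": r.summary_a, "group_b": r.summary_b,
            "n_a": r.n_a, "n_b": r.n_b, "test": r.test,
            "statistic": r.statistic, "p": r.p, "significant": r.significant,
        }
        for r in results
    ])
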