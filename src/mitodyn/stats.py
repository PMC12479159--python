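"""Group statistics: normality, two-group motility tests, ANOVA + Tukey–Kramer.

Net displacements are log-normal, so group comparisons act on the log scale:
the two-group test is Welch's t on log displacements and its effect size is
the geometric-mean ratio.  Multi-group comparisons use one-way ANOVA with
Tukey–Kramer post hoc pairwise tests (studentized range, honoring unequal
group sizes); no additional multiple-testing correction is applied beyond
Tukey–Kramer.  A repeated-measures ANOVA keyed by replicate-day identifier
is available for designs replicated on separate days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: validity floor for the omnibus normality test
MIN_N_NORMALITY = 20


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical comparison: statistic, p-value and the method used."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def normality_test(sample: Sequence[float] | np.ndarray, label: str = "sample"
                   ) -> ComparisonResult:
    """D'Agostino–Pearson omnibus normality test.

    Combines skewness and kurtosis z-scores into K² = z_s² + z_k², referred
    to χ²(2).  Requires n >= 20 — below that the component z approximations
    are unreliable; split or pool data instead of forcing the test.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < MIN_N_NORMALITY:
        raise ValueError(
            f"normality test needs n >= {MIN_N_NORMALITY} (got {x.size}); "
            "pool samples or use a qualitative check at small n"
        )
    k2, p = sps.normaltest(x)
    return ComparisonResult(
        group_a=label,
        group_b="normal",
        statistic=float(k2),
        p_value=float(p),
        method="dagostino-pearson",
    )


def compare_motility(
    log_displacements_a: Sequence[float] | np.ndarray,
    log_displacements_b: Sequence[float] | np.ndarray,
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Two-sided Welch test on log displacements with a geometric-mean ratio.

    ``extra["gm_ratio"]`` is ``exp(mean(log a) - mean(log b))``: the factor
    by which group A's geometric mean displacement exceeds group B's.
    """
    a = np.asarray(log_displacements_a, dtype=float)
    b = np.asarray(log_displacements_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both samples need n >= 3")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        statistic=float(t),
        p_value=float(p),
        method="welch-log",
        extra={"gm_ratio": float(np.exp(a.mean() - b.mean()))},
    )


def anova_tukey(
    groups: Sequence[Sequence[float] | np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """One-way ANOVA with Tukey–Kramer post hoc pairwise comparisons.

    Returns the omnibus ANOVA result first, followed by every pairwise
    Tukey–Kramer comparison (studentized-range p-values, valid for unequal
    group sizes).  Requires at least three groups of n >= 2 — with two
    groups use :func:`compare_motility` or a plain t-test.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("ANOVA + Tukey needs >= 3 groups; use a two-sample test")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    f_stat, f_p = sps.f_oneway(*arrays)
    results = [
        ComparisonResult(
            group_a="all",
            group_b="all",
            statistic=float(f_stat),
            p_value=float(f_p),
            method="anova",
        )
    ]
    values = np.concatenate(arrays)
    codes = np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(tk.groupsunique, 2))
    for (g1, g2), meandiff, p_adj in zip(pairs, tk.meandiffs, tk.pvalues):
        results.append(
            ComparisonResult(
                group_a=str(g1),
                group_b=str(g2),
                statistic=float(meandiff),
                p_value=float(p_adj),
                method="tukey-kramer",
                extra={"anova_p": float(f_p)},
            )
        )
    return results


def repeated_measures_anova(
    values: Sequence[float],
    group: Sequence[str],
    replicate: Sequence[str],
) -> ComparisonResult:
    """Repeated-measures ANOVA keyed by replicate identifier (e.g. day).

    Each replicate must contribute one value per group (balanced design);
    use the one-way path otherwise.
    """
    df = pd.DataFrame({"value": values, "group": group, "replicate": replicate})
    res = AnovaRM(df, depvar="value", subject="replicate", within=["group"]).fit()
    row = res.anova_table.iloc[0]
    return ComparisonResult(
        group_a="all",
        group_b="all",
        statistic=float(row["F Value"]),
        p_value=float(row["Pr > F"]),
        method="anova-rm",
    )


def comparisons_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of comparison results for CSV export."""
    return pd.DataFrame(
        {
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
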