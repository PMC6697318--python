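"""Two-sample comparison machinery for IOU score distributions.

Two score sets are compared with a two-sided, unpaired Welch t-test (unequal
variances) when both samples pass a normality gate, and with a two-sided
unpaired Mann-Whitney U-test otherwise.  The normality gate is Shapiro-Wilk
at alpha = 0.05 by default.  Significance is flagged at the 1% level.

Mann-Whitney p-values use exact enumeration when the pooled sample size is at
most ``exact_threshold`` (default 12) and there are no ties, and the normal
approximation with tie and continuity corrections otherwise, so p-values are
reproducible bit-for-bit across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import COMPARTMENT_NAMES, ScoreSet, TestResult, ValidationError

__all__ = [
    "StatsConfig",
    "normality_gate",
    "welch_t_test",
    "mann_whitney_u",
    "compare_score_sets",
    "comparison_table",
]


@dataclass
class StatsConfig:
    normality_alpha: float = 0.05
    significance_alpha: float = 0.01
    exact_mw_threshold: int = 12

    def __post_init__(self) -> None:
        for a in (self.normality_alpha, self.significance_alpha):
            if not 0.0 < a < 1.0:
                raise ValidationError("alphas must lie in (0, 1)")


def normality_gate(x, alpha: float = 0.05) -> bool:
    """True if Shapiro-Wilk does not reject approximate normality at ``alpha``.

    A degenerate (constant) sample is never called normal.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValidationError("normality gate needs at least 3 values")
    if np.ptp(x) == 0.0:
        return False
    return bool(stats.shapiro(x).pvalue >= alpha)


def welch_t_test(x, y) -> float:
    """Two-sided p-value of the unequal-variance (Welch) t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        if x[0] == y[0]:
            return 1.0  # identical constants: no evidence of difference
        raise ValidationError("both samples are constant with zero variance")
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def mann_whitney_u(x, y, exact_threshold: int = 12) -> float:
    """Two-sided p-value of the unpaired Mann-Whitney U-test.

    Exact enumeration for small tie-free samples (pooled n <= threshold);
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ValidationError("each sample needs at least 1 value")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= exact_threshold and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def compare_score_sets(
    a: ScoreSet, b: ScoreSet, config: StatsConfig | None = None
) -> TestResult:
    """Normality-gated comparison of two IOU score distributions.

    Welch's t-test if both samples pass the normality gate, Mann-Whitney U
    otherwise; two-sided either way, flagged at the 1% significance level.
    """
    config = config or StatsConfig()
    if a.compartment != b.compartment:
        raise ValidationError(
            f"cannot compare different compartments "
            f"({a.compartment.name} vs {b.compartment.name})"
        )
    na = normality_gate(a.scores, alpha=config.normality_alpha)
    nb = normality_gate(b.scores, alpha=config.normality_alpha)
    if na and nb:
        test = "welch_t_two_sided"
        p = welch_t_test(a.scores, b.scores)
    else:
        test = "mann_whitney_u"
        p = mann_whitney_u(
            a.scores, b.scores, exact_threshold=config.exact_mw_threshold
        )
    return TestResult(
        test_used=test,
        p_value=p,
        significant_at_1pct=p < config.significance_alpha,
        normality_verdicts=(na, nb),
    )


def comparison_table(
    pairs: list[tuple[str, ScoreSet, ScoreSet]], config: StatsConfig | None = None
) -> pd.DataFrame:
    """Benchmark-table-shaped report: one row per (group, compartment) pair.

    ``pairs`` holds (group label, score set A, score set B); each row records
    the test used, the p-value and the 1%-level significance flag.
    """
    rows = []
    for group, a, b in pairs:
        res = compare_score_sets(a, b, config=config)
        rows.append(
            {
                "group": group,
                "compartment": COMPARTMENT_NAMES[a.compartment],
                "test": (
                    "Two-sided t test"
                    if res.test_used == "welch_t_two_sided"
                    else "Mann-Whitney U-test"
                ),
                "p_value": res.p_value,
                "significant_at_1pct": res.significant_at_1pct,
            }
        )
    return pd.DataFrame(rows)
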