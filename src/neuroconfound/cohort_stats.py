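"""Descriptive group comparisons from summaries or raw columns.

Cohen's d uses the average-variance denominator sqrt((s1^2 + s2^2)/2); the
two-sample t is the pooled-variance Student t computed from summary
statistics; the 2x2 chi-square is Pearson's without continuity correction;
the Mann-Whitney U uses midranks with a tie-corrected normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "cohens_d",
    "two_sample_t_summary",
    "chi_square_2x2",
    "mann_whitney_u",
    "cohort_comparison_table",
]


@dataclass
class GroupSummary:
    """n, mean and SD of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd <= 0:
            raise ValueError("group SD must be positive")

    @classmethod
    def from_values(cls, values, ddof: int = 1) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=ddof)))


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Standardized mean difference (b - a) / sqrt((sd_a^2 + sd_b^2)/2)."""
    denom = np.sqrt((a.sd**2 + b.sd**2) / 2.0)
    if denom == 0:
        raise ValueError("zero SDs; d undefined")
    return float((b.mean - a.mean) / denom)


def two_sample_t_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance Student t from summary statistics: (t, df, p)."""
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance; t undefined")
    se = np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    t = float((a.mean - b.mean) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square of a 2x2 table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal; chi-square undefined")
    expected = row @ col / total
    x2 = float(np.sum((table - expected) ** 2 / expected))
    p = float(stats.chi2.sf(x2, df=1))
    return x2, p


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with two-tailed normal-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cohort_comparison_table(subjects: pd.DataFrame, train_mask, test_mask) -> pd.DataFrame:
    """Train-vs-test comparison of age, sex, handedness and strength.

    Mirrors the usual cohort-description table: t-test for age, 2x2
    chi-square for sex and handedness, Mann-Whitney U for the (bimodal)
    strength score.
    """
    tr = subjects.loc[np.asarray(train_mask)]
    te = subjects.loc[np.asarray(test_mask)]
    rows = []

    t, df, p = two_sample_t_summary(
        GroupSummary.from_values(tr["age"]), GroupSummary.from_values(te["age"])
    )
    rows.append(
        {
            "variable": "age",
            "train": f"{tr['age'].mean():.1f} ± {tr['age'].std():.1f}",
            "test": f"{te['age'].mean():.1f} ± {te['age'].std():.1f}",
            "statistic": "t",
            "value": t,
            "p": p,
        }
    )

    for var, positive in (("sex", "F"), ("handedness", "right")):
        counts = [
            [(tr[var] == positive).sum(), (tr[var] != positive).sum()],
            [(te[var] == positive).sum(), (te[var] != positive).sum()],
        ]
        x2, p = chi_square_2x2(counts)
        rows.append(
            {
                "variable": var,
                "train": int(counts[0][0]),
                "test": int(counts[1][0]),
                "statistic": "X2",
                "value": x2,
                "p": p,
            }
        )

    u, p = mann_whitney_u(tr["strength"], te["strength"])
    rows.append(
        {
            "variable": "strength",
            "train": f"{tr['strength'].mean():.1f} ± {tr['strength'].std():.1f}",
            "test": f"{te['strength'].mean():.1f} ± {te['strength'].std():.1f}",
            "statistic": "U",
            "value": u,
            "p": p,
        }
    )
    return pd.DataFrame(rows)
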