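"""Group-difference and classifier-comparison statistics.

Demographic tables report mean +/- SD per group; the group comparison is a
pooled-variance two-sample t-test computed directly from those summaries.
Categorical demographics use the Pearson chi-square on the 2x2 table
without continuity correction.  Competing classifiers evaluated on the same
subjects are compared with the exact (binomial) McNemar test on discordant
pairs, which stays valid at the small discordant counts a ~60-subject
cohort produces.  Per-cost group comparisons of global network metrics are
uncorrected two-sample t-tests at alpha = 0.05, with an optional Bonferroni
flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "two_sample_t",
    "two_sample_t_raw",
    "chi_square_2x2",
    "mcnemar",
    "metric_group_comparison",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD (n-1 denominator) of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def two_sample_t(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Two-sided pooled-variance t-test from group summaries."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero variance: t-test undefined")
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    df = a.n + b.n - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def two_sample_t_raw(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Same pooled test from raw samples (convenience / consistency check)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        GroupSummary(len(x), float(x.mean()), float(x.std(ddof=1))),
        GroupSummary(len(y), float(y.mean()), float(y.std(ddof=1))),
    )


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, two-sided, WITHOUT
    Yates continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, _, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(chi2), float(p)


def mcnemar(
    correct_a: np.ndarray,
    correct_b: np.ndarray,
    exact: bool = True,
) -> float:
    """Two-sided McNemar p-value from per-subject correctness indicators.

    Exact variant (default): p = min(1, 2 * BinomCDF(min(b, c); b + c, 1/2))
    on the discordant counts.  ``exact=False`` gives the asymptotic
    chi-square form (b - c)^2 / (b + c).  Zero discordant pairs -> p = 1
    with a warning.
    """
    a = np.asarray(correct_a, dtype=bool)
    c_ = np.asarray(correct_b, dtype=bool)
    if a.shape != c_.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int((a & ~c_).sum())  # A right, B wrong
    c = int((~a & c_).sum())  # A wrong, B right
    if b + c == 0:
        warnings.warn("no discordant pairs: McNemar p = 1", stacklevel=2)
        return 1.0
    if exact:
        return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), b + c, 0.5)))
    chi2 = (b - c) ** 2 / (b + c)
    return float(sps.chi2.sf(chi2, df=1))


def metric_group_comparison(
    metric_table: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(band, cost, metric) two-sample t-tests between groups.

    ``metric_table`` is tidy with columns subject, group (two levels), band,
    cost, metric, value.  Returns a tidy table with t, p and a significance
    flag at ``alpha`` (uncorrected unless ``bonferroni=True``).
    """
    required = {"subject", "group", "band", "cost", "metric", "value"}
    missing = required - set(metric_table.columns)
    if missing:
        raise ValueError(f"metric_table missing columns: {sorted(missing)}")
    groups = sorted(metric_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    rows = []
    for (band, cost, metric), sub in metric_table.groupby(["band", "cost", "metric"]):
        x = sub.loc[sub["group"] == groups[0], "value"].to_numpy(dtype=float)
        y = sub.loc[sub["group"] == groups[1], "value"].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"both groups need >= 2 subjects at ({band}, {cost}, {metric})")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if x.mean() == y.mean() else (float("inf"), 0.0)
        else:
            res = two_sample_t_raw(x, y)
            t, p = res.t, res.p
        rows.append({"band": band, "cost": cost, "metric": metric, "t": t, "p": p})
    out = pd.DataFrame(rows)
    threshold = alpha / len(out) if bonferroni else alpha
    out["significant"] = out["p"] < threshold
    return out
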