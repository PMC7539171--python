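"""Two-group statistics: two-sample t-tests (raw data and summary form)
and the Mann–Whitney U test.

The summary-statistics t-test reconstructs group SDs from printed
mean ± SEM and n (SD = SEM·√n) and evaluates the same t statistic a
raw-data test would produce, enabling verification of published
comparisons without the underlying recordings.  Welch's unequal-variance
form is the default; the pooled-variance (Student) form is available
because published work often leaves the variant unstated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

WELCH = "welch"
POOLED = "pooled"
MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test result with full group summaries."""

    feature: str
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    sem1: float
    sem2: float
    n1: int
    n2: int
    statistic: float
    df: float
    p: float
    test_variant: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def summary(self) -> str:
        stat = "t" if self.test_variant in (WELCH, POOLED) else "U"
        df = f", df = {self.df:.2f}" if math.isfinite(self.df) else ""
        return (f"{self.feature}: {self.mean1:.2f} ± {self.sem1:.2f} (n={self.n1})"
                f" vs {self.mean2:.2f} ± {self.sem2:.2f} (n={self.n2}); "
                f"{stat} = {self.statistic:.3f}{df}, p = {self.p:.4g} "
                f"[{self.test_variant}]")


def _summaries(x: np.ndarray, y: np.ndarray) -> dict:
    return {
        "mean1": float(np.mean(x)), "mean2": float(np.mean(y)),
        "sd1": float(np.std(x, ddof=1)) if x.size > 1 else math.nan,
        "sd2": float(np.std(y, ddof=1)) if y.size > 1 else math.nan,
        "sem1": float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else math.nan,
        "sem2": float(np.std(y, ddof=1) / math.sqrt(y.size)) if y.size > 1 else math.nan,
        "n1": int(x.size), "n2": int(y.size),
    }


def two_sample_ttest(x, y, variant: str = WELCH, *, feature: str = "",
                     ) -> GroupComparison:
    """Two-tailed two-sample t-test on raw values (Welch by default).

    When both groups have zero variance and equal means the comparison is
    degenerate and reported as t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    if variant not in (WELCH, POOLED):
        raise ValueError(f"unknown t-test variant {variant!r}")
    s = _summaries(x, y)
    if s["sd1"] == 0.0 and s["sd2"] == 0.0:
        if s["mean1"] == s["mean2"]:
            t, df, p = 0.0, float(x.size + y.size - 2), 1.0
        else:
            t, df, p = math.inf, float(x.size + y.size - 2), 0.0
    else:
        res = sps.ttest_ind(x, y, equal_var=(variant == POOLED))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(feature=feature, statistic=t, df=df, p=p,
                           test_variant=variant, **s)


def ttest_from_summary(mean1: float, sem1: float, n1: int,
                       mean2: float, sem2: float, n2: int,
                       variant: str = WELCH, *, feature: str = "",
                       ) -> GroupComparison:
    """Two-tailed two-sample t-test from printed mean ± SEM and n.

    Welch: t = (m1 − m2)/√(sem1² + sem2²) with Welch–Satterthwaite df.
    Pooled: group SDs are reconstructed (SD = SEM·√n) and combined into the
    pooled variance with df = n1 + n2 − 2.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    sd1 = sem1 * math.sqrt(n1)
    sd2 = sem2 * math.sqrt(n2)
    diff = mean1 - mean2
    if variant == WELCH:
        se = math.hypot(sem1, sem2)
        df = (sem1 ** 2 + sem2 ** 2) ** 2 / (
            sem1 ** 4 / (n1 - 1) + sem2 ** 4 / (n2 - 1))
    elif variant == POOLED:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se == 0.0:
        t, p = (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
    else:
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(feature=feature, mean1=mean1, mean2=mean2,
                           sd1=sd1, sd2=sd2, sem1=sem1, sem2=sem2,
                           n1=n1, n2=n2, statistic=t, df=df, p=p,
                           test_variant=variant)


def mann_whitney(x, y, *, feature: str = "") -> GroupComparison:
    """Two-tailed Mann–Whitney U test.

    Uses the exact null distribution for combined n ≤ 20 without ties and
    the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least 1 value")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= 20 and not has_ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    s = _summaries(x, y) if (x.size > 1 and y.size > 1) else {
        "mean1": float(np.mean(x)), "mean2": float(np.mean(y)),
        "sd1": math.nan, "sd2": math.nan, "sem1": math.nan, "sem2": math.nan,
        "n1": int(x.size), "n2": int(y.size)}
    return GroupComparison(feature=feature, statistic=float(res.statistic),
                           df=math.nan, p=min(float(res.pvalue), 1.0),
                           test_variant=MANN_WHITNEY, **s)
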