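"""Statistical reporting: unpaired Student's t-test and mean +/- SD.

Comparisons between conditions use the equal-variance (pooled) two-sample
Student's t-test, two-sided, significant at p < 0.05; replicate summaries are
reported as arithmetic mean +/- sample SD (n - 1 denominator).  Welch's
correction is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n - 1 denominator)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError(f"SD undefined for n = {values.size} < 2")
    return float(values.mean()), float(values.std(ddof=1))


def unpaired_t_test(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-sided unpaired t-test between two groups of replicate values.

    Uses the pooled-variance Student's t with n1 + n2 - 2 degrees of freedom
    (or Welch's t when ``welch``).  Degenerate inputs: zero pooled variance
    with equal means yields t = 0, p = 1; zero pooled variance with unequal
    means is an error (the statistic is infinite).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2, got ({a.size}, {b.size})")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))

    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            df = float(a.size + b.size - 2)
            return TTestResult(0.0, df, 1.0, mean_a, mean_b, sd_a, sd_b, a.size, b.size)
        raise ValueError("degenerate variance: zero pooled variance with unequal means")

    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
        n_a=int(a.size), n_b=int(b.size),
    )
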