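"""Streaming two-sample pooled-variance t-test.

The classical Student t-test for two independent groups, built on running
sufficient statistics so that adding one observation and re-testing costs
O(1).  This is the workhorse behind every sequential procedure in the
package: the unadjusted "test after every observation" strategy, interim
(group-sequential) looks, and the effect-size summaries all re-test the
same accumulating samples.

The accumulator uses Welford's update internally (running mean and centered
sum of squares) so the derived sample variance stays accurate to ~1e-10
relative error even for data with a large common offset, where the naive
``sumsq - n*mean**2`` form loses all precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupAccumulator",
    "TestResult",
    "update_accumulator",
    "pooled_t_test",
    "t_and_p",
]


@dataclass(frozen=True)
class GroupAccumulator:
    """Running sufficient statistics for one sample group.

    Exposes ``n``, ``sum`` and ``sumsq`` (the textbook sufficient
    statistics) but stores the numerically stable pair (mean, M2) where
    M2 = sum of squared deviations from the running mean.
    """

    n: int = 0
    _mean: float = 0.0
    _m2: float = 0.0

    @property
    def sum(self) -> float:
        return self.n * self._mean

    @property
    def sumsq(self) -> float:
        return self._m2 + self.n * self._mean * self._mean

    @property
    def mean(self) -> float:
        if self.n == 0:
            raise ValueError("mean undefined for an empty accumulator")
        return self._mean

    @property
    def variance(self) -> float:
        """Unbiased sample variance (ddof=1); requires n >= 2."""
        if self.n < 2:
            raise ValueError("sample variance requires at least 2 observations")
        # M2 is a sum of squares, so clamp tiny negative rounding residue
        return max(self._m2, 0.0) / (self.n - 1)

    def add(self, x: float) -> "GroupAccumulator":
        """Return a new accumulator including observation ``x``."""
        if not math.isfinite(x):
            raise ValueError(f"observation must be finite, got {x!r}")
        n = self.n + 1
        delta = x - self._mean
        mean = self._mean + delta / n
        m2 = self._m2 + delta * (x - mean)
        return GroupAccumulator(n, mean, m2)

    @classmethod
    def from_data(cls, values) -> "GroupAccumulator":
        acc = cls()
        for x in values:
            acc = acc.add(float(x))
        return acc


def update_accumulator(acc: GroupAccumulator, x: float) -> GroupAccumulator:
    """Functional alias for :meth:`GroupAccumulator.add`."""
    return acc.add(x)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one pooled two-sample t-test.

    ``t_stat`` is (mean_A - mean_B) / se, ``df`` = n_A + n_B - 2 and
    ``p_value`` is the two-sided tail probability of the central
    t-distribution.
    """

    t_stat: float
    df: int
    p_value: float
    n_a: int
    n_b: int

    @property
    def n_per_group(self):
        """Per-group sample size; a pair when the groups differ in size."""
        return self.n_a if self.n_a == self.n_b else (self.n_a, self.n_b)


def pooled_t_test(acc_a: GroupAccumulator, acc_b: GroupAccumulator) -> TestResult:
    """Classical equal-variance two-sample t-test from two accumulators.

    Degenerate zero-variance samples are defined rather than rejected so a
    simulator never crashes on pathological draws: equal means give
    (t=0, p=1), different means give (t=+/-inf, p=0).
    """
    if acc_a.n < 2 or acc_b.n < 2:
        raise ValueError(
            "pooled t-test needs at least 2 observations per group "
            f"(got {acc_a.n} and {acc_b.n}); with one measurement the "
            "within-group variance does not exist"
        )
    na, nb = acc_a.n, acc_b.n
    df = na + nb - 2
    mean_a, mean_b = acc_a.mean, acc_b.mean
    sp2 = ((na - 1) * acc_a.variance + (nb - 1) * acc_b.variance) / df

    if sp2 == 0.0:
        if mean_a == mean_b:
            return TestResult(0.0, df, 1.0, na, nb)
        t = math.inf if mean_a > mean_b else -math.inf
        return TestResult(t, df, 0.0, na, nb)

    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = (mean_a - mean_b) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(t, df, min(p, 1.0), na, nb)


def t_and_p(n_a, mean_a, var_a, n_b, mean_b, var_b):
    """Vectorized pooled t-statistic and two-sided p-value.

    All arguments broadcast; ``var_*`` are ddof=1 sample variances.  Used
    by the simulation modules, which compute running means/variances for
    whole trajectories at once.  Zero pooled variance follows the same
    convention as :func:`pooled_t_test`.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    df = n_a + n_b - 2.0
    sp2 = ((n_a - 1) * np.maximum(var_a, 0.0) + (n_b - 1) * np.maximum(var_b, 0.0)) / df
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    degenerate = sp2 == 0.0
    if np.any(degenerate):
        t = np.where(degenerate & (diff == 0.0), 0.0, t)
        t = np.where(degenerate & (diff > 0.0), np.inf, t)
        t = np.where(degenerate & (diff < 0.0), -np.inf, t)
    p = np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, p
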