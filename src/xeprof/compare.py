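"""Statistical comparison layer: t-tests, Mann-Whitney, boxplot summaries.

All p-values are two-sided.  Quartiles use linear interpolation (type 7,
the R/ggplot default) so boxplot summaries are bit-comparable with
ggplot's; whiskers follow the standard rule — upper whisker at
min(max(x), Q3 + 1.5*IQR), lower at max(min(x), Q1 - 1.5*IQR) — and
values outside the whiskers are outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

TEST_NAMES = ("paired_t", "unpaired_t", "mann_whitney")


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool
    mean_a: float
    mean_b: float

    def as_dict(self) -> dict:
        return {
            "test": self.test_name, "statistic": self.statistic,
            "p_value": self.p_value, "n_a": self.n_a, "n_b": self.n_b,
            "paired": self.paired, "mean_a": self.mean_a, "mean_b": self.mean_b,
        }


@dataclass
class BoxSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))


def compare(group_a, group_b, paired: bool = False, test: str = "paired_t",
            keys=None, keys_b=None) -> GroupComparison:
    """Two-group comparison with a two-sided p-value.

    For paired tests the vectors must align element-wise; passing sample
    ``keys`` (and ``keys_b`` when the orders differ) enforces the
    alignment and errors on a mismatch.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if test not in TEST_NAMES:
        raise ValueError(f"unknown test {test!r}; choose from {TEST_NAMES}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "paired_t" and not paired:
        raise ValueError("paired_t requires paired=True")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        if keys is not None:
            kb = keys_b if keys_b is not None else keys
            if list(keys) != list(kb):
                raise ValueError(f"paired keys misaligned: {list(keys)[:3]}... vs "
                                 f"{list(kb)[:3]}...")
    if test == "paired_t":
        if np.allclose(a, b):
            statistic, p_value = 0.0, 1.0  # zero-variance differences
        else:
            statistic, p_value = stats.ttest_rel(a, b)
    elif test == "unpaired_t":
        statistic, p_value = stats.ttest_ind(a, b)
    else:
        statistic, p_value = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(test_name=test, statistic=float(statistic),
                           p_value=float(p_value), n_a=len(a), n_b=len(b),
                           paired=paired, mean_a=float(np.mean(a)),
                           mean_b=float(np.mean(b)))


def box_summary(values) -> BoxSummary:
    """Quartiles, IQR whiskers and outliers of one value vector."""
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("box_summary needs at least one value")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation = type 7
    iqr = q3 - q1
    # ggplot rule: whiskers reach the extreme value capped at the 1.5*IQR fence
    whisker_high = float(min(np.max(x), q3 + 1.5 * iqr))
    whisker_low = float(max(np.min(x), q1 - 1.5 * iqr))
    outliers = x[(x > whisker_high) | (x < whisker_low)]
    return BoxSummary(q1=float(q1), median=float(med), q3=float(q3),
                      whisker_low=whisker_low, whisker_high=whisker_high,
                      outliers=outliers)
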