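"""Group summaries and the unpaired two-sided Student's t-test.

Each treatment timepoint (pre, day 3, week 2, week 4) is an independent
group of animals; every group is compared against the pre-treatment
baseline with a pooled-variance Student's t-test (Welch's correction is
available behind a flag), and effect sizes are reported as percent change
of the group mean relative to baseline.  No multiple-testing correction
is applied; this is recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSample", "GroupComparison", "summarize", "ttest_unpaired",
           "percent_change", "compare_to_baseline"]


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empty group")
        if not np.all(np.isfinite(v)):
            raise ValueError("group values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    percent_change: float
    t_stat: float
    df: float
    p_value: float
    welch: bool = False
    multiple_testing: str = "none"


def summarize(sample: GroupSample) -> tuple[float, float, int]:
    """Arithmetic mean, sample SD (n-1 denominator) and n.

    For a single observation the SD is undefined and returned as NaN.
    """
    v = sample.values
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return mean, sd, v.size


def percent_change(mean_t: float, mean_pre: float) -> float:
    """100 * (mean_t - mean_pre) / mean_pre."""
    if mean_pre == 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return 100.0 * (mean_t - mean_pre) / mean_pre


def ttest_unpaired(a: GroupSample, b: GroupSample, welch: bool = False
                   ) -> GroupComparison:
    """Two-sided unpaired t-test of group ``a`` against group ``b``.

    Default is the classic pooled-variance Student's test with
    df = n_a + n_b - 2.  Degenerate zero-variance inputs yield t = 0 /
    p = 1 for equal means and an infinite t (p = 0) otherwise.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least two observations")
    mean_a, sd_a, n_a = summarize(a)
    mean_b, sd_b, n_b = summarize(b)
    diff = mean_a - mean_b
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        se = np.sqrt(va + vb)
        df = ((va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
              if se > 0 else float(n_a + n_b - 2))
    else:
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = float(n_a + n_b - 2)
    if se == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
        p = 1.0 if diff == 0 else 0.0
    else:
        t = float(diff / se)
        p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(a.label, b.label, mean_a, sd_a, n_a, mean_b, sd_b,
                           n_b, percent_change(mean_a, mean_b), t, df, p,
                           welch=welch)


def compare_to_baseline(df: pd.DataFrame, baseline: str = "pre",
                        group_col: str = "group", value_col: str = "value",
                        welch: bool = False) -> pd.DataFrame:
    """Compare every group in a long-format table against the baseline group.

    Input: one row per animal with columns ``group`` and ``value``.
    Output: one row per non-baseline group with means, SDs, percent change
    vs baseline, t, df and the two-sided p-value.
    """
    if baseline not in set(df[group_col]):
        raise ValueError(f"baseline group {baseline!r} not present")
    base = GroupSample(baseline, df.loc[df[group_col] == baseline, value_col])
    rows = []
    for label, sub in df.groupby(group_col, sort=False):
        if label == baseline:
            continue
        comp = ttest_unpaired(GroupSample(str(label), sub[value_col]), base,
                              welch=welch)
        rows.append(vars(comp))
    return pd.DataFrame(rows)
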