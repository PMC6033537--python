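"""Spike-in-normalized differential quantification.

Per-peak condition/control ratios of spike-in-normalized signal, the
most/least-reduced (or high/low) median split, pooled-variance two-tailed
Student's t tests between groups, and the fraction-increased summary.
With exogenous spike-in chromatin added at a fixed proportion, a genuine
global loss of a mark shows up as ratios well below 1; plain per-sample
depth normalization masks exactly this shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t test: statistic, degrees of freedom, two-tailed p."""

    t: float
    df: float
    p: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p}


def per_peak_ratio(condition: pd.DataFrame, control: pd.Series) -> tuple[pd.Series, list]:
    """Mean over condition samples of per-peak signal / control signal.

    ``condition`` is a peaks x samples frame of normalized signals and
    ``control`` a per-peak series on the same peak universe.  Peaks whose
    control signal is 0 are excluded (their ids are returned and logged).
    """
    cond_ids = set(condition.index)
    ctrl_ids = set(control.index)
    if not (cond_ids & ctrl_ids):
        raise ValueError("condition and control peak universes are disjoint")
    if cond_ids != ctrl_ids:
        raise ValueError(
            f"condition and control peak universes differ "
            f"({len(cond_ids ^ ctrl_ids)} peaks not shared)"
        )
    control = control.reindex(condition.index)
    if (condition.to_numpy() < 0).any() or (control.to_numpy() < 0).any():
        raise ValueError("normalized signals must be nonnegative")
    zero = control.index[control.to_numpy() == 0]
    excluded = list(zero)
    if excluded:
        log.warning("%d peaks excluded from ratios (zero control signal)", len(excluded))
    keep = condition.index.difference(zero, sort=False)
    sub = condition.loc[keep]
    ratios = sub.div(control.loc[keep], axis=0).mean(axis=1)
    return ratios.rename("ratio"), excluded


def median_split(
    values: pd.Series, labels: tuple[str, str] = ("most_reduced", "least_reduced")
) -> dict[str, list]:
    """Deterministic median split of ids by value.

    Ids are sorted ascending by (value, id); the lower ``n // 2`` go to the
    first group, the rest to the second (odd n puts the extra element in
    the second group).
    """
    if len(values) == 0:
        raise ValueError("median_split requires at least one value")
    if len(values) < 2:
        raise ValueError("median_split requires at least two values")
    order = sorted(values.index, key=lambda i: (values[i], str(i)))
    half = len(order) // 2
    return {labels[0]: order[:half], labels[1]: order[half:]}


def students_t(x, y, welch: bool = False) -> TTestResult:
    """Two-sample two-tailed t test (pooled variance by default).

    Degenerate zero-variance inputs: equal means -> (t=0, p=1); unequal
    means -> p=0 sentinel with an infinite statistic (the difference is
    certain under the pooled model).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    n1, n2 = len(x), len(y)
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return _degenerate(m1, m2, float(n1 + n2 - 2))
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = (m1 - m2) / np.sqrt(se2)
    else:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            return _degenerate(m1, m2, df)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def _degenerate(m1: float, m2: float, df: float) -> TTestResult:
    if m1 == m2:
        return TTestResult(t=0.0, df=df, p=1.0)
    return TTestResult(t=float(np.inf if m1 > m2 else -np.inf), df=df, p=0.0)


def fraction_increased(
    condition: pd.Series, reference: pd.Series, threshold: float = 1.0
) -> float:
    """Percentage (0-100) of peaks with condition > threshold x reference.

    The comparison is strict, so a ratio of exactly ``threshold`` does not
    count as increased; peaks at 0 in both samples never count.
    """
    if len(condition) == 0:
        raise ValueError("empty peak universe")
    if set(condition.index) != set(reference.index):
        raise ValueError("condition and reference peak universes differ")
    reference = reference.reindex(condition.index)
    increased = condition.to_numpy() > threshold * reference.to_numpy()
    return 100.0 * increased.sum() / len(condition)


def group_density_compare(
    groups: dict[str, list],
    signal: pd.Series,
    welch: bool = False,
) -> dict:
    """Compare another mark's density between two peak/promoter groups.

    ``groups`` maps two labels to id lists (typically from
    :func:`median_split`); ``signal`` holds the other mark's density on the
    same ids.  Returns per-group summaries (n/mean/median/q1/q3) plus the
    Student's t result between the groups.
    """
    if len(groups) != 2:
        raise ValueError("group_density_compare expects exactly two groups")
    (lab1, ids1), (lab2, ids2) = groups.items()
    missing = (set(ids1) | set(ids2)) - set(signal.index)
    if missing:
        raise KeyError(f"signal missing for {len(missing)} ids, e.g. {sorted(missing)[:5]}")
    x = signal.loc[list(ids1)].to_numpy(dtype=float)
    y = signal.loc[list(ids2)].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two members")
    test = students_t(x, y, welch=welch)

    def summary(v: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"n": int(len(v)), "mean": float(v.mean()), "median": float(med),
                "q1": float(q1), "q3": float(q3)}

    return {"groups": {lab1: summary(x), lab2: summary(y)}, "ttest": test.to_dict()}
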