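"""Small-sample statistics conventions: Dixon's Q outliers and summary-t.

Dixon's Q (classic r10 ratio) compares the gap between the suspect extreme
and its nearest neighbour to the sample range.  Critical values are not
transcribed from published tables; they are the empirical 90% (or requested)
quantile of the two-sided Q statistic under a normal null, generated once
per (n, confidence) by a seeded Monte-Carlo and cached.  This makes the test
self-contained and its calibration directly verifiable: by construction the
null flag rate equals 1 − confidence up to Monte-Carlo error.

``t_from_summary`` recomputes a two-sample t statistic from published
mean ± SEM and n, the only form in which group data are often reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "QResult",
    "SummaryTStat",
    "GroupSummary",
    "dixon_critical_value",
    "dixon_q",
    "q_statistic",
    "t_from_summary",
    "group_report",
]

_MC_SEED = 20_220_913  # fixed: critical values must not depend on analysis seeds


@dataclass
class QResult:
    q_stat: float
    q_crit: float
    n: int
    flagged_index: int | None
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_stat <= 1.0):
            raise ValueError("Q statistic must lie in [0, 1]")
        if (self.flagged_index is not None) != (self.q_stat > self.q_crit):
            raise ValueError("flagged_index must be set iff q_stat exceeds q_crit")


@dataclass
class SummaryTStat:
    t: float
    df: float
    formula_tag: str = "unpooled"

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be > 0")

    @property
    def p_value(self) -> float:
        return float(2.0 * sps.t.sf(abs(self.t), self.df))


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    excluded: list[float] = field(default_factory=list)


def q_statistic(sorted_values: np.ndarray) -> tuple[float, int]:
    """Two-sided r10 Q: the larger of the low-end and high-end gap ratios.

    Returns (Q, index-of-suspect-extreme) for an ascending-sorted 1D array.
    """
    rng_ = sorted_values[-1] - sorted_values[0]
    q_low = (sorted_values[1] - sorted_values[0]) / rng_
    q_high = (sorted_values[-1] - sorted_values[-2]) / rng_
    if q_high >= q_low:
        return float(q_high), len(sorted_values) - 1
    return float(q_low), 0


@lru_cache(maxsize=64)
def dixon_critical_value(
    n: int, confidence: float = 0.90, n_draws: int = 200_000, seed: int = _MC_SEED
) -> float:
    """Monte-Carlo critical value of the two-sided r10 Q statistic.

    The empirical ``confidence`` quantile of Q over ``n_draws`` standard
    normal samples of size ``n``.
    """
    if not (3 <= n <= 30):
        raise ValueError(f"Dixon's r10 supported for 3 <= n <= 30, got n={n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    rng = np.random.default_rng(seed + n)  # independent stream per n
    x = np.sort(rng.standard_normal((n_draws, n)), axis=1)
    span = x[:, -1] - x[:, 0]
    q = np.maximum(x[:, 1] - x[:, 0], x[:, -1] - x[:, -2]) / span
    return float(np.quantile(q, confidence))


def dixon_q(values, confidence: float = 0.90) -> QResult:
    """Test the more extreme end of a small sample for a single outlier.

    At most one value is flagged per call (single-pass convention); the
    flagged index refers to the input ordering.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"Dixon's Q needs at least 3 values, got {n}")
    if n > 30:
        raise ValueError(f"Dixon's Q (r10) is not defined here beyond n=30, got {n}")
    if np.ptp(values) == 0:
        raise ValueError("all values are equal (zero range); Q is undefined")
    order = np.argsort(values, kind="stable")
    q, pos = q_statistic(values[order])
    crit = dixon_critical_value(n, confidence)
    flagged = int(order[pos]) if q > crit else None
    return QResult(q_stat=q, q_crit=crit, n=n, flagged_index=flagged, confidence=confidence)


def t_from_summary(
    m1: float,
    sem1: float,
    n1: int,
    m2: float,
    sem2: float,
    n2: int,
    pooled: bool = False,
) -> SummaryTStat:
    """Two-sample t statistic from published mean ± SEM and n.

    Default is the unpooled (Welch) form t = (m1 − m2)/√(sem1² + sem2²) with
    Welch–Satterthwaite degrees of freedom; ``pooled=True`` gives the
    classic Student form (identical t when n1 = n2).
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    v1, v2 = sem1**2, sem2**2
    if pooled:
        # sem² = s²/n; pooled variance from the implied sample variances
        s2 = ((n1 - 1) * v1 * n1 + (n2 - 1) * v2 * n2) / (n1 + n2 - 2)
        t = (m1 - m2) / math.sqrt(s2 * (1 / n1 + 1 / n2))
        return SummaryTStat(t=t, df=n1 + n2 - 2, formula_tag="pooled")
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return SummaryTStat(t=t, df=df, formula_tag="unpooled")


def group_report(
    groups: list, labels: list[str] | None = None, apply_q: bool = False, confidence: float = 0.90
) -> tuple[list[GroupSummary], list[tuple[str, str, SummaryTStat]]]:
    """Mean ± SEM per group (optional single-pass Dixon exclusion) and
    pairwise unpooled t statistics computed from the cleaned raw values."""
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    cleaned: list[np.ndarray] = []
    summaries: list[GroupSummary] = []
    for lab, vals in zip(labels, groups):
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group '{lab}' needs at least 2 values")
        excluded: list[float] = []
        if apply_q and vals.size >= 3 and np.ptp(vals) > 0:
            res = dixon_q(vals, confidence)
            if res.flagged_index is not None:
                excluded = [float(vals[res.flagged_index])]
                vals = np.delete(vals, res.flagged_index)
        cleaned.append(vals)
        summaries.append(
            GroupSummary(
                label=lab,
                n=int(vals.size),
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / math.sqrt(vals.size)),
                excluded=excluded,
            )
        )
    pairs = []
    for i in range(len(cleaned)):
        for j in range(i + 1, len(cleaned)):
            t, _ = sps.ttest_ind(cleaned[i], cleaned[j], equal_var=False)
            vi = cleaned[i].var(ddof=1) / cleaned[i].size
            vj = cleaned[j].var(ddof=1) / cleaned[j].size
            df = (vi + vj) ** 2 / (
                vi**2 / (cleaned[i].size - 1) + vj**2 / (cleaned[j].size - 1)
            )
            pairs.append((labels[i], labels[j], SummaryTStat(t=float(t), df=float(df))))
    return summaries, pairs
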