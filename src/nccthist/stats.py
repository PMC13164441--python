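"""Two-group statistics for the cortical vs basal-ganglia comparison.

The battery mirrors a standard radiology-cohort analysis: one-way ANOVA,
post hoc pooled-variance t-tests with Bonferroni correction over the four
metrics, Cohen's d on the pooled SD, percentile bootstrap CIs of the mean
difference, and a one-way repeated-measures ANOVA (subjects as blocks,
sphericity assumed) for metric evolution over time.

Every entry point accepts either raw value vectors or ``GroupSummary``
(n, mean, SD) triples, so the printed summary rows of a cohort table can be
fed straight in; summary and raw inputs agree exactly when the summaries
are computed from the vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "pooled_t",
    "oneway_anova",
    "cohens_d",
    "bonferroni",
    "bootstrap_ci",
    "rm_anova",
    "rm_anova_matrix",
    "TABLE_TIME_GRID",
]

#: Default anchor grid (minutes post-onset) for repeated-measures matching:
#: baseline, 60, the 76–87-min peak window midpoint, the 94-min crossover,
#: 120 and 180 minutes.
TABLE_TIME_GRID = (0.0, 60.0, 81.5, 94.0, 120.0, 180.0)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: size, mean and sample SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, x: Sequence[float]) -> "GroupSummary":
        v = np.asarray(x, dtype=float)
        if v.size < 2:
            raise ValueError("group needs n >= 2")
        return cls(n=int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass(frozen=True)
class ComparisonResult:
    """One row of the two-group comparison table for a single metric."""

    metric: str
    group_a: GroupSummary
    group_b: GroupSummary
    mean_difference: float
    F: float
    p_anova: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    ci_low: float
    ci_high: float


def _summarize(x) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_values(x)


def pooled_t(a, b, flavor: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t-test: (t, df, two-sided p).

    ``flavor="pooled"`` (Student, equal variances assumed, df = n_a+n_b−2)
    is the default; ``flavor="welch"`` uses the Welch–Satterthwaite df.
    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means it is degenerate and raises.
    """
    sa, sb = _summarize(a), _summarize(b)
    diff = sa.mean - sb.mean
    if flavor == "pooled":
        df = sa.n + sb.n - 2
        sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
        if sp2 == 0:
            if diff == 0:
                return 0.0, float(df), 1.0
            raise ValueError("degenerate: zero pooled variance, unequal means")
        se = np.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    elif flavor == "welch":
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        if va + vb == 0:
            if diff == 0:
                return 0.0, float(sa.n + sb.n - 2), 1.0
            raise ValueError("degenerate: zero variance, unequal means")
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    else:
        raise ValueError("flavor must be 'pooled' or 'welch'")
    t = float(diff / se)
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return t, float(df), p


def oneway_anova(groups: Sequence) -> tuple[float, int, int, float]:
    """One-way between-groups ANOVA: (F, df_between, df_within, p).

    Accepts raw vectors or summaries; the between-SS comes from the group
    means, the within-SS from the group SDs, so summary input reproduces
    raw-vector input exactly.  For two groups F equals the pooled t².
    """
    sums = [_summarize(g) for g in groups]
    if len(sums) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n_total = sum(s.n for s in sums)
    grand = sum(s.n * s.mean for s in sums) / n_total
    ss_between = sum(s.n * (s.mean - grand) ** 2 for s in sums)
    ss_within = sum((s.n - 1) * s.sd**2 for s in sums)
    df1 = len(sums) - 1
    df2 = n_total - len(sums)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    F = (ss_between / df1) / (ss_within / df2)
    return float(F), df1, df2, float(_sps.f.sf(F, df1, df2))


def cohens_d(a, b) -> float:
    """Standardized mean difference on the (n−1)-weighted pooled SD."""
    sa, sb = _summarize(a), _summarize(b)
    sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / (sa.n + sb.n - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((sa.mean - sb.mean) / np.sqrt(sp2))


def bonferroni(p_values: Sequence[float], m: int = 4) -> list[float]:
    """Bonferroni adjustment: p' = min(1, m·p) with family size m.

    The default family is the four histogram metrics tested at one
    contrast.
    """
    ps = list(p_values)
    if m < len(ps):
        raise ValueError("family size m must be >= number of p-values")
    if any(not (0 <= p <= 1) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, m * p) for p in ps]


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    statistic: Callable | None = None,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI, default 95%, of the mean difference.

    Each group is resampled with replacement within itself (``n_boot``
    replicates); the default statistic is ``mean(x*) − mean(y*)`` (or
    ``mean(x*)`` for a single sample).  A seed is mandatory so every CI in
    a report is reproducible.
    """
    if seed is None:
        raise ValueError("bootstrap_ci requires an explicit seed")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xv = np.asarray(x, dtype=float)
    if xv.size == 0:
        raise ValueError("empty input")
    yv = None
    if y is not None:
        yv = np.asarray(y, dtype=float)
        if yv.size == 0:
            raise ValueError("empty input")

    if statistic is None and yv is not None:
        # vectorized fast path for the default mean-difference statistic
        ix = rng.integers(0, xv.size, size=(n_boot, xv.size))
        iy = rng.integers(0, yv.size, size=(n_boot, yv.size))
        reps = xv[ix].mean(axis=1) - yv[iy].mean(axis=1)
    else:
        stat = statistic or (lambda a: float(np.mean(a)))
        reps = np.empty(n_boot)
        for i in range(n_boot):
            xs = xv[rng.integers(0, xv.size, xv.size)]
            if yv is None:
                reps[i] = stat(xs)
            else:
                ys = yv[rng.integers(0, yv.size, yv.size)]
                reps[i] = stat(xs, ys)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def rm_anova_matrix(data: np.ndarray) -> tuple[float, int, int, float]:
    """One-way within-subject ANOVA on a subjects × times matrix.

    Subjects are blocks; sphericity is assumed (no Greenhouse–Geisser
    correction).  Returns (F_time, df1, df2, p).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects × times matrix with >= 2 of each")
    n_sub, n_time = x.shape
    grand = x.mean()
    ss_time = n_sub * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = n_time * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_time - ss_subj
    df1 = n_time - 1
    df2 = (n_time - 1) * (n_sub - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        ms_err = np.finfo(float).tiny
    F = (ss_time / df1) / ms_err
    return float(F), df1, df2, float(_sps.f.sf(F, df1, df2))


def rm_anova(
    trajectories: Sequence,
    metric: str,
    anchor_times: Sequence[float] = TABLE_TIME_GRID,
    tolerance_min: float = 15.0,
) -> tuple[float, int, int, float]:
    """Repeated-measures ANOVA of a lesion metric across anchor times.

    Each subject's scans are matched to the anchors by nearest time within
    ``tolerance_min``.  Subjects that cannot fill every anchor make the
    design unbalanced, which raises with the offending case ids (nothing is
    imputed across gaps).
    """
    anchors = list(anchor_times)
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchor times")
    rows, bad = [], []
    for tr in trajectories:
        times = tr.times
        vals = tr.lesion_values(metric)
        row = []
        for a in anchors:
            i = int(np.argmin(np.abs(times - a)))
            if abs(times[i] - a) > tolerance_min:
                bad.append(tr.case_id)
                row = None
                break
            row.append(vals[i])
        if row is not None:
            rows.append(row)
    if bad:
        raise ValueError(
            "unbalanced repeated-measures design; subjects missing anchors: "
            + ", ".join(sorted(set(bad)))
        )
    return rm_anova_matrix(np.array(rows))
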