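"""Per-subject metric trajectories over minutes post-onset.

The hyperacute evolution of a stroke lesion on serial NCCT is summarized
here as a time-sorted sequence of lesion/control metric pairs per subject.
On top of that the module provides:

* ``percent_decrease`` / ``hu_gap`` — the worked mean-HU arithmetic,
* ``detect_crossover`` — the time at which lesion mean HU rises to meet or
  exceed its mirrored control (interpreted as possible penumbral salvage),
* ``crossover_fraction`` — the share of a regional subgroup showing it,
* ``window_scan`` — a sliding-window search for the post-onset interval in
  which within-ROI SD and entropy best separate cortical from basal-ganglia
  lesions (the peak diagnostic window),
* ``trajectory_deltas`` — nearest-scan anchored metric changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .histogram import MetricSet
from .stats import pooled_t

__all__ = [
    "TrajectoryPoint",
    "Trajectory",
    "CrossoverEvent",
    "WindowResult",
    "percent_decrease",
    "hu_gap",
    "detect_crossover",
    "crossover_fraction",
    "window_scan",
    "trajectory_deltas",
]

logger = logging.getLogger("nccthist")


@dataclass(frozen=True)
class TrajectoryPoint:
    """One scan: time post-onset plus lesion and mirrored-control metrics."""

    time_min: float
    lesion: MetricSet
    control: MetricSet

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """A subject's time-sorted scan sequence for one lesion region class."""

    case_id: str
    region: str
    points: tuple[TrajectoryPoint, ...]

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.time_min))
        times = [p.time_min for p in pts]
        if len(times) != len(set(times)):
            raise ValueError(f"{self.case_id}: duplicate scan times")
        object.__setattr__(self, "points", pts)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_min for p in self.points])

    def lesion_values(self, metric: str) -> np.ndarray:
        return np.array([p.lesion.value(metric) for p in self.points])


@dataclass(frozen=True)
class CrossoverEvent:
    occurred: bool
    time_min: float | None = None


@dataclass(frozen=True)
class WindowResult:
    """One candidate diagnostic window with its group-separation statistics."""

    start_min: float
    end_min: float
    stats: dict = field(compare=False)
    score: float = np.inf
    n_cortical: int = 0
    n_bg: int = 0


def percent_decrease(
    baseline_mean: float, lesion_mean: float, digits: int | None = 1
) -> float:
    """Percent drop of lesion mean HU relative to a baseline mean.

    ``100 · (baseline − lesion) / baseline``, rounded to one decimal by
    default (``digits=None`` returns full precision).
    """
    if baseline_mean == 0:
        raise ValueError("baseline mean HU is zero")
    pct = 100.0 * (baseline_mean - lesion_mean) / baseline_mean
    return pct if digits is None else round(pct, digits)


def hu_gap(point: TrajectoryPoint) -> float:
    """Control minus lesion mean HU; positive when the lesion is hypodense."""
    return float(point.control.mean_hu - point.lesion.mean_hu)


def detect_crossover(traj: Trajectory) -> CrossoverEvent:
    """First time the lesion−control mean-HU gap goes from negative to ≥ 0.

    The crossing time is linearly interpolated between the bracketing
    scans; a gap of exactly zero at a scan time counts as a crossover at
    that scan (tie rule).  A lesion that is never hypodense (positive gap
    already at the first scan) is not a crossover.
    """
    if len(traj.points) < 2:
        raise ValueError("crossover detection needs at least 2 scans")
    g = np.array([-hu_gap(p) for p in traj.points])  # lesion - control
    t = traj.times
    if g[0] == 0.0:
        return CrossoverEvent(occurred=True, time_min=float(t[0]))
    for i in range(1, len(g)):
        if g[i - 1] < 0 <= g[i]:
            if g[i] == 0.0:
                return CrossoverEvent(occurred=True, time_min=float(t[i]))
            frac = (0.0 - g[i - 1]) / (g[i] - g[i - 1])
            return CrossoverEvent(
                occurred=True, time_min=float(t[i - 1] + frac * (t[i] - t[i - 1]))
            )
    return CrossoverEvent(occurred=False)


def crossover_fraction(
    cohort: list[Trajectory], region: str, digits: int | None = 1
) -> float:
    """Percentage of a regional subgroup with a detected crossover."""
    group = [tr for tr in cohort if tr.region == region]
    if not group:
        raise ValueError(f"no trajectories for region {region!r}")
    k = sum(detect_crossover(tr).occurred for tr in group)
    pct = 100.0 * k / len(group)
    return pct if digits is None else round(pct, digits)


def _subject_window_means(
    traj: Trajectory, start: float, end: float, metrics: tuple[str, ...]
) -> dict | None:
    """Per-metric mean of a subject's lesion metrics over in-window scans."""
    sel = [p for p in traj.points if start <= p.time_min < end]
    if not sel:
        return None
    return {m: float(np.mean([p.lesion.value(m) for p in sel])) for m in metrics}


def window_scan(
    cohort: list[Trajectory],
    width_min: float = 12.0,
    step_min: float = 1.0,
    metrics: tuple[str, ...] = ("sd", "entropy"),
    min_subjects: int = 2,
) -> list[WindowResult]:
    """Slide windows over the pooled time span and rank group separation.

    For each window ``[t, t + width)`` every subject contributes the mean of
    each lesion metric over its in-window scans (subjects with no in-window
    scan are excluded).  Cortical vs basal-ganglia separation is tested per
    metric with a pooled two-sample t; the window score is the *worst*
    (largest) of the per-metric p-values, so the top-ranked window is the
    one where every metric separates.  Windows with fewer than
    ``min_subjects`` contributing subjects in either group are skipped.

    Returns windows sorted ascending by score (ties broken by start time);
    the first entry is the peak diagnostic window.
    """
    if not (width_min >= step_min > 0):
        raise ValueError("need width >= step > 0")
    all_times = np.concatenate([tr.times for tr in cohort])
    t0, t1 = float(all_times.min()), float(all_times.max())
    starts = np.arange(t0, max(t1 - width_min, t0) + 0.5 * step_min, step_min)

    results: list[WindowResult] = []
    for s in starts:
        e = s + width_min
        groups: dict[str, list[dict]] = {"cortical": [], "bg": []}
        for tr in cohort:
            wm = _subject_window_means(tr, s, e, metrics)
            if wm is not None and tr.region in groups:
                groups[tr.region].append(wm)
        n_c, n_b = len(groups["cortical"]), len(groups["bg"])
        if n_c < min_subjects or n_b < min_subjects:
            continue
        stats: dict[str, dict] = {}
        worst_p = 0.0
        for m in metrics:
            a = np.array([d[m] for d in groups["cortical"]])
            b = np.array([d[m] for d in groups["bg"]])
            t_stat, df, p = pooled_t(a, b)
            stats[m] = {"t": t_stat, "df": df, "p": p}
            worst_p = max(worst_p, p)
        results.append(
            WindowResult(
                start_min=float(s),
                end_min=float(e),
                stats=stats,
                score=worst_p,
                n_cortical=n_c,
                n_bg=n_b,
            )
        )
    if not results:
        raise ValueError("every window was skipped (too few subjects per group)")
    results.sort(key=lambda w: (w.score, w.start_min))
    return results


def trajectory_deltas(
    traj_group: list[Trajectory],
    metric: str,
    t0: float,
    t1: float,
    tolerance_min: float = 15.0,
) -> float:
    """Group mean change of a lesion metric between two time anchors.

    Each subject contributes ``metric(nearest scan to t1) − metric(nearest
    scan to t0)``; a subject whose nearest scan misses an anchor by more
    than ``tolerance_min`` is excluded (logged, never silent).
    """
    deltas = []
    for tr in traj_group:
        times = tr.times
        vals = tr.lesion_values(metric)
        pair = []
        for anchor in (t0, t1):
            i = int(np.argmin(np.abs(times - anchor)))
            if abs(times[i] - anchor) > tolerance_min:
                logger.warning(
                    "trajectory_deltas: %s excluded (no scan within %.0f min of t=%.1f)",
                    tr.case_id,
                    tolerance_min,
                    anchor,
                )
                pair = None
                break
            pair.append(vals[i])
        if pair is not None:
            deltas.append(pair[1] - pair[0])
    if not deltas:
        raise ValueError("all subjects excluded: no scans near the anchors")
    return float(np.mean(deltas))
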