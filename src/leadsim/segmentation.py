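"""Changepoint analysis of LT time series: role differentiation detection.

A leader role is *detected*, not defined, from an agent's LT history: the
series is segmented by least-squares multiple-changepoint estimation
(Bai–Perron style: exact dynamic programming over admissible break
positions, minimising the within-segment sum of squared deviations, with
the number of breaks selected by BIC), and a segment whose mean is at or
above the high threshold (default 0.775) marks an emerged leader.  The
differentiation attempt of an evaluation is the earliest attempt index at
which any agent's high segment begins; transitions are post-
differentiation changes of segment class (low <-> high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import EvaluationResult, LTHistory

__all__ = [
    "AnalysisParameters",
    "SegmentationResult",
    "DifferentiationSummary",
    "segment_series",
    "first_high_emergence",
    "count_transitions",
    "summarize_evaluation",
]

HIGH_THRESHOLD = 0.775  # segment mean at/above this marks a high (leader) LT
LOW_THRESHOLD = 0.225  # symmetric low (follower) class bound


@dataclass(frozen=True)
class AnalysisParameters:
    """Knobs of the changepoint analysis.

    ``min_segment_fraction`` is the trimming parameter: no segment may be
    shorter than this fraction of the series.  ``max_points`` bounds the
    series length fed to the exact O(n^2) dynamic program; longer dense
    series are averaged into equal-width bins first (LT trajectories are
    piecewise plateaus, so bin means lose almost nothing).
    """

    max_breaks: int = 5
    min_segment_fraction: float = 0.05
    high_threshold: float = HIGH_THRESHOLD
    low_threshold: float = LOW_THRESHOLD
    max_points: int = 1000

    def __post_init__(self) -> None:
        if self.max_breaks < 0:
            raise ValueError("max_breaks must be >= 0")
        if not 0 < self.min_segment_fraction <= 0.5:
            raise ValueError("min_segment_fraction must be in (0, 0.5]")
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be below high_threshold")


@dataclass
class SegmentationResult:
    """Optimal segmentation of one series.

    ``breakpoints[k]`` is the index of the first observation of segment
    ``k + 1``; segment k spans ``[starts[k], starts[k + 1])`` where
    ``starts = [0, *breakpoints]``.  Classes are 'high', 'low' or
    'intermediate' by comparing segment means with the thresholds.
    """

    breakpoints: np.ndarray
    segment_means: np.ndarray
    segment_classes: list[str]
    rss: float

    @property
    def n_segments(self) -> int:
        return self.segment_means.size

    @property
    def segment_starts(self) -> np.ndarray:
        return np.concatenate(([0], self.breakpoints))


@dataclass
class DifferentiationSummary:
    """Evaluation-level differentiation metrics."""

    evaluation_id: str
    n_attempts: int
    first_high_attempt: list[int | None]  # per agent
    differentiation_attempt: int | None  # earliest over agents
    differentiation_fraction: float | None
    low_to_high_count: int
    high_to_low_count: int
    final_high_count: int


def _classify(mean: float, high: float, low: float) -> str:
    if mean >= high:
        return "high"
    if mean <= low:
        return "low"
    return "intermediate"


def segment_series(
    series: np.ndarray,
    max_breaks: int = 5,
    min_segment_fraction: float = 0.05,
    high_threshold: float = HIGH_THRESHOLD,
    low_threshold: float = LOW_THRESHOLD,
    n_breaks: int | None = None,
) -> SegmentationResult:
    """Exact least-squares multiple-changepoint fit with BIC model selection.

    For each candidate break count m in 0..max_breaks the globally
    optimal placement (minimum total within-segment RSS, every segment at
    least ``h = ceil(min_segment_fraction * n)`` long) is found by
    dynamic programming over the O(n^2) segment-cost matrix; the returned
    m minimises ``n log(RSS/n) + p log n`` with ``p = 2m + 2`` parameters
    (m breaks, m + 1 means, one variance).  ``n_breaks`` forces a given
    break count instead of the BIC choice.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    h = max(int(np.ceil(min_segment_fraction * n)), 1)
    if n < 2 * h:
        raise ValueError(f"series length {n} is below two minimum segments (2 x {h})")

    # Segment cost C[i, j] = RSS of fitting a constant on y[i:j], j - i >= h.
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    idx = np.arange(n + 1)
    length = idx[None, :] - idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (s2[None, :] - s2[:, None]) - (s1[None, :] - s1[:, None]) ** 2 / length
    cost[length < h] = np.inf
    np.maximum(cost, 0.0, out=cost, where=np.isfinite(cost))  # clamp fp noise

    feasible_breaks = min(max_breaks, n // h - 1)
    if n_breaks is not None:
        if not 0 <= n_breaks <= feasible_breaks:
            raise ValueError(
                f"n_breaks={n_breaks} infeasible (0..{feasible_breaks} with min length {h})"
            )
        feasible_breaks = n_breaks
    # dp[m][j]: optimal RSS of y[0:j] split into m+1 segments; arg[m][j] last break.
    dp = [cost[0, :].copy()]
    arg: list[np.ndarray] = []
    for _ in range(feasible_breaks):
        total = dp[-1][:, None] + cost
        arg.append(np.argmin(total, axis=0))
        dp.append(np.min(total, axis=0))

    if n_breaks is not None:
        best_m = n_breaks
    else:
        eps = 1e-12 * max(n, 1)
        best_m, best_bic = 0, np.inf
        for m in range(feasible_breaks + 1):
            rss = dp[m][n]
            if not np.isfinite(rss):
                continue
            bic = n * np.log(max(rss, eps) / n) + (2 * m + 2) * np.log(n)
            if bic < best_bic:
                best_m, best_bic = m, bic

    breaks = []
    j = n
    for m in range(best_m, 0, -1):
        j = int(arg[m - 1][j])
        breaks.append(j)
    breaks = np.asarray(breaks[::-1], dtype=np.int64)

    starts = np.concatenate(([0], breaks, [n]))
    means = np.array([y[a:b].mean() for a, b in zip(starts[:-1], starts[1:])])
    classes = [_classify(mu, high_threshold, low_threshold) for mu in means]
    return SegmentationResult(
        breakpoints=breaks,
        segment_means=means,
        segment_classes=classes,
        rss=float(dp[best_m][n]),
    )


def first_high_emergence(
    segmentation: SegmentationResult, high_threshold: float = HIGH_THRESHOLD
) -> int | None:
    """Start index of the earliest segment with mean >= threshold, or None."""
    for start, mean in zip(segmentation.segment_starts, segmentation.segment_means):
        if mean >= high_threshold:
            return int(start)
    return None


def count_transitions(
    segmentation: SegmentationResult,
    differentiation_attempt: int | None,
    high_threshold: float = HIGH_THRESHOLD,
    low_threshold: float = LOW_THRESHOLD,
) -> tuple[int, int]:
    """Count low->high and high->low class changes at/after differentiation.

    Only breaks at or after ``differentiation_attempt`` count; changes
    into or out of intermediate segments count in neither direction.
    """
    if differentiation_attempt is None:
        return 0, 0
    classes = [
        _classify(mu, high_threshold, low_threshold) for mu in segmentation.segment_means
    ]
    low_to_high = high_to_low = 0
    for brk, before, after in zip(segmentation.breakpoints, classes[:-1], classes[1:]):
        if brk < differentiation_attempt:
            continue
        if before == "low" and after == "high":
            low_to_high += 1
        elif before == "high" and after == "low":
            high_to_low += 1
    return low_to_high, high_to_low


def _coarsen(series: np.ndarray, max_points: int) -> tuple[np.ndarray, int]:
    """Equal-width bin means; returns (binned series, bin width)."""
    n = series.size
    if n <= max_points:
        return series, 1
    width = int(np.ceil(n / max_points))
    edges = np.arange(0, n, width)
    sums = np.add.reduceat(series, edges)
    counts = np.diff(np.concatenate((edges, [n])))
    return sums / counts, width


def summarize_evaluation(
    result: EvaluationResult,
    analysis: AnalysisParameters = AnalysisParameters(),
    evaluation_id: str = "",
) -> DifferentiationSummary:
    """Segment every agent's LT series and extract differentiation metrics.

    Each agent's dense series is coarsened to at most ``max_points`` bin
    means, segmented, and searched for its first high segment; the
    evaluation's differentiation attempt is the earliest such start over
    agents.  Transition counts consider, for every agent, only breaks at
    or after the evaluation-level differentiation attempt.
    """
    return summarize_histories(
        result.lt_histories, result.n_attempts, analysis, evaluation_id
    )


def summarize_histories(
    lt_histories: list[LTHistory],
    n_attempts: int,
    analysis: AnalysisParameters = AnalysisParameters(),
    evaluation_id: str = "",
) -> DifferentiationSummary:
    """As :func:`summarize_evaluation`, but from bare LT histories (e.g. re-read from disk)."""
    segs: list[SegmentationResult] = []
    firsts: list[int | None] = []
    total = n_attempts
    for hist in lt_histories:
        binned, width = _coarsen(hist.dense(), analysis.max_points)
        seg = segment_series(
            binned,
            max_breaks=analysis.max_breaks,
            min_segment_fraction=analysis.min_segment_fraction,
            high_threshold=analysis.high_threshold,
            low_threshold=analysis.low_threshold,
        )
        # rescale bin indices back to attempt indices
        seg = SegmentationResult(
            breakpoints=seg.breakpoints * width,
            segment_means=seg.segment_means,
            segment_classes=seg.segment_classes,
            rss=seg.rss,
        )
        segs.append(seg)
        firsts.append(first_high_emergence(seg, analysis.high_threshold))

    defined = [f for f in firsts if f is not None]
    diff_attempt = min(defined) if defined else None
    l2h = h2l = 0
    for seg in segs:
        a, b = count_transitions(
            seg, diff_attempt, analysis.high_threshold, analysis.low_threshold
        )
        l2h += a
        h2l += b
    return DifferentiationSummary(
        evaluation_id=evaluation_id,
        n_attempts=total,
        first_high_attempt=firsts,
        differentiation_attempt=diff_attempt,
        differentiation_fraction=(diff_attempt / total) if diff_attempt is not None else None,
        low_to_high_count=l2h,
        high_to_low_count=h2l,
        final_high_count=sum(s.segment_classes[-1] == "high" for s in segs),
    )
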