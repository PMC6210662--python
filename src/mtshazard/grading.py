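"""Partition a hazard-score distribution into k ordered grades.

Four class-interval methods are provided: equal interval, quantile, Jenks
natural breaks (exact Fisher-Jenks dynamic program) and geometric interval.
Grade 1 is the least hazardous class and grade k the most hazardous, so
"grade 3 or 4 of 4" reads as the high-hazard half.

Intervals are half-open [low, high) with the final class closed: a score
exactly on a break point belongs to the upper class. Ties (identical scores)
therefore always share a grade.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .ghs_io import DataError

log = logging.getLogger("mtshazard")

METHODS = ("equal_interval", "quantile", "jenks", "geometric_interval")


@dataclasses.dataclass(frozen=True)
class GradeAssignment:
    """Per-chemical grades in 1..k under one classification method.

    ``breaks`` holds at most k-1 strictly ascending cut points; fewer when
    the data cannot support k classes (degenerate or heavily tied input).
    """

    method: str
    k: int
    breaks: tuple[float, ...]
    grades: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise DataError("breaks must be strictly ascending")
        object.__setattr__(self, "grades", dict(self.grades))

    def grade_of(self, score: float) -> int:
        """Grade for a raw score under the half-open interval convention."""
        return int(np.searchsorted(self.breaks, score, side="right")) + 1


def _as_arrays(scores: Sequence[tuple[str, float]]) -> tuple[list[str], np.ndarray]:
    if not scores:
        raise DataError("no scores to classify")
    cas = [c for c, _ in scores]
    if len(set(cas)) != len(cas):
        raise DataError("duplicate CAS numbers in score list")
    values = np.asarray([v for _, v in scores], dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError("scores must be finite")
    return cas, values


def _assemble(
    method: str, k: int, breaks: Sequence[float], cas: list[str], values: np.ndarray
) -> GradeAssignment:
    breaks = tuple(float(b) for b in breaks)
    grades = np.searchsorted(breaks, values, side="right") + 1
    return GradeAssignment(
        method=method,
        k=k,
        breaks=breaks,
        grades={c: int(g) for c, g in zip(cas, grades)},
    )


def _check_k(k: int) -> None:
    if k < 2:
        raise DataError("number of classes k must be at least 2")


def classify_equal_interval(
    scores: Sequence[tuple[str, float]], k: int = 4
) -> GradeAssignment:
    """Breaks at min + i*(max-min)/k for i = 1..k-1."""
    _check_k(k)
    cas, values = _as_arrays(scores)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        log.warning("all scores equal; equal-interval grading collapses to one class")
        return _assemble("equal_interval", k, (), cas, values)
    breaks = [lo + i * (hi - lo) / k for i in range(1, k)]
    return _assemble("equal_interval", k, breaks, cas, values)


def classify_quantile(
    scores: Sequence[tuple[str, float]], k: int = 4
) -> GradeAssignment:
    """Breaks at the i/k empirical quantiles (inverse empirical CDF).

    Each break is the smallest score of the next class in sorted order, so
    with all values distinct the class sizes differ by at most one, and tied
    values are never split across classes.
    """
    _check_k(k)
    cas, values = _as_arrays(scores)
    n = len(values)
    x = np.sort(values)
    breaks: list[float] = []
    for i in range(1, k):
        m = int(np.ceil(n * i / k))  # target size of the lower classes
        if m >= n:
            break
        b = float(x[m])
        if b > x[0] and (not breaks or b > breaks[-1]):
            breaks.append(b)
    if len(breaks) < k - 1:
        log.warning(
            "quantile grading: ties or short input reduce %d classes to %d",
            k,
            len(breaks) + 1,
        )
    return _assemble("quantile", k, breaks, cas, values)


# -- Fisher-Jenks natural breaks -------------------------------------------

def _weighted_sse_matrix_row(
    cum_w: np.ndarray, cum_wx: np.ndarray, cum_wx2: np.ndarray, j: np.ndarray, i: int
) -> np.ndarray:
    """Within-class SSE of classes spanning unique values j..i (inclusive)."""
    w = cum_w[i + 1] - cum_w[j]
    s = cum_wx[i + 1] - cum_wx[j]
    s2 = cum_wx2[i + 1] - cum_wx2[j]
    return s2 - s * s / w


def jenks_breaks(values: Sequence[float], k: int) -> tuple[tuple[float, ...], float]:
    """Exact natural-breaks cut points and the optimal within-class SSD.

    Runs the Fisher-Jenks dynamic program over the *unique* sorted values
    weighted by their multiplicities, which guarantees tied values share a
    class and keeps the program O(k u^2) in the number of unique values u.
    Returns (breaks, total within-class sum of squared deviations).
    """
    x = np.asarray(values, dtype=float)
    uniq, counts = np.unique(x, return_counts=True)
    u = len(uniq)
    k_eff = min(k, u)
    w = counts.astype(float)
    cum_w = np.concatenate([[0.0], np.cumsum(w)])
    cum_wx = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cum_wx2 = np.concatenate([[0.0], np.cumsum(w * uniq**2)])

    # D[m, i]: optimal SSD splitting uniq[0..i] into m+1 classes
    D = np.full((k_eff, u), np.inf)
    back = np.zeros((k_eff, u), dtype=int)
    all_j = np.arange(u)
    D[0, :] = cum_wx2[1:] - cum_wx[1:] ** 2 / cum_w[1:]
    for m in range(1, k_eff):
        for i in range(m, u):
            j = all_j[m : i + 1]  # first index of the last class
            cost = D[m - 1, j - 1] + _weighted_sse_matrix_row(
                cum_w, cum_wx, cum_wx2, j, i
            )
            best = int(np.argmin(cost))
            D[m, i] = cost[best]
            back[m, i] = j[best]
    # recover class-start indices
    starts = []
    i = u - 1
    for m in range(k_eff - 1, 0, -1):
        j = back[m, i]
        starts.append(j)
        i = j - 1
    starts.reverse()
    breaks = tuple(float(uniq[s]) for s in starts)
    return breaks, float(max(D[k_eff - 1, u - 1], 0.0))


def classify_jenks(scores: Sequence[tuple[str, float]], k: int = 4) -> GradeAssignment:
    """Jenks natural-breaks grading: minimizes total within-class SSD."""
    _check_k(k)
    cas, values = _as_arrays(scores)
    if len(values) < k:
        raise DataError(f"need at least k={k} scores for Jenks, got {len(values)}")
    if values.min() == values.max():
        log.warning("all scores equal; Jenks grading collapses to one class")
        return _assemble("jenks", k, (), cas, values)
    breaks, _ = jenks_breaks(values, k)
    return _assemble("jenks", k, breaks, cas, values)


def within_class_ssd(values: Sequence[float], assignment: GradeAssignment) -> float:
    """Total within-class sum of squared deviations under an assignment."""
    x = np.asarray(values, dtype=float)
    grades = np.searchsorted(assignment.breaks, x, side="right") + 1
    total = 0.0
    for g in np.unique(grades):
        cls = x[grades == g]
        total += float(np.sum((cls - cls.mean()) ** 2))
    return total


def classify_geometric_interval(
    scores: Sequence[tuple[str, float]], k: int = 4
) -> GradeAssignment:
    """Geometric-interval grading: multiplicative (log-equal) breaks.

    With positive scores the breaks are min*(max/min)^(i/k); class widths
    then form a geometric progression spanning [min, max]. Non-positive
    minima are handled by shifting the scores by (1 - min), applying the
    rule, and shifting the breaks back. This multiplicative rule is one of
    several conventions that travel under the "geometric interval" name; it
    is the package's documented default.
    """
    _check_k(k)
    cas, values = _as_arrays(scores)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        log.warning("all scores equal; geometric grading collapses to one class")
        return _assemble("geometric_interval", k, (), cas, values)
    shift = 0.0 if lo > 0 else 1.0 - lo
    lo_s, hi_s = lo + shift, hi + shift
    ratio = hi_s / lo_s
    breaks = [lo_s * ratio ** (i / k) - shift for i in range(1, k)]
    return _assemble("geometric_interval", k, breaks, cas, values)


_CLASSIFIERS = {
    "equal_interval": classify_equal_interval,
    "quantile": classify_quantile,
    "jenks": classify_jenks,
    "geometric_interval": classify_geometric_interval,
}


def classify(
    scores: Sequence[tuple[str, float]], method: str, k: int = 4
) -> GradeAssignment:
    """Dispatch to one of the four class-interval methods by name."""
    if method not in _CLASSIFIERS:
        raise DataError(f"unknown classification method {method!r}; one of {METHODS}")
    return _CLASSIFIERS[method](scores, k)
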