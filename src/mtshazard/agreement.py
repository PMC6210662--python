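"""Agreement and validation statistics for hazard rankings.

Compares the MD-based hazard scores/grades with external chemical ranking
and scoring (CRS) results such as EURAM or CHEMS (ingested as opaque numeric
columns — their algorithms are out of scope here) via Pearson correlation
and Cohen's kappa (unweighted, linear- and quadratic-weighted), and
validates grade assignments against a regulatory chemical list by true/false
positive proportions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ghs_io import DataError
from .grading import GradeAssignment

log = logging.getLogger("mtshazard")

WEIGHTINGS = ("unweighted", "linear", "quadratic")


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """k x k co-classification counts (rows: method A grade, cols: method B)."""

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.k, self.k) or (c < 0).any():
            raise DataError("contingency counts must be a k x k non-negative matrix")
        object.__setattr__(self, "counts", c.astype(float))

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    pearson_r: float
    pearson_p: float
    kappa_unweighted: float
    kappa_linear: float
    kappa_quadratic: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """True/false-positive proportions against a regulatory list.

    ``tp_proportion``: fraction of regulated chemicals placed in the high
    grades; ``fp_proportion``: fraction of non-regulated chemicals placed
    there.
    """

    tp_numerator: int
    tp_denominator: int
    fp_numerator: int
    fp_denominator: int
    n_unmatched_regulated: int = 0

    @property
    def tp_proportion(self) -> float:
        return self.tp_numerator / self.tp_denominator

    @property
    def fp_proportion(self) -> float:
        return self.fp_numerator / self.fp_denominator

    def to_dict(self) -> dict[str, float | int]:
        d = dataclasses.asdict(self)
        d["tp_proportion"] = self.tp_proportion
        d["fp_proportion"] = self.fp_proportion
        return d


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DataError("pearson requires two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation is undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def contingency(a: GradeAssignment, b: GradeAssignment) -> ContingencyTable:
    """Cross-tabulate two grade assignments over the same chemical set."""
    if a.k != b.k:
        raise DataError(f"grade assignments use different k: {a.k} vs {b.k}")
    only_a = set(a.grades) - set(b.grades)
    only_b = set(b.grades) - set(a.grades)
    if only_a or only_b:
        raise DataError(
            "grade assignments cover different chemicals "
            f"(only in A: {sorted(only_a)[:5]}, only in B: {sorted(only_b)[:5]})"
        )
    counts = np.zeros((a.k, a.k))
    for cas, ga in a.grades.items():
        counts[ga - 1, b.grades[cas] - 1] += 1
    return ContingencyTable(k=a.k, counts=counts)


def weighted_kappa(table: ContingencyTable, weighting: str = "unweighted") -> float:
    """Cohen's kappa in the disagreement-weight formulation.

    kappa = 1 - sum(w * o) / sum(w * e) with observed proportions o, chance
    expectation e = outer product of marginals, and disagreement weights
    w_ij = (|i-j|/(k-1))^p for p = 1 (linear) or 2 (quadratic); unweighted
    uses w_ij = 1[i != j]. Equivalent to the usual agreement-weight form.
    """
    if weighting not in WEIGHTINGS:
        raise DataError(f"unknown weighting {weighting!r}; one of {WEIGHTINGS}")
    if table.total <= 0:
        raise DataError("empty contingency table")
    k = table.k
    o = table.counts / table.total
    rows = o.sum(axis=1)
    cols = o.sum(axis=0)
    e = np.outer(rows, cols)
    i, j = np.indices((k, k))
    if weighting == "unweighted":
        w = (i != j).astype(float)
    else:
        p = 1 if weighting == "linear" else 2
        w = (np.abs(i - j) / (k - 1)) ** p
    expected = float((w * e).sum())
    if expected == 0.0:
        log.warning("zero expected disagreement (single occupied cell); kappa := 1")
        return 1.0
    return 1.0 - float((w * o).sum()) / expected


def agreement_report(
    a_scores: Mapping[str, float],
    b_scores: Mapping[str, float],
    a_grades: GradeAssignment,
    b_grades: GradeAssignment,
) -> AgreementReport:
    """Full score-level and grade-level agreement between two CRS methods."""
    common = sorted(set(a_scores) & set(b_scores))
    if len(common) < 3:
        raise DataError("need at least 3 common chemicals for agreement analysis")
    r, p = pearson([a_scores[c] for c in common], [b_scores[c] for c in common])
    table = contingency(a_grades, b_grades)
    return AgreementReport(
        pearson_r=r,
        pearson_p=p,
        kappa_unweighted=weighted_kappa(table, "unweighted"),
        kappa_linear=weighted_kappa(table, "linear"),
        kappa_quadratic=weighted_kappa(table, "quadratic"),
    )


def regulatory_validation(
    grades: GradeAssignment,
    regulated: Iterable[str],
    high_grades: Iterable[int] = (3, 4),
) -> ValidationReport:
    """Validate grades against a regulatory membership list.

    A regulated chemical in one of the high grades counts as a true
    positive; a non-regulated one there counts as a false positive.
    Regulated CAS numbers absent from the graded set are dropped with a
    warning and counted in ``n_unmatched_regulated``.
    """
    regulated = set(regulated)
    if not regulated:
        raise DataError("empty regulated set")
    high = set(high_grades)
    graded = set(grades.grades)
    unmatched = regulated - graded
    if unmatched:
        log.warning(
            "%d regulated chemicals not in the graded set; dropped", len(unmatched)
        )
    reg = regulated & graded
    if not reg:
        raise DataError("no regulated chemical matches the graded set")
    unreg = graded - regulated
    tp = sum(grades.grades[c] in high for c in reg)
    fp = sum(grades.grades[c] in high for c in unreg)
    return ValidationReport(
        tp_numerator=tp,
        tp_denominator=len(reg),
        fp_numerator=fp,
        fp_denominator=len(unreg),
        n_unmatched_regulated=len(unmatched),
    )


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    ci_low: float | None
    ci_high: float | None

    @property
    def ci_defined(self) -> bool:
        return self.ci_low is not None


def group_summary(
    scores: Mapping[str, float],
    groups: Mapping[str, str],
    confidence: float = 0.95,
) -> dict[str, GroupSummary]:
    """Per-group arithmetic mean and Student-t confidence interval.

    CI = mean +/- t_{1-(1-confidence)/2, n-1} * sd / sqrt(n). Singleton
    groups report the mean with an undefined (None) interval. Chemicals
    without a group label are collected under "other".
    """
    buckets: dict[str, list[float]] = {}
    for cas, score in scores.items():
        label = groups.get(cas, "other")
        buckets.setdefault(label, []).append(score)
    out: dict[str, GroupSummary] = {}
    for label, vals in buckets.items():
        arr = np.asarray(vals, dtype=float)
        n = len(arr)
        mean = float(arr.mean())
        if n < 2:
            out[label] = GroupSummary(label, n, mean, None, None)
            continue
        sd = float(arr.std(ddof=1))
        tcrit = float(stats.t.ppf(1 - (1 - confidence) / 2, n - 1))
        half = tcrit * sd / np.sqrt(n)
        out[label] = GroupSummary(label, n, mean, mean - half, mean + half)
    return out
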