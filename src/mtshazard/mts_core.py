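"""Mahalanobis-Taguchi System core: unit space construction and MD scoring.

The Mahalanobis-Taguchi System (MTS) scores items by their Mahalanobis
distance (MD) from the center of a reference group (the "Mahalanobis space"
or unit space) of normal items. Here the unit space is built from chemicals
with relatively low health hazards: no Category 1 or 2 classification on any
endpoint and a total quantified score below a cut-off.

For a chemical with quantified scores x over the k usable variables, the
scaled MD is

    MD = z' R^{-1} z / k,    z_i = (x_i - m_i) / s_i,

where m and s are the unit-space per-variable means and sample standard
deviations (n-1 divisor), and R is the unit-space sample correlation matrix
(pseudo-inverted when near-singular). Scaling by k gives the classical MTS
property that the average MD over the fitting sample equals (n-1)/n.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ghs_io import DataError, GhsRecord, HazardCategory, ScoreVector, VARIABLES

log = logging.getLogger("mtshazard")

# Relative eigenvalue cut-off below which the correlation matrix is treated
# as singular and the Moore-Penrose pseudoinverse is used.
SINGULARITY_RTOL = 1e-10


@dataclasses.dataclass(frozen=True)
class SelectionCriteria:
    """Criteria for admitting a chemical into the low-hazard normal group.

    Defaults: no Category 1 endpoints, no Category 2 endpoints, and a total
    quantified score of at most 280 points (inclusive by default; set
    ``inclusive=False`` for a strict ``<`` threshold).
    """

    max_cat1_count: int = 0
    max_cat2_count: int = 0
    total_score_limit: float = 280.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_cat1_count < 0 or self.max_cat2_count < 0:
            raise DataError("category count limits must be non-negative")
        if self.total_score_limit <= 0:
            raise DataError("total score limit must be positive")

    def admits(self, record: GhsRecord, score: ScoreVector) -> bool:
        cats = list(record.endpoints.values())
        n1 = sum(c is HazardCategory.CAT1 for c in cats)
        n2 = sum(c is HazardCategory.CAT2 for c in cats)
        if n1 > self.max_cat1_count or n2 > self.max_cat2_count:
            return False
        if self.inclusive:
            return score.total <= self.total_score_limit
        return score.total < self.total_score_limit


@dataclasses.dataclass(frozen=True)
class ReferenceSpace:
    """Unit-space statistics: center, scatter and correlation structure.

    ``degenerate`` lists zero-variance variables; they are excluded from the
    correlation matrix and from the distance (``corr`` etc. cover only the
    ``k`` non-degenerate variables, in the order of ``variables`` minus
    ``degenerate``).
    """

    variables: tuple[str, ...]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    degenerate: tuple[str, ...]
    corr: np.ndarray
    corr_inv: np.ndarray
    n_members: int
    member_cas: tuple[str, ...]

    @property
    def active_variables(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if v not in self.degenerate)

    @property
    def k(self) -> int:
        return len(self.active_variables)

    def to_json(self) -> str:
        payload = {
            "variables": list(self.variables),
            "means": {v: self.means[v] for v in self.variables},
            "sds": {v: self.sds[v] for v in self.variables},
            "degenerate": list(self.degenerate),
            "corr": self.corr.tolist(),
            "corr_inv": self.corr_inv.tolist(),
            "n_members": self.n_members,
            "member_cas": list(self.member_cas),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceSpace":
        d = json.loads(text)
        return cls(
            variables=tuple(d["variables"]),
            means=d["means"],
            sds=d["sds"],
            degenerate=tuple(d["degenerate"]),
            corr=np.asarray(d["corr"], dtype=float),
            corr_inv=np.asarray(d["corr_inv"], dtype=float),
            n_members=int(d["n_members"]),
            member_cas=tuple(d["member_cas"]),
        )


@dataclasses.dataclass(frozen=True)
class MDResult:
    """Scaled Mahalanobis distance and hazard rank (1 = largest MD)."""

    cas: str
    md: float
    rank: int


def select_normal_group(
    scores: Sequence[ScoreVector],
    records: Sequence[GhsRecord],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[str]:
    """Return the CAS numbers admitted to the normal group.

    Selection is deterministic: a chemical is admitted iff it has no more
    than the allowed Category 1 / Category 2 counts and its total score is
    within the limit. Fails if fewer than (number of variables + 2) members
    remain, since the correlation matrix would be singular or ill-determined.
    """
    by_cas = {r.cas: r for r in records}
    if set(by_cas) != {s.cas for s in scores}:
        raise DataError("scores and records must cover the same CAS set")
    members = [s.cas for s in scores if criteria.admits(by_cas[s.cas], s)]
    minimum = len(VARIABLES) + 2
    if len(members) < minimum:
        raise DataError(
            f"normal group has only {len(members)} members (< {minimum}); "
            "relax the selection criteria (higher total-score limit or "
            "allowed category counts) to obtain a usable reference group"
        )
    return members


def fit_reference(
    member_scores: Sequence[ScoreVector],
    variables: Sequence[str] = VARIABLES,
) -> ReferenceSpace:
    """Fit unit-space statistics from the normal group's score vectors.

    Means and standard deviations are per-variable sample statistics (n-1
    divisor); the correlation matrix is the sample Pearson correlation over
    the non-degenerate (non-constant) variables. Near-singular correlation
    matrices fall back to the Moore-Penrose pseudoinverse.
    """
    variables = tuple(variables)
    n = len(member_scores)
    if n < len(variables) + 2:
        raise DataError(
            f"need at least {len(variables) + 2} members to fit a reference, got {n}"
        )
    order = {v: i for i, v in enumerate(VARIABLES)}
    X = np.array(
        [[sv.values[order[v]] for v in variables] for sv in member_scores],
        dtype=float,
    )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    degenerate = tuple(v for v, s in zip(variables, sds) if s == 0.0)
    if len(degenerate) == len(variables):
        raise DataError("all variables are constant over the normal group")
    if degenerate:
        log.warning(
            "zero-variance variables excluded from the unit space: %s",
            ", ".join(degenerate),
        )
    active = [i for i, v in enumerate(variables) if v not in degenerate]
    Z = (X[:, active] - means[active]) / sds[active]
    corr = (Z.T @ Z) / (n - 1)
    # symmetrize against round-off before inversion
    corr = (corr + corr.T) / 2.0
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < SINGULARITY_RTOL * max(eigvals[-1], 1.0):
        log.warning(
            "unit-space correlation matrix is near-singular "
            "(min eigenvalue %.3e); using pseudoinverse",
            eigvals[0],
        )
        corr_inv = np.linalg.pinv(corr, hermitian=True)
    else:
        corr_inv = np.linalg.inv(corr)
    return ReferenceSpace(
        variables=variables,
        means={v: float(m) for v, m in zip(variables, means)},
        sds={v: float(s) for v, s in zip(variables, sds)},
        degenerate=degenerate,
        corr=corr,
        corr_inv=corr_inv,
        n_members=n,
        member_cas=tuple(sv.cas for sv in member_scores),
    )


def mahalanobis_distance(score: ScoreVector, ref: ReferenceSpace) -> float:
    """Scaled Mahalanobis distance of one chemical from the unit-space center.

    ``md = z' R^{-1} z / k`` over the k non-degenerate variables; zero iff
    the chemical sits exactly at the reference means on all of them.
    """
    order = {v: i for i, v in enumerate(VARIABLES)}
    active = ref.active_variables
    if not set(ref.variables) <= set(VARIABLES):
        raise DataError("reference variables are not a subset of the score variables")
    z = np.empty(len(active))
    for j, v in enumerate(active):
        sd = ref.sds[v]
        if sd == 0.0:
            raise AssertionError(
                f"variable {v} has zero SD but was not flagged degenerate"
            )
        z[j] = (score.values[order[v]] - ref.means[v]) / sd
    md = float(z @ ref.corr_inv @ z) / len(active)
    # Quadratic form of a PSD (pseudo)inverse; clip parasitic negatives.
    return max(md, 0.0)


def score_all(
    scores: Iterable[ScoreVector], ref: ReferenceSpace
) -> list[MDResult]:
    """Score every chemical against the reference and rank by descending MD.

    Unit-space members are scored like everyone else. Ties get standard
    competition ranks (equal MD, equal rank; the next rank is skipped). The
    result is independent of input order up to the order of the returned
    list, which follows the input.
    """
    scores = list(scores)
    if not scores:
        raise DataError("no score vectors to rank")
    mds = np.array([mahalanobis_distance(sv, ref) for sv in scores])
    # competition ("min") rank on descending md
    from scipy.stats import rankdata

    ranks = rankdata(-mds, method="min").astype(int)
    return [
        MDResult(cas=sv.cas, md=float(md), rank=int(rk))
        for sv, md, rk in zip(scores, mds, ranks)
    ]


def top_n(results: Sequence[MDResult], n: int = 10) -> list[MDResult]:
    """The n largest-MD chemicals in rank order (ties broken by CAS)."""
    return sorted(results, key=lambda r: (r.rank, r.cas))[:n]
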