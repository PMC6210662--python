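"""Synthetic GHS hazard tables with controllable correlation structure.

Real GHS classification tables give only ordinal categories per endpoint,
yet their quantified scores show a distinct pairwise correlation pattern
(e.g. skin and eye irritation correlate strongly, as do the oral and dermal
acute-toxicity routes). The minimal generative model reproducing both
marginal categories and such correlations is a latent-Gaussian threshold
model: each chemical draws a correlated multivariate-normal latent severity
vector, and each coordinate is discretized through per-variable thresholds
into that variable's valid categories. Data-gap outcomes (Classification
Not Possible) and out-of-definition outcomes (Not Applicable) are masked in
independently per cell.

A configurable number of "planted" hazards — records forced to the top
category on at least six endpoints — provides ground truth for testing that
the MD pipeline surfaces known hazardous chemicals.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ghs_io import (
    DataError,
    GhsRecord,
    HazardCategory,
    VARIABLES,
    allowed_categories,
)

C = HazardCategory

# Per-variable discretization: ordered categories (least -> most severe) and
# ascending cut points on the standard-normal latent scale. The top cut at
# z = 1.645 puts ~5% of background cells in Category 1/2, leaving a usable
# low-hazard normal group.
_ACUTE_CATS = (C.NOT_CLASSIFIED, C.CAT5, C.CAT4, C.CAT3, C.CAT2, C.CAT1)
_ACUTE_CUTS = (0.8, 1.1, 1.35, 1.645, 2.1)
_TWO_CATS = (C.NOT_CLASSIFIED, C.CAT2, C.CAT1)
_TWO_CUTS = (1.645, 2.1)
_STOT_SINGLE_CATS = (C.NOT_CLASSIFIED, C.CAT3, C.CAT2, C.CAT1)
_STOT_SINGLE_CUTS = (1.3, 1.645, 2.1)

DEFAULT_THRESHOLDS: dict[str, tuple[tuple[float, ...], tuple[HazardCategory, ...]]] = {
    "acute_oral": (_ACUTE_CUTS, _ACUTE_CATS),
    "acute_dermal": (_ACUTE_CUTS, _ACUTE_CATS),
    "acute_inhalation": (_ACUTE_CUTS, _ACUTE_CATS),
    "skin": (_TWO_CUTS, _TWO_CATS),
    "eye": (_TWO_CUTS, _TWO_CATS),
    "mutagenicity": (_TWO_CUTS, _TWO_CATS),
    "carcinogenicity": (_TWO_CUTS, _TWO_CATS),
    "reproductive": (_TWO_CUTS, _TWO_CATS),
    "stot_single": (_STOT_SINGLE_CUTS, _STOT_SINGLE_CATS),
    "stot_repeated": (_TWO_CUTS, _TWO_CATS),
}


def default_latent_corr() -> np.ndarray:
    """Default 10x10 latent correlation emulating observed score correlations.

    Strong pairs: skin/eye (0.70), acute oral/dermal (0.60), STOT single/
    repeated (0.53); moderate associations among the CMR endpoints and the
    acute-toxicity routes; a weak 0.05 background elsewhere.
    """
    idx = {v: i for i, v in enumerate(VARIABLES)}
    R = np.full((10, 10), 0.05)
    np.fill_diagonal(R, 1.0)
    pairs = {
        ("acute_oral", "acute_dermal"): 0.60,
        ("acute_oral", "acute_inhalation"): 0.28,
        ("acute_dermal", "acute_inhalation"): 0.25,
        ("skin", "eye"): 0.70,
        ("skin", "carcinogenicity"): 0.36,
        ("mutagenicity", "carcinogenicity"): 0.37,
        ("carcinogenicity", "reproductive"): 0.32,
        ("mutagenicity", "reproductive"): 0.25,
        ("stot_single", "stot_repeated"): 0.53,
        ("acute_oral", "stot_single"): 0.22,
        ("acute_inhalation", "stot_single"): 0.27,
        ("eye", "stot_single"): 0.20,
        ("reproductive", "stot_single"): 0.21,
    }
    for (a, b), r in pairs.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the latent-Gaussian threshold generator.

    ``n_chemicals`` is the total table size; the last ``n_planted_hazards``
    rows are forced high-severity records. ``p_cnp`` / ``p_na`` are the
    per-cell masking probabilities for Classification Not Possible and Not
    Applicable (applied to non-forced cells only).
    """

    n_chemicals: int = 3000
    latent_corr: np.ndarray = dataclasses.field(default_factory=default_latent_corr)
    category_thresholds: Mapping[
        str, tuple[tuple[float, ...], tuple[HazardCategory, ...]]
    ] = dataclasses.field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    p_cnp: float = 0.25
    p_na: float = 0.05
    n_planted_hazards: int = 10
    seed: int = 0

    def validate(self) -> None:
        R = np.asarray(self.latent_corr, dtype=float)
        if R.shape != (len(VARIABLES),) * 2 or not np.allclose(R, R.T):
            raise DataError("latent_corr must be a symmetric 10x10 matrix")
        lam = np.linalg.eigvalsh(R)
        if lam[0] < -1e-10:
            raise DataError(
                f"latent_corr is not positive semi-definite "
                f"(smallest eigenvalue {lam[0]:.3e})"
            )
        for p, what in ((self.p_cnp, "p_cnp"), (self.p_na, "p_na")):
            if not 0.0 <= p <= 1.0:
                raise DataError(f"{what} must be in [0, 1]")
        if not 0 <= self.n_planted_hazards <= self.n_chemicals:
            raise DataError("n_planted_hazards must be in [0, n_chemicals]")
        for var, (cuts, cats) in self.category_thresholds.items():
            if list(cuts) != sorted(cuts):
                raise DataError(f"thresholds for {var} must be ascending")
            if len(cats) != len(cuts) + 1:
                raise DataError(f"{var}: need one more category than cut points")


def _psd_factor(R: np.ndarray) -> np.ndarray:
    """Factor L with L L' = R, tolerating a semi-definite boundary."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        lam, V = np.linalg.eigh(R)
        lam = np.clip(lam, 0.0, None)
        return V * np.sqrt(lam)


def generate(config: SimulationConfig) -> tuple[list[GhsRecord], pd.DataFrame]:
    """Draw a synthetic GHS table and its ground-truth labels.

    Returns the records plus a DataFrame with columns ``cas``, ``name`` and
    ``planted``. Fully reproducible for a fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_chemicals
    L = _psd_factor(np.asarray(config.latent_corr, dtype=float))
    Z = rng.standard_normal((n, len(VARIABLES))) @ L.T
    mask_cnp = rng.random((n, len(VARIABLES))) < config.p_cnp
    mask_na = rng.random((n, len(VARIABLES))) < config.p_na

    records: list[GhsRecord] = []
    planted_flags = np.zeros(n, dtype=bool)
    planted_flags[n - config.n_planted_hazards :] = True

    for i in range(n):
        endpoints: dict[str, HazardCategory] = {}
        forced: set[str] = set()
        if planted_flags[i]:
            n_forced = int(rng.integers(6, len(VARIABLES) + 1))
            forced = set(rng.choice(VARIABLES, size=n_forced, replace=False))
        for j, var in enumerate(VARIABLES):
            cuts, cats = config.category_thresholds[var]
            if var in forced:
                endpoints[var] = cats[-1]  # most severe defined category
                continue
            if mask_cnp[i, j]:
                endpoints[var] = C.CLASSIFICATION_NOT_POSSIBLE
            elif mask_na[i, j]:
                endpoints[var] = C.NOT_APPLICABLE
            else:
                endpoints[var] = cats[int(np.searchsorted(cuts, Z[i, j]))]
        cas = f"{800000 + i:06d}-{(i % 90) + 10:02d}-{i % 10}"
        name = ("planted hazard" if planted_flags[i] else "synthetic chemical") + f" {i:05d}"
        rec = GhsRecord(cas=cas, name=name, endpoints=endpoints)
        records.append(rec)

    truth = pd.DataFrame(
        {
            "cas": [r.cas for r in records],
            "name": [r.name for r in records],
            "planted": planted_flags,
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# Literature-derived fixtures
# ---------------------------------------------------------------------------

def fixture_flutolanil() -> GhsRecord:
    """Flutolanil (CAS 66332-96-5): the canonical low-hazard worked example.

    Nine endpoints Not Classified and one Classification Not Possible, for a
    default-scheme total of 9*10 + 30 = 120 points — inside the normal-group
    criteria. The single data-gap endpoint is placed on acute inhalation;
    the published example does not name it and the total is unaffected.
    """
    endpoints = {v: C.NOT_CLASSIFIED for v in VARIABLES}
    endpoints["acute_inhalation"] = C.CLASSIFICATION_NOT_POSSIBLE
    return GhsRecord(cas="66332-96-5", name="flutolanil", endpoints=endpoints)


_TABLE_TOP10: list[tuple[str, str, tuple[HazardCategory, ...]]] = [
    # (cas, name, categories in canonical variable order)
    ("505-60-2", "bis(2-chloroethyl)sulfide",
     (C.CAT2, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT2, C.CAT1)),
    ("51-75-2", "bis(2-chloroethyl)methylamine",
     (C.CAT2, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT1,
      C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1, C.CLASSIFICATION_NOT_POSSIBLE)),
    ("151-56-4", "aziridine",
     (C.CAT2, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT1, C.CAT2, C.CAT2, C.CAT1, C.CAT1)),
    ("10588-01-9", "sodium dichromate",
     (C.CAT3, C.CAT3, C.CAT2, C.CAT1, C.CAT1, C.CAT2, C.CAT1,
      C.NOT_CLASSIFIED, C.CAT1, C.CAT1)),
    ("64-67-5", "diethyl sulfate",
     (C.CAT4, C.CAT3, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1, C.CAT1, C.CAT1,
      C.CAT1, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT2, C.CLASSIFICATION_NOT_POSSIBLE)),
    ("107-30-2", "chloromethyl methyl ether",
     (C.CAT4, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1, C.CAT1, C.CAT1, C.CAT2,
      C.CAT1, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1, C.CLASSIFICATION_NOT_POSSIBLE)),
    ("108-95-2", "phenol",
     (C.CAT4, C.CAT3, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1, C.CAT1, C.CAT1,
      C.NOT_CLASSIFIED, C.CAT1, C.CAT1, C.CAT1)),
    ("2425-06-1", "captafol",
     (C.CAT5, C.NOT_CLASSIFIED, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT2, C.CAT2,
      C.CAT1, C.CAT1, C.NOT_CLASSIFIED, C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1)),
    ("764-41-0", "1,4-dichloro-2-butene",
     (C.CAT3, C.CAT3, C.CAT1, C.CAT1, C.CAT1, C.CAT2, C.CAT1,
      C.CLASSIFICATION_NOT_POSSIBLE, C.CAT1, C.CAT1)),
    ("60-57-1", "dieldrin",
     (C.CAT1, C.CAT1, C.CAT1, C.CLASSIFICATION_NOT_POSSIBLE,
      C.CLASSIFICATION_NOT_POSSIBLE, C.NOT_CLASSIFIED, C.NOT_CLASSIFIED,
      C.CAT1, C.CAT1, C.CAT1)),
]


def fixture_table5() -> list[GhsRecord]:
    """Ten well-known extreme-hazard chemicals with their GHS profiles.

    Used as extreme-profile fixtures: every one carries at least one
    Category 1 or 2 classification, so none can enter the normal group, and
    all should land far from any low-hazard unit space.
    """
    records = []
    for cas, name, cats in _TABLE_TOP10:
        rec = GhsRecord(
            cas=cas, name=name, endpoints=dict(zip(VARIABLES, cats))
        )
        rec.validate_shapes(strict=True)
        records.append(rec)
    return records
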