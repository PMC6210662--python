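"""GHS hazard records: data model, CSV I/O, inhalation aggregation, quantification.

The Globally Harmonized System (GHS) classifies each health-hazard endpoint of
a chemical into ordered categories (Category 1 = most hazardous), or into one
of three special outcomes: Not Classified (evidence of no hazard at the
classification criteria), Classification Not Possible (insufficient data), and
Not Applicable (outside the endpoint's definition).

This module models one chemical's classifications over ten health endpoints,
reads and writes them as CSV tables, merges the three acute-inhalation routes
(gas / vapor / dust-and-mist) into their most conservative value, and maps
categories to numeric hazard scores so that downstream multivariate analysis
can operate on a score matrix.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger("mtshazard")


class ConfigurationError(Exception):
    """Bad configuration or malformed input schema (CLI exit code 2)."""


class DataError(Exception):
    """Invalid data content encountered at run time (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Hazard categories
# ---------------------------------------------------------------------------

class HazardCategory(enum.Enum):
    """One GHS classification outcome for a single health endpoint.

    Sub-categories 1A/1B (mutagenicity, carcinogenicity, reproductive
    toxicity) normalize to ``CAT1``: GHS treats them as Category 1 severity
    and the default quantification scheme scores only "Category 1".
    """

    CAT1 = "CAT1"
    CAT2 = "CAT2"
    CAT3 = "CAT3"
    CAT4 = "CAT4"
    CAT5 = "CAT5"
    NOT_CLASSIFIED = "NOT_CLASSIFIED"
    CLASSIFICATION_NOT_POSSIBLE = "CLASSIFICATION_NOT_POSSIBLE"
    NOT_APPLICABLE = "NOT_APPLICABLE"

    def __repr__(self) -> str:  # compact in test output
        return f"HazardCategory.{self.name}"


# Most-to-least conservative. The ordering follows the default quantification
# scores in descending order: absence of information (Classification Not
# Possible, 30 points) is treated as more conservative than Category 4 but
# less than Category 3, because missing data is not evidence of no hazard.
CONSERVATIVENESS_ORDER: tuple[HazardCategory, ...] = (
    HazardCategory.CAT1,
    HazardCategory.CAT2,
    HazardCategory.CAT3,
    HazardCategory.CLASSIFICATION_NOT_POSSIBLE,
    HazardCategory.CAT4,
    HazardCategory.CAT5,
    HazardCategory.NOT_CLASSIFIED,
    HazardCategory.NOT_APPLICABLE,
)

_CONSERVATIVENESS_RANK = {c: i for i, c in enumerate(CONSERVATIVENESS_ORDER)}


def conservativeness_rank(category: HazardCategory) -> int:
    """Position in the conservativeness order (0 = most conservative)."""
    return _CONSERVATIVENESS_RANK[category]


# The ten aggregated health-hazard variables, in canonical column order.
VARIABLES: tuple[str, ...] = (
    "acute_oral",
    "acute_dermal",
    "acute_inhalation",
    "skin",
    "eye",
    "mutagenicity",
    "carcinogenicity",
    "reproductive",
    "stot_single",
    "stot_repeated",
)

# Raw (pre-aggregation) columns: acute inhalation split into three routes.
INHALATION_ROUTES: tuple[str, ...] = (
    "acute_inhalation_gas",
    "acute_inhalation_vapor",
    "acute_inhalation_dust_mist",
)
RAW_VARIABLES: tuple[str, ...] = (
    "acute_oral",
    "acute_dermal",
    *INHALATION_ROUTES,
    "skin",
    "eye",
    "mutagenicity",
    "carcinogenicity",
    "reproductive",
    "stot_single",
    "stot_repeated",
)

# Deepest numbered category defined for each variable. Acute-toxicity routes
# run to Category 5; skin/eye corrosion-irritation and STOT (repeated) stop at
# Category 2, the CMR endpoints at Category 2 (1A/1B fold into 1), and STOT
# (single) at Category 3.
_MAX_CAT: dict[str, int] = {
    "acute_oral": 5,
    "acute_dermal": 5,
    "acute_inhalation": 5,
    "acute_inhalation_gas": 5,
    "acute_inhalation_vapor": 5,
    "acute_inhalation_dust_mist": 5,
    "skin": 2,
    "eye": 2,
    "mutagenicity": 2,
    "carcinogenicity": 2,
    "reproductive": 2,
    "stot_single": 3,
    "stot_repeated": 2,
}

_NUMBERED = {
    1: HazardCategory.CAT1,
    2: HazardCategory.CAT2,
    3: HazardCategory.CAT3,
    4: HazardCategory.CAT4,
    5: HazardCategory.CAT5,
}


def allowed_categories(variable: str) -> frozenset[HazardCategory]:
    """Set of categories defined for ``variable`` (numbered + three specials)."""
    if variable not in _MAX_CAT:
        raise ConfigurationError(f"unknown variable: {variable!r}")
    cats = {_NUMBERED[i] for i in range(1, _MAX_CAT[variable] + 1)}
    cats |= {
        HazardCategory.NOT_CLASSIFIED,
        HazardCategory.CLASSIFICATION_NOT_POSSIBLE,
        HazardCategory.NOT_APPLICABLE,
    }
    return frozenset(cats)


# Case-insensitive aliases accepted when parsing category cells.
DEFAULT_ALIASES: dict[str, HazardCategory] = {
    "1": HazardCategory.CAT1,
    "1a": HazardCategory.CAT1,
    "1b": HazardCategory.CAT1,
    "2": HazardCategory.CAT2,
    "3": HazardCategory.CAT3,
    "4": HazardCategory.CAT4,
    "5": HazardCategory.CAT5,
    "cat1": HazardCategory.CAT1,
    "cat2": HazardCategory.CAT2,
    "cat3": HazardCategory.CAT3,
    "cat4": HazardCategory.CAT4,
    "cat5": HazardCategory.CAT5,
    "category 1": HazardCategory.CAT1,
    "category 1a": HazardCategory.CAT1,
    "category 1b": HazardCategory.CAT1,
    "category 2": HazardCategory.CAT2,
    "category 3": HazardCategory.CAT3,
    "category 4": HazardCategory.CAT4,
    "category 5": HazardCategory.CAT5,
    "nc": HazardCategory.NOT_CLASSIFIED,
    "not classified": HazardCategory.NOT_CLASSIFIED,
    "not_classified": HazardCategory.NOT_CLASSIFIED,
    "cnp": HazardCategory.CLASSIFICATION_NOT_POSSIBLE,
    "classification not possible": HazardCategory.CLASSIFICATION_NOT_POSSIBLE,
    "classification_not_possible": HazardCategory.CLASSIFICATION_NOT_POSSIBLE,
    "na": HazardCategory.NOT_APPLICABLE,
    "n/a": HazardCategory.NOT_APPLICABLE,
    "not applicable": HazardCategory.NOT_APPLICABLE,
    "not_applicable": HazardCategory.NOT_APPLICABLE,
}


def parse_category(
    text: str,
    *,
    aliases: Mapping[str, HazardCategory] | None = None,
    strict: bool = False,
) -> HazardCategory:
    """Parse one category cell.

    Matching is case-insensitive after trimming. An empty cell is treated as
    Classification Not Possible (insufficient information) with a warning. In
    strict mode unknown strings raise :class:`DataError`; otherwise they also
    fall back to Classification Not Possible with a warning.
    """
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.strip().lower(): v for k, v in aliases.items()})
    key = text.strip().lower()
    if not key:
        log.warning("empty category cell treated as Classification Not Possible")
        return HazardCategory.CLASSIFICATION_NOT_POSSIBLE
    if key in table:
        return table[key]
    if strict:
        raise DataError(f"unrecognized category string: {text!r}")
    log.warning(
        "unrecognized category %r treated as Classification Not Possible", text
    )
    return HazardCategory.CLASSIFICATION_NOT_POSSIBLE


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GhsRecord:
    """One chemical's identity and its ten aggregated endpoint classifications."""

    cas: str
    name: str
    endpoints: Mapping[str, HazardCategory]

    def __post_init__(self) -> None:
        missing = set(VARIABLES) - set(self.endpoints)
        extra = set(self.endpoints) - set(VARIABLES)
        if missing or extra:
            raise DataError(
                f"record {self.cas}: endpoints must be exactly the 10 variables "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        object.__setattr__(self, "endpoints", dict(self.endpoints))

    def validate_shapes(self, *, strict: bool = True) -> list[str]:
        """Check each category against its variable's defined set.

        Returns the list of violations; raises in strict mode.
        """
        bad = [
            f"{var}={cat.name}"
            for var, cat in self.endpoints.items()
            if cat not in allowed_categories(var)
        ]
        if bad and strict:
            raise DataError(f"record {self.cas}: undefined categories: {bad}")
        for msg in bad:
            log.warning("record %s: category outside defined set: %s", self.cas, msg)
        return bad


@dataclasses.dataclass(frozen=True)
class RawGhsRecord:
    """Pre-aggregation record with the inhalation routes still split."""

    cas: str
    name: str
    endpoints: Mapping[str, HazardCategory]  # keyed by RAW_VARIABLES

    def aggregate(self) -> GhsRecord:
        ep = dict(self.endpoints)
        merged = aggregate_inhalation(
            ep.pop("acute_inhalation_gas"),
            ep.pop("acute_inhalation_vapor"),
            ep.pop("acute_inhalation_dust_mist"),
        )
        ep["acute_inhalation"] = merged
        return GhsRecord(self.cas, self.name, {v: ep[v] for v in VARIABLES})


def aggregate_inhalation(
    gas: HazardCategory, vapor: HazardCategory, dust_mist: HazardCategory
) -> HazardCategory:
    """Merge the three acute-inhalation routes into the most conservative value.

    "Most conservative" follows :data:`CONSERVATIVENESS_ORDER` (descending
    default score); the operation is symmetric in its arguments.
    """
    return min((gas, vapor, dust_mist), key=conservativeness_rank)


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class QuantificationScheme:
    """Mapping from hazard category to a numeric score in points.

    The default assigns Category n a score of 100/n, Not Classified 10 points
    (below Category 5), Classification Not Possible 30 points (near Category
    3, since missing information is not evidence of no hazard) and Not
    Applicable the minimum of 1 point.
    """

    scores: Mapping[HazardCategory, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", dict(self.scores))
        if set(self.scores) != set(HazardCategory):
            raise ConfigurationError(
                "quantification scheme must score every hazard category"
            )
        if any(s <= 0 for s in self.scores.values()):
            raise ConfigurationError("all quantification scores must be positive")
        if self.scores[HazardCategory.CAT1] < max(self.scores.values()):
            raise ConfigurationError("Category 1 must carry the maximum score")

    def __getitem__(self, category: HazardCategory) -> float:
        return self.scores[category]

    @classmethod
    def default(cls) -> "QuantificationScheme":
        return cls(
            {
                HazardCategory.CAT1: 100.0,
                HazardCategory.CAT2: 50.0,
                HazardCategory.CAT3: 100.0 / 3.0,
                HazardCategory.CAT4: 25.0,
                HazardCategory.CAT5: 20.0,
                HazardCategory.NOT_CLASSIFIED: 10.0,
                HazardCategory.CLASSIFICATION_NOT_POSSIBLE: 30.0,
                HazardCategory.NOT_APPLICABLE: 1.0,
            }
        )


DEFAULT_SCHEME = QuantificationScheme.default()


@dataclasses.dataclass(frozen=True)
class ScoreVector:
    """Quantified scores for one chemical, in canonical variable order."""

    cas: str
    values: tuple[float, ...]
    total: float

    def __post_init__(self) -> None:
        if len(self.values) != len(VARIABLES):
            raise DataError(
                f"score vector for {self.cas} must have {len(VARIABLES)} values"
            )
        if not math.isclose(self.total, sum(self.values), rel_tol=0, abs_tol=1e-9):
            raise DataError(f"score vector for {self.cas}: total != sum(values)")


def quantify(record: GhsRecord, scheme: QuantificationScheme = DEFAULT_SCHEME) -> ScoreVector:
    """Map a record's ten endpoint categories through the scheme.

    The total is the plain sum of the ten scores; with the default scheme it
    ranges from 10 (all Not Applicable) to 1000 (all Category 1).
    """
    values = tuple(scheme[record.endpoints[v]] for v in VARIABLES)
    return ScoreVector(cas=record.cas, values=values, total=sum(values))


def quantify_all(
    records: Iterable[GhsRecord], scheme: QuantificationScheme = DEFAULT_SCHEME
) -> list[ScoreVector]:
    return [quantify(r, scheme) for r in records]


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReadReport:
    """Bookkeeping from one CSV ingest: rows read, dropped, deduplicated."""

    n_rows: int = 0
    n_dropped_no_cas: int = 0
    n_deduplicated: int = 0
    parse_issues: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_rows - self.n_dropped_no_cas - self.n_deduplicated


def read_ghs_table(
    path: str | Path,
    *,
    aliases: Mapping[str, HazardCategory] | None = None,
    strict: bool = False,
) -> tuple[list[GhsRecord], ReadReport]:
    """Read a GHS classification table from CSV.

    The header must contain ``cas``, ``name`` and either the 12 raw endpoint
    columns (three inhalation routes) or the 10 aggregated ones; raw tables
    are aggregated on the fly. Rows without a CAS number are dropped and
    counted; duplicate CAS numbers keep the first occurrence. Unparseable
    category strings are reported with their row number (and rejected in
    strict mode).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    report = ReadReport()
    records: list[GhsRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError(f"empty input file: {path}")
        cols = [c.strip().lower() for c in reader.fieldnames]
        if "cas" not in cols or "name" not in cols:
            raise ConfigurationError("header must contain 'cas' and 'name' columns")
        if set(RAW_VARIABLES) <= set(cols):
            variables: tuple[str, ...] = RAW_VARIABLES
            raw_layout = True
        elif set(VARIABLES) <= set(cols):
            variables = VARIABLES
            raw_layout = False
        else:
            missing = sorted(
                (set(RAW_VARIABLES) - set(cols)) & (set(VARIABLES) - set(cols))
            )
            raise ConfigurationError(f"missing required endpoint columns: {missing}")
        colmap = {c.strip().lower(): orig for orig, c in zip(reader.fieldnames, cols)}
        for lineno, row in enumerate(reader, start=2):
            report.n_rows += 1
            cas = (row.get(colmap["cas"]) or "").strip()
            if not cas:
                report.n_dropped_no_cas += 1
                log.info("row %d dropped: no CAS number", lineno)
                continue
            if cas in seen:
                report.n_deduplicated += 1
                log.info("row %d dropped: duplicate CAS %s", lineno, cas)
                continue
            seen.add(cas)
            name = (row.get(colmap["name"]) or "").strip()
            endpoints: dict[str, HazardCategory] = {}
            for var in variables:
                raw = row.get(colmap[var]) or ""
                try:
                    endpoints[var] = parse_category(raw, aliases=aliases, strict=strict)
                except DataError as exc:
                    report.parse_issues.append(f"row {lineno}: {exc}")
                    raise DataError(f"row {lineno}: {exc}") from exc
            if raw_layout:
                rec = RawGhsRecord(cas, name, endpoints).aggregate()
            else:
                rec = GhsRecord(cas, name, endpoints)
            rec.validate_shapes(strict=strict)
            records.append(rec)
    if report.n_rows == 0:
        raise ConfigurationError(f"input file has a header but no data rows: {path}")
    return records, report


def write_ghs_table(records: Sequence[GhsRecord], path: str | Path) -> None:
    """Write aggregated records as CSV (cas, name, 10 endpoint columns)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cas", "name", *VARIABLES])
        for rec in records:
            writer.writerow(
                [rec.cas, rec.name, *(rec.endpoints[v].name for v in VARIABLES)]
            )


def write_raw_ghs_table(
    records: Sequence[GhsRecord], path: str | Path
) -> None:
    """Write records in the 12-column raw dialect.

    The merged inhalation value is placed on the gas route with Not Applicable
    on the other two, which round-trips through the conservative merge.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cas", "name", *RAW_VARIABLES])
        for rec in records:
            row = [rec.cas, rec.name]
            for var in RAW_VARIABLES:
                if var == "acute_inhalation_gas":
                    row.append(rec.endpoints["acute_inhalation"].name)
                elif var in INHALATION_ROUTES:
                    row.append(HazardCategory.NOT_APPLICABLE.name)
                else:
                    row.append(rec.endpoints[var].name)
            writer.writerow(row)


def write_score_csv(scores: Sequence[ScoreVector], path: str | Path) -> None:
    """Write score vectors as CSV: cas, ten score columns, total."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cas", *VARIABLES, "total"])
        for sv in scores:
            writer.writerow([sv.cas, *(repr(v) for v in sv.values), repr(sv.total)])


def read_score_csv(path: str | Path) -> list[ScoreVector]:
    path = Path(path)
    out: list[ScoreVector] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(VARIABLES) <= set(reader.fieldnames):
            raise ConfigurationError(f"not a score CSV: {path}")
        for row in reader:
            values = tuple(float(row[v]) for v in VARIABLES)
            out.append(ScoreVector(row["cas"], values, float(row["total"])))
    return out


def records_to_json(records: Sequence[GhsRecord]) -> str:
    """Serialize records to a JSON array (category names as strings)."""
    payload = [
        {
            "cas": r.cas,
            "name": r.name,
            "endpoints": {v: r.endpoints[v].name for v in VARIABLES},
        }
        for r in records
    ]
    return json.dumps(payload, indent=2)


def records_from_json(text: str) -> list[GhsRecord]:
    payload = json.loads(text)
    return [
        GhsRecord(
            d["cas"],
            d["name"],
            {v: HazardCategory[d["endpoints"][v]] for v in VARIABLES},
        )
        for d in payload
    ]
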