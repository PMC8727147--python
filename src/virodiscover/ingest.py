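"""Reading, validating, filtering and deduplicating host–virus association records.

The canonical unit of analysis downstream is the unique (host species, virus)
pair together with its discovery year — the earliest calendar year the virus
was reported in that host. This module turns raw association tables
(VIRION-like CSVs, one row per report) into that pair table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HostStatus",
    "Resolution",
    "Detection",
    "AssociationRecord",
    "FilterConfig",
    "ReadResult",
    "RejectedRow",
    "read_associations",
    "apply_filters",
    "dedupe_to_pairs",
    "DEFAULT_SCHEMA",
    "PAIR_COLUMNS",
]


class HostStatus(str, Enum):
    WILD = "wild"
    DOMESTIC = "domestic"
    LABORATORY = "laboratory"


class Resolution(str, Enum):
    """Taxonomic resolution of the virus name.

    ICTV-ratified and PREDICT-resolved names count as taxonomically
    resolved; everything else is treated as an unresolved strain name.
    """

    ICTV = "ictv"
    PREDICT = "predict"
    UNRESOLVED = "unresolved"


class Detection(str, Enum):
    SEROLOGY = "serology"
    PCR = "pcr"
    ISOLATION = "isolation"


# Reporting convenience only: serology < pcr < isolation. No analysis ranks on
# this; the strict detection filter is a set membership test.
DETECTION_RANK = {Detection.SEROLOGY: 0, Detection.PCR: 1, Detection.ISOLATION: 2}

STRICT_DETECTIONS = frozenset({Detection.PCR, Detection.ISOLATION})

YEAR_MIN_VALID = 1900
YEAR_MAX_VALID = 2100

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    """Trim and collapse internal whitespace, preserving case."""
    return _WS.sub(" ", str(name).strip())


def _key(name: str) -> str:
    """Case-folded matching key for a normalized name."""
    return _norm(name).casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One host–virus report: who, what, when, and how it was detected."""

    host_species: str
    host_family: str
    host_order: str
    host_status: HostStatus
    virus: str
    virus_resolution: Resolution
    detection: Detection
    year: int
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "host_species", _norm(self.host_species))
        object.__setattr__(self, "host_family", _norm(self.host_family))
        object.__setattr__(self, "host_order", _norm(self.host_order))
        object.__setattr__(self, "virus", _norm(self.virus))
        if not self.host_species:
            raise ValueError("host_species must be non-empty")
        if not self.virus:
            raise ValueError("virus must be non-empty")
        if not isinstance(self.year, int) or isinstance(self.year, bool):
            raise ValueError(f"year must be an integer, got {self.year!r}")
        if not (YEAR_MIN_VALID <= self.year <= YEAR_MAX_VALID):
            raise ValueError(
                f"year {self.year} outside plausible range "
                f"[{YEAR_MIN_VALID}, {YEAR_MAX_VALID}]"
            )
        object.__setattr__(self, "host_status", HostStatus(self.host_status))
        object.__setattr__(self, "virus_resolution", Resolution(self.virus_resolution))
        object.__setattr__(self, "detection", Detection(self.detection))


@dataclass(frozen=True)
class FilterConfig:
    """Predicates applied to association records before pair construction.

    ``year_min`` does NOT drop records: reports earlier than the analysis
    window still define a pair's discovery year (an early first report must
    not resurface as a post-window "discovery"); series construction clips
    to [year_min, year_max] downstream. Only ``year_max`` filters records.
    """

    require_resolved: bool = True
    allowed_resolution: frozenset = frozenset({Resolution.ICTV, Resolution.PREDICT})
    wild_only: bool = True
    detection_rule: str = "any_evidence"  # or "pcr_or_isolation_only"
    year_min: int = 1930
    year_max: int = 2018

    def __post_init__(self) -> None:
        if self.year_min > self.year_max:
            raise ValueError(f"year_min {self.year_min} > year_max {self.year_max}")
        if self.detection_rule not in ("any_evidence", "pcr_or_isolation_only"):
            raise ValueError(f"unknown detection_rule {self.detection_rule!r}")
        object.__setattr__(
            self, "allowed_resolution", frozenset(Resolution(r) for r in self.allowed_resolution)
        )

    @classmethod
    def permissive(cls) -> "FilterConfig":
        """A configuration with every predicate disabled (identity filter)."""
        return cls(
            require_resolved=False,
            wild_only=False,
            detection_rule="any_evidence",
            year_min=YEAR_MIN_VALID,
            year_max=YEAR_MAX_VALID,
        )


# field name -> default CSV column name; users rebind via a schema map
DEFAULT_SCHEMA: Mapping[str, str] = {
    "host_species": "host_species",
    "host_family": "host_family",
    "host_order": "host_order",
    "host_status": "host_status",
    "virus": "virus",
    "virus_resolution": "virus_resolution",
    "detection": "detection",
    "year": "year",
    "source": "source",
}

_MANDATORY_FIELDS = [f for f in DEFAULT_SCHEMA if f != "source"]


@dataclass(frozen=True)
class RejectedRow:
    index: int
    reason: str


@dataclass
class ReadResult:
    """Accepted records plus per-row rejection reasons.

    Row conservation holds by construction:
    ``len(result.records) + len(result.rejected)`` equals the number of data
    rows in the input file.
    """

    records: list
    rejected: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_associations(path, schema: Mapping[str, str] | None = None) -> ReadResult:
    """Read an association CSV into validated :class:`AssociationRecord` s.

    Parameters
    ----------
    path
        CSV file: UTF-8, comma-separated, header row required.
    schema
        Map from record field names to the file's column names, to bind
        databases whose headers differ (e.g. VIRION exports). Missing keys
        fall back to :data:`DEFAULT_SCHEMA`.

    Raises
    ------
    ValueError
        If a mandatory column is absent from the file.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [colmap[f] for f in _MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path}: {missing}")

    has_source = colmap["source"] in df.columns
    records: list[AssociationRecord] = []
    rejected: list[RejectedRow] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            year = int(str(rowd[colmap["year"]]).strip())
        except ValueError:
            reason = f"unparseable year {rowd[colmap['year']]!r}"
            logger.warning("row %d rejected: %s", idx, reason)
            rejected.append(RejectedRow(idx, reason))
            continue
        try:
            rec = AssociationRecord(
                host_species=rowd[colmap["host_species"]],
                host_family=rowd[colmap["host_family"]],
                host_order=rowd[colmap["host_order"]],
                host_status=rowd[colmap["host_status"]].strip().lower(),
                virus=rowd[colmap["virus"]],
                virus_resolution=rowd[colmap["virus_resolution"]].strip().lower(),
                detection=rowd[colmap["detection"]].strip().lower(),
                year=year,
                source=rowd[colmap["source"]] if has_source else "",
            )
        except ValueError as exc:
            logger.warning("row %d rejected: %s", idx, exc)
            rejected.append(RejectedRow(idx, str(exc)))
            continue
        records.append(rec)
    return ReadResult(records=records, rejected=rejected)


def apply_filters(
    records: Iterable[AssociationRecord], cfg: FilterConfig
) -> list:
    """Return the subset of ``records`` satisfying every enabled predicate.

    Pure and order-preserving; an empty result is legal.
    """
    out = []
    for r in records:
        if cfg.require_resolved and r.virus_resolution not in cfg.allowed_resolution:
            continue
        if cfg.wild_only and r.host_status is not HostStatus.WILD:
            continue
        if cfg.detection_rule == "pcr_or_isolation_only" and r.detection not in STRICT_DETECTIONS:
            continue
        if r.year > cfg.year_max:
            continue
        out.append(r)
    return out


PAIR_COLUMNS = [
    "host_species",
    "host_family",
    "host_order",
    "virus",
    "discovery_year",
    "detection_best",
    "strict_year",
]


def dedupe_to_pairs(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Collapse association records to the canonical earliest-discovery pair table.

    One row per unique (host_species, virus) pair, matched case-insensitively
    after whitespace normalization. Per pair:

    - ``discovery_year``: minimum year over all contributing records;
    - ``detection_best``: strongest evidence seen (serology < pcr < isolation),
      a reporting convenience only;
    - ``strict_year``: earliest year among PCR-or-isolation records (pandas
      NA if the pair has serology-only evidence) — the discovery year under
      the stricter evidence definition used by the snapshot regressions.

    Idempotent and invariant to the order of the input records. Name display
    forms and taxonomy keys are resolved deterministically (lexicographic
    minimum over contributing records) so permutations of the input yield an
    identical table.
    """
    agg: dict[tuple[str, str], dict] = {}
    for r in records:
        k = (_key(r.host_species), _key(r.virus))
        strict = r.year if r.detection in STRICT_DETECTIONS else None
        if k not in agg:
            agg[k] = {
                "host_species": r.host_species,
                "host_family": r.host_family,
                "host_order": r.host_order,
                "virus": r.virus,
                "discovery_year": r.year,
                "detection_best": r.detection,
                "strict_year": strict,
            }
        else:
            a = agg[k]
            a["host_species"] = min(a["host_species"], r.host_species)
            a["host_family"] = min(a["host_family"], r.host_family)
            a["host_order"] = min(a["host_order"], r.host_order)
            a["virus"] = min(a["virus"], r.virus)
            a["discovery_year"] = min(a["discovery_year"], r.year)
            if DETECTION_RANK[r.detection] > DETECTION_RANK[a["detection_best"]]:
                a["detection_best"] = r.detection
            if strict is not None:
                a["strict_year"] = strict if a["strict_year"] is None else min(a["strict_year"], strict)

    if not agg:
        df = pd.DataFrame(columns=PAIR_COLUMNS)
    else:
        df = pd.DataFrame(list(agg.values()))
        df["detection_best"] = df["detection_best"].map(lambda d: d.value)
    df["discovery_year"] = df.get("discovery_year", pd.Series(dtype="int64")).astype("int64")
    df["strict_year"] = df.get("strict_year", pd.Series(dtype="Int64")).astype("Int64")
    df = df.sort_values(["host_species", "virus"], kind="mergesort").reset_index(drop=True)
    return df[PAIR_COLUMNS]


def pairs_from_records(records, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Convenience: filter then dedupe in one call (default filters if cfg None)."""
    cfg = cfg or FilterConfig()
    return dedupe_to_pairs(apply_filters(records, cfg))
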