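"""Ingestion, normalization, and deduplication of spontaneous safety reports.

A spontaneous report names one or more suspect products, the adverse drug
events (ADEs) observed, and bookkeeping fields (case identifier, report
origin, demographics, submission date, outcomes, indications).  Cohorts are
built by matching a normalized drug term against either the suspect product
names or the suspect active ingredients, mirroring how public
adverse-event-dashboard exports are filtered.

Term handling is deliberately exact-match: terms are case-folded,
whitespace-trimmed, and passed through an explicit synonym map (by default
the brand name "precedex" and the salt form "dexmedetomidine hydrochloride"
both map to "dexmedetomidine").  No fuzzy matching is attempted, so every
normalization is auditable.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Default synonym map: brand name and salt form collapse to the generic term.
DEFAULT_SYNONYMS: dict[str, str] = {
    "dexmedetomidine hydrochloride": "dexmedetomidine",
    "precedex": "dexmedetomidine",
}

#: Report-source values matching any of these substrings mark a report as
#: literature-derived (indirect).  Configurable because dashboards phrase the
#: origin field inconsistently.
DEFAULT_LITERATURE_PATTERNS: tuple[str, ...] = ("literature",)


class SourceKind(str, Enum):
    DIRECT = "direct"
    LITERATURE = "literature"


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


def normalize_term(raw: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Canonicalize a drug or ADE term.

    Case-folds, trims, collapses internal whitespace, then maps through
    ``synonym_map`` (defaults to :data:`DEFAULT_SYNONYMS`).

    Raises
    ------
    ValueError
        If ``raw`` is empty or whitespace-only.
    """
    if synonym_map is None:
        synonym_map = DEFAULT_SYNONYMS
    term = " ".join(raw.split()).casefold()
    if not term:
        raise ValueError("cannot normalize an empty term")
    return synonym_map.get(term, term)


def _normalize_list(values: Iterable[str], synonym_map: Mapping[str, str] | None) -> list[str]:
    """Normalize each term, dropping empties and duplicates, order-preserving."""
    seen: set[str] = set()
    out: list[str] = []
    for v in values:
        v = v.strip()
        if not v:
            continue
        term = normalize_term(v, synonym_map)
        if term not in seen:
            seen.add(term)
            out.append(term)
    return out


@dataclass
class SafetyReport:
    """One spontaneous adverse-event report with normalized term lists."""

    case_id: str
    source_kind: SourceKind = SourceKind.DIRECT
    suspect_products: list[str] = field(default_factory=list)
    suspect_active_ingredients: list[str] = field(default_factory=list)
    adverse_events: list[str] = field(default_factory=list)
    sex: Sex | None = None
    age_years: float | None = None
    received_date: _dt.date | None = None
    outcomes: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.adverse_events:
            raise ValueError(f"report {self.case_id!r} has no adverse events")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        for name in ("suspect_products", "suspect_active_ingredients", "adverse_events"):
            vals = getattr(self, name)
            if len(vals) != len(set(vals)):
                raise ValueError(f"duplicate normalized terms in {name} of {self.case_id!r}")

    @property
    def all_suspect_drugs(self) -> set[str]:
        """Union of suspect product names and suspect active ingredients."""
        return set(self.suspect_products) | set(self.suspect_active_ingredients)


@dataclass
class ReportSet:
    """An ordered, immutable-by-convention collection of reports."""

    reports: tuple[SafetyReport, ...]
    provenance: str = ""

    def __init__(self, reports: Iterable[SafetyReport], provenance: str = "") -> None:
        object.__setattr__(self, "reports", tuple(reports))
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[SafetyReport]:
        return iter(self.reports)

    def __getitem__(self, i: int) -> SafetyReport:
        return self.reports[i]


@dataclass(frozen=True)
class LoadLog:
    """Row accounting produced by :func:`load_reports`."""

    n_loaded: int
    n_dropped_empty_case_id: int
    n_dropped_empty_reactions: int

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_empty_case_id + self.n_dropped_empty_reactions

    def __str__(self) -> str:  # "1 dropped" style audit line
        return f"{self.n_loaded} loaded, {self.n_dropped} dropped"


@dataclass(frozen=True)
class Dialect:
    """Column-name map for one delimited export layout."""

    name: str
    delimiter: str
    columns: Mapping[str, str]  # logical field -> header name
    list_separator: str = ";"


DIALECTS: dict[str, Dialect] = {
    "faers_dashboard": Dialect(
        name="faers_dashboard",
        delimiter=",",
        columns={
            "case_id": "Case ID",
            "suspect_products": "Suspect Product Names",
            "suspect_active_ingredients": "Suspect Product Active Ingredients",
            "adverse_events": "Reactions",
            "source_kind": "Report Source",
            "sex": "Sex",
            "age_years": "Patient Age",
            "received_date": "Initial FDA Received Date",
            "outcomes": "Outcomes",
            "indications": "Reason for Use",
        },
    ),
    "faers_dashboard_tsv": Dialect(
        name="faers_dashboard_tsv",
        delimiter="\t",
        columns={
            "case_id": "Case ID",
            "suspect_products": "Suspect Product Names",
            "suspect_active_ingredients": "Suspect Product Active Ingredients",
            "adverse_events": "Reactions",
            "source_kind": "Report Source",
            "sex": "Sex",
            "age_years": "Patient Age",
            "received_date": "Initial FDA Received Date",
            "outcomes": "Outcomes",
            "indications": "Reason for Use",
        },
    ),
}


def _parse_source(value: str, literature_patterns: Sequence[str]) -> SourceKind:
    v = value.casefold()
    if any(p in v for p in literature_patterns):
        return SourceKind.LITERATURE
    return SourceKind.DIRECT


def _parse_sex(value: str) -> Sex | None:
    v = value.strip().upper()
    if not v:
        return None
    if v in ("F", "FEMALE"):
        return Sex.F
    if v in ("M", "MALE"):
        return Sex.M
    return Sex.UNKNOWN


def _parse_date(value: str) -> _dt.date | None:
    v = value.strip()
    if not v:
        return None
    for fmt in ("%Y-%m-%d", "%Y%m%d", "%m/%d/%Y"):
        try:
            return _dt.datetime.strptime(v, fmt).date()
        except ValueError:
            continue
    logger.warning("unparseable date %r kept as missing", value)
    return None


def load_reports(
    path: str | Path,
    dialect: str = "faers_dashboard",
    synonym_map: Mapping[str, str] | None = None,
    literature_patterns: Sequence[str] = DEFAULT_LITERATURE_PATTERNS,
) -> tuple[ReportSet, LoadLog]:
    """Read a delimited dashboard-style export into a :class:`ReportSet`.

    Rows with an empty case ID or an empty reaction field are dropped and
    counted in the returned :class:`LoadLog`; they are never silently lost.

    Raises
    ------
    ConfigurationError
        Unknown dialect, missing required columns, or duplicated headers.
    OSError
        Unreadable file.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    d = DIALECTS[dialect]

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=d.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigurationError(f"{path}: empty file, no header row") from None
        if len(header) != len(set(header)):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ConfigurationError(f"{path}: duplicated column headers {dupes}")
        col_idx = {h: i for i, h in enumerate(header)}
        for logical in ("case_id", "adverse_events"):
            if d.columns[logical] not in col_idx:
                raise ConfigurationError(
                    f"{path}: required column {d.columns[logical]!r} missing"
                )

        def cell(row: list[str], logical: str) -> str:
            name = d.columns.get(logical)
            if name is None or name not in col_idx:
                return ""
            i = col_idx[name]
            return row[i] if i < len(row) else ""

        reports: list[SafetyReport] = []
        n_no_case = n_no_reaction = 0
        for lineno, row in enumerate(reader, start=2):
            if not any(f.strip() for f in row):
                continue
            case_id = cell(row, "case_id").strip()
            if not case_id:
                n_no_case += 1
                logger.info("%s:%d dropped: empty case ID", path, lineno)
                continue
            ades = _normalize_list(
                cell(row, "adverse_events").split(d.list_separator), synonym_map
            )
            if not ades:
                n_no_reaction += 1
                logger.info("%s:%d dropped: empty reaction field", path, lineno)
                continue
            age_raw = cell(row, "age_years").strip()
            try:
                age = float(age_raw) if age_raw else None
            except ValueError:
                logger.warning("%s:%d unparseable age %r kept as missing", path, lineno, age_raw)
                age = None
            reports.append(
                SafetyReport(
                    case_id=case_id,
                    source_kind=_parse_source(cell(row, "source_kind"), literature_patterns),
                    suspect_products=_normalize_list(
                        cell(row, "suspect_products").split(d.list_separator), synonym_map
                    ),
                    suspect_active_ingredients=_normalize_list(
                        cell(row, "suspect_active_ingredients").split(d.list_separator),
                        synonym_map,
                    ),
                    adverse_events=ades,
                    sex=_parse_sex(cell(row, "sex")),
                    age_years=age,
                    received_date=_parse_date(cell(row, "received_date")),
                    outcomes=_normalize_list(
                        cell(row, "outcomes").split(d.list_separator), synonym_map
                    ),
                    indications=_normalize_list(
                        cell(row, "indications").split(d.list_separator), synonym_map
                    ),
                )
            )

    log = LoadLog(
        n_loaded=len(reports),
        n_dropped_empty_case_id=n_no_case,
        n_dropped_empty_reactions=n_no_reaction,
    )
    return ReportSet(reports, provenance=f"{path} ({dialect})"), log


def filter_drug_cohort(
    rs: ReportSet, drug: str, synonym_map: Mapping[str, str] | None = None
) -> ReportSet:
    """Keep reports naming ``drug`` among suspect products OR active ingredients.

    ``drug`` must already be a normalized term; report terms are normalized
    through ``synonym_map`` when matching (a no-op on already-normalized
    lists), so a report listing only the brand name still qualifies.  A drug
    appearing only in the indications field does not.  An empty result is
    permitted.
    """
    kept = [
        r for r in rs
        if drug in {normalize_term(t, synonym_map) for t in r.all_suspect_drugs}
    ]
    if not kept:
        logger.warning("cohort filter for %r matched no reports", drug)
    return ReportSet(kept, provenance=f"{rs.provenance} | cohort:{drug}")


def deduplicate(rs: ReportSet) -> tuple[ReportSet, dict[str, int]]:
    """Remove literature-derived reports, then collapse duplicate case IDs.

    Literature (indirect) reports — those extracted from publications rather
    than submitted directly — are removed wholesale: the same patient-event
    pair can be re-reported many times under fresh case IDs, inflating counts.
    Among the remaining direct reports sharing a case ID the most recently
    received one wins; ties (including all-missing dates) keep the first in
    input order.

    Returns the filtered set and removal counts by reason.  Idempotent.
    """
    direct = [r for r in rs if r.source_kind is not SourceKind.LITERATURE]
    n_literature = len(rs) - len(direct)

    best: dict[str, tuple[int, SafetyReport]] = {}
    order: list[str] = []
    for pos, r in enumerate(direct):
        if r.case_id not in best:
            best[r.case_id] = (pos, r)
            order.append(r.case_id)
        else:
            _, incumbent = best[r.case_id]
            # strictly later date replaces; missing date never beats a date
            new_d, old_d = r.received_date, incumbent.received_date
            if new_d is not None and (old_d is None or new_d > old_d):
                best[r.case_id] = (best[r.case_id][0], r)
    kept = [best[cid][1] for cid in order]
    n_dupes = len(direct) - len(kept)
    removed = {"literature": n_literature, "duplicate_case_id": n_dupes}
    return ReportSet(kept, provenance=f"{rs.provenance} | deduplicated"), removed


# ---------------------------------------------------------------------------
# Serialization

def _report_to_dict(r: SafetyReport) -> dict:
    return {
        "case_id": r.case_id,
        "source_kind": r.source_kind.value,
        "suspect_products": r.suspect_products,
        "suspect_active_ingredients": r.suspect_active_ingredients,
        "adverse_events": r.adverse_events,
        "sex": r.sex.value if r.sex else None,
        "age_years": r.age_years,
        "received_date": r.received_date.isoformat() if r.received_date else None,
        "outcomes": r.outcomes,
        "indications": r.indications,
    }


def _report_from_dict(d: dict) -> SafetyReport:
    return SafetyReport(
        case_id=d["case_id"],
        source_kind=SourceKind(d.get("source_kind", "direct")),
        suspect_products=list(d.get("suspect_products", [])),
        suspect_active_ingredients=list(d.get("suspect_active_ingredients", [])),
        adverse_events=list(d["adverse_events"]),
        sex=Sex(d["sex"]) if d.get("sex") else None,
        age_years=d.get("age_years"),
        received_date=_dt.date.fromisoformat(d["received_date"]) if d.get("received_date") else None,
        outcomes=list(d.get("outcomes", [])),
        indications=list(d.get("indications", [])),
    )


def write_jsonl(rs: ReportSet, path: str | Path) -> None:
    """Serialize a normalized ReportSet as JSON-lines."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in rs:
            fh.write(json.dumps(_report_to_dict(r), sort_keys=True) + "\n")


def read_jsonl(path: str | Path, provenance: str | None = None) -> ReportSet:
    with Path(path).open(encoding="utf-8") as fh:
        reports = [_report_from_dict(json.loads(line)) for line in fh if line.strip()]
    return ReportSet(reports, provenance=provenance or str(path))
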