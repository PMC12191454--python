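"""Synthetic report cohorts and gene universes with known statistical structure.

Two cohort modes:

* **exact-marginal** — every configured item pair realizes its 2x2 table
  against the consequent event *exactly* (joint, consequent-only,
  antecedent-only, remainder), so downstream support/confidence/lift and
  odds-ratio values are deterministic functions of the configured counts.
  Different pairs are packed independently into report slots: because each
  pair involves a distinct item, overlap between pairs cannot perturb any
  pair's own table.  Consequent-bearing slots are allocated first.
* **stochastic** — items are drawn independently at their marginal
  probabilities, except configured pairs, which are drawn from the 2x2
  joint their counts imply (conditionally on the consequent), so empirical
  lift converges to the configured target as the cohort grows.

Unspecified labels come from a fixed synthetic vocabulary ("ade_001", ...,
"drug_001", ...); real event or drug terms appear only where a spec names
them.  All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np

from .enrichment import GeneSet
from .errors import UnsatisfiableSpecError
from .reports import DIALECTS, ReportSet, SafetyReport, SourceKind
from .transactions import ItemKind

_BASE_DATE = _dt.date(2024, 1, 1)


@dataclass(frozen=True)
class PairSpec:
    """One antecedent item with its exact 2x2 against the consequent."""

    label: str
    kind: ItemKind
    antecedent_count: int
    joint_count: int


@dataclass(frozen=True)
class BackgroundItemSpec:
    """An item included independently per report at a marginal probability."""

    label: str
    kind: ItemKind
    probability: float


@dataclass(frozen=True)
class ItemSpec:
    """An item with an exact marginal count but no pair constraint."""

    label: str
    kind: ItemKind
    count: int


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic report cohort."""

    n_reports: int
    consequent_label: str = "bradycardia"
    consequent_count: int = 0
    pair_specs: tuple[PairSpec, ...] = ()
    item_specs: tuple[ItemSpec, ...] = ()
    background_items: tuple[BackgroundItemSpec, ...] = ()
    literature_extra: int = 0
    cohort_drug: str = "dexmedetomidine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if not 0 <= self.consequent_count <= self.n_reports:
            raise ValueError("consequent_count must lie in [0, n_reports]")
        for p in self.pair_specs:
            if p.joint_count > min(p.antecedent_count, self.consequent_count):
                raise ValueError(
                    f"pair {p.label!r}: joint_count {p.joint_count} exceeds "
                    f"min(antecedent, consequent)"
                )
            if p.antecedent_count > self.n_reports:
                raise ValueError(f"pair {p.label!r}: antecedent_count exceeds n_reports")

    # -- JSON round-trip ----------------------------------------------------
    @staticmethod
    def from_json(path: str | Path) -> "CohortSpec":
        with Path(path).open(encoding="utf-8") as fh:
            d = json.load(fh)
        return CohortSpec.from_dict(d)

    @staticmethod
    def from_dict(d: dict) -> "CohortSpec":
        return CohortSpec(
            n_reports=d["n_reports"],
            consequent_label=d.get("consequent_label", "bradycardia"),
            consequent_count=d.get("consequent_count", 0),
            pair_specs=tuple(PairSpec(**p) for p in d.get("pair_specs", [])),
            item_specs=tuple(ItemSpec(**p) for p in d.get("item_specs", [])),
            background_items=tuple(
                BackgroundItemSpec(**p) for p in d.get("background_items", [])
            ),
            literature_extra=d.get("literature_extra", 0),
            cohort_drug=d.get("cohort_drug", "dexmedetomidine"),
            seed=d.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass(frozen=True)
class EnrichmentSpec:
    """Parameters of a synthetic gene universe with exact pathway overlaps."""

    background_size: int
    list_size: int
    pathway_specs: tuple[tuple[str, int, int], ...]  # (name, size, overlap)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.list_size <= self.background_size:
            raise ValueError("need 0 < list_size <= background_size")
        for name, size, overlap in self.pathway_specs:
            if not 0 < size <= self.background_size:
                raise ValueError(f"pathway {name!r}: size outside (0, background]")
            if overlap > min(size, self.list_size):
                raise UnsatisfiableSpecError(
                    f"pathway {name!r}: overlap {overlap} exceeds min(size, list_size)"
                )
            if size - overlap > self.background_size - self.list_size:
                raise UnsatisfiableSpecError(
                    f"pathway {name!r}: {size - overlap} non-list genes needed but "
                    f"only {self.background_size - self.list_size} exist"
                )


def _check_exact_satisfiable(spec: CohortSpec) -> None:
    n_non_consequent = spec.n_reports - spec.consequent_count
    for p in spec.pair_specs:
        if p.antecedent_count - p.joint_count > n_non_consequent:
            raise UnsatisfiableSpecError(
                f"pair {p.label!r}: needs {p.antecedent_count - p.joint_count} "
                f"antecedent-only slots but only {n_non_consequent} reports "
                f"lack the consequent"
            )
        if p.joint_count > spec.consequent_count:
            raise UnsatisfiableSpecError(
                f"pair {p.label!r}: joint_count exceeds consequent_count"
            )
    for it in spec.item_specs:
        if it.count > spec.n_reports:
            raise UnsatisfiableSpecError(f"item {it.label!r}: count exceeds n_reports")


def _assemble_reports(
    spec: CohortSpec,
    ade_slots: dict[str, np.ndarray],
    drug_slots: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> ReportSet:
    n = spec.n_reports
    ades: list[list[str]] = [[] for _ in range(n)]
    drugs: list[list[str]] = [[] for _ in range(n)]
    for label, slots in ade_slots.items():
        for s in slots:
            ades[s].append(label)
    for label, slots in drug_slots.items():
        for s in slots:
            drugs[s].append(label)

    reports = []
    for i in range(n):
        report_ades = sorted(set(ades[i])) or ["ade_filler"]
        reports.append(
            SafetyReport(
                case_id=f"CASE-{i + 1:07d}",
                source_kind=SourceKind.DIRECT,
                suspect_products=[spec.cohort_drug],
                suspect_active_ingredients=sorted(set(drugs[i])),
                adverse_events=report_ades,
                received_date=_BASE_DATE,
            )
        )
    # duplicate literature-sourced copies of existing cases, for dedup testing
    if spec.literature_extra:
        src = rng.integers(0, n, size=spec.literature_extra)
        for j, i in enumerate(src):
            base = reports[int(i)]
            reports.append(
                SafetyReport(
                    case_id=base.case_id,
                    source_kind=SourceKind.LITERATURE,
                    suspect_products=list(base.suspect_products),
                    suspect_active_ingredients=list(base.suspect_active_ingredients),
                    adverse_events=list(base.adverse_events),
                    received_date=_BASE_DATE,
                )
            )
    return ReportSet(reports, provenance=f"synthetic exact cohort (seed={spec.seed})")


def generate_exact(spec: CohortSpec) -> ReportSet:
    """Deterministically realize every configured 2x2 cell count.

    The consequent occupies ``consequent_count`` randomly chosen report
    slots.  For each pair, ``joint_count`` slots are drawn from the
    consequent slots and ``antecedent_count - joint_count`` from the rest,
    so the realized table against the consequent is exactly
    (joint, consequent-joint, antecedent-joint, remainder) regardless of
    how pairs overlap each other.
    """
    _check_exact_satisfiable(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reports
    perm = rng.permutation(n)
    cons_slots = perm[: spec.consequent_count]
    other_slots = perm[spec.consequent_count:]

    ade_slots: dict[str, np.ndarray] = {spec.consequent_label: cons_slots}
    drug_slots: dict[str, np.ndarray] = {}
    sink = {"ade": ade_slots, "drug": drug_slots}
    for p in spec.pair_specs:
        joint = rng.choice(cons_slots, size=p.joint_count, replace=False)
        only = rng.choice(
            other_slots, size=p.antecedent_count - p.joint_count, replace=False
        )
        sink[p.kind][p.label] = np.concatenate([joint, only]).astype(int)
    for it in spec.item_specs:
        sink[it.kind][it.label] = rng.choice(n, size=it.count, replace=False)
    for b in spec.background_items:
        mask = rng.random(n) < b.probability
        sink[b.kind][b.label] = np.flatnonzero(mask)
    return _assemble_reports(spec, ade_slots, drug_slots, rng)


def generate_stochastic(spec: CohortSpec) -> ReportSet:
    """Sample a cohort whose pair statistics converge to the configured 2x2.

    The consequent is Bernoulli(consequent_count / n_reports) per report;
    each pair's antecedent is then drawn conditionally (joint/consequent
    given the consequent, (antecedent-joint)/(n-consequent) otherwise), so
    the configured lift is the large-sample limit of the mined lift.
    Background items are independent Bernoulli draws.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reports
    p_cons = spec.consequent_count / n
    has_cons = rng.random(n) < p_cons
    cons_slots = np.flatnonzero(has_cons)
    other_slots = np.flatnonzero(~has_cons)

    ade_slots: dict[str, np.ndarray] = {spec.consequent_label: cons_slots}
    drug_slots: dict[str, np.ndarray] = {}
    sink = {"ade": ade_slots, "drug": drug_slots}
    n_other = n - spec.consequent_count
    for p in spec.pair_specs:
        p_given = p.joint_count / spec.consequent_count if spec.consequent_count else 0.0
        p_not = (p.antecedent_count - p.joint_count) / n_other if n_other else 0.0
        take_c = cons_slots[rng.random(cons_slots.size) < p_given]
        take_o = other_slots[rng.random(other_slots.size) < p_not]
        sink[p.kind][p.label] = np.concatenate([take_c, take_o])
    for it in spec.item_specs:
        mask = rng.random(n) < it.count / n
        sink[it.kind][it.label] = np.flatnonzero(mask)
    for b in spec.background_items:
        mask = rng.random(n) < b.probability
        sink[b.kind][b.label] = np.flatnonzero(mask)
    rs = _assemble_reports(spec, ade_slots, drug_slots, rng)
    return ReportSet(rs.reports, provenance=f"synthetic stochastic cohort (seed={spec.seed})")


def generate_gene_universe(
    spec: EnrichmentSpec,
) -> tuple[list[str], list[GeneSet], list[str]]:
    """Build (gene list, gene-set collection, background) with exact overlaps.

    Symbols are synthetic ("gene000001", ...).  The query list is a fixed
    prefix of the background; each pathway draws its overlap from the list
    and the rest from outside it, so ``enrich`` recovers every configured
    (overlap, size) pair exactly.
    """
    rng = np.random.default_rng(spec.seed)
    background = [f"gene{i + 1:06d}" for i in range(spec.background_size)]
    gene_list = background[: spec.list_size]
    rest = background[spec.list_size:]
    collection = []
    for name, size, overlap in spec.pathway_specs:
        inside = rng.choice(spec.list_size, size=overlap, replace=False)
        outside = rng.choice(len(rest), size=size - overlap, replace=False)
        genes = [gene_list[i] for i in inside] + [rest[i] for i in outside]
        collection.append(GeneSet.from_symbols(name, genes))
    return gene_list, collection, background


# ---------------------------------------------------------------------------
# Dashboard-style export writer (inverse of reports.load_reports)

def write_export(rs: ReportSet, path: str | Path, dialect: str = "faers_dashboard") -> None:
    """Write a ReportSet as a delimited dashboard-style export.

    ``load_reports(write_export(rs))`` reproduces the reports exactly
    (terms are already normalized, so re-normalization is the identity).
    """
    import csv

    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    d = DIALECTS[dialect]
    logical_order = list(d.columns)
    sep = d.list_separator
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=d.delimiter)
        writer.writerow([d.columns[l] for l in logical_order])
        for r in rs:
            row = {
                "case_id": r.case_id,
                "suspect_products": sep.join(r.suspect_products),
                "suspect_active_ingredients": sep.join(r.suspect_active_ingredients),
                "adverse_events": sep.join(r.adverse_events),
                "source_kind": r.source_kind.value,
                "sex": r.sex.value if r.sex else "",
                "age_years": "" if r.age_years is None else repr(r.age_years),
                "received_date": r.received_date.isoformat() if r.received_date else "",
                "outcomes": sep.join(r.outcomes),
                "indications": sep.join(r.indications),
            }
            writer.writerow([row[l] for l in logical_order])


def bundled_spec_path(name: str = "table4_table6") -> Path:
    """Path to a spec shipped with the package (JSON under pvsignal/data)."""
    return Path(__file__).parent / "data" / f"{name}.json"


def load_bundled_spec(name: str = "table4_table6") -> CohortSpec:
    return CohortSpec.from_json(bundled_spec_path(name))
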