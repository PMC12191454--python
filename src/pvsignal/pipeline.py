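"""End-to-end orchestration: reports -> rules -> validation -> tables.

The :class:`CohortSignalModel` is the library-level entry point: built from
a deduplicated report set, its :meth:`~CohortSignalModel.fit` mines
co-presenting-event and co-drug rules against the index event and validates
each by exact 2x2 odds-ratio analysis.  :func:`run_pipeline` wraps it with
file I/O, an audit trail, and a JSON manifest for command-line use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .disproportionality import (
    OrResult,
    validate_rules,
    validation_summary,
)
from .enrichment import EnrichmentAnalysis, EnrichmentResults, read_gmt
from .errors import ConfigurationError, PvSignalError
from .reports import ReportSet, deduplicate, filter_drug_cohort, load_reports
from .rules import AssociationRule, AssociationRuleMiner, RuleFilter, RuleMiningResults
from .simulate import CohortSpec, generate_exact
from .transactions import Item, TransactionDB, build_transactions, top_items

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, terms, and I/O settings for one pipeline run."""

    cohort_drug: str = "dexmedetomidine"
    consequent_ade: str = "bradycardia"
    min_lift: float = 1.5
    min_count: int = 10
    alpha: float = 0.05
    fdr_cutoff: float = 0.05
    top_k: int = 10
    max_antecedent_size: int = 1
    # exactly one of reports_path / simulate_spec feeds the run
    reports_path: str | None = None
    dialect: str = "faers_dashboard"
    simulate_spec: str | None = None
    seed: int | None = None  # overrides the spec's seed when simulating
    # optional enrichment stage
    gene_list_path: str | None = None
    gmt_path: str | None = None
    background_path: str | None = None
    out_dir: str = "pvsignal_out"

    def __post_init__(self) -> None:
        if self.min_lift < 0 or self.min_count < 0:
            raise ConfigurationError("thresholds must be non-negative")
        for name in ("alpha", "fdr_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")

    @staticmethod
    def from_file(path: str | Path, **overrides) -> "PipelineConfig":
        """Read TOML or JSON config; keyword overrides win."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with path.open("rb") as fh:
                data = tomllib.load(fh)
        else:
            with path.open(encoding="utf-8") as fh:
                data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**data)


class CohortSignalModel:
    """Signal-detection model for one drug cohort and one index event.

    Parameters
    ----------
    reports
        Deduplicated report set (the model filters to the drug cohort
        itself).
    cohort_drug
        Normalized term defining the cohort; excluded from transactions so
        the implicit cohort condition is never mined as an item.
    consequent_ade
        The index adverse event anchoring every rule.
    """

    def __init__(
        self,
        reports: ReportSet,
        cohort_drug: str = "dexmedetomidine",
        consequent_ade: str = "bradycardia",
    ) -> None:
        self.cohort_drug = cohort_drug
        self.consequent_ade = consequent_ade
        self.cohort = filter_drug_cohort(reports, cohort_drug)
        if len(self.cohort) == 0:
            raise PvSignalError(f"no reports name {cohort_drug!r} as a suspect drug")
        self.db: TransactionDB = build_transactions(
            self.cohort, kinds=("ade", "drug"), exclude=(cohort_drug,)
        )

    def fit(
        self,
        min_lift: float = 1.5,
        min_count: int = 10,
        alpha: float = 0.05,
        max_antecedent_size: int = 1,
    ) -> "CohortSignalResults":
        consequent = frozenset({Item(self.consequent_ade, "ade")})
        rf = RuleFilter(min_lift=min_lift, min_count=min_count, consequent=consequent)
        ade_rules = AssociationRuleMiner(
            self.db, rf, antecedent_kind="ade",
            max_antecedent_size=max_antecedent_size,
        ).fit()
        ddi_rules = AssociationRuleMiner(
            self.db, rf, antecedent_kind="drug",
            max_antecedent_size=max_antecedent_size,
        ).fit()

        def _validatable(res: RuleMiningResults):
            return [r for r in res if len(r.antecedent) == 1]

        ade_validation = validate_rules(self.db, _validatable(ade_rules), alpha=alpha)
        ddi_validation = validate_rules(self.db, _validatable(ddi_rules), alpha=alpha)
        return CohortSignalResults(
            model=self,
            ade_rules=ade_rules,
            ddi_rules=ddi_rules,
            ade_validation=tuple(ade_validation),
            ddi_validation=tuple(ddi_validation),
            alpha=alpha,
        )

    def top_adverse_events(self, k: int = 10) -> pd.DataFrame:
        ranked = top_items(self.db, "ade", k)
        return pd.DataFrame(
            {
                "rank": range(1, len(ranked) + 1),
                "adverse_event": [label for label, _ in ranked],
                "count": [c for _, c in ranked],
            }
        )


@dataclass(frozen=True)
class CohortSignalResults:
    """Mined and validated signal tables for one cohort."""

    model: CohortSignalModel
    ade_rules: RuleMiningResults
    ddi_rules: RuleMiningResults
    ade_validation: tuple[tuple[AssociationRule, OrResult], ...]
    ddi_validation: tuple[tuple[AssociationRule, OrResult], ...]
    alpha: float

    def summary(self) -> str:
        n = self.model.db.n_transactions
        lines = [
            "Cohort signal analysis",
            "======================",
            f"cohort drug:      {self.model.cohort_drug}",
            f"index event:      {self.model.consequent_ade}",
            f"cohort reports:   {n}",
            f"index-event count: {self.ade_rules.consequent_count}",
            "",
            f"Co-presenting-event rules ({len(self.ade_rules)}):",
            self.ade_rules.summary().to_string(index=False),
            "",
            f"Validation ({self._n_sig(self.ade_validation)} significant "
            f"of {len(self.ade_validation)} at alpha={self.alpha}):",
            validation_summary(self.ade_validation).to_string(index=False),
            "",
            f"Co-drug (DDI screening) rules ({len(self.ddi_rules)}):",
            self.ddi_rules.summary().to_string(index=False),
            "",
            f"Validation ({self._n_sig(self.ddi_validation)} significant "
            f"of {len(self.ddi_validation)} at alpha={self.alpha}):",
            validation_summary(self.ddi_validation).to_string(index=False),
        ]
        return "\n".join(lines)

    @staticmethod
    def _n_sig(validated: Sequence[tuple[AssociationRule, OrResult]]) -> int:
        return sum(1 for _, res in validated if res.significant)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PvSignalError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Writes to ``config.out_dir``: dedup_audit.tsv, top_ades.tsv,
    ade_rules.tsv, ade_validation.tsv, ddi_rules.tsv, ddi_validation.tsv,
    optionally enrichment.tsv, and manifest.json.  Any stage failure aborts
    with the stage name and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> None:
        p = out_dir / name
        writer(p)
        written.append(p)

    try:
        with _stage("ingest"):
            if (config.reports_path is None) == (config.simulate_spec is None):
                raise ConfigurationError(
                    "exactly one of reports_path / simulate_spec must be set"
                )
            if config.reports_path is not None:
                rs, load_log = load_reports(config.reports_path, config.dialect)
                load_info = dataclasses.asdict(load_log)
            else:
                spec = CohortSpec.from_json(config.simulate_spec)
                if config.seed is not None:
                    spec = dataclasses.replace(spec, seed=config.seed)
                rs = generate_exact(spec)
                load_info = {"n_generated": len(rs), "seed": spec.seed}

        with _stage("dedup"):
            rs, removed = deduplicate(rs)
            audit = pd.DataFrame(
                [{"reason": k, "n_removed": v} for k, v in removed.items()]
            )
            _write("dedup_audit.tsv", lambda p: audit.to_csv(p, sep="\t", index=False))

        with _stage("model"):
            model = CohortSignalModel(
                rs, cohort_drug=config.cohort_drug, consequent_ade=config.consequent_ade
            )

        with _stage("top_ades"):
            top = model.top_adverse_events(config.top_k)
            _write("top_ades.tsv", lambda p: top.to_csv(p, sep="\t", index=False))

        with _stage("mine_and_validate"):
            results = model.fit(
                min_lift=config.min_lift,
                min_count=config.min_count,
                alpha=config.alpha,
                max_antecedent_size=config.max_antecedent_size,
            )
            _write("ade_rules.tsv", results.ade_rules.to_tsv)
            _write("ddi_rules.tsv", results.ddi_rules.to_tsv)
            _write(
                "ade_validation.tsv",
                lambda p: validation_summary(results.ade_validation).to_csv(
                    p, sep="\t", index=False
                ),
            )
            _write(
                "ddi_validation.tsv",
                lambda p: validation_summary(results.ddi_validation).to_csv(
                    p, sep="\t", index=False
                ),
            )

        enrichment_rows = None
        if config.gene_list_path and config.gmt_path:
            with _stage("enrich"):
                genes = [
                    line.strip()
                    for line in Path(config.gene_list_path).read_text().splitlines()
                    if line.strip()
                ]
                collection = read_gmt(config.gmt_path)
                background = None
                if config.background_path:
                    background = [
                        line.strip()
                        for line in Path(config.background_path).read_text().splitlines()
                        if line.strip()
                    ]
                enr: EnrichmentResults = EnrichmentAnalysis(
                    genes, collection, background
                ).fit(fdr_cutoff=config.fdr_cutoff)
                _write("enrichment.tsv", enr.to_tsv)
                enrichment_rows = len(enr)

        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "load": load_info,
            "dedup_removed": removed,
            "n_cohort_reports": model.db.n_transactions,
            "row_counts": {
                "top_ades": len(top),
                "ade_rules": len(results.ade_rules),
                "ddi_rules": len(results.ddi_rules),
                "ade_validation": len(results.ade_validation),
                "ddi_validation": len(results.ddi_validation),
                **({"enrichment": enrichment_rows} if enrichment_rows is not None else {}),
            },
            "n_significant": {
                "ade": CohortSignalResults._n_sig(results.ade_validation),
                "ddi": CohortSignalResults._n_sig(results.ddi_validation),
            },
        }
        with _stage("manifest"):
            mp = out_dir / "manifest.json"
            mp.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
            written.append(mp)
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
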