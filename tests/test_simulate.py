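"""Synthetic cohort and gene-universe generators."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pvsignal import (
    CohortSpec,
    EnrichmentSpec,
    Item,
    build_transactions,
    deduplicate,
    enrich,
    generate_exact,
    generate_gene_universe,
    generate_stochastic,
    lift,
    table_for_pair,
)
from pvsignal.errors import UnsatisfiableSpecError
from pvsignal.simulate import PairSpec, write_export
from pvsignal.reports import load_reports

BRADY = Item("bradycardia", "ade")


class TestGenerateExact:
    def test_every_configured_cell_recovered_bit_exactly(self, paper_spec, paper_db):
        n = paper_spec.n_reports
        c = paper_spec.consequent_count
        for p in paper_spec.pair_specs:
            t = table_for_pair(paper_db, BRADY, Item(p.label, p.kind))
            expected = (
                p.joint_count,
                c - p.joint_count,
                p.antecedent_count - p.joint_count,
                n - c - (p.antecedent_count - p.joint_count),
            )
            assert (t.n11, t.n12, t.n21, t.n22) == expected, p.label

    def test_printed_lift_from_minimal_spec(self):
        spec = CohortSpec(n_reports=1611, consequent_count=209,
                          pair_specs=(PairSpec("syncope", "ade", 18, 11),), seed=99)
        db = build_transactions(deduplicate(generate_exact(spec))[0])
        assert round(lift(db, [Item("syncope", "ade")], [BRADY]), 3) == 4.711

    def test_integer_independence_gives_unit_lift(self):
        # joint = antecedent * consequent / N exactly: 40 * 20 / 100 = 8
        spec = CohortSpec(n_reports=100, consequent_count=20,
                          pair_specs=(PairSpec("x", "ade", 40, 8),), seed=1)
        db = build_transactions(generate_exact(spec))
        assert lift(db, [Item("x", "ade")], [BRADY]) == 1.0

    def test_unsatisfiable_pair_named_in_error(self):
        spec = CohortSpec(n_reports=50, consequent_count=40,
                          pair_specs=(PairSpec("huge", "ade", 40, 5),), seed=0)
        # 35 antecedent-only slots needed, only 10 reports lack the consequent
        with pytest.raises(UnsatisfiableSpecError, match="huge"):
            generate_exact(spec)

    def test_infeasible_joint_rejected_at_spec_construction(self):
        with pytest.raises(ValueError):
            CohortSpec(n_reports=100, consequent_count=5,
                       pair_specs=(PairSpec("x", "ade", 10, 7),))

    def test_same_seed_reproduces_identical_reports(self, paper_spec):
        a = generate_exact(paper_spec)
        b = generate_exact(paper_spec)
        assert a.reports == b.reports

    def test_different_seeds_differ(self, paper_spec):
        other = dataclasses.replace(paper_spec, seed=paper_spec.seed + 1)
        assert generate_exact(paper_spec).reports != generate_exact(other).reports

    def test_literature_extras_share_case_ids(self, paper_spec):
        rs = generate_exact(paper_spec)
        direct_ids = {r.case_id for r in rs if r.source_kind.value == "direct"}
        lit_ids = {r.case_id for r in rs if r.source_kind.value == "literature"}
        assert lit_ids <= direct_ids


class TestGenerateStochastic:
    def test_determinism(self):
        spec = CohortSpec(n_reports=500, consequent_count=60,
                          pair_specs=(PairSpec("x", "ade", 50, 20),), seed=4)
        assert generate_stochastic(spec).reports == generate_stochastic(spec).reports

    def test_null_pair_lift_near_one(self):
        # joint at independence: mean mined lift ~ 1 across replicates
        lifts = []
        for seed in range(60):
            spec = CohortSpec(n_reports=500, consequent_count=100,
                              pair_specs=(PairSpec("x", "ade", 100, 20),), seed=seed)
            db = build_transactions(generate_stochastic(spec))
            try:
                lifts.append(lift(db, [Item("x", "ade")], [BRADY]))
            except Exception:
                continue
        assert np.mean(lifts) == pytest.approx(1.0, abs=0.05)

    def test_target_lift_recovered_at_scale(self):
        # target lift 3: consequent 500/5000, antecedent 250, joint 75
        # lift = 75*5000/(250*500) = 3
        # per-replicate sd of mined lift is ~0.28, so 40 replicates put a
        # 5% band at ~3.4 standard errors
        lifts = []
        for seed in range(40):
            spec = CohortSpec(n_reports=5000, consequent_count=500,
                              pair_specs=(PairSpec("x", "ade", 250, 75),), seed=seed)
            db = build_transactions(generate_stochastic(spec))
            lifts.append(lift(db, [Item("x", "ade")], [BRADY]))
        assert np.mean(lifts) == pytest.approx(3.0, rel=0.05)

    def test_sampling_error_shrinks_with_cohort_size(self):
        def spread(n, reps=8):
            vals = []
            for seed in range(reps):
                spec = CohortSpec(
                    n_reports=n, consequent_count=n // 10,
                    pair_specs=(PairSpec("x", "ade", n // 20, int(n * 0.015)),),
                    seed=seed,
                )
                db = build_transactions(generate_stochastic(spec))
                vals.append(lift(db, [Item("x", "ade")], [BRADY]))
            return float(np.std(vals))

        assert spread(5000) < spread(500)


class TestGeneUniverse:
    def test_exact_overlaps_realized(self):
        spec = EnrichmentSpec(
            background_size=500, list_size=40,
            pathway_specs=(("p1", 30, 6), ("p2", 100, 0), ("p3", 40, 40)),
            seed=2,
        )
        gene_list, collection, background = generate_gene_universe(spec)
        by_name = {gs.name: gs for gs in collection}
        listed = set(gene_list)
        assert len(by_name["p1"].genes & listed) == 6
        assert len(by_name["p2"].genes & listed) == 0
        assert len(by_name["p3"].genes & listed) == 40
        assert all(len(by_name[n].genes) == s for n, s, _ in spec.pathway_specs)

    def test_zero_overlap_everywhere_enriches_nothing(self):
        spec = EnrichmentSpec(background_size=200, list_size=10,
                              pathway_specs=(("p", 50, 0),), seed=0)
        gene_list, collection, background = generate_gene_universe(spec)
        assert enrich(gene_list, collection, background) == []

    def test_pathway_equal_to_background_saturates_at_unit_fe(self):
        spec = EnrichmentSpec(background_size=100, list_size=10,
                              pathway_specs=(("all", 100, 10),), seed=0)
        gene_list, collection, background = generate_gene_universe(spec)
        rows = enrich(gene_list, collection, background, fdr_cutoff=None)
        assert rows[0].fold_enrichment == pytest.approx(1.0)

    def test_unsatisfiable_overlap_rejected(self):
        with pytest.raises(UnsatisfiableSpecError):
            EnrichmentSpec(background_size=100, list_size=5,
                           pathway_specs=(("p", 10, 7),))


class TestWriteExport:
    def test_empty_report_set_yields_header_only(self, tmp_path):
        from pvsignal import ReportSet

        p = tmp_path / "empty.csv"
        write_export(ReportSet([]), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and "Case ID" in lines[0]

    def test_row_count_matches_cohort(self, tmp_path, paper_spec):
        rs = generate_exact(paper_spec)
        p = tmp_path / "cohort.csv"
        write_export(rs, p)
        n_rows = len(p.read_text().strip().splitlines()) - 1
        assert n_rows == len(rs) == 1611 + paper_spec.literature_extra

    def test_round_trip_identity(self, tmp_path):
        spec = CohortSpec(n_reports=120, consequent_count=30,
                          pair_specs=(PairSpec("x", "ade", 20, 10),
                                      PairSpec("d", "drug", 15, 5)),
                          literature_extra=7, seed=21)
        rs = generate_exact(spec)
        p = tmp_path / "rt.csv"
        write_export(rs, p)
        back, log = load_reports(p)
        assert log.n_dropped == 0
        assert back.reports == rs.reports
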