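"""Association-rule statistics and consequent-anchored mining."""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from pvsignal import (
    AssociationRule,
    AssociationRuleMiner,
    Item,
    RuleFilter,
    confidence,
    lift,
    mine_rules,
    support,
)
from pvsignal.errors import UndefinedRuleError
from pvsignal.transactions import itemset_count

from conftest import ADE_ROWS, CONSEQUENT_COUNT, DDI_ROWS, N_COHORT
from test_transactions import make_db

BRADY = Item("bradycardia", "ade")


def pair_db(n, n_cons, n_ant, joint, ant_label="x", ant_kind="ade"):
    """Minimal DB realizing one exact 2x2 against bradycardia."""
    ant = Item(ant_label, ant_kind)
    vocab = [BRADY, ant]
    ts = (
        [frozenset({0, 1})] * joint
        + [frozenset({0})] * (n_cons - joint)
        + [frozenset({1})] * (n_ant - joint)
        + [frozenset()] * (n - n_cons - (n_ant - joint))
    )
    from pvsignal import TransactionDB

    return TransactionDB(vocab, ts), ant


class TestPointStatistics:
    def test_support_printed_example(self):
        db, ant = pair_db(N_COHORT, CONSEQUENT_COUNT, 18, 11, "syncope")
        s = support(db, [ant, BRADY])
        assert s == 11 / 1611
        assert round(s, 4) == 0.0068

    def test_support_saturated(self):
        db, ant = pair_db(4, 4, 4, 4)
        assert support(db, [ant]) == 1.0

    def test_support_matches_exhaustive_scan(self):
        rng = random.Random(9)
        labels = [f"i{j}" for j in range(6)]
        sets = [rng.sample(labels, rng.randint(0, 4)) for _ in range(50)]
        db = make_db(sets)
        for a, b in combinations(labels, 2):
            expected = sum(1 for s in sets if a in s and b in s) / 50
            assert support(db, [Item(a, "ade"), Item(b, "ade")]) == expected

    @pytest.mark.parametrize(
        "n_ant, joint, printed",
        [(18, 11, 0.611), (27, 14, 0.519)],
    )
    def test_confidence_printed_examples(self, n_ant, joint, printed):
        db, ant = pair_db(N_COHORT, CONSEQUENT_COUNT, n_ant, joint)
        assert round(confidence(db, [ant], [BRADY]), 3) == printed

    def test_confidence_of_perfect_implication(self):
        db, ant = pair_db(100, 20, 15, 15)
        assert confidence(db, [ant], [BRADY]) == 1.0

    def test_confidence_undefined_for_unseen_antecedent(self):
        db, ant = pair_db(10, 5, 0, 0)
        with pytest.raises(UndefinedRuleError):
            confidence(db, [ant], [BRADY])

    @pytest.mark.parametrize(
        "n_ant, joint, printed",
        [(18, 11, 4.711), (17, 12, 5.441)],
    )
    def test_lift_printed_examples(self, n_ant, joint, printed):
        db, ant = pair_db(N_COHORT, CONSEQUENT_COUNT, n_ant, joint)
        assert round(lift(db, [ant], [BRADY]), 3) == printed

    def test_lift_of_independent_items_is_one(self):
        # joint = count(X) count(Y) / N exactly: 100*20*10/200... use 8 = 20*40/100
        db, ant = pair_db(100, 20, 40, 8)
        assert lift(db, [ant], [BRADY]) == 1.0

    def test_lift_undefined_on_zero_marginal(self):
        db, ant = pair_db(10, 0, 3, 0)
        with pytest.raises(UndefinedRuleError):
            lift(db, [ant], [BRADY])


class TestRuleInvariants:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            AssociationRule(
                antecedent=frozenset({BRADY}), consequent=frozenset({BRADY}),
                count=1, support=0.1, confidence=0.5, coverage=0.2, lift=1.0,
            )

    def test_mined_rule_identities(self, paper_db):
        """support = count/N, confidence = support/coverage, and
        confidence/lift = support(consequent) for every mined rule."""
        for kind in ("ade", "drug"):
            res = AssociationRuleMiner(paper_db, antecedent_kind=kind).fit()
            assert len(res) > 0
            n = paper_db.n_transactions
            s_cons = res.consequent_count / n
            for r in res:
                assert r.support == r.count / n
                assert r.confidence == pytest.approx(r.support / r.coverage)
                assert r.confidence / r.lift == pytest.approx(s_cons)
                assert r.support <= min(r.coverage, s_cons) + 1e-12


def exhaustive_rules(db, rule_filter, antecedent_kind, max_size):
    """Brute-force oracle: score every eligible antecedent subset."""
    items = [it for it in db.items_of_kind(antecedent_kind)
             if it not in rule_filter.consequent]
    out = []
    n = db.n_transactions
    n_cons = itemset_count(db, rule_filter.consequent)
    for size in range(1, max_size + 1):
        for ant in combinations(items, size):
            ant = frozenset(ant)
            joint = itemset_count(db, ant | rule_filter.consequent)
            n_ant = itemset_count(db, ant)
            if joint < rule_filter.min_count or n_ant == 0:
                continue
            lift_v = joint * n / (n_ant * n_cons)
            if lift_v >= rule_filter.min_lift:
                out.append((ant, joint, lift_v))
    return {(a, c) for a, c, _ in out}


def random_small_db(seed, n_items=10, n_transactions=30):
    rng = random.Random(seed)
    labels = ["brady"] + [f"i{j}" for j in range(n_items - 1)]
    sets = [
        [l for l in labels if rng.random() < 0.3] for _ in range(n_transactions)
    ]
    return make_db(sets)


class TestMining:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_apriori_equals_exhaustive_enumeration(self, seed):
        db = random_small_db(seed)
        rf = RuleFilter(min_lift=1.0, min_count=2,
                        consequent=frozenset({Item("brady", "ade")}))
        mined = AssociationRuleMiner(db, rf, "ade", max_antecedent_size=2).fit()
        got = {(r.antecedent, r.count) for r in mined}
        assert got == exhaustive_rules(db, rf, "ade", 2)

    def test_sorted_lift_descending_with_tiebreaks(self, paper_db):
        res = AssociationRuleMiner(paper_db, antecedent_kind="ade").fit()
        keys = [(-r.lift, -r.count, r.antecedent_label) for r in res]
        assert keys == sorted(keys)

    def test_independent_items_yield_no_rules(self):
        # all items mutually independent at exact integer joints -> lift == 1
        db, _ = pair_db(100, 20, 40, 8)
        rf = RuleFilter(min_lift=1.5, min_count=1,
                        consequent=frozenset({BRADY}))
        assert mine_rules(db, rf) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotonicity_in_thresholds(self, seed):
        db = random_small_db(seed)
        cons = frozenset({Item("brady", "ade")})
        base = {r.antecedent for r in mine_rules(
            db, RuleFilter(1.0, 1, cons), "ade", 2)}
        for min_lift, min_count in [(1.2, 1), (1.0, 3), (1.5, 4)]:
            tighter = {r.antecedent for r in mine_rules(
                db, RuleFilter(min_lift, min_count, cons), "ade", 2)}
            assert tighter <= base

    def test_lift_symmetry(self, paper_db):
        for r in mine_rules(paper_db) + mine_rules(paper_db, antecedent_kind="drug"):
            assert lift(paper_db, r.antecedent, r.consequent) == pytest.approx(
                lift(paper_db, r.consequent, r.antecedent)
            )


class TestPublishedRegression:
    """All 16 printed rule rows from the exact-marginal cohort."""

    @pytest.mark.parametrize("kind, rows", [("ade", ADE_ROWS), ("drug", DDI_ROWS)])
    def test_rows_reproduce_at_printed_rounding(self, paper_db, kind, rows):
        res = AssociationRuleMiner(paper_db, antecedent_kind=kind).fit()
        mined = {r.antecedent_label: r for r in res}
        assert set(rows) <= set(mined)
        for label, (a, j, sup4, conf3, cov3, lift3, *_rest) in rows.items():
            r = mined[label]
            assert r.count == j
            assert round(r.support, 4) == sup4
            assert round(r.confidence, 3) == conf3
            assert round(r.coverage, 3) == cov3
            assert round(r.lift, 3) == lift3

    def test_lift_ordering_matches_published_tables(self, paper_db):
        res = AssociationRuleMiner(paper_db, antecedent_kind="ade").fit()
        labels = [r.antecedent_label for r in res if r.antecedent_label in ADE_ROWS]
        assert labels == sorted(ADE_ROWS, key=lambda l: -ADE_ROWS[l][5])

    def test_reconstructed_marginals_are_consistent(self):
        """The frozen marginals satisfy the printed tables' own arithmetic:
        antecedent = round(count/confidence) and a single consequent
        marginal (209) explains confidence/lift across every row."""
        for rows in (ADE_ROWS, DDI_ROWS):
            for label, (a, j, _s, conf3, _c, lift3, *_rest) in rows.items():
                assert a == round(j / conf3), label
                # confidence / lift = support(consequent): solve for the marginal
                cons = (j / a) / lift3 * N_COHORT
                assert abs(cons - CONSEQUENT_COUNT) < 1.0, (label, cons)
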