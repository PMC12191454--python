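"""Association-rule mining over report transactions.

A rule ``{X} -> {Y}`` is scored by

* support:     count(X ∪ Y) / N          — joint reporting frequency,
* coverage:    count(X) / N              — antecedent frequency,
* confidence:  count(X ∪ Y) / count(X)  — conditional frequency of Y given X,
* lift:        support / (coverage × support(Y)) — observed over expected
  joint frequency; 1 under independence, symmetric in X and Y.

Mining here is deliberately consequent-anchored: antecedents are enumerated
level-wise (Apriori-style) with pruning on the *joint* count with the fixed
consequent, which is anti-monotone in the antecedent, so the minimum-count
threshold prunes exactly.  Lift carries no sampling distribution, so mined
rules are screening output; the disproportionality module supplies the
inferential validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import UndefinedRuleError
from .transactions import Item, ItemKind, TransactionDB, itemset_count


def support(db: TransactionDB, items: Iterable[Item]) -> float:
    """Fraction of transactions containing every item of ``items``."""
    return itemset_count(db, items) / db.n_transactions


def confidence(db: TransactionDB, antecedent: Iterable[Item], consequent: Iterable[Item]) -> float:
    """Joint count over antecedent count; undefined for an unseen antecedent."""
    antecedent = frozenset(antecedent)
    consequent = frozenset(consequent)
    n_ant = itemset_count(db, antecedent)
    if n_ant == 0:
        raise UndefinedRuleError(f"antecedent {sorted(antecedent)} occurs in no transaction")
    return itemset_count(db, antecedent | consequent) / n_ant


def lift(db: TransactionDB, antecedent: Iterable[Item], consequent: Iterable[Item]) -> float:
    """Observed/expected joint frequency; symmetric in its arguments."""
    antecedent = frozenset(antecedent)
    consequent = frozenset(consequent)
    n_ant = itemset_count(db, antecedent)
    n_con = itemset_count(db, consequent)
    if n_ant == 0 or n_con == 0:
        raise UndefinedRuleError("lift undefined: a marginal support is zero")
    joint = itemset_count(db, antecedent | consequent)
    return joint * db.n_transactions / (n_ant * n_con)


@dataclass(frozen=True)
class AssociationRule:
    """A scored rule antecedent -> consequent over a transaction database."""

    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    count: int
    support: float
    confidence: float
    coverage: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def antecedent_label(self) -> str:
        return " + ".join(sorted(it.label for it in self.antecedent))

    @property
    def consequent_label(self) -> str:
        return " + ".join(sorted(it.label for it in self.consequent))


@dataclass(frozen=True)
class RuleFilter:
    """Thresholds a mined rule must pass: lift >= 1.5 and count >= 10 by default."""

    min_lift: float = 1.5
    min_count: int = 10
    consequent: frozenset[Item] = field(
        default_factory=lambda: frozenset({Item("bradycardia", "ade")})
    )

    def __post_init__(self) -> None:
        if self.min_lift < 0:
            raise ValueError("min_lift must be >= 0")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if not self.consequent:
            raise ValueError("consequent must be non-empty")


def _score(db: TransactionDB, antecedent: frozenset[Item], consequent: frozenset[Item],
           n_consequent: int) -> AssociationRule:
    n = db.n_transactions
    n_ant = itemset_count(db, antecedent)
    joint = itemset_count(db, antecedent | consequent)
    return AssociationRule(
        antecedent=antecedent,
        consequent=consequent,
        count=joint,
        support=joint / n,
        confidence=joint / n_ant if n_ant else 0.0,
        coverage=n_ant / n,
        lift=(joint * n) / (n_ant * n_consequent) if n_ant and n_consequent else 0.0,
    )


class AssociationRuleMiner:
    """Model object: mine consequent-anchored rules from a transaction DB.

    Parameters
    ----------
    db
        The cohort transactions.
    rule_filter
        Lift/count thresholds and the consequent itemset.
    antecedent_kind
        Item kind eligible as antecedent ("ade" for co-presenting events,
        "drug" for interaction screening).
    max_antecedent_size
        Largest antecedent itemset enumerated (default 1: single-item rules).
    """

    def __init__(
        self,
        db: TransactionDB,
        rule_filter: RuleFilter | None = None,
        antecedent_kind: ItemKind = "ade",
        max_antecedent_size: int = 1,
    ) -> None:
        if max_antecedent_size < 1:
            raise ValueError("max_antecedent_size must be >= 1")
        self.db = db
        self.rule_filter = rule_filter or RuleFilter()
        self.antecedent_kind = antecedent_kind
        self.max_antecedent_size = max_antecedent_size
        for it in self.rule_filter.consequent:
            db.index_of(it)  # consequent must be in vocabulary

    def _frequent_antecedents(self) -> list[frozenset[Item]]:
        """Level-wise enumeration pruned on joint count with the consequent."""
        db = self.db
        consequent = self.rule_filter.consequent
        min_count = self.rule_filter.min_count
        candidates = [
            frozenset({it})
            for it in db.items_of_kind(self.antecedent_kind)
            if it not in consequent
        ]
        frequent: list[frozenset[Item]] = []
        level = [
            c for c in candidates
            if itemset_count(db, c | consequent) >= min_count
        ]
        frequent.extend(level)
        size = 1
        while level and size < self.max_antecedent_size:
            size += 1
            prev = set(level)
            seen: set[frozenset[Item]] = set()
            nxt: list[frozenset[Item]] = []
            for a, b in combinations(level, 2):
                cand = a | b
                if len(cand) != size or cand in seen:
                    continue
                seen.add(cand)
                # classic Apriori prune: every (size-1)-subset must be frequent
                if any(cand - {it} not in prev for it in cand):
                    continue
                if itemset_count(db, cand | consequent) >= min_count:
                    nxt.append(cand)
            frequent.extend(nxt)
            level = nxt
        return frequent

    def fit(self) -> "RuleMiningResults":
        db = self.db
        f = self.rule_filter
        n_consequent = itemset_count(db, f.consequent)
        rules = []
        for ant in self._frequent_antecedents():
            rule = _score(db, ant, f.consequent, n_consequent)
            if rule.lift >= f.min_lift and rule.count >= f.min_count:
                rules.append(rule)
        rules.sort(key=lambda r: (-r.lift, -r.count, r.antecedent_label))
        return RuleMiningResults(
            rules=tuple(rules),
            n_transactions=db.n_transactions,
            consequent_count=n_consequent,
            rule_filter=f,
            antecedent_kind=self.antecedent_kind,
        )


@dataclass(frozen=True)
class RuleMiningResults:
    """Mined rules, lift-descending, with the marginals they were scored on."""

    rules: tuple[AssociationRule, ...]
    n_transactions: int
    consequent_count: int
    rule_filter: RuleFilter
    antecedent_kind: ItemKind

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def summary(self, rounded: bool = True) -> pd.DataFrame:
        """Rule table in display form.

        With ``rounded`` (the default) support/coverage print at 4 decimals
        and confidence/lift at 3, the conventional reporting precision; full
        precision is retained on the rule objects either way.
        """
        rows = []
        for r in self.rules:
            rows.append(
                {
                    "antecedent": r.antecedent_label,
                    "consequent": r.consequent_label,
                    "support": round(r.support, 4) if rounded else r.support,
                    "confidence": round(r.confidence, 3) if rounded else r.confidence,
                    "coverage": round(r.coverage, 4) if rounded else r.coverage,
                    "lift": round(r.lift, 3) if rounded else r.lift,
                    "count": r.count,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["antecedent", "consequent", "support", "confidence",
                     "coverage", "lift", "count"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def mine_rules(
    db: TransactionDB,
    rule_filter: RuleFilter | None = None,
    antecedent_kind: ItemKind = "ade",
    max_antecedent_size: int = 1,
) -> list[AssociationRule]:
    """Functional wrapper around :class:`AssociationRuleMiner`."""
    return list(
        AssociationRuleMiner(db, rule_filter, antecedent_kind, max_antecedent_size).fit()
    )
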