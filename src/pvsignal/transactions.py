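"""Report cohorts as itemset transactions.

Each deduplicated report becomes one transaction whose items are its ADE
terms and/or its co-reported suspect drugs.  The cohort drug itself is
excluded by default: it appears in every report of the cohort by
construction, so as an item it would contaminate every mined rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import PvSignalError
from .reports import ReportSet

ItemKind = Literal["drug", "ade"]


@dataclass(frozen=True, order=True)
class Item:
    """A vocabulary entry: a canonical label tagged with its kind.

    The same label may legitimately exist with both kinds (a drug name
    reported as a reaction term, for instance), so identity is the pair.
    """

    label: str
    kind: ItemKind


class TransactionDB:
    """A cohort as itemsets over a fixed vocabulary.

    Transactions store vocabulary indices as frozensets; the vocabulary is a
    list of :class:`Item`.  Instances are value-comparable on (vocabulary
    item per transaction) content, independent of index assignment.
    """

    def __init__(self, vocabulary: Sequence[Item], transactions: Iterable[frozenset[int]]):
        self.vocabulary: tuple[Item, ...] = tuple(vocabulary)
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("duplicate (label, kind) pairs in vocabulary")
        self.transactions: tuple[frozenset[int], ...] = tuple(
            frozenset(t) for t in transactions
        )
        n_items = len(self.vocabulary)
        for t in self.transactions:
            for i in t:
                if not 0 <= i < n_items:
                    raise ValueError(f"item id {i} outside vocabulary of size {n_items}")
        self._index = {item: i for i, item in enumerate(self.vocabulary)}

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def __len__(self) -> int:
        return len(self.transactions)

    def index_of(self, item: Item) -> int:
        try:
            return self._index[item]
        except KeyError:
            raise KeyError(f"item {item} not in vocabulary") from None

    def items_of_kind(self, kind: ItemKind) -> list[Item]:
        return [it for it in self.vocabulary if it.kind == kind]

    def as_label_sets(self) -> list[frozenset[Item]]:
        return [frozenset(self.vocabulary[i] for i in t) for t in self.transactions]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransactionDB):
            return NotImplemented
        return self.as_label_sets() == other.as_label_sets()

    def __repr__(self) -> str:
        return (
            f"TransactionDB(n_transactions={self.n_transactions}, "
            f"vocabulary_size={len(self.vocabulary)})"
        )


def build_transactions(
    rs: ReportSet,
    kinds: Iterable[ItemKind] = ("ade", "drug"),
    exclude: Iterable[str] = ("dexmedetomidine",),
) -> TransactionDB:
    """Turn a deduplicated cohort into a :class:`TransactionDB`.

    Parameters
    ----------
    rs
        Deduplicated report set; must be non-empty.
    kinds
        Which item kinds populate each transaction: "ade" takes the report's
        adverse events, "drug" its suspect products and active ingredients.
    exclude
        Labels omitted from transactions regardless of kind.  Defaults to the
        cohort drug so that the implicit cohort condition is not mined.
    """
    if len(rs) == 0:
        raise ValueError("cannot build transactions from an empty report set")
    kinds = set(kinds)
    bad = kinds - {"ade", "drug"}
    if bad:
        raise ValueError(f"unknown item kinds: {sorted(bad)}")
    exclude = set(exclude)

    vocab: dict[Item, int] = {}
    transactions: list[frozenset[int]] = []
    for r in rs:
        items: set[Item] = set()
        if "ade" in kinds:
            items.update(Item(t, "ade") for t in r.adverse_events if t not in exclude)
        if "drug" in kinds:
            items.update(Item(t, "drug") for t in r.all_suspect_drugs if t not in exclude)
        ids = set()
        for it in sorted(items):
            if it not in vocab:
                vocab[it] = len(vocab)
            ids.add(vocab[it])
        transactions.append(frozenset(ids))
    return TransactionDB(list(vocab), transactions)


def item_count(db: TransactionDB, item: Item) -> int:
    """Number of transactions containing ``item`` (KeyError if unknown)."""
    i = db.index_of(item)
    return sum(1 for t in db.transactions if i in t)


def itemset_count(db: TransactionDB, items: Iterable[Item]) -> int:
    """Number of transactions containing every item of ``items``."""
    ids = frozenset(db.index_of(it) for it in items)
    if not ids:
        raise ValueError("itemset must be non-empty")
    return sum(1 for t in db.transactions if ids <= t)


def top_items(db: TransactionDB, kind: ItemKind, k: int) -> list[tuple[str, int]]:
    """The ``k`` most frequent items of a kind, count-descending.

    Ties break lexicographically by label.  ``k`` larger than the vocabulary
    returns the full ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = [(it.label, item_count(db, it)) for it in db.items_of_kind(kind)]
    counts.sort(key=lambda lc: (-lc[1], lc[0]))
    return counts[:k]


# ---------------------------------------------------------------------------
# Basket serialization: one transaction per line, tab-separated "kind:label"
# tokens.  Empty transactions serialize as empty lines.

def write_basket(db: TransactionDB, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in db.transactions:
            items = sorted(db.vocabulary[i] for i in t)
            fh.write("\t".join(f"{it.kind}:{it.label}" for it in items) + "\n")


def read_basket(path: str | Path) -> TransactionDB:
    vocab: dict[Item, int] = {}
    transactions: list[frozenset[int]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            ids = set()
            if line:
                for token in line.split("\t"):
                    kind, sep, label = token.partition(":")
                    if not sep or kind not in ("ade", "drug") or not label:
                        raise PvSignalError(
                            f"{path}:{lineno}: malformed basket token {token!r}"
                        )
                    it = Item(label, kind)  # type: ignore[arg-type]
                    if it not in vocab:
                        vocab[it] = len(vocab)
                    ids.add(vocab[it])
            transactions.append(frozenset(ids))
    return TransactionDB(list(vocab), transactions)
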