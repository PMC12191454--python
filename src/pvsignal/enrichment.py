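"""Over-representation analysis: fold enrichment, hypergeometric tails, BH FDR.

Given a gene list (for instance, genes downregulated after drug treatment)
and a collection of gene sets, each set is scored by

* fold enrichment  FE = (k / n) / (K / N): observed over expected hit rate,
  where k = list genes in the set, n = list size, K = set size within the
  background, N = background size;
* an upper hypergeometric tail p-value  P(X >= k), X ~ Hypergeom(N, K, n),
  computed in log space for stability;
* a Benjamini-Hochberg FDR over all sets actually tested (those with at
  least one overlapping gene).

Gene symbols are treated as plain case-insensitive strings; no ortholog or
identifier mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import GmtParseError


@dataclass(frozen=True)
class GeneSet:
    """A named set of (case-folded) gene symbols."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @staticmethod
    def from_symbols(name: str, symbols: Iterable[str], description: str = "") -> "GeneSet":
        return GeneSet(
            name=name,
            genes=frozenset(s.strip().casefold() for s in symbols if s.strip()),
            description=description,
        )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a line collapse (sets are sets).  A line with
    fewer than three fields is a parse error naming the line.
    """
    sets: list[GeneSet] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: GMT line needs name, description, and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            sets.append(GeneSet.from_symbols(fields[0], fields[2:], description=fields[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 < n <= N):
        raise ValueError(f"need 0 < n <= N (got n={n}, N={N})")
    if not (0 < K <= N):
        raise ValueError(f"need 0 < K <= N (got K={K}, N={N})")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K) (got k={k})")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed over expected overlap rate: (k/n) / (K/N); 0 when k = 0."""
    _check_counts(k, n, K, N)
    return (k / n) / (K / N)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N, K, n), stable in log space."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    q_(i) = min over j >= i of min(1, m p_(j) / j) on the sorted scale.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested gene set with its enrichment statistics."""

    pathway: str
    k_overlap: int
    K_pathway: int
    n_list: int
    N_background: int
    fold_enrichment: float
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]


class EnrichmentAnalysis:
    """Model object: over-representation of a gene list in a set collection.

    Parameters
    ----------
    gene_list
        Query symbols (e.g. a differential-expression list); must be a
        subset of the background.
    collection
        Gene sets to test.  Each set is intersected with the background
        before testing, so K counts background genes only.
    background
        The gene universe.  Defaults to the union of all collection genes —
        a conservative fallback; supply the assayed universe when known.
    """

    def __init__(
        self,
        gene_list: Iterable[str],
        collection: Sequence[GeneSet],
        background: Iterable[str] | None = None,
    ) -> None:
        self.gene_list = frozenset(g.strip().casefold() for g in gene_list if g.strip())
        if not self.gene_list:
            raise ValueError("gene list is empty")
        self.collection = list(collection)
        if background is None:
            bg: set[str] = set()
            for gs in self.collection:
                bg |= gs.genes
        else:
            bg = {g.strip().casefold() for g in background if g.strip()}
        self.background = frozenset(bg)
        missing = self.gene_list - self.background
        if missing:
            raise ValueError(
                f"{len(missing)} query genes absent from the background "
                f"(e.g. {sorted(missing)[:3]})"
            )

    def fit(self, fdr_cutoff: float | None = 0.05) -> "EnrichmentResults":
        """Test every set with non-zero overlap; FDR over the tested sets.

        Rows passing ``fdr_cutoff`` (default 0.05; ``None`` disables the
        filter) are returned sorted by fold enrichment, descending.
        """
        n = len(self.gene_list)
        N = len(self.background)
        tested: list[tuple[GeneSet, int, int, frozenset[str]]] = []
        for gs in self.collection:
            genes = gs.genes & self.background
            if not genes:
                continue
            overlap = genes & self.gene_list
            if not overlap:
                continue
            tested.append((gs, len(overlap), len(genes), frozenset(overlap)))
        pvals = [hypergeom_pvalue(k, n, K, N) for _, k, K, _ in tested]
        fdrs = bh_fdr(pvals)
        rows = [
            EnrichmentRow(
                pathway=gs.name,
                k_overlap=k,
                K_pathway=K,
                n_list=n,
                N_background=N,
                fold_enrichment=fold_enrichment(k, n, K, N),
                p_value=p,
                fdr=q,
                overlap_genes=overlap,
            )
            for (gs, k, K, overlap), p, q in zip(tested, pvals, fdrs)
        ]
        if fdr_cutoff is not None:
            rows = [r for r in rows if r.fdr <= fdr_cutoff]
        rows.sort(key=lambda r: (-r.fold_enrichment, r.pathway))
        return EnrichmentResults(rows=tuple(rows), n_tested=len(tested),
                                 fdr_cutoff=fdr_cutoff)


@dataclass(frozen=True)
class EnrichmentResults:
    """Filtered, fold-enrichment-sorted over-representation rows."""

    rows: tuple[EnrichmentRow, ...]
    n_tested: int
    fdr_cutoff: float | None

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pathway": r.pathway,
                    "n_genes": r.k_overlap,
                    "pathway_genes": r.K_pathway,
                    "fold_enrichment": round(r.fold_enrichment, 2),
                    "fdr": r.fdr,
                    "gene_list": ";".join(sorted(r.overlap_genes)),
                }
                for r in self.rows
            ],
            columns=["pathway", "n_genes", "pathway_genes", "fold_enrichment",
                     "fdr", "gene_list"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def enrich(
    gene_list: Iterable[str],
    collection: Sequence[GeneSet],
    background: Iterable[str] | None = None,
    fdr_cutoff: float | None = 0.05,
) -> list[EnrichmentRow]:
    """Functional wrapper around :class:`EnrichmentAnalysis`."""
    return list(EnrichmentAnalysis(gene_list, collection, background).fit(fdr_cutoff))
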