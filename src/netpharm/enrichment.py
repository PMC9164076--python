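"""Pathway over-representation analysis with rich factors.

For a query of n targets against a background of N assayable genes, a pathway
annotated with K genes that contains k of the query targets gets

* a **rich factor** k / K — the fraction of the pathway touched by the query;
* a one-sided **hypergeometric p-value** P(X ≥ k), X ~ Hypergeom(N, K, n);
* a Benjamini–Hochberg **FDR** across all tested pathways.

Pathways are ranked ascending by rich factor, and the *key pathway* is the
one with the minimum rich factor among significant rows: a broad pathway
touched selectively, read as the dominant pharmacological mechanism.  Rich
factors are carried at full precision internally and rounded to 4 decimals
only for display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InvalidAnnotationError, NoResultError
from .ingest import PathwayDB
from .overlap import TargetSet

log = logging.getLogger(__name__)

DEFAULT_BACKGROUND = 20_000  # human protein-coding scale
DEFAULT_ALPHA = 0.05


def rich_factor(k: int, K: int) -> float:
    """k / K: fraction of a pathway's K annotated genes hit by the query."""
    if K <= 0:
        raise InvalidAnnotationError(f"pathway background size must be positive, got K={K}")
    if not 1 <= k <= K:
        raise InvalidAnnotationError(f"hit count k={k} outside [1, K={K}]")
    return k / K


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeom(N, K, n).

    N: background size, K: pathway size, n: query size, k: observed hits.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise InvalidAnnotationError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise InvalidAnnotationError(f"hit count k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes stable log-space terms internally
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_pvalue_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact rational P(X ≥ k) by enumerating the tail with integer binomials.

    Independent of :func:`hypergeom_pvalue`; intended for validation at small
    N, where it is exact arithmetic rather than floating point.
    """
    total = math.comb(N, n)
    tail = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(tail, total)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-aligned with the input.

    Adjusted value for the i-th smallest p is min over j ≥ i of p_(j)·m/j,
    capped at 1; always ≥ the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise InvalidAnnotationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's enrichment result.

    ``k``/``K`` may be omitted (None) when a row is reconstructed from a
    published table that prints only the rich factor and FDR; in that case
    ``rich_factor`` is taken as given.
    """

    pathway_id: str
    name: str
    hit_genes: tuple[str, ...]
    k: int | None
    K: int | None
    rich_factor: float
    p_value: float | None
    fdr: float
    significant: bool = True

    @classmethod
    def from_counts(
        cls,
        pathway_id: str,
        name: str,
        hit_genes: Sequence[str],
        K: int,
        p_value: float,
        fdr: float,
        significant: bool = True,
    ) -> "EnrichmentRow":
        hits = tuple(sorted(set(hit_genes)))
        return cls(
            pathway_id=pathway_id,
            name=name,
            hit_genes=hits,
            k=len(hits),
            K=K,
            rich_factor=rich_factor(len(hits), K),
            p_value=p_value,
            fdr=fdr,
            significant=significant,
        )


@dataclass(frozen=True)
class EnrichmentTable:
    """Rows sorted ascending by rich factor, with the test's frame sizes."""

    rows: tuple[EnrichmentRow, ...]
    background_size: int | None = None  # N
    query_size: int | None = None  # n

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.rows],
                "name": [r.name for r in self.rows],
                "hits": [",".join(r.hit_genes) for r in self.rows],
                "k": [r.k for r in self.rows],
                "K": [r.K for r in self.rows],
                "rich_factor": [round(r.rich_factor, 4) for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "fdr": [r.fdr for r in self.rows],
                "significant": [r.significant for r in self.rows],
            }
        )


def _sorted_rows(rows: Sequence[EnrichmentRow]) -> tuple[EnrichmentRow, ...]:
    return tuple(sorted(rows, key=lambda r: (r.rich_factor, r.fdr, r.pathway_id)))


def make_table(
    rows: Sequence[EnrichmentRow],
    background_size: int | None = None,
    query_size: int | None = None,
) -> EnrichmentTable:
    """Assemble rows into a table, enforcing the ascending rich-factor order."""
    return EnrichmentTable(rows=_sorted_rows(rows), background_size=background_size, query_size=query_size)


def enrich(
    query: TargetSet,
    db: PathwayDB,
    background_size: int = DEFAULT_BACKGROUND,
    alpha: float = DEFAULT_ALPHA,
    strict: bool = False,
) -> EnrichmentTable:
    """Over-representation test of a target set against a pathway annotation.

    One row per pathway with at least one hit; rows with FDR ≥ alpha are
    flagged not-significant (dropped entirely under ``strict``).  A query
    disjoint from every pathway yields an empty table with a warning.
    """
    n = len(query.members)
    candidates = []
    for entry in db:
        hits = tuple(sorted(query.members & entry.genes))
        if hits:
            candidates.append((entry, hits))
    if not candidates:
        log.warning("query '%s' hits no pathway in the annotation (%d pathways)", query.label, len(db))
        return EnrichmentTable(rows=(), background_size=background_size, query_size=n)

    p_values = [
        hypergeom_pvalue(len(hits), entry.background_size, n, background_size)
        for entry, hits in candidates
    ]
    fdrs = bh_fdr(p_values)
    rows = []
    for (entry, hits), p, q in zip(candidates, p_values, fdrs):
        significant = q < alpha
        if strict and not significant:
            continue
        rows.append(
            EnrichmentRow(
                pathway_id=entry.pathway_id,
                name=entry.name,
                hit_genes=hits,
                k=len(hits),
                K=entry.background_size,
                rich_factor=rich_factor(len(hits), entry.background_size),
                p_value=p,
                fdr=q,
                significant=significant,
            )
        )
    return EnrichmentTable(rows=_sorted_rows(rows), background_size=background_size, query_size=n)


def key_pathway(table: EnrichmentTable) -> str:
    """Pathway id of the row with the minimum rich factor.

    Ties break by smaller FDR, then lexicographic pathway id.  The lowest
    rich factor marks a broad pathway touched selectively — the candidate key
    mechanism.
    """
    if not table.rows:
        raise NoResultError("key_pathway() on an empty enrichment table")
    best = min(table.rows, key=lambda r: (r.rich_factor, r.fdr, r.pathway_id))
    return best.pathway_id


def bubble_data(table: EnrichmentTable) -> pd.DataFrame:
    """Plot-ready bubble-chart records: rich factor vs −log10 FDR, sized by hits."""
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in table.rows],
            "name": [r.name for r in table.rows],
            "rich_factor": [r.rich_factor for r in table.rows],
            "neg_log10_fdr": [-math.log10(r.fdr) for r in table.rows],
            "hits": [len(r.hit_genes) for r in table.rows],
        }
    )
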