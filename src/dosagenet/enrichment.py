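"""Hypergeometric over-representation analysis of predicted drug targets.

Each pathway (gene set) is tested for over-representation among the
predicted drug targets with the one-sided hypergeometric tail
P(X >= k), where k is the overlap size, against a universe defaulting
to all genes in the collection.  Pathways with p below the cutoff and
at least ``min_genes`` overlapping (enriched) genes are reported; the
set of reported pathway ids is what the pathway-difference indicator
(DePy) compares between the two network variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeometric_p",
    "enrich",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the background universe.

    ``sets`` maps pathway_id -> (name, genes).  The universe defaults to
    the union of all sets; an explicit universe must contain every set.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        norm = {
            pid: (name, frozenset(g.upper() for g in genes))
            for pid, (name, genes) in dict(self.sets).items()
        }
        universe = frozenset(g.upper() for g in self.universe)
        if not universe:
            universe = frozenset().union(*(g for _, g in norm.values())) if norm else frozenset()
        for pid, (_, genes) in norm.items():
            if not genes <= universe:
                raise ValueError(f"gene set {pid!r} not contained in universe")
        if not universe:
            raise ValueError("gene-set collection has an empty universe")
        object.__setattr__(self, "sets", norm)
        object.__setattr__(self, "universe", universe)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    overlap_genes: frozenset[str]
    overlap_count: int
    p_value: float


def hypergeometric_p(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """Exact upper tail P(X >= overlap) for X ~ Hypergeom(N, m, q).

    Drawing ``query_size`` genes from a universe of ``universe_size``
    containing ``set_size`` pathway genes, the p-value is the probability
    of an overlap at least as large as observed.
    """
    k, q, m, N = overlap, query_size, set_size, universe_size
    if not (0 <= k <= min(q, m) <= N) or q > N or m > N:
        raise ValueError(
            f"inconsistent counts: overlap={k}, query={q}, set={m}, universe={N}"
        )
    # sf(k-1) = P(X >= k); exact tail sum
    return float(hypergeom.sf(k - 1, N, m, q))


def enrich(
    drug_targets: Iterable[str],
    collection: GeneSetCollection,
    p_cutoff: float = 0.05,
    min_genes: int = 10,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation test of drug targets against every gene set.

    Returns pathways with p < ``p_cutoff`` and overlap >= ``min_genes``,
    sorted by ascending p (ties broken by pathway id).  Query genes
    outside the universe are dropped with a warning.  ``bh_correct``
    applies Benjamini-Hochberg to the p-values before the cutoff; it is
    off by default (raw p < 0.05 is the conventional threshold here).
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    query = frozenset(g.upper() for g in drug_targets)
    dropped = query - collection.universe
    if dropped:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    query &= collection.universe
    if not query:
        return []

    N, q = len(collection.universe), len(query)
    rows = []
    for pid in sorted(collection.sets):
        name, genes = collection.sets[pid]
        overlap = query & genes
        p = hypergeometric_p(len(overlap), q, len(genes), N)
        rows.append(EnrichmentResult(pid, name, overlap, len(overlap), p))

    if bh_correct:
        order = sorted(range(len(rows)), key=lambda i: (rows[i].p_value, rows[i].pathway_id))
        n = len(rows)
        adj, running_min = [0.0] * n, 1.0
        for rank_from_end, i in enumerate(reversed(order)):
            rank = n - rank_from_end
            running_min = min(running_min, rows[i].p_value * n / rank)
            adj[i] = running_min
        rows = [
            EnrichmentResult(r.pathway_id, r.name, r.overlap_genes, r.overlap_count, adj[i])
            for i, r in enumerate(rows)
        ]

    kept = [r for r in rows if r.p_value < p_cutoff and r.overlap_count >= min_genes]
    kept.sort(key=lambda r: (r.p_value, r.pathway_id))
    return kept
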