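"""Hypergeometric over-representation analysis (ORA) of DE gene lists.

Given a background universe of N genes, a pathway annotating M of them, and
a DE list of n genes of which k fall in the pathway, the number of pathway
genes in a random n-gene draw follows the hypergeometric distribution

    P(X = x) = C(M, x) C(N - M, n - x) / C(N, n).

Over-representation is scored by the upper tail P(X >= k) (the default).
A "literal" mode is also provided that evaluates the partial lower sum
sum_{x=1..k} P(X = x) instead; it exists for transparency, since some
published write-ups print the formula this way, but it is not an
enrichment tail and cannot produce the very small p-values that strong
over-representation yields. Probabilities are computed by scipy's
hypergeometric implementation (log-gamma based, stable at p ~ 1e-14).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps

from .expression import DEGeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentCounts",
    "EnrichmentResult",
    "hypergeom_pmf",
    "enrichment_pvalue",
    "count_overlap",
    "enrich_all",
]

#: smallest reportable p-value; keeps results inside (0, 1]
_P_FLOOR = float(np.finfo(float).tiny)

TAIL_MODES = ("upper", "literal")


def _normalize(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).upper() for g in genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways) over a background universe.

    Pathway members outside the universe do not participate in counting;
    they are dropped at construction with a logged total. Pathway names are
    unique by construction (dict keys); empty input sets are rejected.
    """

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]
    n_dropped: int = 0

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        uni = _normalize(universe)
        if not uni:
            raise ValueError("universe must be non-empty")
        clean: dict[str, frozenset[str]] = {}
        dropped = 0
        for name, members in sets.items():
            mem = _normalize(members)
            if not mem:
                raise ValueError(f"pathway {name!r} has no members")
            kept = mem & uni
            dropped += len(mem) - len(kept)
            clean[str(name)] = kept
        if dropped:
            logger.info(
                "dropped %d pathway member(s) absent from the universe", dropped
            )
        return cls(sets=clean, universe=uni, n_dropped=dropped)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class EnrichmentCounts:
    """The four counts of the hypergeometric draw: universe size N, pathway
    size M, DE-list size n, and overlap k."""

    N: int
    M: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if min(self.N, self.M, self.n, self.k) < 0:
            raise ValueError("counts must be non-negative")
        if self.M > self.N or self.n > self.N:
            raise ValueError("M and n cannot exceed the universe size N")
        if self.k > min(self.M, self.n):
            raise ValueError("overlap k cannot exceed min(M, n)")
        if self.N == 0:
            raise ValueError("universe must be non-empty")


def hypergeom_pmf(x: int, counts: EnrichmentCounts) -> float:
    """P(X = x) for the hypergeometric draw; exactly 0 outside the support."""
    if x < 0 or x > min(counts.M, counts.n):
        raise ValueError(f"x={x} outside [0, min(M, n)]")
    return float(sps.hypergeom.pmf(x, counts.N, counts.M, counts.n))


def enrichment_pvalue(counts: EnrichmentCounts, tail_mode: str = "upper") -> float:
    """Enrichment p-value for an observed overlap k.

    ``"upper"`` (default) returns the over-representation tail
    P(X >= k) — equal to 1 when k = 0. ``"literal"`` returns the partial
    lower sum sum_{x=1..k} P(X = x). The result is clipped into (0, 1].
    """
    if tail_mode not in TAIL_MODES:
        raise ValueError(f"unknown tail_mode {tail_mode!r}; expected {TAIL_MODES}")
    N, M, n, k = counts.N, counts.M, counts.n, counts.k
    if tail_mode == "upper":
        p = float(sps.hypergeom.sf(k - 1, N, M, n))
    else:
        p = float(sps.hypergeom.cdf(k, N, M, n) - sps.hypergeom.pmf(0, N, M, n))
    return float(np.clip(p, _P_FLOOR, 1.0))


def count_overlap(
    de_genes: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> EnrichmentCounts:
    """Build the (N, M, n, k) counts for one pathway.

    Symbols are uppercased; DE genes and pathway members outside the
    universe are dropped (logged) before counting.
    """
    uni = _normalize(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    de = _normalize(de_genes)
    outside = de - uni
    if outside:
        logger.info("dropped %d DE gene(s) absent from the universe", len(outside))
        de &= uni
    pw = _normalize(pathway) & uni
    return EnrichmentCounts(N=len(uni), M=len(pw), n=len(de), k=len(de & pw))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    counts: EnrichmentCounts
    p_value: float
    tail_mode: str
    significant: bool


def enrich_all(
    de: DEGeneTable | Iterable[str],
    collection: GeneSetCollection,
    cutoff: float = 1e-4,
    bonferroni_alpha: float | None = None,
    tail_mode: str = "upper",
) -> list[EnrichmentResult]:
    """Test every pathway of a collection against one DE gene list.

    Parameters
    ----------
    de:
        A :class:`~diffpath.expression.DEGeneTable` (its retained genes are
        used) or any iterable of gene symbols.
    collection:
        Pathways plus the background universe.
    cutoff:
        Fixed significance cutoff on the p-value (default 1e-4).
    bonferroni_alpha:
        If given, overrides ``cutoff`` with alpha / (number of pathways).
    tail_mode:
        ``"upper"`` or ``"literal"``; see :func:`enrichment_pvalue`.

    Returns
    -------
    Results sorted by ascending p-value (pathway name breaks ties).
    """
    genes = de.genes if isinstance(de, DEGeneTable) else set(de)
    if not genes:
        logger.warning("empty DE gene list: all enrichment p-values are 1")
    if bonferroni_alpha is not None:
        if not len(collection):
            raise ValueError("Bonferroni cutoff needs a non-empty collection")
        cutoff = bonferroni_alpha / len(collection)
    results = []
    for name, members in collection.sets.items():
        counts = count_overlap(genes, members, collection.universe)
        p = enrichment_pvalue(counts, tail_mode=tail_mode)
        results.append(
            EnrichmentResult(
                pathway=name,
                counts=counts,
                p_value=p,
                tail_mode=tail_mode,
                significant=p < cutoff,
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.pathway))
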