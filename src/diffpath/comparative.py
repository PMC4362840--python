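"""Cross-dataset comparisons: gene-list overlaps, treatment-reversal
classification, and pathway-level direction summaries.

The reversal analysis joins two filtered DE tables — a disease-vs-control
contrast and a treated-vs-untreated contrast — and classifies each gene by
the signs of its two signed fold changes: a gene down in disease but up
after treatment is ``reversed_up``, the mirror case ``reversed_down``,
matching signs are ``concordant``, and genes present in only one (or
neither) table are ``disease_only`` / ``treatment_only`` / ``absent``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .expression import DEGeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "REVERSAL_CATEGORIES",
    "ReversalRecord",
    "PathwayDirectionSummary",
    "venn_counts",
    "classify_reversal",
    "reversal_table",
    "pathway_direction_summary",
]

REVERSAL_CATEGORIES = (
    "reversed_up",
    "reversed_down",
    "concordant",
    "disease_only",
    "treatment_only",
    "absent",
)


def venn_counts(tables: Mapping[str, DEGeneTable | Iterable[str]]) -> dict[str, int]:
    """Exclusive-region sizes for 2 or 3 labeled gene sets.

    Keys of the result name each region by the ``&``-joined labels of the
    sets it belongs to (e.g. ``"fat"``, ``"fat&muscle"``); each key counts
    the genes in exactly those sets and no others, so the values sum to the
    size of the union.
    """
    if not 2 <= len(tables) <= 3:
        raise ValueError("venn_counts supports exactly 2 or 3 gene sets")
    sets = {
        label: (t.genes if isinstance(t, DEGeneTable) else set(t))
        for label, t in tables.items()
    }
    labels = list(sets)
    out: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(
                *(sets[l] for l in labels if l not in combo), set()
            ) if len(combo) < len(labels) else set()
            out["&".join(combo)] = len(inside - outside)
    return out


def _is_na(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def classify_reversal(
    fc_disease: float | None, fc_treatment: float | None
) -> str:
    """Joint sign classification of a gene across the disease and treatment
    contrasts. Arguments are signed fold changes (magnitude >= 1) or NA
    (``None``/``nan``)."""
    for val in (fc_disease, fc_treatment):
        if not _is_na(val):
            if not np.isfinite(val) or abs(val) < 1.0:
                raise ValueError(
                    f"signed fold change must be NA or have magnitude >= 1, got {val!r}"
                )
    na_d, na_t = _is_na(fc_disease), _is_na(fc_treatment)
    if na_d and na_t:
        return "absent"
    if na_t:
        return "disease_only"
    if na_d:
        return "treatment_only"
    if fc_disease < 0 and fc_treatment > 0:
        return "reversed_up"
    if fc_disease > 0 and fc_treatment < 0:
        return "reversed_down"
    return "concordant"


@dataclass(frozen=True)
class ReversalRecord:
    gene_id: str
    fc_disease: float  # nan for NA
    fc_treatment: float
    category: str
    in_both_universes: bool = True


def reversal_table(
    disease: DEGeneTable, treatment: DEGeneTable
) -> list[ReversalRecord]:
    """Classify every gene in the union of the two tables' universes.

    A gene present in one contrast's universe but not the other is treated
    as NA in the missing contrast and flagged via ``in_both_universes``.
    """
    uni_d, uni_t = set(disease.universe), set(treatment.universe)
    records = []
    for gene in sorted(uni_d | uni_t):
        fc_d = disease.get(gene) if gene in uni_d else float("nan")
        fc_t = treatment.get(gene) if gene in uni_t else float("nan")
        records.append(
            ReversalRecord(
                gene_id=gene,
                fc_disease=fc_d,
                fc_treatment=fc_t,
                category=classify_reversal(
                    None if math.isnan(fc_d) else fc_d,
                    None if math.isnan(fc_t) else fc_t,
                ),
                in_both_universes=gene in uni_d and gene in uni_t,
            )
        )
    return records


@dataclass(frozen=True)
class PathwayDirectionSummary:
    """Up/down/NA member counts for one pathway in one DE table."""

    pathway: str
    n_up: int
    n_down: int
    n_na: int
    majority: str  # "up", "down", "tied", or "none"

    @property
    def size(self) -> int:
        return self.n_up + self.n_down + self.n_na

    @property
    def fractions(self) -> tuple[float, float, float]:
        total = self.size
        if total == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_up / total, self.n_down / total, self.n_na / total)


def pathway_direction_summary(
    table: DEGeneTable, collection: GeneSetCollection
) -> list[PathwayDirectionSummary]:
    """Per-pathway regulation-direction counts for a filtered DE table.

    Counts each universe-restricted pathway member as up (signed_fc > 0),
    down (signed_fc < 0), or NA (not retained by the filter), and labels
    the majority direction among retained members.
    """
    out = []
    for name, members in collection.sets.items():
        if not members:
            logger.info("pathway %r has no members in the universe", name)
            out.append(PathwayDirectionSummary(name, 0, 0, 0, "none"))
            continue
        up = sum(1 for g in members if g in table.records and table.records[g] > 0)
        down = sum(1 for g in members if g in table.records and table.records[g] < 0)
        na = len(members) - up - down
        if up == down == 0:
            majority = "none"
        elif up == down:
            majority = "tied"
        else:
            majority = "up" if up > down else "down"
        out.append(PathwayDirectionSummary(name, up, down, na, majority))
    return out


def reversal_frame(records: Iterable[ReversalRecord]) -> pd.DataFrame:
    """Records as a DataFrame (gene, fc_disease, fc_treatment, category,
    in_both_universes) ready for TSV export with NA tokens."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "fc_disease": [r.fc_disease for r in records],
            "fc_treatment": [r.fc_treatment for r in records],
            "category": [r.category for r in records],
            "in_both_universes": [r.in_both_universes for r in records],
        }
    )
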