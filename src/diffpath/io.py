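"""Readers and writers for the pipeline's plain-text formats.

All tabular files are TSV with ``NA`` as the single missing-value token
(matching the gene-table convention). Gene sets use the GMT format: one set
per line — name, description, then tab-separated member symbols.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .comparative import ReversalRecord, reversal_frame
from .enrichment import EnrichmentResult, GeneSetCollection
from .expression import DEGeneTable, ExpressionMatrix, SampleDesign, export_gene_table

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
    "read_universe",
    "write_universe",
    "write_enrichment_report",
    "write_venn_report",
    "write_reversal_report",
    "write_direction_report",
]


def read_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "factor_a"}
    if not required <= set(frame.columns):
        raise ValueError(f"design file {path} must have columns {sorted(required)}")
    return SampleDesign.from_frame(frame)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_expression_matrix(
    matrix_path: str | Path, design_path: str | Path
) -> ExpressionMatrix:
    """Load a log2 expression TSV (first column gene id, header of sample
    ids) together with its design table."""
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = read_design(design_path)
    missing = set(design.sample_ids) - set(frame.columns)
    if missing:
        raise ValueError(f"samples in design but not in matrix: {sorted(missing)}")
    frame = frame[list(design.sample_ids)]
    return ExpressionMatrix(list(frame.index), frame.to_numpy(), design)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_table(path: str | Path) -> pd.Series:
    """Read a gene-table TSV (columns gene, signed_fc; literal NA) into a
    float Series indexed by uppercase gene symbol."""
    frame = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"gene": str}
    )
    if list(frame.columns) != ["gene", "signed_fc"]:
        raise ValueError(
            f"gene table {path} must have columns ['gene', 'signed_fc'], "
            f"got {list(frame.columns)}"
        )
    series = pd.Series(
        frame["signed_fc"].astype(float).to_numpy(),
        index=[g.upper() for g in frame["gene"]],
        name="signed_fc",
    )
    if series.index.has_duplicates:
        raise ValueError(f"duplicate gene symbols in {path}")
    return series


def write_gene_table(
    table: DEGeneTable | pd.Series,
    path: str | Path,
    universe: Sequence[str] | None = None,
) -> None:
    """Write a gene table with one row per universe gene and literal NA for
    genes outside the filtered set."""
    if isinstance(table, DEGeneTable):
        frame = export_gene_table(table, universe)
    else:
        frame = pd.DataFrame({"gene": table.index, "signed_fc": table.to_numpy()})
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into name -> member-set, reporting the line number
    of any malformed line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 gene (got {len(parts)} field(s))"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(set(members))]) + "\n")


def read_universe(path: str | Path) -> list[str]:
    """One gene symbol per line; uppercased, de-duplicated, order kept."""
    with open(path) as fh:
        genes = [line.strip().upper() for line in fh if line.strip()]
    return list(dict.fromkeys(genes))


def write_universe(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def load_collection(
    gmt_path: str | Path, universe_path: str | Path
) -> GeneSetCollection:
    return GeneSetCollection.from_dict(read_gmt(gmt_path), read_universe(universe_path))


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "N": [r.counts.N for r in results],
            "M": [r.counts.M for r in results],
            "n": [r.counts.n for r in results],
            "k": [r.counts.k for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def write_enrichment_report(
    results: Sequence[EnrichmentResult] | Mapping[str, Sequence[EnrichmentResult]],
    path: str | Path,
) -> None:
    """Write an enrichment report TSV.

    A single result list produces columns pathway/N/M/n/k/p_value/
    significant. A mapping of dataset label -> results produces the wide
    layout with one p-value column per dataset (pathways as rows).
    """
    if isinstance(results, Mapping):
        frames = []
        for label, res in results.items():
            f = enrichment_frame(res).set_index("pathway")
            frames.append(f["p_value"].rename(f"p_value_{label}"))
        wide = pd.concat(frames, axis=1).reset_index()
        wide.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        enrichment_frame(results).to_csv(path, sep="\t", index=False)


def write_venn_report(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"region": list(counts), "count": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


def write_reversal_report(
    records: Sequence[ReversalRecord], path: str | Path
) -> None:
    reversal_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_direction_report(summaries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "pathway": [s.pathway for s in summaries],
            "n_up": [s.n_up for s in summaries],
            "n_down": [s.n_down for s in summaries],
            "n_na": [s.n_na for s in summaries],
            "majority": [s.majority for s in summaries],
        }
    ).to_csv(path, sep="\t", index=False)
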