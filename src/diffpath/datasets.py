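"""Packaged reference tables.

Five gene tables of signed fold changes for the fatty acid oxidation
pathway, transcribed once from the source study's printed tables (including
their NA entries), and the pathway-level enrichment p-value table. Each
gene table covers one contrast:

- ``fat``: adipose tissue, diabetic MKR vs WT
- ``muscle``: skeletal muscle, diabetic MKR vs WT
- ``liver``: liver, diabetic MKR vs WT
- ``preliver``: liver, pre-diabetic (3-week-old) MKR vs WT
- ``treated_fat``: adipose tissue, CL-316,243-treated MKR vs vehicle MKR
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as dio

__all__ = ["GENE_TABLE_NAMES", "load_gene_table", "load_enrichment_pvalues", "fixture_path"]

GENE_TABLE_NAMES = {
    "fat": "table2_fat.tsv",
    "muscle": "table3_muscle.tsv",
    "liver": "table4_liver.tsv",
    "preliver": "table5_preliver.tsv",
    "treated_fat": "table7_treated_fat.tsv",
}


def fixture_path(filename: str):
    """Filesystem path of a packaged data file."""
    return resources.files("diffpath.data") / filename


def load_gene_table(name: str) -> pd.Series:
    """Load one packaged gene table as a float Series (nan for NA)."""
    if name not in GENE_TABLE_NAMES:
        raise KeyError(
            f"unknown gene table {name!r}; choose from {sorted(GENE_TABLE_NAMES)}"
        )
    with resources.as_file(fixture_path(GENE_TABLE_NAMES[name])) as path:
        return dio.read_gene_table(path)


def load_enrichment_pvalues() -> pd.DataFrame:
    """The published pathway-enrichment p-values (pathways x 5 contrasts).

    These are context for ordering/magnitude checks only: the DE lists and
    the 2014 pathway annotation behind them were never deposited, so the
    values cannot be recomputed from shipped data.
    """
    with resources.as_file(fixture_path("table1_enrichment.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="pathway")
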