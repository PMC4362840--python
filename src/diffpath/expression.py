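"""Expression-matrix preprocessing and per-gene differential expression.

This module covers the statistical front end of the pipeline: rank-mean
quantile normalization of a log2 expression matrix, classical fixed-effects
ANOVA computed gene-by-gene against a one- or two-factor sample design, the
signed linear fold-change convention used throughout microarray reporting
(ratio when >= 1, negative reciprocal when < 1, so no value ever lies
strictly between -1 and +1), and the significance filter that turns per-gene
statistics into a differentially-expressed (DE) gene table with explicit
``NA`` entries for every other gene in the analysis universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SampleDesign",
    "ExpressionMatrix",
    "GeneStat",
    "FilterCriteria",
    "DEGeneTable",
    "quantile_normalize",
    "two_way_anova_per_gene",
    "signed_fold_change",
    "signed_to_log2",
    "apply_de_filter",
    "export_gene_table",
]

#: residual sum-of-squares below this is treated as zero variance
_DEGENERATE_SS = 1e-18


@dataclass(frozen=True)
class SampleDesign:
    """Factor assignments for the samples of an expression matrix.

    Parameters
    ----------
    sample_ids:
        Sample names, in matrix column order.
    factor_a:
        Primary factor level per sample (e.g. genotype: WT vs MKR). This is
        the factor whose main effect drives the DE filter.
    factor_b:
        Optional second crossed factor (e.g. treatment or batch); either
        assigned for every sample or absent entirely.
    """

    sample_ids: tuple[str, ...]
    factor_a: tuple[str, ...]
    factor_b: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids in design")
        if len(self.factor_a) != len(self.sample_ids):
            raise ValueError("factor_a must assign a level to every sample")
        if self.factor_b is not None and len(self.factor_b) != len(self.sample_ids):
            raise ValueError("factor_b must cover all samples or be None")
        counts = pd.Series(self.factor_a).value_counts()
        if (counts < 2).any():
            lonely = counts[counts < 2].index.tolist()
            raise ValueError(
                f"each factor_a level needs >= 2 samples for a residual "
                f"variance estimate; offending level(s): {lonely}"
            )

    @property
    def levels_a(self) -> list[str]:
        """factor_a levels in order of first appearance."""
        return list(dict.fromkeys(self.factor_a))

    @property
    def levels_b(self) -> list[str]:
        if self.factor_b is None:
            return []
        return list(dict.fromkeys(self.factor_b))

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids, "factor_a": self.factor_a}
        if self.factor_b is not None:
            data["factor_b"] = self.factor_b
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        fb = None
        if "factor_b" in frame.columns and frame["factor_b"].notna().all():
            fb = tuple(str(v) for v in frame["factor_b"])
        return cls(
            sample_ids=tuple(str(v) for v in frame["sample_id"]),
            factor_a=tuple(str(v) for v in frame["factor_a"]),
            factor_b=fb,
        )


@dataclass
class ExpressionMatrix:
    """A genes-by-samples matrix of log2 intensities plus its design.

    Gene symbols are uppercased on construction and must be unique; values
    must be finite (the matrix is assumed already log2-transformed).
    """

    gene_ids: list[str]
    values: np.ndarray
    design: SampleDesign

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        if len(self.gene_ids) != len(set(self.gene_ids)):
            dupes = pd.Series(self.gene_ids).value_counts()
            raise ValueError(
                "duplicate gene symbols after uppercasing: "
                f"{dupes[dupes > 1].index.tolist()}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if self.values.shape[1] != len(self.design.sample_ids):
            raise ValueError("column count does not match design samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (log2 scale)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.design.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-mean quantile normalization across samples.

    Every column is forced onto the common target distribution formed by
    averaging the column-sorted values at each rank. Ties within a column
    receive average ranks and are mapped by linear interpolation between the
    neighbouring target values, which keeps the procedure deterministic.
    For tie-free columns the transform is exactly idempotent.
    """
    x = matrix.values
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    n = x.shape[0]
    # target distribution: mean across columns of the sorted values
    target = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(axis=0, method="average").to_numpy()
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, target)
    return ExpressionMatrix(list(matrix.gene_ids), out, matrix.design)


@dataclass(frozen=True)
class GeneStat:
    """Per-gene ANOVA p-values and fold change for one contrast.

    ``p_value_a`` is the main-effect p-value of the primary factor and is
    ``nan`` for degenerate genes (zero residual variance). ``log2fc`` is
    mean(alt) - mean(ref) on the log2 scale; ``signed_fc`` its signed linear
    counterpart (never in the open interval (-1, 1)).
    """

    gene_id: str
    p_value_a: float
    log2fc: float
    signed_fc: float
    p_value_b: float | None = None
    p_value_interaction: float | None = None
    degenerate: bool = False


def signed_fold_change(mean_log2_ref: float, mean_log2_alt: float) -> float:
    """Signed linear fold change between two log2 group means.

    With d = alt - ref on the log2 scale, returns 2**d when d >= 0 and
    -2**(-d) when d < 0, so up-regulation is the plain linear ratio and
    down-regulation its negative reciprocal. d = 0 maps to +1.
    """
    if not (np.isfinite(mean_log2_ref) and np.isfinite(mean_log2_alt)):
        raise ValueError("group means must be finite")
    d = mean_log2_alt - mean_log2_ref
    return float(2.0 ** d) if d >= 0 else float(-(2.0 ** (-d)))


def signed_to_log2(signed_fc: float) -> float:
    """Inverse of :func:`signed_fold_change`: log2 difference implied by a
    signed fold change (|signed_fc| must be >= 1)."""
    if not np.isfinite(signed_fc) or abs(signed_fc) < 1.0:
        raise ValueError(
            f"signed fold change must have magnitude >= 1, got {signed_fc!r}"
        )
    return float(np.log2(signed_fc)) if signed_fc > 0 else float(-np.log2(-signed_fc))


def _anova_balanced_two_way(
    x: np.ndarray, a_codes: np.ndarray, b_codes: np.ndarray, n_a: int, n_b: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Vectorized textbook sums-of-squares two-way ANOVA for a balanced
    crossed design; returns (p_a, p_b, p_ab, ss_within). p_ab is None when
    the design has a single replicate per cell (additive model)."""
    n_obs = x.shape[1]
    reps = n_obs // (n_a * n_b)
    grand = x.mean(axis=1, keepdims=True)
    ss_total = ((x - grand) ** 2).sum(axis=1)

    def _factor_ss(codes: np.ndarray, n_levels: int) -> np.ndarray:
        ss = np.zeros(x.shape[0])
        for lev in range(n_levels):
            sel = codes == lev
            m = x[:, sel].mean(axis=1)
            ss += sel.sum() * (m - grand[:, 0]) ** 2
        return ss

    ss_a = _factor_ss(a_codes, n_a)
    ss_b = _factor_ss(b_codes, n_b)
    cell_codes = a_codes * n_b + b_codes
    ss_cells = _factor_ss(cell_codes, n_a * n_b)

    df_a, df_b = n_a - 1, n_b - 1
    if reps > 1:
        ss_ab = np.maximum(ss_cells - ss_a - ss_b, 0.0)
        ss_within = np.maximum(ss_total - ss_cells, 0.0)
        df_ab = df_a * df_b
        df_within = n_obs - n_a * n_b
    else:
        ss_ab = None
        ss_within = np.maximum(ss_total - ss_a - ss_b, 0.0)
        df_within = df_a * df_b

    with np.errstate(divide="ignore", invalid="ignore"):
        ms_within = ss_within / df_within
        p_a = sps.f.sf(ss_a / df_a / ms_within, df_a, df_within)
        p_b = sps.f.sf(ss_b / df_b / ms_within, df_b, df_within)
        p_ab = (
            sps.f.sf(ss_ab / df_ab / ms_within, df_ab, df_within)
            if ss_ab is not None
            else None
        )
    return p_a, p_b, p_ab, ss_within


def _anova_one_way(
    x: np.ndarray, a_codes: np.ndarray, n_a: int
) -> tuple[np.ndarray, np.ndarray]:
    grand = x.mean(axis=1, keepdims=True)
    ss_total = ((x - grand) ** 2).sum(axis=1)
    ss_between = np.zeros(x.shape[0])
    for lev in range(n_a):
        sel = a_codes == lev
        m = x[:, sel].mean(axis=1)
        ss_between += sel.sum() * (m - grand[:, 0]) ** 2
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    df_between = n_a - 1
    df_within = x.shape[1] - n_a
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
        p = sps.f.sf(f, df_between, df_within)
    return p, ss_within


def _anova_unbalanced(
    x: np.ndarray,
    fa: pd.Series,
    fb: pd.Series,
    with_interaction: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene Type-II ANOVA via statsmodels for unbalanced crossed
    designs. Slow path; only taken when cell counts are unequal."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    n_genes = x.shape[0]
    p_a = np.full(n_genes, np.nan)
    p_b = np.full(n_genes, np.nan)
    p_ab = np.full(n_genes, np.nan)
    ss_within = np.zeros(n_genes)
    base = pd.DataFrame({"a": fa.to_numpy(), "b": fb.to_numpy()})
    formula = "y ~ C(a) + C(b)" + (" + C(a):C(b)" if with_interaction else "")
    for i in range(n_genes):
        df = base.assign(y=x[i])
        fit = smf.ols(formula, data=df).fit()
        ss_within[i] = fit.ssr
        if fit.ssr <= _DEGENERATE_SS:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = anova_lm(fit, typ=2)
        p_a[i] = tab.loc["C(a)", "PR(>F)"]
        p_b[i] = tab.loc["C(b)", "PR(>F)"]
        if with_interaction:
            p_ab[i] = tab.loc["C(a):C(b)", "PR(>F)"]
    return p_a, p_b, p_ab, ss_within


def two_way_anova_per_gene(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str] | None = None,
) -> list[GeneStat]:
    """Classical fixed-effects ANOVA for every gene of an expression matrix.

    When the design carries a single factor this degrades to one-way ANOVA;
    with two crossed factors the main effects are tested, plus the
    interaction when the design is replicated within cells. Balanced designs
    use a vectorized sums-of-squares computation; unbalanced designs fall
    back to per-gene Type-II ANOVA (interaction omitted if any cell is
    empty, with a logged warning).

    Parameters
    ----------
    matrix:
        Log2 expression matrix with its sample design.
    contrast:
        ``(ref_level, alt_level)`` of the primary factor used for the fold
        change; defaults to the first two levels in order of appearance.

    Returns
    -------
    list of :class:`GeneStat`, one per gene. Genes with zero residual
    variance are flagged degenerate with ``nan`` p-values.
    """
    design = matrix.design
    x = matrix.values
    fa = pd.Series(design.factor_a)
    levels_a = design.levels_a
    if len(levels_a) < 2:
        raise ValueError("ANOVA needs >= 2 levels of factor_a")
    if contrast is None:
        contrast = (levels_a[0], levels_a[1])
    ref, alt = contrast
    if ref not in levels_a or alt not in levels_a:
        raise ValueError(f"contrast levels {contrast} not found in factor_a")

    a_codes = fa.map({lev: i for i, lev in enumerate(levels_a)}).to_numpy()
    p_b_arr = p_ab_arr = None

    if design.factor_b is None:
        p_a_arr, ss_within = _anova_one_way(x, a_codes, len(levels_a))
    else:
        fb = pd.Series(design.factor_b)
        levels_b = design.levels_b
        b_codes = fb.map({lev: i for i, lev in enumerate(levels_b)}).to_numpy()
        cell_counts = pd.crosstab(fa, fb)
        full = cell_counts.reindex(
            index=levels_a, columns=levels_b, fill_value=0
        ).to_numpy()
        if (full > 0).all() and len(np.unique(full)) == 1:
            p_a_arr, p_b_arr, p_ab_arr, ss_within = _anova_balanced_two_way(
                x, a_codes, b_codes, len(levels_a), len(levels_b)
            )
        else:
            with_inter = (full > 0).all() and x.shape[1] > len(levels_a) * len(levels_b)
            if not with_inter:
                logger.warning(
                    "unbalanced design with empty cells: interaction omitted"
                )
            p_a_arr, p_b_arr, p_ab_arr, ss_within = _anova_unbalanced(
                x, fa, fb, with_inter
            )

    ref_sel = fa.to_numpy() == ref
    alt_sel = fa.to_numpy() == alt
    mean_ref = x[:, ref_sel].mean(axis=1)
    mean_alt = x[:, alt_sel].mean(axis=1)

    out: list[GeneStat] = []
    for i, gene in enumerate(matrix.gene_ids):
        degenerate = bool(ss_within[i] <= _DEGENERATE_SS)
        d = mean_alt[i] - mean_ref[i]
        out.append(
            GeneStat(
                gene_id=gene,
                p_value_a=np.nan if degenerate else float(p_a_arr[i]),
                p_value_b=(
                    None
                    if p_b_arr is None
                    else (np.nan if degenerate else float(p_b_arr[i]))
                ),
                p_value_interaction=(
                    None
                    if p_ab_arr is None
                    else (np.nan if degenerate else float(p_ab_arr[i]))
                ),
                log2fc=float(d),
                signed_fc=signed_fold_change(float(mean_ref[i]), float(mean_alt[i])),
                degenerate=degenerate,
            )
        )
    return out


@dataclass(frozen=True)
class FilterCriteria:
    """Significance filter: p-value threshold on the primary main effect
    and a minimum signed fold-change magnitude, both strict by default."""

    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    strict: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.fc_cutoff < 1.0:
            raise ValueError("fc_cutoff must be >= 1")

    def passes(self, p_value: float, signed_fc: float) -> bool:
        if not np.isfinite(p_value):
            return False
        if self.strict:
            return p_value < self.p_cutoff and abs(signed_fc) > self.fc_cutoff
        return p_value <= self.p_cutoff and abs(signed_fc) >= self.fc_cutoff


@dataclass
class DEGeneTable:
    """Filtered DE gene table: retained genes with their signed fold change;
    every other universe gene is implicitly NA."""

    label: str
    universe: tuple[str, ...]
    records: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.records) - set(self.universe)
        if missing:
            raise ValueError(f"retained genes outside universe: {sorted(missing)}")

    @property
    def genes(self) -> set[str]:
        return set(self.records)

    @property
    def up_genes(self) -> set[str]:
        return {g for g, fc in self.records.items() if fc > 0}

    @property
    def down_genes(self) -> set[str]:
        return {g for g, fc in self.records.items() if fc < 0}

    def get(self, gene: str) -> float:
        """signed_fc for a retained gene, nan for any other universe gene."""
        return self.records.get(gene, float("nan"))

    def to_series(self) -> pd.Series:
        vals = [self.records.get(g, np.nan) for g in self.universe]
        return pd.Series(vals, index=list(self.universe), name="signed_fc")

    @classmethod
    def from_series(cls, label: str, series: pd.Series) -> "DEGeneTable":
        series = series.copy()
        series.index = [str(g).upper() for g in series.index]
        records = {g: float(v) for g, v in series.items() if np.isfinite(v)}
        bad = [g for g, v in records.items() if abs(v) < 1.0]
        if bad:
            raise ValueError(f"signed fold changes with magnitude < 1: {bad}")
        return cls(label=label, universe=tuple(series.index), records=records)


def apply_de_filter(
    stats: Sequence[GeneStat],
    criteria: FilterCriteria | None = None,
    label: str = "contrast",
) -> DEGeneTable:
    """Apply the significance filter to per-gene statistics.

    Retains genes whose primary-factor p-value and signed fold-change
    magnitude both pass :class:`FilterCriteria` (strict inequalities by
    default, so boundary values are excluded). Degenerate genes are never
    retained.
    """
    criteria = criteria or FilterCriteria()
    if not stats:
        logger.warning("apply_de_filter called with empty statistics")
        return DEGeneTable(label=label, universe=())
    universe = tuple(s.gene_id for s in stats)
    records = {
        s.gene_id: s.signed_fc
        for s in stats
        if not s.degenerate and criteria.passes(s.p_value_a, s.signed_fc)
    }
    return DEGeneTable(label=label, universe=universe, records=records)


def export_gene_table(
    table: DEGeneTable, universe: Iterable[str] | None = None
) -> pd.DataFrame:
    """Tabular report with one row per universe gene: the signed fold change
    for retained genes, NA for the rest. Round-trips losslessly through
    :func:`diffpath.io.read_gene_table`."""
    genes = list(universe) if universe is not None else list(table.universe)
    extra = set(table.records) - set(genes)
    if extra:
        raise ValueError(f"table contains genes outside the given universe: {sorted(extra)}")
    return pd.DataFrame(
        {"gene": genes, "signed_fc": [table.records.get(g, np.nan) for g in genes]}
    )
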