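"""Synthetic expression data with known ground truth.

Two kinds of data are generated here. :func:`generate_dataset` emulates
normalized microarray log2 expression — a common baseline intensity,
additive group-mean shifts for differentially expressed genes, and
homoscedastic Gaussian gene-level noise — with an optional pathway "spike"
that forces a chosen fraction of a pathway's members to be DE, for
calibration and power studies of the enrichment test.
:func:`matrix_from_gene_table` goes the other way: it encodes a published
gene table (signed fold changes with NA entries) into a calibrated matrix
whose group-mean differences reproduce every printed fold change exactly,
for end-to-end golden tests of the DE stage.

All randomness flows through a mandatory integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix, SampleDesign, signed_to_log2

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "generate_dataset",
    "matrix_from_gene_table",
    "generate_gene_sets",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a simulated two-group expression experiment.

    Defaults mirror a small-animal microarray study: three replicates per
    group, log2 baseline intensity around 8, gene-level noise SD 0.3 on the
    log2 scale, 5% of genes DE with a 1.0 log2 (two-fold) shift of random
    sign.
    """

    n_genes: int = 2000
    reps_per_group: int = 3
    baseline: float = 8.0
    noise_sd: float = 0.3
    de_fraction: float = 0.05
    effect_size: float = 1.0
    pathway_spike: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    group_labels: tuple[str, str] = ("WT", "MKR")
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.reps_per_group < 2:
            raise ValueError("need >= 1 gene and >= 2 replicates per group")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be non-negative")
        for name, frac in self.pathway_spike.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"spike fraction for {name!r} must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Injected truth of a simulation: per-gene log2 shifts (0 for non-DE)
    and which pathways were spiked."""

    shifts: pd.Series
    spiked_pathways: frozenset[str]

    @property
    def de_genes(self) -> set[str]:
        return set(self.shifts.index[self.shifts != 0.0])


def _gene_ids(n: int, prefix: str) -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}".upper() for i in range(1, n + 1)]


def generate_dataset(
    spec: SimulationSpec, collection: GeneSetCollection | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a two-group log2 expression matrix with known truth.

    DE genes receive a log2 shift of magnitude ``spec.effect_size`` with
    random sign in the second group. If ``spec.pathway_spike`` names
    pathways of ``collection``, the stated fraction of each pathway's
    members (rounded to the nearest gene) is forced DE on top of the
    background ``de_fraction`` drawn from the remaining genes. The same
    seed always reproduces the same dataset.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes, spec.gene_prefix)
    gene_index = {g: i for i, g in enumerate(genes)}

    de_mask = np.zeros(spec.n_genes, dtype=bool)
    if spec.pathway_spike:
        if collection is None:
            raise ValueError("pathway_spike requires a gene-set collection")
        for name, frac in spec.pathway_spike.items():
            members = sorted(collection.sets[name] & set(genes))
            n_force = int(round(frac * len(members)))
            chosen = rng.choice(members, size=n_force, replace=False)
            for g in chosen:
                de_mask[gene_index[g]] = True
    n_background = int(round(spec.de_fraction * spec.n_genes))
    free = np.flatnonzero(~de_mask)
    n_background = min(n_background, free.size)
    if n_background:
        de_mask[rng.choice(free, size=n_background, replace=False)] = True

    signs = rng.choice([-1.0, 1.0], size=spec.n_genes)
    shifts = np.where(de_mask, signs * spec.effect_size, 0.0)

    r = spec.reps_per_group
    n_samples = 2 * r
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    values = spec.baseline + noise
    values[:, r:] += shifts[:, None]

    ref, alt = spec.group_labels
    design = SampleDesign(
        sample_ids=tuple(
            f"{lab}_{i + 1}" for lab in (ref, alt) for i in range(r)
        ),
        factor_a=tuple([ref] * r + [alt] * r),
    )
    matrix = ExpressionMatrix(genes, values, design)
    truth = GroundTruth(
        shifts=pd.Series(shifts, index=genes, name="log2_shift"),
        spiked_pathways=frozenset(spec.pathway_spike),
    )
    return matrix, truth


def matrix_from_gene_table(
    table: pd.Series,
    reps_per_group: int = 3,
    baseline: float = 8.0,
    jitter: float = 1e-3,
    group_labels: tuple[str, str] = ("WT", "MKR"),
) -> ExpressionMatrix:
    """Encode a published gene table as a calibrated expression matrix.

    Each non-NA signed fold change becomes an exact log2 group-mean shift
    between the two groups; NA genes get zero shift. A small deterministic
    within-group offset pattern (``jitter``; zero-sum within each group, so
    group means are untouched) provides the positive residual variance the
    ANOVA stage needs — without it every gene would be degenerate. Running
    the DE stage on the result recovers every non-NA fold change to
    floating-point accuracy, while NA genes show fold change +1 and a
    non-significant p-value.

    Parameters
    ----------
    table:
        Series of signed fold changes indexed by gene symbol, ``nan`` for
        NA entries. Finite values with magnitude < 1 are rejected.
    reps_per_group:
        Replicates per group (>= 2).
    """
    if reps_per_group < 2:
        raise ValueError("reps_per_group must be >= 2")
    genes = [str(g).upper() for g in table.index]
    shifts = np.array(
        [0.0 if not np.isfinite(v) else signed_to_log2(float(v)) for v in table]
    )
    r = reps_per_group
    pattern = jitter * (np.arange(r) - (r - 1) / 2.0)  # sums to zero
    row = np.concatenate([pattern, pattern])
    values = np.tile(row, (len(genes), 1)) + baseline
    values[:, r:] += shifts[:, None]
    ref, alt = group_labels
    design = SampleDesign(
        sample_ids=tuple(f"{lab}_{i + 1}" for lab in (ref, alt) for i in range(r)),
        factor_a=tuple([ref] * r + [alt] * r),
    )
    return ExpressionMatrix(genes, values, design)


def generate_gene_sets(
    n_pathways: int,
    size_range: tuple[int, int],
    universe: list[str],
    seed: int,
) -> GeneSetCollection:
    """Random non-degenerate gene sets over a universe, reproducible by seed.

    Sizes are drawn uniformly from ``size_range`` (inclusive); members are
    sampled without replacement within each set. Pathways are named
    ``PW0001`` onward.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= |universe|")
    rng = np.random.default_rng(seed)
    uni = [str(g).upper() for g in universe]
    width = max(4, len(str(n_pathways)))
    sets = {}
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni, size=size, replace=False)
        sets[f"PW{i:0{width}d}"] = set(members)
    return GeneSetCollection.from_dict(sets, uni)
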