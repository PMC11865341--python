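"""Gene-signature module scores with expression-bin-matched control genes.

The score of a signature in a bin (or cell) is the mean normalized expression
of the signature genes minus the mean normalized expression of a control gene
pool.  Controls are matched on average expression: all genes are ranked by
dataset-mean normalized expression and cut into equal-frequency expression
groups; each signature gene contributes ``n_controls_per_gene`` genes drawn
(with replacement, seeded) from its own group.  Counts are normalized to a
fixed library size of 10,000 per bin and log1p-transformed before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix, ParameterError, SpatialBinMatrix

LIBRARY_SIZE = 10_000.0


@dataclass
class ScoreVector:
    """Per-bin signature score with the parameters that produced it."""

    name: str
    bin_ids: list[str]
    values: np.ndarray
    n_expression_bins: int
    n_controls_per_gene: int
    seed: int | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bin_ids),):
            raise ParameterError("one score per bin required")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("scores must be finite")

    def __len__(self) -> int:
        return len(self.bin_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.bin_ids, name=self.name)


def _normalized_expression(matrix: SpatialBinMatrix | CellMatrix) -> np.ndarray:
    """Genes x units array: counts scaled to 10,000 per unit, then log1p."""
    if isinstance(matrix, CellMatrix):
        counts = np.asarray(matrix.counts.todense(), dtype=float).T
    else:
        counts = np.asarray(matrix.counts.todense(), dtype=float)
    totals = counts.sum(axis=0)
    scale = np.divide(LIBRARY_SIZE, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    return np.log1p(counts * scale[np.newaxis, :])


def module_score(
    matrix: SpatialBinMatrix | CellMatrix,
    gene_set: list[str],
    *,
    name: str = "signature",
    n_expression_bins: int = 24,
    n_controls_per_gene: int = 100,
    seed: int | None = 0,
    exhaustive_controls: bool = False,
) -> ScoreVector:
    """Score a gene set per bin against expression-matched controls.

    Parameters
    ----------
    matrix
        Spatial bin matrix (scored per bin) or cell matrix (scored per cell).
    gene_set
        Signature genes; genes absent from the matrix raise an error listing
        them.
    n_expression_bins
        Number of equal-frequency expression groups used to match controls.
    n_controls_per_gene
        Control genes drawn (with replacement) per signature gene.
    seed
        Seed for control sampling; identical seeds give identical scores.
    exhaustive_controls
        Use every gene of each signature gene's expression group as controls
        (deterministic limit of the sampling scheme) instead of sampling.
    """
    genes = matrix.genes
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in gene_set if g not in gene_index]
    if missing:
        raise ParameterError(
            f"signature genes missing from matrix: {missing}")
    if not gene_set:
        raise ParameterError("gene_set is empty")
    if n_expression_bins > len(genes):
        raise ParameterError(
            f"n_expression_bins={n_expression_bins} exceeds the "
            f"{len(genes)} genes in the matrix")

    expr = _normalized_expression(matrix)  # genes x units
    mean_expr = expr.mean(axis=1)

    # Equal-frequency expression groups on the rank of dataset-mean expression.
    order = pd.Series(mean_expr).rank(method="first").to_numpy() - 1
    group = np.floor(order * n_expression_bins / len(genes)).astype(int)
    group = np.clip(group, 0, n_expression_bins - 1)

    members: dict[int, np.ndarray] = {
        g: np.flatnonzero(group == g) for g in np.unique(group)}

    sig_idx = np.array([gene_index[g] for g in gene_set])
    rng = np.random.default_rng(seed)
    control_rows: list[np.ndarray] = []
    for gi in sig_idx:
        pool = members[group[gi]]
        if exhaustive_controls:
            control_rows.append(pool)
        else:
            control_rows.append(rng.choice(pool, size=n_controls_per_gene,
                                           replace=True))
    controls = np.concatenate(control_rows)

    score = expr[sig_idx].mean(axis=0) - expr[controls].mean(axis=0)
    if isinstance(matrix, CellMatrix):
        ids = matrix.cell_ids
    else:
        ids = matrix.bin_ids
    return ScoreVector(
        name=name, bin_ids=ids, values=score,
        n_expression_bins=n_expression_bins,
        n_controls_per_gene=(0 if exhaustive_controls else n_controls_per_gene),
        seed=seed)
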