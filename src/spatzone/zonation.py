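"""Liver lobule zonation: landmark scores, nine layers, expressing fractions.

Each bin's position along the lobule axis is summarized by the *zonation
score*, the periportal landmark module score minus the pericentral one
(PV score − CV score), computed with the expression-matched control scheme of
:mod:`spatzone.scoring`.  Per slide, bins are ranked by increasing zonation
score and divided into nine rank-equal layers: layer 1 is the most
pericentral (central vein, CV) and layer 9 the most periportal (portal vein,
PV).  The classic landmark panels are three pericentral genes
(Glul, Cyp2e1, Cyp1a2) and four periportal genes (Alb, Ass1, Asl, Cyp2f2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ParameterError, SpatialBinMatrix
from .scoring import ScoreVector, module_score

CV_LANDMARKS = ("Glul", "Cyp2e1", "Cyp1a2")
PV_LANDMARKS = ("Alb", "Ass1", "Asl", "Cyp2f2")


@dataclass
class ZonationResult:
    """Per-bin CV/PV/zonation scores and (optionally) layer assignments."""

    bin_ids: list[str]
    cv_score: ScoreVector
    pv_score: ScoreVector
    zonation_score: np.ndarray
    layer: np.ndarray | None = None  # integers 1..n_layers
    n_layers: int = 9
    slide_id: str | None = None

    def __post_init__(self) -> None:
        self.zonation_score = np.asarray(self.zonation_score, dtype=float)
        if not np.all(np.isfinite(self.zonation_score)):
            raise ParameterError("zonation scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cv_score": self.cv_score.values,
            "pv_score": self.pv_score.values,
            "zonation_score": self.zonation_score,
        }, index=self.bin_ids)
        if self.layer is not None:
            df["layer"] = self.layer
        return df


@dataclass
class LayerExpressionProfile:
    """Per-layer fraction of bins with a raw count > 0 for one gene."""

    gene: str
    fractions: np.ndarray  # length n_layers, layer 1 first
    n_bins: np.ndarray
    condition: str | None = None


def zonation_scores(
    matrix: SpatialBinMatrix,
    cv_genes: tuple[str, ...] = CV_LANDMARKS,
    pv_genes: tuple[str, ...] = PV_LANDMARKS,
    *,
    n_expression_bins: int = 24,
    n_controls_per_gene: int = 100,
    seed: int | None = 0,
    exhaustive_controls: bool = False,
) -> ZonationResult:
    """Compute CV, PV and zonation (= PV − CV) scores for every bin."""
    missing = [g for g in (*cv_genes, *pv_genes) if g not in matrix.genes]
    if missing:
        raise ParameterError(f"landmark genes missing from matrix: {missing}")
    kwargs = dict(n_expression_bins=n_expression_bins,
                  n_controls_per_gene=n_controls_per_gene,
                  exhaustive_controls=exhaustive_controls)
    # the panels share one seed so that swapping them negates the score exactly
    cv = module_score(matrix, list(cv_genes), name="cv_score", seed=seed, **kwargs)
    pv = module_score(matrix, list(pv_genes), name="pv_score", seed=seed, **kwargs)
    return ZonationResult(
        bin_ids=matrix.bin_ids, cv_score=cv, pv_score=pv,
        zonation_score=pv.values - cv.values, slide_id=matrix.slide_id)


def assign_layers(result: ZonationResult, n_layers: int = 9) -> ZonationResult:
    """Assign bins to rank-equal zonation layers (1 = CV ... n_layers = PV).

    Bins are stably sorted by (zonation score, bin id) and cut into
    ``n_layers`` contiguous rank blocks whose sizes differ by at most one;
    when the bin count is not divisible, the larger blocks go to the
    lowest-numbered (pericentral) layers.  Layering is per slide — the
    result it operates on must come from a single slide.
    """
    n = len(result.bin_ids)
    if n_layers < 1:
        raise ParameterError(f"n_layers must be >= 1, got {n_layers}")
    if n < n_layers:
        raise ParameterError(
            f"cannot split {n} bins into {n_layers} layers")
    ids = np.array(result.bin_ids, dtype=object)
    order = np.lexsort((ids, result.zonation_score))
    base, extra = divmod(n, n_layers)
    sizes = [base + 1 if i < extra else base for i in range(n_layers)]
    layer = np.empty(n, dtype=int)
    start = 0
    for i, size in enumerate(sizes, start=1):
        layer[order[start:start + size]] = i
        start += size
    result.layer = layer
    result.n_layers = n_layers
    return result


def layer_expressing_fraction(
    matrix: SpatialBinMatrix,
    result: ZonationResult,
    gene: str,
    *,
    condition: str | None = None,
) -> LayerExpressionProfile:
    """Fraction of bins per layer with a raw count > 0 for ``gene``."""
    if result.layer is None:
        raise ParameterError("layers not assigned; call assign_layers first")
    if matrix.bin_ids != result.bin_ids:
        raise ParameterError("matrix bins differ from the zonation result")
    if gene not in matrix.genes:
        raise ParameterError(f"gene {gene!r} not present in matrix")
    expressed = matrix.gene_counts(gene) > 0
    fractions = np.empty(result.n_layers)
    n_bins = np.empty(result.n_layers, dtype=int)
    for i in range(1, result.n_layers + 1):
        mask = result.layer == i
        n_bins[i - 1] = mask.sum()
        fractions[i - 1] = expressed[mask].mean() if mask.any() else np.nan
    return LayerExpressionProfile(
        gene=gene, fractions=fractions, n_bins=n_bins,
        condition=condition if condition is not None else matrix.condition)
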