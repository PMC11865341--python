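"""Spatial immune-cell aggregation index on positive bins.

The index combines two metrics computed on the bins positive for a cell-type
signature: *cell density* — the mean Euclidean distance from each positive
bin to its eight nearest positive bins — and *aggregation area* — the size of
each connected component (minimum two nodes) of the positive-bin graph found
by breadth-first search, with 8-neighborhood lattice adjacency by default.
The *aggregation proportion* is the fraction of positive bins belonging to a
retained component.  Components larger than 500 bins are called significantly
clustered; condition contrasts dichotomize bins by component size and test
the 2x2 table with a two-sided Fisher's exact test evaluated by exact
hypergeometric enumeration.

Positive bins are selected from a signature :class:`~spatzone.scoring.ScoreVector`
by removing bins with score < 0 and then the bottom 5% of the remainder.
All aggregation statistics are intended for the bin20 scale; a matrix with a
different bin size is rejected unless explicitly overridden.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy.spatial import cKDTree

from .io import ParameterError, SpatialBinMatrix
from .scoring import ScoreVector

logger = logging.getLogger("spatzone")

#: Significance-star mapping shared by every test in the pipeline.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to ns/*/**/***/**** (ns means p > 0.05)."""
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Positive-bin selection
# ---------------------------------------------------------------------------

@dataclass
class PositiveBinSet:
    """Bins retained by the score filter, with coordinates and provenance."""

    bin_ids: list[str]
    coords: np.ndarray  # (n, 2) lattice coordinates
    scores: np.ndarray  # retained scores, aligned with bin_ids
    lower_quantile: float
    n_input: int
    n_negative_removed: int
    n_quantile_removed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.bin_ids)


def select_positive_bins(
    scores: ScoreVector,
    lower_quantile: float = 0.05,
    *,
    coords: np.ndarray | None = None,
    matrix: SpatialBinMatrix | None = None,
    order: str = "sequential",
    allow_any_bin_size: bool = False,
) -> PositiveBinSet:
    """Select signature-positive bins for aggregation analysis.

    With ``order='sequential'`` (default) bins with score < 0 are removed
    first and the lowest ``lower_quantile`` fraction of the *remaining* bins
    removed next (floor count, ties broken by bin id);
    ``order='quantile_first'`` removes the global bottom quantile before the
    negative-score rule.

    Coordinates are taken from ``coords`` (aligned with the score vector) or
    from ``matrix``; when a matrix is supplied its ``bin_size`` must be 20
    unless ``allow_any_bin_size`` is set, since the aggregation index is
    defined at the bin20 scale.
    """
    if not 0 <= lower_quantile < 1:
        raise ParameterError(f"lower_quantile must be in [0, 1), got {lower_quantile}")
    if order not in ("sequential", "quantile_first"):
        raise ParameterError(f"unknown order {order!r}")
    if matrix is not None:
        if matrix.bin_ids != scores.bin_ids:
            raise ParameterError("score vector and matrix bins differ")
        if matrix.bin_size != 20 and not allow_any_bin_size:
            raise ParameterError(
                f"aggregation is defined at bin20; matrix has bin_size="
                f"{matrix.bin_size} (pass allow_any_bin_size=True to override)")
        coords = matrix.coords
    if coords is None:
        coords = np.zeros((len(scores), 2), dtype=int)
    coords = np.asarray(coords)
    if coords.shape != (len(scores), 2):
        raise ParameterError("coords must align with the score vector")

    values = scores.values
    ids = np.array(scores.bin_ids, dtype=object)
    keep = np.ones(len(values), dtype=bool)

    def drop_quantile(mask: np.ndarray) -> int:
        n = int(mask.sum())
        k = int(np.floor(lower_quantile * n))
        if k > 0:
            idx = np.flatnonzero(mask)
            order_ = idx[np.lexsort((ids[idx], values[idx]))]
            mask[order_[:k]] = False
        return k

    if order == "sequential":
        neg = values < 0
        keep &= ~neg
        n_neg = int(neg.sum())
        n_quant = drop_quantile(keep)
    else:
        n_quant = drop_quantile(keep)
        neg = keep & (values < 0)
        keep &= ~neg
        n_neg = int(neg.sum())

    if not keep.any():
        logger.warning("no bins retained by the positive-bin filter")
    return PositiveBinSet(
        bin_ids=list(ids[keep]), coords=coords[keep], scores=values[keep],
        lower_quantile=lower_quantile, n_input=len(values),
        n_negative_removed=n_neg, n_quantile_removed=n_quant)


# ---------------------------------------------------------------------------
# Same-type cell density
# ---------------------------------------------------------------------------

def same_type_density(bins: PositiveBinSet, k: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Mean distance from each bin to its ``k`` nearest same-type bins.

    Returns ``(density, truncated)``: when fewer than ``k`` other bins exist
    the mean is over all available neighbors and the bin is flagged in
    ``truncated``.  A singleton set yields a NaN density with a flag rather
    than an error.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    n = len(bins)
    density = np.full(n, np.nan)
    truncated = np.zeros(n, dtype=bool)
    if n == 0:
        return density, truncated
    if n == 1:
        truncated[0] = True
        logger.warning("singleton positive-bin set: density undefined")
        return density, truncated
    k_eff = min(k, n - 1)
    truncated[:] = k_eff < k
    tree = cKDTree(bins.coords.astype(float))
    # first neighbor is the bin itself (distance 0)
    dists, _ = tree.query(bins.coords.astype(float), k=k_eff + 1)
    density = dists[:, 1:].mean(axis=1)
    if truncated.any():
        logger.warning(
            "fewer than %d same-type neighbors available; k truncated to %d",
            k, k_eff)
    return density, truncated


# ---------------------------------------------------------------------------
# Connected components (BFS on the lattice adjacency graph)
# ---------------------------------------------------------------------------

@dataclass
class AggregationResult:
    """Connected-component aggregation statistics for one slide/condition."""

    positive: PositiveBinSet
    components: list[list[str]]       # bin ids, each component of size >= 2
    areas: list[int]
    proportion: float
    adjacency: int
    thresholds: tuple[int, ...] = (30, 500)
    density: np.ndarray | None = None
    density_truncated: np.ndarray | None = None
    condition: str | None = None

    def member_count(self, threshold: int) -> int:
        """Number of positive bins inside a component of area > threshold."""
        return sum(a for a in self.areas if a > threshold)


_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def connected_components(
    bins: PositiveBinSet,
    adjacency: int = 8,
    *,
    thresholds: tuple[int, ...] = (30, 500),
    condition: str | None = None,
) -> AggregationResult:
    """Find aggregation components among positive bins by breadth-first search.

    Two bins are adjacent when their coordinates differ by at most one in
    both x and y (``adjacency=8``, Chebyshev distance 1) or by exactly one in
    a single axis (``adjacency=4``).  Components with fewer than two nodes
    are discarded; ``proportion`` is the fraction of positive bins belonging
    to a retained component.
    """
    if adjacency == 8:
        offsets = _OFFSETS_8
    elif adjacency == 4:
        offsets = _OFFSETS_4
    else:
        raise ParameterError(f"adjacency must be 4 or 8, got {adjacency}")

    coords = [tuple(c) for c in bins.coords.tolist()]
    index = {c: i for i, c in enumerate(coords)}
    visited = np.zeros(len(coords), dtype=bool)
    components: list[list[str]] = []
    areas: list[int] = []
    for start in range(len(coords)):
        if visited[start]:
            continue
        visited[start] = True
        queue = deque([start])
        comp = [start]
        while queue:
            i = queue.popleft()
            x, y = coords[i]
            for dx, dy in offsets:
                j = index.get((x + dx, y + dy))
                if j is not None and not visited[j]:
                    visited[j] = True
                    queue.append(j)
                    comp.append(j)
        if len(comp) >= 2:
            components.append([bins.bin_ids[i] for i in comp])
            areas.append(len(comp))

    n = len(bins)
    proportion = (sum(areas) / n) if n else 0.0
    return AggregationResult(
        positive=bins, components=components, areas=areas,
        proportion=proportion, adjacency=adjacency, thresholds=thresholds,
        condition=condition)


def classify_significant(areas: list[int], threshold: int = 500) -> list[bool]:
    """Flag components whose area strictly exceeds ``threshold``."""
    return [a > threshold for a in areas]


# ---------------------------------------------------------------------------
# Fisher's exact test by exact hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, by exact enumeration.

    The p-value sums the probabilities of every table with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table.  Probabilities are compared as exact integers (the
    common denominator cancels), so ties at the observed probability are
    handled without floating-point ambiguity.  A table with a zero margin
    has p = 1 by convention.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {t.shape}")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ParameterError("table entries must be non-negative")
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        logger.warning("zero-margin contingency table: p = 1 by convention")
        return 1.0

    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    num_obs = comb(col1, a) * comb(n_total - col1, row1 - a)
    num_sum = 0
    for k in range(k_min, k_max + 1):
        num_k = comb(col1, k) * comb(n_total - col1, row1 - k)
        if num_k <= num_obs:
            num_sum += num_k
    return float(Fraction(num_sum, comb(n_total, row1)))


@dataclass
class ContingencyResult:
    """2x2 condition-by-size-category spot counts with Fisher's exact test."""

    table: np.ndarray  # rows: conditions; cols: (> threshold, <= threshold)
    threshold: int
    p_value: float
    stars: str
    conditions: tuple[str, str]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)


def fisher_contingency(
    result_a: AggregationResult,
    result_b: AggregationResult,
    threshold: int = 500,
) -> ContingencyResult:
    """Contrast two conditions at a component-size threshold.

    For each condition, positive bins are dichotomized into members of a
    component of area > ``threshold`` versus all other positive bins; the
    resulting 2x2 table is tested with the two-sided Fisher's exact test.
    Both results must have been computed with identical adjacency.
    """
    if result_a.adjacency != result_b.adjacency:
        raise ParameterError(
            "aggregation results computed with different adjacency")
    rows = []
    for res in (result_a, result_b):
        above = res.member_count(threshold)
        rows.append([above, len(res.positive) - above])
    table = np.array(rows, dtype=int)
    p = fisher_exact_p(table)
    return ContingencyResult(
        table=table, threshold=threshold, p_value=p,
        stars=significance_stars(p),
        conditions=(result_a.condition or "A", result_b.condition or "B"))


def category_spot_counts(
    result: AggregationResult,
    thresholds: tuple[int, int] = (30, 500),
) -> dict[str, int]:
    """Spot counts in nested and partitioned component-size categories.

    Reports both readings of the {>30, >500} categories: nested counts
    (``above_30``, ``above_500``) and the partition ``30_to_500`` (component
    area in (30, 500]) next to ``above_500``.
    """
    lo, hi = thresholds
    above_lo = result.member_count(lo)
    above_hi = result.member_count(hi)
    return {
        "n_positive": len(result.positive),
        f"above_{lo}": above_lo,
        f"above_{hi}": above_hi,
        f"{lo}_to_{hi}": above_lo - above_hi,
        "in_component": sum(result.areas),
    }
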