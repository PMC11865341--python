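"""scRNA-seq quality-control filters as pure, auditable rules.

Cell-level rules (each independent of the other cells):

* mitochondrial fraction above 50% for gut tissues (ileum, colon, cecum) or
  above 15% for any other tissue;
* fewer than 200 detected gene features;
* more than 50,000 UMIs.

The feature and UMI rules are applied disjunctively by default (either one
removes the cell); the literal conjunctive reading ("< 200 features AND
> 50,000 UMIs") is available via ``conjunctive_feature_umi=True``.  After the
cell rules, genes detected in fewer than three *retained* cells are dropped.
Doublet removal is out of scope; ``extra_cell_filter`` is the hook point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .io import CellMatrix, ParameterError

GUT_TISSUES = frozenset({"gut", "ileum", "colon", "cecum"})
OTHER_TISSUES = frozenset({"other", "liver", "spleen", "thymus", "blood",
                           "bone_marrow"})

MITO_FRACTION_GUT = 0.50
MITO_FRACTION_OTHER = 0.15
MIN_FEATURES = 200
MAX_UMI = 50_000
MIN_CELLS_PER_GENE = 3


@dataclass
class QCReport:
    """Removal bookkeeping for one :func:`apply_qc` run.

    ``removed_first`` attributes each removed cell to the first failing rule
    (rule order: mito, low_feature, high_umi); ``removed_any`` counts every
    rule a cell fails, so the counts can overlap.
    """

    removed_first: dict[str, int]
    removed_any: dict[str, int]
    retained_cells: list[str]
    removed_cells: list[str]
    retained_genes: list[str]
    n_genes_removed: int
    thresholds: dict[str, float] = field(default_factory=dict)


def _cell_rule_failures(
    cells: CellMatrix, conjunctive_feature_umi: bool
) -> dict[str, np.ndarray]:
    counts = cells.counts.tocsr()
    umi = np.asarray(counts.sum(axis=1)).ravel()
    features = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito = cells.mito_mask()
    mito_counts = np.asarray(counts[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        mito_frac = np.divide(mito_counts, umi, out=np.zeros_like(mito_counts,
                              dtype=float), where=umi > 0)

    limits = np.empty(cells.n_cells)
    for i, t in enumerate(cells.tissue):
        t = str(t)
        if t in GUT_TISSUES:
            limits[i] = MITO_FRACTION_GUT
        elif t in OTHER_TISSUES:
            limits[i] = MITO_FRACTION_OTHER
        else:
            allowed = sorted(GUT_TISSUES | OTHER_TISSUES)
            raise ParameterError(
                f"unknown tissue label {t!r}; allowed labels: {allowed}")

    low_feature = features < MIN_FEATURES
    high_umi = umi > MAX_UMI
    if conjunctive_feature_umi:
        both = low_feature & high_umi
        low_feature = high_umi = both
    return {
        "mito": mito_frac > limits,
        "low_feature": low_feature,
        "high_umi": high_umi,
    }


def apply_qc(
    cells: CellMatrix,
    *,
    conjunctive_feature_umi: bool = False,
    extra_cell_filter: Callable[[CellMatrix], np.ndarray] | None = None,
) -> tuple[CellMatrix, QCReport]:
    """Apply the QC rules; returns the filtered matrix and a report.

    ``extra_cell_filter``, if given, receives the input matrix and returns a
    boolean removal mask (hook point for e.g. doublet removal); its removals
    are reported under the rule name ``"extra"``.
    """
    failures = _cell_rule_failures(cells, conjunctive_feature_umi)
    if extra_cell_filter is not None:
        failures["extra"] = np.asarray(extra_cell_filter(cells), dtype=bool)

    removed_any = {rule: int(mask.sum()) for rule, mask in failures.items()}
    remove = np.zeros(cells.n_cells, dtype=bool)
    removed_first = {}
    for rule, mask in failures.items():
        removed_first[rule] = int((mask & ~remove).sum())
        remove |= mask

    keep_cells = ~remove
    counts = cells.counts.tocsr()[keep_cells]
    # gene rule counts *retained* cells, hence applied after the cell rules
    cells_per_gene = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= MIN_CELLS_PER_GENE

    filtered = CellMatrix(
        cell_ids=[c for c, k in zip(cells.cell_ids, keep_cells) if k],
        genes=[g for g, k in zip(cells.genes, keep_genes) if k],
        counts=counts[:, keep_genes],
        tissue=cells.tissue[keep_cells],
        mito_genes=None if cells.mito_genes is None else
        {g for g, k in zip(cells.genes, keep_genes) if k} & set(cells.mito_genes),
    )
    report = QCReport(
        removed_first=removed_first,
        removed_any=removed_any,
        retained_cells=filtered.cell_ids,
        removed_cells=[c for c, k in zip(cells.cell_ids, keep_cells) if not k],
        retained_genes=filtered.genes,
        n_genes_removed=int((~keep_genes).sum()),
        thresholds={
            "mito_fraction_gut": MITO_FRACTION_GUT,
            "mito_fraction_other": MITO_FRACTION_OTHER,
            "min_features": MIN_FEATURES,
            "max_umi": MAX_UMI,
            "min_cells_per_gene": MIN_CELLS_PER_GENE,
        },
    )
    return filtered, report
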