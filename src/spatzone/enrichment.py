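"""Cell-type abundance enrichment for labeled tissue zones.

Each bin's deconvolved abundance row is first normalized to percentages, so
the score does not depend on per-bin total abundance (which deconvolution
does not calibrate across bins).  The enrichment of cell type ``c`` in zone
``z`` is then ``log2(mean percentage of c over bins in z / mean percentage
of c over all bins)``; a positive score means the type is over-represented
in the zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError

logger = logging.getLogger("spatzone")


@dataclass
class AbundanceMatrix:
    """Bins x cell-types abundance estimates with a zone label per bin."""

    abundances: pd.DataFrame     # bins x cell types, non-negative
    zones: pd.Series             # zone label per bin
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not self.abundances.index.equals(self.zones.index):
            raise FormatError("zone labels must align with abundance rows")
        values = self.abundances.to_numpy(dtype=float)
        if values.size and (np.nanmin(values) < 0 or not np.all(np.isfinite(values))):
            raise FormatError("abundances must be finite and non-negative")

    @classmethod
    def from_tsv(cls, path, tissue=None) -> "AbundanceMatrix":
        """Read a TSV with columns ``bin_id``, ``zone``, then one per cell type."""
        df = pd.read_csv(path, sep="\t")
        for col in ("bin_id", "zone"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        df = df.set_index("bin_id")
        return cls(abundances=df.drop(columns=["zone"]).astype(float),
                   zones=df["zone"], tissue=tissue)


def zone_enrichment(ab: AbundanceMatrix) -> pd.DataFrame:
    """Zones x cell-types log2 enrichment scores.

    All-zero abundance rows are excluded with a warning; a cell type whose
    global mean percentage is zero gets NaN scores (undefined, not clamped).
    """
    totals = ab.abundances.sum(axis=1)
    zero_rows = totals == 0
    if zero_rows.any():
        logger.warning("excluding %d all-zero abundance bins", int(zero_rows.sum()))
    abund = ab.abundances.loc[~zero_rows]
    zones = ab.zones.loc[~zero_rows]
    if abund.empty:
        raise FormatError("no bins with non-zero abundance")

    percent = abund.div(abund.sum(axis=1), axis=0) * 100.0
    global_mean = percent.mean(axis=0)
    zone_mean = percent.groupby(zones, sort=True).mean()

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log2(zone_mean.div(global_mean, axis=1))
    zero_types = global_mean.index[global_mean == 0].tolist()
    scores[zero_types] = np.nan
    if zero_types:
        logger.warning("cell types with zero global mean percentage "
                       "(enrichment undefined): %s", zero_types)
    scores.index.name = "zone"
    return scores
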