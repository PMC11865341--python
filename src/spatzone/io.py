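"""Data model and I/O for spatial bin matrices, cell matrices and bile-acid tables.

Conventions (stated here because the upstream formats never state them):
coordinates are 0-based integers in bin-lattice units, ``x`` is the column and
``y`` the row with the origin at the top-left.  On disk a spatial matrix is a
MatrixMarket coordinate file plus a TSV sidecar (``bin_id``, ``x``, ``y``), a
gene-name TSV and a small YAML metadata file, or alternatively a single
long-format TSV (``gene``, ``x``, ``y``, ``count``) at DNB resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("spatzone")


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


class ParameterError(ValueError):
    """Invalid parameter value."""


#: The 36 bile-acid analytes accepted by default (free species, taurine (T-)
#: and glycine (G-) conjugates). Extensible: unknown analytes are accepted
#: with a logged warning.
CANONICAL_ANALYTES = (
    "CA", "CDCA", "DCA", "LCA", "UDCA", "HDCA", "HCA",
    "a-MCA", "b-MCA", "w-MCA",
    "UCA", "APCA", "NorCA", "NorDCA", "3-oxoCA", "7-KetoLCA",
    "Dio-LCA", "Iso-LCA",
    "TCA", "TCDCA", "TDCA", "TLCA", "TUDCA", "THDCA", "THCA",
    "T-a-MCA", "T-b-MCA", "T-w-MCA",
    "GCA", "GCDCA", "GDCA", "GLCA", "GUDCA", "GHDCA", "GHCA",
    "G-b-MCA",
)

#: Accepted spellings for analytes whose canonical short name uses an ASCII
#: letter in place of a Greek one.
ANALYTE_ALIASES = {
    "alpha-MCA": "a-MCA", "beta-MCA": "b-MCA", "omega-MCA": "w-MCA",
    "α-MCA": "a-MCA", "β-MCA": "b-MCA", "ω-MCA": "w-MCA",
    "T-alpha-MCA": "T-a-MCA", "T-beta-MCA": "T-b-MCA", "T-omega-MCA": "T-w-MCA",
    "T-α-MCA": "T-a-MCA", "T-β-MCA": "T-b-MCA", "T-ω-MCA": "T-w-MCA",
    "G-beta-MCA": "G-b-MCA", "G-β-MCA": "G-b-MCA",
}


def canonical_analyte(name: str) -> str:
    """Map alias spellings (Greek letters, spelled-out prefixes) to canonical names."""
    return ANALYTE_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# Spatial bin matrix
# ---------------------------------------------------------------------------

@dataclass
class SpatialBinMatrix:
    """Gene x bin count matrix on an integer bin lattice.

    Parameters
    ----------
    genes
        Gene names, one per matrix row.
    bin_ids
        Bin identifiers, one per matrix column.
    counts
        Sparse or dense gene x bin matrix of non-negative counts.
    coords
        ``(n_bins, 2)`` integer array of ``(x, y)`` lattice coordinates,
        unique per bin.
    bin_size
        Side length of the bin in DNBs (20 for bin20, 50 for bin50).
    tissue, condition, slide_id
        Free-text provenance labels.
    integer_counts
        Counts are required to be integer-valued.  Only the noise-free
        diagnostic simulations relax this (they emit real-valued means).
    """

    genes: list[str]
    bin_ids: list[str]
    counts: sp.spmatrix
    coords: np.ndarray
    bin_size: int = 20
    tissue: str | None = None
    condition: str | None = None
    slide_id: str | None = None
    integer_counts: bool = True

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.bin_ids = list(self.bin_ids)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.coords = np.asarray(self.coords)
        self.validate()

    def validate(self) -> None:
        n_genes, n_bins = self.counts.shape
        if n_genes != len(self.genes):
            raise FormatError(
                f"counts has {n_genes} rows but {len(self.genes)} gene names")
        if n_bins != len(self.bin_ids):
            raise FormatError(
                f"counts has {n_bins} columns but {len(self.bin_ids)} bin ids")
        if self.coords.shape != (n_bins, 2):
            raise FormatError(
                f"coords has shape {self.coords.shape}, expected ({n_bins}, 2)")
        if len(set(map(tuple, self.coords.tolist()))) != n_bins:
            raise FormatError("bin coordinates are not unique")
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)) or np.any(data < 0):
                raise FormatError("counts must be finite and non-negative")
            if self.integer_counts and not np.allclose(data, np.round(data)):
                raise FormatError("counts must be integer-valued")
        if int(self.bin_size) < 1:
            raise ParameterError(f"bin_size must be >= 1, got {self.bin_size}")
        self.bin_size = int(self.bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_counts(self, gene: str) -> np.ndarray:
        """Raw counts of one gene across bins (dense 1-D array)."""
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None
        return np.asarray(self.counts[i].todense()).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Dense genes x bins DataFrame (small matrices only)."""
        return pd.DataFrame(
            np.asarray(self.counts.todense()),
            index=self.genes, columns=self.bin_ids)


# ---------------------------------------------------------------------------
# Long-format DNB reader and re-binning
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ("gene", "x", "y", "count")


def read_long_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-format TSV of DNB-resolution counts.

    Expected header columns: ``gene``, ``x``, ``y``, ``count``.  Duplicate
    ``(gene, x, y)`` rows are summed; a row with a non-positive count or a
    non-integer coordinate is a :class:`FormatError` naming its line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _LONG_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: header line is missing column(s) {missing}")
        idx = {c: header.index(c) for c in _LONG_COLUMNS}
        records: list[tuple[str, int, int, int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(header)} fields, got {len(parts)}")
            gene = parts[idx["gene"]]
            try:
                x = int(parts[idx["x"]])
                y = int(parts[idx["y"]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate "
                    f"({parts[idx['x']]!r}, {parts[idx['y']]!r})") from None
            try:
                count = int(parts[idx["count"]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count "
                    f"{parts[idx['count']]!r}") from None
            if count <= 0:
                raise FormatError(
                    f"{path}:{lineno}: count must be positive, got {count}")
            records.append((gene, x, y, count))
    df = pd.DataFrame(records, columns=list(_LONG_COLUMNS))
    if len(df):
        df = (df.groupby(["gene", "x", "y"], as_index=False, sort=False)
                ["count"].sum())
    return df


def rebin(
    dnb_counts: pd.DataFrame,
    n: int,
    *,
    tissue: str | None = None,
    condition: str | None = None,
    slide_id: str | None = None,
) -> SpatialBinMatrix:
    """Consolidate DNB-resolution counts into non-overlapping ``n x n`` bins.

    A DNB at ``(x, y)`` belongs to the bin with lattice coordinate
    ``(x // n, y // n)``; counts of identical genes are summed within each
    bin.  Negative coordinates are rejected (a bin must not straddle the
    origin).  ``n = 1`` is the identity re-binning.
    """
    if int(n) < 1:
        raise ParameterError(f"bin size must be >= 1, got {n}")
    n = int(n)
    for col in _LONG_COLUMNS:
        if col not in dnb_counts.columns:
            raise FormatError(f"dnb_counts is missing column {col!r}")
    x = dnb_counts["x"].to_numpy()
    y = dnb_counts["y"].to_numpy()
    if len(x) and (x.min() < 0 or y.min() < 0):
        raise FormatError("negative DNB coordinates are not supported")
    bx, by = x // n, y // n

    df = pd.DataFrame({
        "gene": dnb_counts["gene"].to_numpy(),
        "bx": bx, "by": by,
        "count": dnb_counts["count"].to_numpy(),
    })
    grouped = df.groupby(["gene", "bx", "by"], as_index=False, sort=False)["count"].sum()

    genes = sorted(grouped["gene"].unique().tolist())
    coords_df = (grouped[["bx", "by"]].drop_duplicates()
                 .sort_values(["by", "bx"]).reset_index(drop=True))
    bin_key = {(r.bx, r.by): i for i, r in enumerate(coords_df.itertuples())}
    gene_key = {g: i for i, g in enumerate(genes)}

    rows = grouped["gene"].map(gene_key).to_numpy()
    cols = [bin_key[(bx_, by_)] for bx_, by_ in zip(grouped["bx"], grouped["by"])]
    counts = sp.coo_matrix(
        (grouped["count"].to_numpy(), (rows, cols)),
        shape=(len(genes), len(coords_df)),
    ).tocsr()

    coords = coords_df.to_numpy(dtype=int)
    bin_ids = [f"bin_{bx_}_{by_}" for bx_, by_ in coords]
    return SpatialBinMatrix(
        genes=genes, bin_ids=bin_ids, counts=counts, coords=coords,
        bin_size=n, tissue=tissue, condition=condition, slide_id=slide_id)


# ---------------------------------------------------------------------------
# Spatial matrix round-trip (MTX + sidecars, or long TSV)
# ---------------------------------------------------------------------------

def write_bin_matrix(matrix: SpatialBinMatrix, prefix: str | Path,
                     fmt: str = "mtx") -> list[Path]:
    """Write a :class:`SpatialBinMatrix`; returns the files written.

    ``fmt='mtx'`` writes ``<prefix>.mtx`` (counts), ``<prefix>.genes.tsv``,
    ``<prefix>.bins.tsv`` (bin_id, x, y) and ``<prefix>.meta.yaml``.
    ``fmt='long'`` writes ``<prefix>.long.tsv`` plus the metadata YAML; the
    long format stores bin-lattice coordinates and drops bin ids.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "bin_size": matrix.bin_size, "tissue": matrix.tissue,
        "condition": matrix.condition, "slide_id": matrix.slide_id,
        "format": fmt,
    }
    meta_path = prefix.with_suffix(".meta.yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    written = [meta_path]

    if fmt == "mtx":
        mtx_path = prefix.with_suffix(".mtx")
        scipy.io.mmwrite(str(mtx_path), matrix.counts)
        genes_path = prefix.with_suffix(".genes.tsv")
        pd.Series(matrix.genes, name="gene").to_csv(
            genes_path, sep="\t", index=False)
        bins_path = prefix.with_suffix(".bins.tsv")
        pd.DataFrame({
            "bin_id": matrix.bin_ids,
            "x": matrix.coords[:, 0], "y": matrix.coords[:, 1],
        }).to_csv(bins_path, sep="\t", index=False)
        written += [mtx_path, genes_path, bins_path]
    elif fmt == "long":
        long_path = prefix.with_suffix(".long.tsv")
        coo = matrix.counts.tocoo()
        pd.DataFrame({
            "gene": [matrix.genes[i] for i in coo.row],
            "x": matrix.coords[coo.col, 0],
            "y": matrix.coords[coo.col, 1],
            "count": coo.data,
        }).to_csv(long_path, sep="\t", index=False)
        written.append(long_path)
    else:
        raise ParameterError(f"unknown format {fmt!r} (use 'mtx' or 'long')")
    return written


def read_bin_matrix(prefix: str | Path) -> SpatialBinMatrix:
    """Read a matrix written by :func:`write_bin_matrix` (format auto-detected)."""
    prefix = Path(prefix)
    meta_path = prefix.with_suffix(".meta.yaml")
    if not meta_path.exists():
        raise FormatError(f"{meta_path}: metadata file not found")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    fmt = meta.get("format", "mtx")
    common = dict(
        bin_size=meta.get("bin_size", 20), tissue=meta.get("tissue"),
        condition=meta.get("condition"), slide_id=meta.get("slide_id"))

    if fmt == "long":
        df = read_long_tsv(prefix.with_suffix(".long.tsv"))
        m = rebin(df, 1)
        m.bin_size = common["bin_size"]
        m.tissue, m.condition, m.slide_id = (
            common["tissue"], common["condition"], common["slide_id"])
        return m

    counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t")["gene"]
    genes = genes.astype(str).tolist() if len(genes) else []
    bins = pd.read_csv(prefix.with_suffix(".bins.tsv"), sep="\t")
    if len(bins) != counts.shape[1]:
        raise FormatError(
            f"{prefix}: sidecar lists {len(bins)} bins but matrix has "
            f"{counts.shape[1]} columns")
    return SpatialBinMatrix(
        genes=genes, bin_ids=bins["bin_id"].astype(str).tolist(),
        counts=counts, coords=bins[["x", "y"]].to_numpy(dtype=int), **common)


# ---------------------------------------------------------------------------
# Cell matrix
# ---------------------------------------------------------------------------

@dataclass
class CellMatrix:
    """Cells x genes count matrix with per-cell tissue labels.

    ``mito_genes`` lists mitochondrial genes explicitly; when ``None`` they
    are identified by the case-insensitive name prefix ``"mt-"``.
    """

    cell_ids: list[str]
    genes: list[str]
    counts: sp.spmatrix
    tissue: np.ndarray  # per-cell label
    mito_genes: set[str] | None = None

    def __post_init__(self) -> None:
        self.cell_ids = list(self.cell_ids)
        self.genes = list(self.genes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.tissue = np.asarray(self.tissue, dtype=object)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"counts has {n_cells} rows but {len(self.cell_ids)} cell ids")
        if n_genes != len(self.genes):
            raise FormatError(
                f"counts has {n_genes} columns but {len(self.genes)} genes")
        if self.tissue.shape != (n_cells,):
            raise FormatError("tissue labels must be one per cell")
        data = self.counts.data
        if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
            raise FormatError("counts must be non-negative integers")
        if self.mito_genes is not None:
            extra = set(self.mito_genes) - set(self.genes)
            if extra:
                raise FormatError(
                    f"mito_genes not present in gene list: {sorted(extra)}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def mito_mask(self) -> np.ndarray:
        """Boolean mask over genes marking mitochondrial genes."""
        if self.mito_genes is not None:
            mito = set(self.mito_genes)
            return np.array([g in mito for g in self.genes])
        return np.array([g.lower().startswith("mt-") for g in self.genes])


def write_cell_matrix(cells: CellMatrix, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx = prefix.with_suffix(".mtx")
    scipy.io.mmwrite(str(mtx), cells.counts)
    genes = prefix.with_suffix(".genes.tsv")
    pd.DataFrame({
        "gene": cells.genes,
        "mito": [bool(b) for b in cells.mito_mask()],
    }).to_csv(genes, sep="\t", index=False)
    cellf = prefix.with_suffix(".cells.tsv")
    pd.DataFrame({"cell_id": cells.cell_ids, "tissue": cells.tissue}).to_csv(
        cellf, sep="\t", index=False)
    return [mtx, genes, cellf]


def read_cell_matrix(prefix: str | Path) -> CellMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    genes_df = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t")
    cells_df = pd.read_csv(prefix.with_suffix(".cells.tsv"), sep="\t")
    if len(cells_df) != counts.shape[0]:
        raise FormatError(
            f"{prefix}: sidecar lists {len(cells_df)} cells but matrix has "
            f"{counts.shape[0]} rows")
    genes = genes_df["gene"].astype(str).tolist()
    mito = set(genes_df.loc[genes_df.get("mito", False) == True, "gene"].astype(str))  # noqa: E712
    return CellMatrix(
        cell_ids=cells_df["cell_id"].astype(str).tolist(), genes=genes,
        counts=counts, tissue=cells_df["tissue"].to_numpy(),
        mito_genes=mito or None)


# ---------------------------------------------------------------------------
# Bile-acid concentration table
# ---------------------------------------------------------------------------

_BA_META_COLUMNS = ("sample", "group", "matrix_type", "volume_l", "mass_g")


@dataclass
class BAConcentrationTable:
    """Sample x analyte concentrations (nmol/L) with extraction metadata.

    ``meta`` is indexed by sample with columns ``group``, ``matrix_type``
    (``solid`` or ``liquid``), ``volume_l`` (extraction volume V, litres) and
    ``mass_g`` (weighed mass M, grams; required positive for solid samples).
    """

    concentrations: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.concentrations.index.equals(self.meta.index):
            raise FormatError("concentration and metadata sample sets differ")
        for col in ("group", "matrix_type", "volume_l", "mass_g"):
            if col not in self.meta.columns:
                raise FormatError(f"metadata is missing column {col!r}")
        bad_type = set(self.meta["matrix_type"]) - {"solid", "liquid"}
        if bad_type:
            raise FormatError(
                f"matrix_type must be 'solid' or 'liquid', got {sorted(bad_type)}")
        conc = self.concentrations.to_numpy(dtype=float)
        if conc.size and np.nanmin(conc) < 0:
            raise FormatError("concentrations must be non-negative")
        solid = self.meta["matrix_type"] == "solid"
        if (self.meta.loc[solid, "volume_l"] <= 0).any():
            raise FormatError("extraction volume V must be positive")
        if (self.meta.loc[solid, "mass_g"] <= 0).any():
            raise FormatError("sample mass M must be positive for solid samples")
        unknown = [a for a in self.concentrations.columns
                   if canonical_analyte(a) not in CANONICAL_ANALYTES]
        if unknown:
            logger.warning("unknown bile-acid analytes accepted: %s", unknown)
        self.concentrations = self.concentrations.rename(
            columns=canonical_analyte)

    @property
    def samples(self) -> list[str]:
        return self.concentrations.index.tolist()

    @property
    def analytes(self) -> list[str]:
        return self.concentrations.columns.tolist()


def read_ba_csv(path: str | Path) -> BAConcentrationTable:
    """Read a bile-acid table CSV: metadata columns then one column per analyte."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _BA_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df.set_index("sample")
    meta = df[["group", "matrix_type", "volume_l", "mass_g"]]
    conc = df.drop(columns=["group", "matrix_type", "volume_l", "mass_g"])
    return BAConcentrationTable(concentrations=conc.astype(float), meta=meta)


def write_ba_csv(table: BAConcentrationTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.concat([table.meta, table.concentrations], axis=1)
    out.index.name = "sample"
    out.to_csv(path)
    return path
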