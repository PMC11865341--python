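"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume, not
real tissue: spatially clustered vs dispersed signature-positive bins on a
lattice (disc-shaped planted clusters, Bernoulli positivity inside/outside),
monotone zonated expression gradients for landmark gene panels with count
noise, cell populations with planted QC violations, and group-structured
log-normal bile-acid concentration tables.  A single study seed
deterministically spawns per-slide seeds via :class:`numpy.random.SeedSequence`
(a splitmix-style derivation), so replicate studies are reproducible and
identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import BAConcentrationTable, CellMatrix, ParameterError, SpatialBinMatrix
from .scoring import ScoreVector
from .zonation import CV_LANDMARKS, PV_LANDMARKS

MITO_GENES = tuple(f"mt-{g}" for g in (
    "Nd1", "Nd2", "Co1", "Co2", "Atp8", "Atp6", "Co3",
    "Nd3", "Nd4l", "Nd4", "Nd5", "Nd6", "Cytb"))


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministically spawn ``n`` child seeds (< 2^31) from a study seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted truth sufficient to score downstream recovery."""

    in_cluster: np.ndarray | None = None        # per-bin cluster membership
    positive: np.ndarray | None = None          # per-bin positivity draw
    cluster_centers: np.ndarray | None = None   # (n_clusters, 2)
    t: np.ndarray | None = None                 # per-bin lobule coordinate
    qc_flags: dict[str, np.ndarray] | None = None  # rule -> per-cell flag
    group_effects: dict[str, float] | None = None  # analyte -> group-B effect


# ---------------------------------------------------------------------------
# Clustered lattice tissue
# ---------------------------------------------------------------------------

@dataclass
class LatticeSimSpec:
    """Clustered-tissue generator parameters.

    ``p_in``/``p_out`` are the probabilities that a bin inside/outside a
    planted disc cluster is positive for the target cell type;
    ``score_mean_pos``/``score_mean_neg``/``score_sd`` parametrize the
    Gaussian signature-score emissions for positive and negative bins.
    """

    width: int = 50
    height: int = 50
    n_clusters: int = 3
    cluster_radius: float = 5.0
    p_in: float = 0.9
    p_out: float = 0.01
    score_mean_pos: float = 1.0
    score_mean_neg: float = -1.0
    score_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.width) != self.width or int(self.height) != self.height:
            raise ParameterError("lattice dimensions must be integers")
        if self.width < 1 or self.height < 1:
            raise ParameterError("lattice dimensions must be >= 1")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ParameterError(
                f"require 0 <= p_out <= p_in <= 1, got "
                f"p_in={self.p_in}, p_out={self.p_out}")
        if self.score_sd <= 0:
            raise ParameterError("score_sd must be > 0")
        if self.n_clusters < 0 or self.cluster_radius < 0:
            raise ParameterError("n_clusters and cluster_radius must be >= 0")


def simulate_clustered_tissue(
    spec: LatticeSimSpec,
    *,
    condition: str | None = None,
    slide_id: str | None = None,
) -> tuple[SpatialBinMatrix, ScoreVector, GroundTruth]:
    """Generate one slide with planted disc clusters of positive bins.

    Every lattice bin is present exactly once.  Cluster centers are uniform
    on the lattice; a bin within Euclidean distance ``cluster_radius`` of
    any center is in-cluster and positive with probability ``p_in``, other
    bins with ``p_out``.  Signature scores are Gaussian: positive bins from
    ``N(score_mean_pos, score_sd)``, the rest from ``N(score_mean_neg,
    score_sd)``.  A single marker gene carries Poisson counts (rate 3 for
    positive bins, 0.1 otherwise) so the matrix is a valid count object.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    xs, ys = np.meshgrid(np.arange(spec.width), np.arange(spec.height))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    n = len(coords)

    if spec.n_clusters > 0:
        centers = np.column_stack([
            rng.integers(0, spec.width, spec.n_clusters),
            rng.integers(0, spec.height, spec.n_clusters)])
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        in_cluster = (d2 <= spec.cluster_radius ** 2).any(axis=1)
    else:
        centers = np.empty((0, 2), dtype=int)
        in_cluster = np.zeros(n, dtype=bool)

    p = np.where(in_cluster, spec.p_in, spec.p_out)
    positive = rng.random(n) < p
    scores = np.where(
        positive,
        rng.normal(spec.score_mean_pos, spec.score_sd, n),
        rng.normal(spec.score_mean_neg, spec.score_sd, n))
    counts = rng.poisson(np.where(positive, 3.0, 0.1))[np.newaxis, :]

    bin_ids = [f"bin_{x}_{y}" for x, y in coords]
    matrix = SpatialBinMatrix(
        genes=["marker"], bin_ids=bin_ids, counts=sp.csr_matrix(counts),
        coords=coords, bin_size=20, tissue="synthetic",
        condition=condition, slide_id=slide_id)
    score_vec = ScoreVector(
        name="simulated_signature", bin_ids=bin_ids, values=scores,
        n_expression_bins=0, n_controls_per_gene=0, seed=spec.seed)
    truth = GroundTruth(in_cluster=in_cluster, positive=positive,
                        cluster_centers=centers)
    return matrix, score_vec, truth


def simulate_two_condition_study(
    spec_a: LatticeSimSpec,
    spec_b: LatticeSimSpec,
    n_slides: int = 1,
) -> dict[str, list[tuple[SpatialBinMatrix, ScoreVector, GroundTruth]]]:
    """Generate paired slide collections for a two-condition contrast.

    Each condition's slides are generated independently with per-slide seeds
    spawned from that condition's study seed, and tagged with condition
    labels ``"A"`` and ``"B"``.
    """
    if n_slides < 1:
        raise ParameterError("n_slides must be >= 1")
    study: dict[str, list] = {}
    for label, spec in (("A", spec_a), ("B", spec_b)):
        seeds = derive_seeds(spec.seed, n_slides)
        slides = []
        for i, s in enumerate(seeds):
            slide_spec = replace(spec, seed=s)
            slides.append(simulate_clustered_tissue(
                slide_spec, condition=label, slide_id=f"{label}{i + 1}"))
        study[label] = slides
    return study


# ---------------------------------------------------------------------------
# Zonated liver slide
# ---------------------------------------------------------------------------

@dataclass
class ZonationSimSpec:
    """Zonated-slide generator parameters.

    Each bin gets a latent lobule coordinate ``t`` uniform on [0, 1]
    (0 = pericentral, 1 = periportal).  Periportal landmark means increase
    linearly in ``t`` with slope ``gradient_slope`` (counts per unit of t),
    pericentral ones decrease; background genes are flat in ``t``.  Counts
    come from the chosen noise model (``poisson``, ``nb`` with
    ``dispersion``, or ``none`` which emits the means exactly — a
    diagnostic mode with non-integer counts).
    """

    n_bins: int = 2000
    cv_genes: tuple[str, ...] = CV_LANDMARKS
    pv_genes: tuple[str, ...] = PV_LANDMARKS
    gradient_slope: float = 10.0
    baseline: float = 1.0
    n_background_genes: int = 200
    noise_model: str = "poisson"
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 9:
            raise ParameterError("n_bins must be >= 9")
        overlap = set(self.cv_genes) & set(self.pv_genes)
        if overlap or not self.cv_genes or not self.pv_genes:
            raise ParameterError(
                "cv_genes and pv_genes must be disjoint and non-empty"
                + (f"; overlapping: {sorted(overlap)}" if overlap else ""))
        if self.noise_model not in ("poisson", "nb", "none"):
            raise ParameterError(
                f"noise_model must be poisson|nb|none, got {self.noise_model!r}")
        if self.noise_model == "nb" and self.dispersion <= 0:
            raise ParameterError("nb dispersion must be > 0")
        if self.gradient_slope < 0:
            raise ParameterError("gradient_slope must be >= 0")


def simulate_zonated_slide(
    spec: ZonationSimSpec,
    *,
    condition: str | None = None,
    slide_id: str | None = None,
) -> tuple[SpatialBinMatrix, GroundTruth]:
    """Generate a liver slide with a planted monotone zonation gradient."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_bins
    t = rng.uniform(0.0, 1.0, n)

    genes = list(spec.cv_genes) + list(spec.pv_genes) + [
        f"bg{i:04d}" for i in range(spec.n_background_genes)]
    means = np.empty((len(genes), n))
    row = 0
    for _ in spec.cv_genes:
        means[row] = spec.baseline + spec.gradient_slope * (1.0 - t)
        row += 1
    for _ in spec.pv_genes:
        means[row] = spec.baseline + spec.gradient_slope * t
        row += 1
    bg_levels = rng.uniform(0.5, 5.0, spec.n_background_genes)
    means[row:] = bg_levels[:, np.newaxis]

    if spec.noise_model == "poisson":
        counts = rng.poisson(means).astype(float)
        integer_counts = True
    elif spec.noise_model == "nb":
        # NB as gamma-Poisson with shape = dispersion (variance m + m^2/r)
        lam = rng.gamma(spec.dispersion, means / spec.dispersion)
        counts = rng.poisson(lam).astype(float)
        integer_counts = True
    else:
        counts = means
        integer_counts = False

    side = int(np.ceil(np.sqrt(n)))
    coords = np.column_stack([np.arange(n) % side, np.arange(n) // side])
    bin_ids = [f"bin{i:05d}" for i in range(n)]
    matrix = SpatialBinMatrix(
        genes=genes, bin_ids=bin_ids, counts=sp.csr_matrix(counts),
        coords=coords, bin_size=20, tissue="liver", condition=condition,
        slide_id=slide_id, integer_counts=integer_counts)
    return matrix, GroundTruth(t=t)


# ---------------------------------------------------------------------------
# QC cell populations
# ---------------------------------------------------------------------------

def simulate_qc_cells(
    n_clean: int = 50,
    n_high_mito_gut: int = 0,
    n_high_mito_other: int = 0,
    n_low_feature: int = 0,
    n_high_umi: int = 0,
    seed: int = 0,
    *,
    n_genes: int = 300,
) -> tuple[CellMatrix, GroundTruth]:
    """Generate cells with disjoint planted QC violations.

    Clean cells satisfy every rule with margin (~280 features, ~8,000 UMIs,
    ~5% mitochondrial reads).  ``high_mito_gut`` cells carry a gut tissue
    label and > 50% mitochondrial reads; ``high_mito_other`` cells carry a
    liver label and a 20–40% fraction (violating only the 15% rule);
    ``low_feature`` cells have exactly 150 features; ``high_umi`` cells have
    ~80,000 UMIs.  Each violator breaks exactly one rule, so per-rule
    removal counts are checkable against the planted counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"g{i:04d}" for i in range(n_genes)] + list(MITO_GENES)
    n_regular = n_genes

    rows: list[np.ndarray] = []
    tissues: list[str] = []
    flags = {"mito": [], "low_feature": [], "high_umi": []}

    def add_cell(tissue: str, umi: int, n_features: int, mito_frac: float,
                 is_mito: bool, is_lowf: bool, is_highumi: bool) -> None:
        # the feature budget includes the mito gene, so planted feature
        # counts are exact (the low-feature rule is checked against them)
        counts = np.zeros(len(genes))
        mito_umi = int(round(mito_frac * umi))
        body_umi = umi - mito_umi
        n_body = n_features - (1 if mito_umi > 0 else 0)
        chosen = rng.choice(n_regular, size=n_body, replace=False)
        body = rng.multinomial(body_umi - n_body, np.full(n_body, 1 / n_body))
        counts[chosen] = body + 1  # each chosen feature detected at least once
        if mito_umi > 0:
            counts[n_regular + int(rng.integers(len(MITO_GENES)))] = mito_umi
        rows.append(counts)
        tissues.append(tissue)
        flags["mito"].append(is_mito)
        flags["low_feature"].append(is_lowf)
        flags["high_umi"].append(is_highumi)

    for i in range(n_clean):
        add_cell("ileum" if i % 2 == 0 else "liver",
                 umi=int(rng.integers(6000, 10000)),
                 n_features=int(rng.integers(260, 295)),
                 mito_frac=float(rng.uniform(0.03, 0.08)),
                 is_mito=False, is_lowf=False, is_highumi=False)
    for _ in range(n_high_mito_gut):
        add_cell("ileum", umi=int(rng.integers(6000, 10000)),
                 n_features=int(rng.integers(260, 295)),
                 mito_frac=float(rng.uniform(0.6, 0.9)),
                 is_mito=True, is_lowf=False, is_highumi=False)
    for _ in range(n_high_mito_other):
        add_cell("liver", umi=int(rng.integers(6000, 10000)),
                 n_features=int(rng.integers(260, 295)),
                 mito_frac=float(rng.uniform(0.2, 0.4)),
                 is_mito=True, is_lowf=False, is_highumi=False)
    for _ in range(n_low_feature):
        add_cell("liver", umi=int(rng.integers(3000, 5000)),
                 n_features=150, mito_frac=float(rng.uniform(0.03, 0.08)),
                 is_mito=False, is_lowf=True, is_highumi=False)
    for _ in range(n_high_umi):
        add_cell("liver", umi=int(rng.integers(70000, 90000)),
                 n_features=int(rng.integers(260, 295)),
                 mito_frac=float(rng.uniform(0.03, 0.08)),
                 is_mito=False, is_lowf=False, is_highumi=True)

    n_cells = len(rows)
    counts = sp.csr_matrix(np.array(rows) if rows else
                           np.zeros((0, len(genes))))
    cells = CellMatrix(
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        genes=genes, counts=counts, tissue=np.array(tissues, dtype=object),
        mito_genes=set(MITO_GENES))
    truth = GroundTruth(qc_flags={k: np.array(v, dtype=bool)
                                  for k, v in flags.items()})
    return cells, truth


# ---------------------------------------------------------------------------
# Bile-acid concentration tables
# ---------------------------------------------------------------------------

def simulate_ba_table(
    n_per_group: int = 6,
    analytes: tuple[str, ...] = ("CA", "CDCA", "b-MCA", "TCA", "T-b-MCA", "DCA"),
    group_effects: dict[str, float] | None = None,
    seed: int = 0,
    *,
    matrix_type: str = "solid",
    sigma: float = 0.4,
) -> tuple[BAConcentrationTable, GroundTruth]:
    """Generate a two-group bile-acid concentration table.

    Concentrations are log-normal with an analyte-specific median drawn once
    (log-uniform between 50 and 5,000 nmol/L) and log-scale spread
    ``sigma``.  ``group_effects`` scales group-B medians analyte-wise; an
    effect of 0 plants exact zeros.  Sample metadata uses an extraction
    volume of 2 mL and masses around 50 mg for solid matrices, emulating a
    6-vs-6 targeted metabolomics design.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    group_effects = dict(group_effects or {})
    unknown = set(group_effects) - set(analytes)
    if unknown:
        raise ParameterError(f"group_effects for absent analytes: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    medians = np.exp(rng.uniform(np.log(50.0), np.log(5000.0), len(analytes)))

    samples, groups = [], []
    conc = np.empty((2 * n_per_group, len(analytes)))
    for gi, group in enumerate(("A", "B")):
        for i in range(n_per_group):
            samples.append(f"{group}{i + 1}")
            groups.append(group)
    conc[:n_per_group] = medians * np.exp(
        rng.normal(0.0, sigma, (n_per_group, len(analytes))))
    effects = np.array([group_effects.get(a, 1.0) for a in analytes])
    conc[n_per_group:] = (medians * effects) * np.exp(
        rng.normal(0.0, sigma, (n_per_group, len(analytes))))
    conc[n_per_group:, effects == 0] = 0.0

    meta = pd.DataFrame({
        "group": groups,
        "matrix_type": matrix_type,
        "volume_l": 0.002,
        "mass_g": (rng.normal(0.05, 0.005, 2 * n_per_group).clip(0.02)
                   if matrix_type == "solid" else np.nan),
    }, index=pd.Index(samples, name="sample"))
    if matrix_type == "liquid":
        meta["mass_g"] = 0.0
        meta["volume_l"] = 0.0002
    table = BAConcentrationTable(
        concentrations=pd.DataFrame(conc, index=meta.index,
                                    columns=list(analytes)),
        meta=meta)
    return table, GroundTruth(group_effects={a: group_effects.get(a, 1.0)
                                             for a in analytes})
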