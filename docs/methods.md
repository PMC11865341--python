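# Methods

This note records the models and procedures spatzone implements, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions adopted where the underlying
procedures leave details open.

## Data model and re-binning

A `SpatialBinMatrix` is a gene × bin matrix of non-negative integer counts
on an integer lattice. Coordinates are 0-based, x = column, y = row, origin
top-left — a convention that must be fixed somewhere, and matches array
indexing. Re-binning maps a DNB (sub-micron capture spot) at `(x, y)` to
bin `(x // N, y // N)` and sums counts of identical genes per bin; N = 20
(bin20, ≈ 10 μm) is the scale at which aggregation and liver zonation are
defined, N = 50 (bin50, ≈ 25 μm) is coarser. The physical size is recorded
as metadata only; no physical-unit arithmetic is performed anywhere.
Negative DNB coordinates are rejected rather than floor-divided so a bin
never straddles the origin. Re-binning conserves per-gene totals exactly
and composes: `rebin(rebin(X, a), b)` occupies the same bins as
`rebin(X, a·b)` for non-negative coordinates.

## Module scores

The signature score of a bin is the mean normalized expression of the gene
set minus the mean over a control pool matched on average expression.
Normalization is counts-per-10,000 followed by log1p; genes are ranked by
dataset-mean normalized expression and cut into `n_expression_bins = 24`
equal-frequency groups (rank ties broken by gene order); each signature
gene contributes `n_controls_per_gene = 100` control genes drawn with
replacement from its own group, one seeded independent draw per signature
gene. The upstream tools this emulates document the same control scheme but
not the normalization; both parameters and the seed are recorded in the
returned `ScoreVector`. An `exhaustive_controls` mode uses every gene of
each signature gene's group, the deterministic limit of the sampling
scheme, and is what the order-exact tests use. Scores are invariant to
adding a constant to every gene's normalized expression, and a constant
matrix scores exactly zero for any gene set.

## Aggregation index

Positive-bin selection removes bins with score < 0, then the lowest 5% of
the remainder (floor count; ties broken by bin id). The sequential order
follows the natural reading of the procedure; a `quantile_first` variant is
available since the order is genuinely ambiguous. Density is the mean
Euclidean distance to the k = 8 nearest positive bins (k-d tree; the mean
of the k smallest distances is tie-invariant as a multiset); with fewer
than k neighbors the mean is over all available and the bin is flagged.
Components are found by breadth-first search under 8-neighborhood
(Chebyshev distance 1) adjacency — chosen over 4-neighborhood so diagonal
strands of bins are not fragmented; 4-neighborhood is available. Components
need ≥ 2 nodes; the proportion is members / positive bins. Aggregation is
enforced at bin20 (override flag available) so indices are comparable
across tissues.

The condition contrast dichotomizes *spots* (bins), not components, at a
component-size threshold, following the spot-level proportions the
categories {> 30, > 500} describe; both the nested counts and the
partitioned (30, 500] band are reported since the categories' nesting is
unstated. The threshold is strict (> 500, so 500 is not significant).
Fisher's two-sided p sums hypergeometric probabilities ≤ the observed
table's probability; probabilities are compared as exact integers (shared
denominator cancelled), so tie terms are handled without floating-point
ambiguity, and a zero-margin table yields p = 1 by convention.

**Known limitation — pseudo-replication.** Spots inside one connected
component are perfectly correlated, so the spot-level Fisher test is
strongly anticonservative whenever the configuration of components varies
between replicates: under independent draws of an identical clustered
process it rejects far above the nominal level, and for dense dispersed
bins the rejection rate can exceed 70%. The test is exactly calibrated
only in the degenerate sense that identical slides give p = 1. The
acceptance script reports the measured independent-draw rejection rate
(`independent_null_rejection_pct`) so this behavior is visible rather than
hidden; detected differences between conditions should be read as
descriptive, not as spot-level inference.

## Liver zonation

CV and PV scores are module scores of the three pericentral and four
periportal landmark genes (both panels share one control-sampling seed so
swapping the panels negates the zonation score exactly);
zonation score = PV − CV. Per slide — never pooled across slides — bins are
stably sorted by (score, bin id) and cut into nine contiguous rank blocks;
when the bin count is not divisible by nine the larger blocks go to the
lowest-numbered layers. Layer 1 is pericentral (central vein), layer 9
periportal (portal vein). Layer assignment is invariant under strictly
monotone transforms of the score. No spatial smoothing precedes scoring.
Per-layer expressing fractions count bins with raw count > 0.

## Zone enrichment

Each bin's deconvolved abundance row is normalized to percentages first, so
the score is independent of per-bin total abundance (which deconvolution
does not calibrate across bins); enrichment(z, c) =
log2(mean percentage of c in zone z / mean percentage of c over all bins).
No pseudocount is added: a cell type with zero global mean is reported as
missing, and all-zero bins are excluded with a warning. The ratio
decomposition is conserved: Σ_z (n_z/N)·2^score(z,c) = 1 for every type.

## QC filters

Cell rules are independent of other cells: mitochondrial fraction > 0.50
for gut tissues (ileum, colon, cecum) or > 0.15 otherwise; feature count
< 200; UMIs > 50,000. The feature and UMI rules are disjunctive by default
— the conjunctive literal reading ("< 200 features AND > 50,000 UMIs")
would retain absurd cells, but is available behind a flag. Mitochondrial
genes are identified by the case-insensitive "mt-" name prefix unless an
explicit list is supplied. The gene rule (detected in < 3 cells) counts
*retained* cells, hence runs after the cell rules. Reports give removals
both disjointly (first failing rule) and overlapping (all failing rules).
Filtering is idempotent on data where retained cells pass with margin, as
the generator guarantees; a pathological cell exactly at a boundary could
in principle fail a second pass after gene removal. Doublet removal is out
of scope; `extra_cell_filter` is the hook point.

## Bile-acid summaries

Solid-sample content is A·V/M (nmol/g; concentration nmol/L × extraction
volume L / mass g); liquid samples report the concentration directly
(nmol/L). Totals accumulate all measured analytes, treating missing values
as zero with a logged count; class sums cover classified analytes only, so
total = 12-OH + non-12-OH + unclassified exactly. The shipped 36-analyte
class map assigns the cholic-acid family (CA, DCA and their conjugates) to
12-OH and the CDCA/MCA families plus other alternative-pathway species to
non-12-OH; conjugates inherit their core's class since conjugation does not
touch the C-12 position; UCA, APCA, NorCA, NorDCA, 3-oxoCA and Dio-LCA are
left unclassified rather than guessed, and coverage is reported. The map is
data (a CSV), not code. Ratios CDCA/CA and β-MCA/CA are missing when the CA
content is zero. Greek-letter analyte spellings are accepted as aliases.

The Wilcoxon rank-sum test is exact for groups of ≤ 10 observations: the
midrank statistic is computed for all C(n1+n2, n1) labelings and the
two-sided p is the fraction at least as far from the null center — a rule
that is tie-safe and symmetric, gives p = 1 for identical samples and
matches the standard exact distribution on tie-free data. Larger groups use
the normal approximation with continuity and tie correction. At n = 6 per
group the exact test's true level at α = 0.05 is 38/924 ≈ 0.0411, the
discrete level closest to the nominal one from below; Monte-Carlo estimates
of it carry an SE of ≈ 0.002 at 10,000 replicates.

The pathway-activity rescale maps scores to [0, 1] within each
pathway × group as (V_cur − V_min)/(V_max − V_min); a constant group maps
to zeros with a warning.

## Synthetic data

The generators produce the statistical structure the analyses assume, with
planted truth sufficient to score recovery; they do not simulate
transcriptome-scale matrices, realistic spatial autocorrelation beyond the
cluster/gradient models, or sequencing reads — so passing tests demonstrate
correctness of the computations, not fidelity to any real tissue.

*Clustered tissue*: a fixed number of cluster centers uniform on the
lattice, disc membership by Euclidean distance — the simplest process with
reproducible geometry for oracles. Bins are positive with probability
`p_in` inside a disc and `p_out` outside; signature scores are Gaussian
(positive bins N(1, 0.5), others N(−1, 0.5)). Defaults (50×50 lattice, 3
clusters of radius 5, p_in = 0.9, p_out = 0.01) give slides whose positive
sets have unambiguous planted structure at realistic sparsity.

*Zonated slide*: each bin receives a lobule coordinate t ~ U(0, 1);
periportal landmark means rise linearly in t (default slope 10 counts per
unit t over baseline 1), pericentral ones fall, 200 background genes are
flat. Counts are Poisson by default, negative binomial (gamma–Poisson,
variance m + m²/r) optionally, or exact means in the diagnostic noise-free
mode — the one place non-integer counts are permitted, flagged explicitly.
The linear-mean/uniform-t model is the simplest monotone generative model
that makes layer recovery checkable; no generative model is implied by the
real data.

*QC cells*: planted violators exceed exactly one rule by construction
(gut mito 60–90%, other-tissue mito 20–40%, exactly 150 features, or
~80,000 UMIs) while clean cells pass everything with margin, so per-rule
removal counts are exactly checkable.

*Bile-acid tables*: log-normal concentrations with analyte medians drawn
log-uniformly in 50–5,000 nmol/L and spread σ = 0.4; group-B medians scaled
by per-analyte effects (effect 0 plants exact zeros); 6 samples per group
with 2 mL extraction volume and ~50 mg masses, emulating a typical targeted
metabolomics design.

Seeding: a single study seed spawns per-slide seeds through
`numpy.random.SeedSequence` (a splitmix-style derivation), so identical
spec + seed reproduces byte-identical output and replicate studies are
reproducible.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use sizes chosen to make every
oracle comparison exact yet quick: 2,000-bin slides for layer recovery and
the union-find comparison, 30 bins for the all-pairs density oracle,
exhaustive Fisher enumeration for all tables with total ≤ 12 plus 200
random tables with margins ≤ 30 (the exact-fraction oracle is
factorial-based and slow on larger exhaustive sweeps), Wilcoxon enumeration
for all group-size pairs ≤ 6, 100-replicate power studies and 10,000
Wilcoxon null replicates. Detection power for the strong two-condition
contrast (5 clusters radius 6 vs 1 cluster radius 2) is 100% at α = 0.05
and the >30-bin dichotomy.

## Known limitations

- The spot-level Fisher contrast is anticonservative under replicate-level
  spatial variability (see above).
- Module-score values depend on the control-sampling seed and parameters;
  the upstream tools' unstated normalization means absolute score values
  are not comparable to theirs, only the induced orderings and signs.
- The 12-OH classification of six ambiguous analytes is deliberately left
  open; class sums depend on the supplied map.
- Layer boundaries at tied zonation scores are resolved by bin id, an
  arbitrary but deterministic convention.
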