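# spatzone

Bin-level spatial transcriptomics and multi-omics analyses for germ-free
(GF) vs conventionally colonized (SPF) mouse studies: the spatial
immune-cell aggregation index, liver lobule zonation layering, tissue-zone
cell-type enrichment, scRNA-seq quality control, signature module scoring,
Stereo-seq style re-binning, and targeted bile-acid summary statistics —
each reusable on its own and exercisable end-to-end on synthetic data with
planted ground truth.

## Who this is for

Groups analyzing Stereo-seq (or comparable lattice-binned) data who want
the bespoke statistics from GF/SPF tissue-atlas studies as tested,
scriptable building blocks rather than one-off notebook code: spatial
biologists quantifying immune-cell clustering, hepatologists scoring lobule
zonation, and metabolomics analysts summarizing bile-acid panels.

## The statistics implemented

**Aggregation index.** For a cell-type signature scored per bin, positive
bins are those with score ≥ 0 after also dropping the bottom 5% of the
remainder. Two metrics follow: *cell density*, the mean Euclidean distance
from each positive bin to its 8 nearest positive bins; and *aggregation
area*, the size of each connected component (≥ 2 nodes, 8-neighborhood
lattice adjacency, found by BFS). The *aggregation proportion* is the
fraction of positive bins inside retained components; a component of area
> 500 is called significantly clustered. Conditions are contrasted by
dichotomizing bins at a component-size threshold (30 or 500) and applying
a two-sided Fisher's exact test, computed here by exact big-integer
hypergeometric enumeration.

**Zonation.** Per liver bin, CV score and PV score are module scores of the
pericentral (*Glul*, *Cyp2e1*, *Cyp1a2*) and periportal (*Alb*, *Ass1*,
*Asl*, *Cyp2f2*) landmark panels; the zonation score is PV − CV. Bins are
ranked by zonation score per slide and split into nine rank-equal layers,
layer 1 pericentral (CV) to layer 9 periportal (PV). Per-layer fractions of
bins expressing a gene summarize gradients (e.g. the ZBTB20–LPL axis).

**Module score.** Mean normalized expression (counts per 10,000, log1p) of
a gene set minus that of control genes sampled from expression-matched
bins: genes are ranked by dataset-mean expression, cut into 24
equal-frequency groups, and each signature gene contributes 100 seeded
control draws from its group.

**Zone enrichment.** log2(mean cell-type percentage within a zone / mean
percentage over all bins), after normalizing each bin's deconvolved
abundances to percentages.

**QC filters.** Cells removed at mitochondrial fraction > 50% (gut) or
> 15% (other tissues), feature count < 200 or UMIs > 50,000; genes
detected in < 3 retained cells dropped afterwards.

**Bile acids.** Content = A·V/M (nmol/g) for solid samples (concentration ×
extraction volume / mass; liquid samples report nmol/L directly); totals,
12-OH vs non-12-OH class sums (classic vs alternative synthesis pathway),
CDCA/CA and β-MCA/CA ratios, two-sided Wilcoxon rank-sum group comparisons
(exact by full enumeration for small groups), and the per-pathway min–max
rescale (V\_cur − V\_min)/(V\_max − V\_min) for activity scores.

## Worked example

A two-condition study with strong clustering in condition A (five planted
clusters of radius 6) and weak clustering in condition B (one cluster of
radius 2), contrasted at the 30-bin component threshold:

```python
import numpy as np
from spatzone.simulate import LatticeSimSpec, simulate_two_condition_study
from spatzone import (select_positive_bins, connected_components,
                      same_type_density, fisher_contingency)

spec_spf = LatticeSimSpec(n_clusters=5, cluster_radius=6.0, seed=1)
spec_gf = LatticeSimSpec(n_clusters=1, cluster_radius=2.0, seed=2)
study = simulate_two_condition_study(spec_spf, spec_gf, n_slides=1)

results = {}
for label in ("A", "B"):
    matrix, scores, truth = study[label][0]
    pos = select_positive_bins(scores, matrix=matrix)
    res = connected_components(pos, condition=label)
    res.density, _ = same_type_density(pos, k=8)
    results[label] = res
    print(f"{label}: {len(pos)} positive bins, "
          f"{len(res.areas)} components, largest area {max(res.areas)}, "
          f"proportion {res.proportion:.3f}, "
          f"median density {np.nanmedian(res.density):.3f}")

c = fisher_contingency(results["A"], results["B"], threshold=30)
print(f"contingency table {c.table.tolist()}, p = {c.p_value:.3g} ({c.stars})")
```

prints

```
A: 426 positive bins, 8 components, largest area 174, proportion 0.880, median density 1.405
B: 76 positive bins, 5 components, largest area 13, proportion 0.276, median density 6.878
contingency table [[367, 59], [0, 76]], p = 4.3e-53 (****)
```

Condition A's positive bins are dense (median distance to the 8 nearest
same-type bins ≈ 1.4 lattice units) and 88% of them sit in aggregates, 367
of them in components larger than 30 bins; condition B's sparse bins form
only small components, and the Fisher contrast flags the difference.

The same stages run from the shell:

```bash
spatzone simulate study --out demo --seed 1
spatzone aggregate --scores A=demo/A_A1.scores.tsv --scores B=demo/B_B1.scores.tsv --out demo/agg
spatzone zonate --bins liver_slide --profile-genes Lpl,Zbtb20 --out zonation
spatzone qc --cells cells --out qc_out
spatzone ba --table ba_table.csv --out ba_out
spatzone run --config config.yaml --out run1   # end-to-end with manifest
```

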