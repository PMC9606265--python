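# engram

Quantitative analysis of day-to-day turnover of cFos ensembles in the
hippocampus, for labs working with activity-dependent tagging (TetTag-style
mKate2 / shEGFP reporters, CaMPARI2 photoconversion) and segmented confocal
sections. The package starts where spot detection ends: per-cell tables
(id, position in µm, label flags, channel intensities) plus a cell-body-layer
mask.

## What it computes

**Ensemble overlap against chance.** For a section with `N` granule cells,
`n_tagged` cFos-tagged, `n_cfos` currently cFos+ and `n_double` double-positive
cells,

    overlap/chance = (n_double / N) / [(n_tagged / N) · (n_cfos / N)]

together with the conditional overlap `n_double / n_tagged`. Double positives
come from <5 µm closest-pair spot matching (separate detections) or shared
labels (single segmentation).

**Spatial cluster overlap with permutation nulls.** Each ensemble is clustered
by connectivity-constrained Ward agglomeration (k-NN graph, k = n/10); cluster
quality is the clustering index C_c = ⟨median intra-cluster distance / minimum
extra-cluster distance⟩ (smaller = stronger). The cluster count n_c ∈ [5, 20]
is chosen against 500 maps with randomly redistributed cells; cluster convex
hulls are scored by best Jaccard overlap I_c between ensembles, with a 200-map
null for calibration.

**A negative-feedback simulator** of cFos refractoriness: induction hazard
gated by a slowly decaying suppressor (ΔFosB-like). The suppressed preset
reproduces a linear decay of normalized ensemble overlap to below chance
within 24 h; the persistence-plus-heterogeneity preset (CA1-like) never drops
below chance.

**Expression-state maps.** ΔFosB per cell by antibody difference
(pan-FosB − C-terminal FosB after 99th-percentile normalization), Spearman
rank correlation with permutation p, peak-scaled 2-D KDEs against 100
scrambled-pairing KDEs, per-gridpoint z-scores, and repressed / permissive /
other quadrant fractions.

**CaMPARI2 photoconversion.** Conversion ratio R/(R+G), photoconverted at
ratio > 0.3, analysis restricted to cells within 200 µm of the fiber tip.

Because the original imaging data are not deposited, a synthetic-data module
generates cell maps, intensity tables and CaMPARI tables with the same
statistical structure (sparse labels, tunable overlap-over-chance, planted
clusters with between-day drift, anticorrelated intensity components) and
known ground truth; all analyses are validated against it.

## Worked example

```
$ engram simulate-map --n-cells 5000 --rho 3 --rows 512 --cols 512 \
      --seed 2 --out map.csv --mask-out mask.png
wrote 5000 cells to map.csv
$ engram overlap --table map.csv --mask mask.png --gc-count 5000 --out overlap.json
overlap/chance = 4.222
```

The generated section has 150 tagged and 150 cfos cells (3 % each of 5000
granule cells), so the chance expectation for double positives is
0.0009 · 5000 = 4.5 cells; this draw contains 19, i.e. 4.2× chance (single
sections scatter widely around the planted 3× — the analysis scripts average
over replicate sections, giving 3.08 ± 0.14 over 50). The same JSON reports
both conventions: `overlap_over_chance` (4.22) and `conditional_overlap`
(0.127, the fraction of tagged cells currently cFos+).

```
$ engram feedback-sim --preset dg --n-cells 100000 --seed 1 --out traj.csv
tagged 8.3%; linear fit slope=-0.499/h r²=1.000
```

The suppressed preset tags ~8 % of cells and its normalized overlap falls
linearly (r² = 1.00) from ~12× chance at Δt = 0 to below chance at 24 h.

The numbered scripts under `analysis/` run the full study on synthetic data
(generate → overlap vs rho → cluster overlap vs null → feedback simulation →
expression states → photoconversion) and write tables under `results/`.

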