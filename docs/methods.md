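# Methods

This package re-implements, as seeded and tested code, the quantitative
analyses by which day-to-day turnover of cFos ensembles in the dentate
gyrus (DG) is established from segmented confocal sections: ensemble
overlap against chance, spatial cluster overlap against randomization
nulls, a stochastic model of cFos refractoriness, single-cell cFos/ΔFosB
expression-state maps, and CaMPARI2 photoconversion scoring. Real inputs
are per-cell spot tables (Imaris-style exports); since no imaging data are
available, a first-class synthetic generator produces tables with the same
statistical structure and known ground truth, and every analysis is
validated against that ground truth or an independent oracle.

## Coordinate and data conventions

Cell tables are CSV with columns `id, x_um, y_um, tagged, cfos` plus
intensity channels; positions are continuous µm with the origin at the
top-left corner of the layer-mask raster (pixel `(r, c)` covers
`[c·p, (c+1)·p) × [r·p, (r+1)·p)` for pixel size `p`). Masks are 8-bit
PNG/TIFF (nonzero = inside) or 0/1 text matrices. Cell bodies follow the
standardized 16×16-pixel footprint convention: a cell position is
admissible only when that footprint lies fully inside the mask, both in
the generator and in all randomizations. Footprints may overlap — no
exclusion radius is imposed, matching the randomization convention of the
original procedure, which standardizes neuron size but does not forbid
contact.

## Synthetic cell maps

`make_layer_mask` draws the DG granule-cell layer as two curved parabolic
blades (or a single band for CA1), with a smooth seeded perturbation;
band thickness must exceed the cell footprint. `sample_cellmap` places
`n_cells` cells uniformly over admissible pixels and assigns labels by a
two-stage scheme: the tagged set is a uniform subset of size
`round(f_tagged·n)`; the number of double positives is binomial with
per-tagged-cell probability `rho·f_cfos`, so its expectation is exactly
`rho·f_tagged·f_cfos·n`, and the remaining cfos labels fall uniformly on
untagged cells. `rho` is therefore the planted overlap-over-chance; the
calibration is verified empirically over 200 seeds for
`rho ∈ {0, 1, 3, 12}` (the 12× value mirrors the same-day coupling
regime, and ~1–5 % label fractions mirror sparse DG ensembles).

Planted spatial structure scatters labeled cells around `k` centers
(Gaussian spread, centers dart-thrown with a minimum separation, default
6× spread); the cfos ensemble's centers can be displaced by `shift` µm in
a seeded random direction to emulate ensembles that drift between days.
Cluster-recovery analyses default to maps of 1000 cells with 10 % label
fractions, spread 50 µm and separation 115 µm on a 1024² µm section:
clusters strong enough to be detected, but weak enough that randomized
maps occasionally beat them — the regime in which the optimal-cluster
procedure is informative (see below). These are design constants of the
study conditions, chosen once.

## Ensemble overlap (per section)

With `N` granule cells, `n_tagged` mKate2+ (cFos-tagged), `n_cfos`
shEGFP+ (currently cFos+) and `n_double` double-positive cells:

    frac_x      = n_x / N
    expected    = frac_tagged · frac_cfos
    over_chance = frac_double / expected
    conditional = n_double / n_tagged

Both reporting conventions coexist in the field — percentages conditional
on the tagged ensemble, and the chance-normalized fraction of all
granule cells — so both are emitted. `N` comes from the map's known
ground truth (synthetic data) or from layer measure × published density;
the result records which. When the two ensembles come from separate spot
detections, double positives are greedy closest-pair matches at
< 5 µm (ties by index order, each spot used once); when one segmentation
produced a single cell table, a cell is double positive iff it carries
both labels. Aggregation across sections is by summing counts before
taking fractions.

## Spatial cluster analysis

Each ensemble (always including double positives) is clustered separately
by connectivity-constrained agglomerative clustering, Ward linkage, on a
symmetrized k-nearest-neighbor graph with `k = floor(n/10)` (minimum 1).
One Ward tree is built per dataset and cut at every candidate cluster
count `n_c ∈ [5, 20]`; the cut (undoing the last `n_c − 1` merges) is
verified in tests to reproduce scikit-learn's estimator exactly.
Cluster quality is the clustering index

    C_c = ⟨ median_{j∈cluster(i)} D_ij / min_{j∉cluster(i)} D_ij ⟩_i

averaged over clustered neurons (singleton members, and points whose
nearest outsider is coincident, are excluded and listed); smaller C_c
means stronger clustering. The minimum in the denominator is over
same-ensemble outsiders, since clustering is per ensemble.

The optimal `n_c` compares each candidate against 500 artificial maps in
which tagged-only, cfos-only and double-positive cells (a third type,
counts preserved) are redistributed uniformly over admissible pixels.
The proportion of artificial sets clustering more strongly than the data
is computed per `n_c`; the smallest proportion wins and ties go to the
largest `n_c`. Because the proportion saturates at zero once clusters
beat every artificial set at many `n_c`, the tie rule selects the largest
saturated candidate; recovery of a planted `k` is therefore only
meaningful — and only claimed — for maps whose clustering strength is
moderate, and recovery is assessed as the median optimal `n_c` over a few
replicate maps, as one would across images of one brain.

Cluster footprints are convex hulls; each tagged cluster scores its best
Jaccard index (intersection over union of hull areas) against the cfos
clusters. Degenerate hulls (< 3 points or collinear) score 0 with a flag
so sparse artificial sets remain analyzable. A further 200 artificial
maps give the null distribution of best-I_c values; by default they are
clustered at the empirical optimal `n_c` (a `recompute_nc_in_null` switch
re-optimizes inside every null set; it is off by default because the
optimization itself costs 500 clusterings per set and the percentile
calibration is already uniform under the default, as verified by test).
The per-map summary is the median best-I_c; its percentile is the
mid-rank among null-set medians on the `(r + 0.5)/(n + 1)` grid, which is
uniform under exchangeability.

Random draws for artificial sets use one root seed with per-set
substreams, so enlarging the set count never reshuffles earlier sets.

## Negative-feedback simulator

Discrete-time (1 h step) per-cell model. A non-expressing cell inducts
with probability `h0 · propensity_i · gate(S_i)`; induction adds
`suppressor_gain` to a suppressor `S_i` that decays with a long half-life
(ΔFosB-like, default 200 h); the reporter stays visible for
`reporter_lifetime` (default 24 h — the stable shEGFP reporter outlives
cFos itself); at expiry a cell can renew expression with `sustain_prob`
per step. `propensity_i` is lognormal with unit mean. The tagged
ensemble is everyone who expressed during the 24 h tagging window; the
similarity trajectory reports, per hour after the window closes, the
fraction of tagged cells expressing, the population expressing fraction,
and their ratio (normalized overlap; 1 = chance).

Presets (documented constants, not fits to data):

* `dg` — hard gate (threshold 0.5, gain 1): one induction suppresses
  re-expression for days. Induction times are near-uniform across the
  window, so overlap decays *linearly* as reporters expire, reaching zero
  (below chance) at 24 h; `h0 = 0.0035` puts the normalized overlap near
  12 at Δt = 0 and tags ~8 % of cells.
* `ca1` — gate off, `sustain_prob = 0.5`, heterogeneity SD 1: persistent,
  heterogeneous expression keeps normalized overlap ≥ 1 at every lag
  (positive dependence between tagging and later expression).
* `independent` — gate off, no heterogeneity, no sustain: renewal-process
  control whose normalized overlap is 1 for lags beyond the reporter
  lifetime (closed-form `P(on) = 1 − (1 − h0)^L` verified in tests).

The below-chance mechanism is explicit: suppression makes re-expression
of tagged cells rarer than the population rate, pushing the ratio under 1.

## Expression states (cFos vs ΔFosB)

ΔFosB is quantified by antibody difference: each channel (pan-FosB,
C-terminal FosB, cFos) is normalized by its own 99th percentile (robust
to hot pixels) and ΔFosB = max(pan − cterm, 0). This calibration is
meaningful when both FosB channels' upper percentiles reflect the same
protein scale; the generator therefore gives FosB-proper a wide lognormal
distribution with a right tail, and tests verify the recovered signal
ranks with the planted component (Spearman > 0.9).

The (cFos, ΔFosB) plane is analyzed by a peak-scaled Gaussian KDE
(axis-aligned kernels, per-axis Scott bandwidth `n^{-1/6}·sd` or a scalar
override) against 100 scrambled KDEs (ΔFosB permuted against cFos:
marginals preserved, pairing broken). Per-gridpoint z-scores use the
scramble mean and SD (floored at 1e-6); each scrambled KDE is peak-scaled
before aggregation (a switch rescales the aggregate instead). Quadrant
thresholds default to the midpoints between the two strongest positive-z
local maxima per axis — the repressed (low cFos / high ΔFosB) and
permissive (high cFos / low ΔFosB) modes — and are overridable; the
placement is recorded in the output. State fractions partition the
analyzed (labeled) cells. The Spearman correlation carries a seeded
permutation p-value (9999 shuffles, add-one rule).

## CaMPARI2 scoring

Conversion ratio R/(R+G); photoconverted iff strictly > 0.3 (the printed
cutoff); analysis restricted to cells within 200 µm of the fiber tip
(inclusive boundary, "within"); cells with R+G = 0 are excluded from
denominators and counted in a diagnostics field. The generator draws
reactivated cells' ratios strictly above and others strictly below the
cutoff via scaled Beta distributions, with synthetic fiber distances
uniform on [0, 400] µm — distance is a scalar covariate, not a modeled
light field, since only the filter needs exercising.

## What the generator does and does not emulate

It reproduces: two-blade layer geometry, sparse labels, exact-count label
dependence with tunable overlap-over-chance, clustered label positions
with between-day drift, bimodal anticorrelated intensity components with
an antibody-difference-recoverable ΔFosB, and bimodal conversion ratios.
It does not reproduce: nuclei shapes or image noise (the pipeline starts
at spot tables), 3-D structure (analyses are 2-D, as the projected spot
workflow effectively is), biological coupling between position and
intensity, or optics of photoconversion. Passing tests therefore
validate the statistical machinery, not segmentation quality on real
images.

## Problem sizes and numerical choices

Test and analysis problem sizes are chosen so the full suite runs on one
CPU in minutes: overlap calibration at 5000 cells × 200 seeds;
cluster-recovery maps of 1000 cells (100 labeled per ensemble) with 500
artificial sets; null-calibration maps with 50-point ensembles, candidate
range [5, 12], 25 optimization sets and a 200-set I_c null over 50 seeds;
simulator runs at 100,000 cells; expression tables of 2000 cells with 100
scrambles. Degenerate inputs (empty ensembles, singleton clusters,
collinear hulls, zero-intensity cells) are either excluded-and-flagged or
raise a parameter error, as documented per function. All randomness
derives from explicit integer seeds; there are no hidden entropy sources.

## Known limitations

The optimal-n_c procedure is uninformative for very tight clusters (the
proportion statistic saturates and the tie rule returns the upper range
bound) and noisy for ensembles under ~50 points. The feedback model is a
minimal stand-in with the qualitative behavior of the biology — linear
decay below chance with suppression, persistence above chance without —
and its parameters are presets, not estimates. The antibody-difference
ΔFosB recovery degrades when the two FosB channels' intensity scales
diverge at the calibration percentile.
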