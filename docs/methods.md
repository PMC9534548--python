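# Methods

This note documents the models implemented in `syncytia`, the
assumptions behind the synthetic-data generators, and the numerical and
statistical choices where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Network-diffusion model and apparent permeability

A confluent monolayer is represented as a graph of cells (area `A_i`
μm², perimeter `p_i` μm) with contact edges carrying shared boundary
lengths `L_ij` μm. Each cell is well stirred — intracellular diffusion
is fast compared with junctional transfer — so the dye obeys the linear
system

    dC_i/dt = (P / A_i) · Σ_j L_ij (C_j − C_i),

with a single junctional permeability `P` (μm/min). Total mass
`Σ A_i C_i` is exactly conserved; any connected graph relaxes to the
mass-weighted mean concentration.

**Integrator.** Explicit Euler with automatic sub-stepping. The
stability bound is the reciprocal of the fastest per-cell relaxation
rate `P·ΣL_ij/A_i`; sub-steps are sized at 2% of that bound because a
step near the bound, while stable, biases the effective rate by
~`dt·rate/2`, which is material when recovered time constants feed a
2%-level round trip. An exact matrix-exponential path (`method="expm"`)
is available for small graphs and is used where machine-precision
agreement with closed forms matters. Concentrations are clipped at zero
after each output step as a guard; with stable steps the scheme cannot
produce negatives.

**Permeability from a recovery time constant.** When a bleached cell's
neighbors act as an effectively constant reservoir, its recovery is
monoexponential with `τ = A / (P · L_total)`. Identifying the total
contact length with the cell perimeter gives the geometric estimator

    P_app = A / (p · τ)   [μm/min],

the unique arrangement of the three measured quantities with the right
units. In a real monolayer neighbors deplete, so `P_app` from a full
network recovery is an *apparent* value biased slightly upward relative
to the reservoir idealization; the tests characterize this bias rather
than correct it, matching how whole-cell FRAP is analyzed in practice.

## FRAP fitting

Post-bleach samples are fitted to
`F(t) = plateau − (plateau − F0)·exp(−(t − t_b)/τ)` by bounded
least squares (`scipy.optimize.curve_fit`), initialized from a
log-linearized regression; τ is bounded to (sampling interval, 100×
trace span). **No-recovery rule:** the trace is declared non-recovering
(τ = ∞, hence `P_app = 0` — the connexin-null phenotype) when the
recovery *realized within the observed window*,
`(plateau − F0)(1 − exp(−span/τ))`, is below 2× the residual SD. The
realized amplitude is used rather than the fitted amplitude because a
flat noisy trace is often best fitted by an enormous τ whose
extrapolated amplitude is large while the data never actually rise.
Drift correction by a remote-cell reference (divide and renormalize) is
available but off by default: the standard protocol normalizes only to
the prebleach intensity.

Intracellular diffusivity estimates (small-region bleaching in sparse
cells) are summarized by the recovery rate constant per dye and its
rank correlation against molecular weight; the expected relation is
negative.

## Dye-mixing statistics

Channels are normalized to the mean signal of paired single-dye
mono-culture controls. The coupling coefficient
`CC = 2·min(F_O, F_V)/(F_O + F_V)` is computed per pixel; a pixel
enters the map only when its summed normalized signal exceeds 3× the
background SD (estimated from the darkest image corner unless
supplied). Excluded pixels are absent (NaN), never zero-filled: a dark
pixel carries no mixing information and zero-filling would masquerade
as "unmixed". With a segmentation label image the per-cell CC is the
median over the cell's included pixels; the pixel remains the primitive
unit. Optional linear unmixing hooks exist for bleed-through, which the
imaging protocol already minimizes by sequential acquisition.

**Cytometry gating.** Off-channel thresholds are the 95th percentile of
each single-dye mono-culture's signal on its *other* detection channel
— per mono-culture, the only self-consistent reading of percentile
gating. An event above both off-channel thresholds is dual-positive. By
construction, a fraction `α = 1 − percentile/100` of genuinely
single-positive events still exceeds their off-channel threshold, so
the raw dual-positive fraction overestimates the exchanged fraction by
`(1 − f)·α`. The default estimator inverts this analytically,
`f = (p_dual − α)/(1 − α)` clipped to [0, 1], making it unbiased while
an acute-mix null still reads ≈ 0; `fp_correction=False` returns the
raw gated fraction. Doublet gating is a pass-through: synthetic events
are singlets by construction.

## Rescue analysis

KO mono-culture wells give the calibration `GFP = g·SRB`, fitted
linear-through-origin pooled over days (the simplest form consistent
with both signals measuring the same biomass); per-day mean residuals
are reported so nonlinearity would be visible. Expected GFP for a
co-culture is `g · SRB · f_KO` with `f_KO` the seeded *cell* fraction
(e.g. 0.5 for 1:1).

**Enrichment significance.** The measured-vs-expected comparison is a
two-factor analysis (trajectory kind × day) run on per-well
`log(GFP/SRB)` ratios: co-culture wells contribute their seeding-
corrected log ratio, KO mono-culture wells their raw log ratio. Two
reasons for this form rather than ANOVA on raw signals: (i) plate
readings grow ~50-fold over a week with multiplicative noise, so raw
residuals are wildly heteroscedastic; (ii) every expected value shares
one fitted calibration slope, whose error shifts all expectations
coherently — invisible to a raw-scale residual but captured here
because the calibration wells sit in the comparison as their own group.
A ratio is flagged when p < 0.05 *and* endpoint measured exceeds
expected. A seeded within-day permutation test over well labels is
provided as a nonparametric oracle; wells are exchangeable under the
null in this formulation. Wells seeded without KO cells are excluded —
enrichment of an absent labeled compartment is undefined. The endpoint
defaults to the last common day. With a single replicate only the
enrichment ratio is reported.

**pH summaries.** Inputs are already calibrated pH time courses or
per-cell pH values (indicator chemistry is upstream). The
acid-extrusion rate is the linear slope over a fixed window (default
5 min) after the trace nadir; a flat window reports 0 (transporter-null
or inhibitor phenotype) and a negative slope is returned as-is with a
warning flag. Resting-pH spread is measured after offsetting each
distribution to its histogram mode (default bin 0.05 pH), reported as
SD and central-90% width.

## Histology pipeline

The nuclear (Hoechst) channel is thresholded (Otsu by default),
dilated with a disk so neighboring nuclei fuse, and regions below a
minimum size are dropped; the union is the tumor mask. The phrase
"rolling ball, 50 pixels" in the originating protocol is read as
morphological dilation with radius 50 — the stated purpose is to
*expand* beyond nuclei, which a rolling-ball background subtraction
would not do. GFP background mean and SD are computed over the full
mask (clusters included, matching the protocol's order of operations);
pixels strictly above `mean + k·SD` for k ∈ {4, 5, 6} are retained.
Connected components (8-connectivity) with area in
[`min_cluster_px` = 10, 5% of tumor area] are counted; larger particles
are treated as noncellular stains. Totals are summed over slides, and a
concordance report checks that group orderings agree at all three k.
Small/large cutoffs are configuration parameters because the protocol
does not state them.

## Bimodality classification

One- and two-component Gaussian mixtures are fitted by EM with seeded
restarts. The verdict is bimodal only if the two-component model wins
on BIC *and* both weights are ≥ 0.10 *and* the means are ≥ 2 pooled
SDs apart; the cutoff is the equal-posterior point between the means.
The BIC difference, weight rule and separation rule are all invariant
under affine transforms of the input, so the verdict is scale-free and
the cutoff transforms with the data. This is a deliberately lean
decision surface: background-bin handling and tail-shape chi-square
refinements found in specialized expression-mixture tools are out of
scope here, where bimodality is supporting context for grouping cell
lines into low/high expressors.

## Synthetic-data generators

Each generator's defaults are the study conditions of the assay it
emulates, and its truth record suffices to predict the downstream
result without re-reading the data. Identical seeds give byte-identical
outputs.

* **Cell graphs**: jittered hexagonal lattices (regular hexagons at
  mean area 400 μm², ±10% area jitter); contact lengths are the shorter
  of the two hexagon sides, so contact totals never exceed perimeters.
  Connected by construction.
* **FRAP traces**: the diffusion model itself generates recoveries
  (half-bleach, 0.25-min sampling, 20 min), with optional neighbor
  clamping to realize the reservoir geometry under which the
  monoexponential estimator is exact, plus additive Gaussian noise.
* **Co-culture images**: non-overlapping disk cells assigned pure dye
  A, pure dye B, or (with the planted probability) a mixture drawn
  around 0.5; paired single-dye control images are emitted for
  normalization. No optics are simulated (no PSF; bleed-through only as
  an optional linear term).
* **Cytometry events**: bivariate log-normal clusters (signal ~1e4,
  log-SD 0.35; background ~50, log-SD 0.4), n = 5000 per population;
  mono-culture and acute-mix tables accompany every co-culture table.
* **Growth plates**: two-compartment logistic growth with shared
  carrying capacity (r = 0.7/day for both compartments under the null,
  capacity 2×10⁵, seeded 2000 cells/well across KO:WT ratios 2000:0,
  1500:500, 1000:1000, 500:1500, 0:2000; days 0–7; five replicates; 3%
  multiplicative read noise). Rescue inflates the KO rate by
  `rescue_strength ×` the current WT fraction — at 1:1 seeding,
  `rescue_strength = 1` is a ~1.5× KO growth benefit.
* **Histology slides**: 1024×1024 px, elliptical tumor (440×350 px)
  carrying dense nuclear spots; the GFP channel is a diffuse Gaussian
  staining background over the whole section (mean 500, SD 20,
  truncated at ±4 SD so no stray background pixel can cross a k ≤ 6
  threshold) plus rectangular clusters of exactly the requested pixel
  area at 12 background SDs. The cluster load is kept below ~1% of the
  mask so that the clusters' own contribution to the measured in-mask
  SD does not lift the k = 6 threshold above them. Tests use dilation
  radius 3 on these slides (nuclei are 5 px apart; the default radius
  50 corresponds to slide-scanner scales).
* **Expression cohorts**: one or two Gaussians on the log2 scale,
  n = 79 lines by default.

**What passing on synthetic data does and does not show.** The
generators reproduce the statistical structure the estimators rely on
(exponential recoveries on a contact graph, log-normal cytometry
clusters, multiplicative plate noise, Gaussian image background) but
not microscope optics, segmentation error, uneven illumination,
cytometer spillover matrices, spatially correlated histology artifacts,
or growth interactions beyond a rate benefit. Green tests therefore
validate the estimators' correctness and calibration under their stated
assumptions, not robustness to every artifact of real acquisitions.

## Problem sizes and runtime

The test suite and acceptance script run at desk scale: diffusion
graphs up to 200 cells, 50 noisy FRAP replicates, 5000-event cytometry
tables, 200 simulated plates each for null error and power, single
1024² histology slides, and 200 expression cohorts. These sizes were
chosen to give stable statistics (binomial/3-SD bands, ±2% on rates)
while keeping the full pipeline in the tens of seconds on one CPU.

## Known limitations

* Heterotypic channels and per-isoform conductances are not modeled;
  coupling enters as one scalar permeability.
* Geometry is 2-D; no 3-D tissue or spheroid diffusion.
* The monoexponential/reservoir assumption biases `P_app` upward on
  full networks (quantified by the round-trip tests, not corrected).
* The enrichment analysis detects a growth benefit; it does not infer
  its mechanism, and no growth model is fitted to real plates.
* The bimodality classifier's information-criterion rule is an
  approximation to more elaborate mixture-refinement heuristics.
* FCS files are not read directly; cytometry enters as CSV event
  tables.
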