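# Methods

This note documents the models and procedures `mitoscreen` implements,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Screen model and normalization

A well measurement is the pair of whole-well fluorescence intensities
(F590 red, F520 green) of the JC-10 MMP dye; the readout is the
dimensionless ratio F590/F520, recomputed from the channels whenever both
are present (a supplied ratio column is cross-checked at 1e-6 relative
tolerance). Each plate's values are divided by the arithmetic mean of its
own WT-control well ratios, making the per-plate mean of normalized WT
wells exactly 1 and the normalization invariant to any common rescaling
of a plate's raw intensities (illumination, gain, dye lot). Treatments
run on duplicate plates; the reported value is the mean of the replicate
normalized values and reproducibility is the percent coefficient of
variation with the sample SD (n−1) — duplicates are two draws, and the
sample SD is the conventional CV numerator at small n. Treatments present
on a single plate are kept and flagged, never dropped.

Drug plates carry 3 WT, 3 MT and 2 FCCP wells; siRNA plates carry 4 WT
and 4 MT wells and up to 80 treatments. Well addresses use the microplate
convention (letter row + 1-based column, "B7").

## Quality control

Z′ = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg| with sample SDs, computed per
plate on normalized ratios (equivalent to raw values up to the plate
scale). The positive group is the untreated WT wells and the negative
group the untreated MT wells: the screen asks whether a treatment moves
MT toward WT, so that window — not the WT-vs-FCCP assay range — is the
relevant separation, and including the fully depolarized FCCP wells would
inflate it. FCCP wells are kept as an assay-range control. Low-Z′ plates
are reported, not discarded. The screen-level report summarizes duplicate
CVs (mean, median, fraction below 10% and 15%, and an all-below-15% flag).

## Mixture model and hit calling

The value distribution of a screen decides the hit rule. With two
biological populations (non-responders and rescuers) the pooled SD mixes
between- and within-population variance and a pooled μ + 2σ cutoff is
meaningless; with one population it is the natural rare-tail criterion.

`fit_gmm` fits k ∈ {1, 2} Gaussian mixtures by EM:

* k = 1 is the closed-form MLE (mean, 1/n-denominator SD).
* k = 2 starts from a deterministic one-dimensional two-means partition
  (Lloyd iterations seeded at the 10th/90th percentiles) and iterates
  E/M steps until the relative log-likelihood change falls below
  tol = 1e-8 (max 500 iterations). The log-likelihood is asserted
  non-decreasing at every iteration. A component SD falling below
  sd_floor = 1e-4 (normalized-ratio units) or a vanishing weight
  triggers a restart from seeded Dirichlet-random responsibilities, at
  most 5 times.
* BIC = −2·loglik + p·ln n with p = 3k − 1 free parameters.

The two-means initialization is a deliberate choice over a median split.
A screen with planted high-value rescuers admits two EM fixed points: the
screening-relevant one (dominant non-responder component + low
component), and a higher-likelihood one in which a broad component
absorbs both the low population and the extreme rescuers. The median
split starts with one very wide group and converges to the latter, which
misclassifies the screen as unimodal; the cluster-structure start
converges to the former, which is the fit the hit rule is defined on (and
the solution a k-means-initialized standard EM implementation returns).

A screen is labelled bimodal only if all three hold: BIC(k=1) − BIC(k=2)
> 10 (strong evidence on the usual BIC scale), smallest weight ≥ 0.05
(both components non-negligible), and separation |μ₂ − μ₁|/max(σ₁, σ₂)
≥ 2 (modes genuinely apart). If the k=2 fit collapses persistently
(near-degenerate data), the screen is treated as unimodal. Bimodal
screens threshold at μ_high + 2σ_high of the higher-mean (dominant)
component; unimodal screens at pooled mean + 2·sample SD. The comparison
is inclusive (≥). Hits are called on replicate-aggregated values, and no
multiple-testing correction is applied at the primary stage — hit lists
feed independent biological validation, not inference.

## Imaging quantification

Cells are segmented by thresholding the red+green sum (Otsu by default,
fixed threshold optional), 8-connected components, minimum area 50 px.
The per-cell ratio is mean(red)/mean(green) over the cell's pixels —
ratio of means rather than mean of per-pixel ratios, which is unstable
for near-zero green pixels — and the per-image statistic is the
unweighted mean over cells.

Mitochondrial objects are 8-connected components of a binary mask with
area ≥ 4 px. Axis lengths are 4·√eigenvalue of the pixel-set second
central moment matrix (the moment-matched ellipse); AR = major/minor.
FF = perimeter²/(4π·area), so a circle scores 1 and elongated or complex
outlines score higher; some literature uses the reciprocal, so note the
direction: *fragmentation into rounder organelles lowers both AR and FF*.
Perimeter is the length of the 0.5-level marching-squares contour of the
mask after light Gaussian smoothing (σ = 0.8 px). Unsmoothed boundary
polygons systematically overestimate smooth outlines (≈5–7% for a
radius-20 disc, enough to push a disc's FF above 1.1), while Crofton-type
estimators underestimate thin rectangles by a similar margin; the
smoothed subpixel contour tracks true perimeter within a few percent for
objects of minor width ≥ 3 px. Very small blocky objects (≲10 px) are
underestimated — a known limitation. Single-pixel-wide objects (zero
minor axis) are excluded.

## Calcium transients

Traces are per-ROI fluorescence at dt = 2 s. Baseline F0 is the 10th
percentile of the raw trace — robust when transients occupy a minority of
frames. Because that percentile sits slightly below the noise center, the
detector estimates the quiescent level of F/F0 itself: median first, then
(two-pass) mean and sample SD of sub-threshold frames after excluding
frames above a MAD-based provisional threshold. Events are contiguous
excursions above center + k·σ_noise (k = 3) lasting at least 2 frames
(rejecting single-frame noise spikes); peaks closer than 4 s merge.
Amplitude is peak F/F0; frequency is events per minute of the recording
span dt·(n−1); a cell oscillates if it shows ≥ 2 events. Group statistics
follow the screening convention: % oscillating over all cells; amplitude
and frequency mean ± SEM over oscillating cells only. All thresholds are
arguments (and CLI flags). Detection is exactly invariant to rescaling a
trace, since F/F0 cancels gain.

## Neurite morphology

SWC files are validated into a rooted tree (unique ids, single root,
no cycles or orphans). Edges are straight polylines between node
coordinates without radius weighting. Total length sums parent–child
Euclidean distances; terminal points are non-root leaves (optionally
filtered by SWC type code, off by default); the Sholl count at radius r
is the number of edges whose endpoint distances from the soma straddle r
(d_near < r ≤ d_far), each edge counting at most once per sphere — the
endpoint-straddle convention, documented because a segment can in
principle cross a sphere twice.

## Synthetic data: what it emulates

The generators reproduce the statistical structure of the screening
campaign so recovery can be asserted end to end; they are pure functions
of config + seed (bit-reproducible).

**Drug screen** (defaults): 1,134 compounds, 88 per plate layout,
duplicated. Background normalized values follow the two-component
mixture with dominant component (0.734, 0.085, weight 0.91); the low
component (μ ≈ 0.2118, σ ≈ 0.1064) is derived by moment matching so the
pooled mean/SD equal 0.687/0.173 — both identities are verified against a
brute-force mixture-moment oracle in the tests. For hit-count runs,
background draws are rejection-capped at 0.90 and 20 planted rescuers
are uniform in [0.95, 1.20], so the planted-hit count is exact by
construction; calibration runs disable the cap. **siRNA screen**: 336
genes, Normal(0.710, 0.084) background with a configurable right tail
(default 5% of genes shifted by +1σ plus a half-normal), cap 0.87, 9
planted rescuers in [0.95, 1.10].

Plates are assembled backwards from the target normalized values:
control wells are drawn with *exact* per-plate sample moments
(standardized Gaussian draws), and treatment raw ratios are
back-computed as target × WT-mean, so normalization reproduces the
targets to machine precision and each plate's Z′ equals a target drawn
uniformly from the configured band ([0.10, 0.50] drug; [0.302, 0.370]
siRNA — the campaign's reported per-plate ranges). Duplicate noise is
symmetric, t·(1 ± d), making the replicate mean exact and the duplicate
CV equal to its drawn value; per-compound CVs come from a Beta scaled to
[0, 15%) with mean `well_noise_cv` (default 8.5%), which guarantees the
all-below-15% acceptability criterion.

**Calcium traces**: oscillating cells (Bernoulli p) receive a
truncated-Poisson (≥ 2) number of events whose rate is solved
numerically so the *conditional* mean equals rate·duration — without
this, the frequency averaged over oscillating cells overshoots the
nominal rate by the truncation bias (~11% at 0.73/min). Events have a
16 s refractory separation, double-exponential shapes (rise 1.5 s, decay
2.5 s), peaks snapped to the frame grid so the sampled peak equals the
drawn amplitude (Normal, default SD 0.3, floored at 1.2 F/F0), and 1%
additive Gaussian noise on a baseline of 100.

**Images/masks/trees**: non-overlapping discs with planted per-cell
ratios and multiplicative channel noise; non-contacting rotated ellipses
with sampled axis ratios (semi-minor 4–6 px); random binary-branching
trees with exact length/terminal bookkeeping.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: spatial plate effects (edge wells, gradients),
compound toxicity and fluorescence interference, segmentation errors
from touching cells or uneven illumination, bleaching and focus drift in
traces, and reconstruction errors in trees. The duplicate-noise and
control-moment constructions are deliberately exact rather than sampled,
trading realism for sharp recovery assertions; the acceptance quantities
would survive relaxing them at the cost of wider tolerances.

## Problem sizes and determinism

Tests and the acceptance script use the campaign's own sizes (1,134 and
336 treatments; 363-cell trace populations; the percent-oscillating rate
additionally on 1,500 cells to shrink its binomial sampling error), which
run in seconds. Every stochastic routine takes an explicit seed; nothing
uses global random state.

## Known limitations

* The EM fitter supports k ≤ 2; screens with more structure need an
  external model.
* Perimeter (hence FF) is biased low for objects under ~10 px.
* The calcium detector assumes a stationary baseline; slow drift would
  require detrending before `detect_events`.
* The siRNA right-tail model is an assumption (the campaign did not
  characterize it); `tail_fraction`/`tail_shift` exist to vary it in
  sensitivity analyses.
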