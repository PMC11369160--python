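# Methods

This note documents the models, estimators and numerical choices behind
`spirocell`, and what the synthetic-data studies do and do not show about
real microscopy data.

## Coordinate and unit conventions

All continuous coordinates are micrometres with the image-array
convention: origin at the top-left pixel corner, x rightward, y downward.
Times are seconds (FRAP rates are per minute, declared per series).
Pixels appear only when images are rendered or sampled; every writer
records the pixel size and frame interval in the TIFF metadata.

## Synthetic cells and images

A cell is a tube: an open centerline (straight, circular arc, sinusoid,
or projected helix — the latter two share one functional form) swept by a
disc of radius `half_width`, giving hemispherical poles.  Arcs and
sinusoids were chosen because both have closed-form or
quadrature-checkable arc lengths, which supplies independent oracles for
sinuosity and boundary-length tests.  The fluorescent ribbon is a band
hugging the convex-side membrane: pixels on the outer side with
centerline distance in [r − 2·band_halfwidth, r] are boosted β-fold.
Rendering applies a Gaussian PSF (σ = 0.1 µm default), then Poisson shot
noise (configurable gain) and additive Gaussian read noise — the standard
sCMOS approximation.  Defaults r = 0.4 µm and R_c = 5.7 µm are package
choices of realistic dimensions for a spiral-shaped alphaproteobacterium;
they are not measured values, and outputs flag them as package defaults.

What the generator does **not** emulate: optical sectioning, structured
illumination, fluorophore photophysics beyond a constant activation rate
and fixed blink count, cell crowding, and segmentation-confounding debris.
Passing tests therefore demonstrate correctness of the estimators on
clean, known-truth data, not robustness to every real-world artefact.

## Morphometry

* **Sinuosity** = centerline arc length / pole-to-pole Euclidean
  distance.  This is the standard tool definition (dimensionless, 1 for a
  straight cell); the semicircle value π/2 and a quadrature oracle for
  sinusoids pin the implementation.
* **Centerline extraction**: rasterize the outline, skeletonize, take the
  longest skeleton path (two Dijkstra sweeps; exact on the tree-shaped
  skeletons of tube cells), smooth with a cubic spline whose smoothing
  parameter tolerates ~half-pixel deviations, and extend the ends along
  their tangents to the outline so the centerline spans pole to pole.
  Discs and branched blobs raise errors rather than returning a
  meaningless axis.
* **Inner/outer partition**: the convex (outer) side is the sign of the
  integrated signed curvature of the centerline; cells whose mean
  |curvature| falls below a configurable threshold (default 0.02 µm⁻¹)
  are flagged "not clearly curved" instead of partitioned.  Outline
  vertices are classified by the side of their nearest centerline
  segment; pole caps (vertices projecting within 1.5·r of a centerline
  endpoint) are excluded.  Each half keeps the outline's own cyclic
  vertex order — ordering by projected centerline position would zigzag
  among near-coincident vertices and inflate boundary lengths.
* **Outer/inner ratio**: intensity is integrated per unit scan length
  from the centerline to the outline along normals on each side, after
  subtracting the median intensity outside all outlines.  Per-unit-length
  normalization makes ratio = 1 the true null on uniform signal despite
  the outer half being geometrically longer.
* **Superplot statistics**: Welch's t-test on replicate means (the
  biological replicate is the unit of inference); a pooled-cell mode
  exists behind a flag.  Degenerate zero-variance inputs return t = 0,
  p = 1 when the means agree.
* **Area overlap** is 100·|A∩B|/|A| with the first-named channel as
  denominator; the symmetric Jaccard index is reported alongside because
  the denominator convention is not universal.

## FRAP

Normalization follows the double-ratio form
F_t = (R_t/R_PB)/(W_t/W_PB), which cancels uniform acquisition
bleaching exactly (asserted as an algebraic identity in the tests).  The
post-bleach trace, rebased to t = 0 at the first post-bleach frame, is
fitted to f(t) = A·(1−e^(−r·t)) + N by bounded trust-region least squares
with eight multi-starts over log-spaced rates; t_1/2 = ln2/r.

Percentage recovery is PR = 100·A·(1−e^(−r·T))/(1−N), the recovered share
of the bleached depth over the observation window T.  The effective
amplitude A·(1−e^(−r·T)) equals A whenever recovery completes within the
window; for flat immobile traces the plain parameters sit on two
degenerate ridges (r → ∞ trades A against N; r → 0 inflates A at fixed
A·r), where the effective form correctly reports ≈0.  The whole-cell
trace in the generator carries only the acquisition decay; the small step
loss from the bleach pulse itself is not modelled, which biases nothing
in the double normalization.

## Single-particle tracking

* **Detection**: median prefilter, multi-scale LoG at the scale of the
  expected 0.5-µm diameter, SNR threshold 5 computed from the
  centre-pixel value over a robust (MAD) noise estimate — the centre
  value rather than the patch maximum, so flank responses of bright
  neighbours are rejected — followed by intensity-weighted sub-pixel
  centroids and distance-based duplicate suppression.
* **Linking**: per-frame optimal assignment (Hungarian) within 300 nm,
  then gap closing of track ends to later starts across one missing frame
  within 500 nm, then removal of tracks shorter than 5 observations.
  Per-frame optimal matching implements the "simple" two-step scheme; a
  global multi-frame LAP is intentionally out of scope.
* **MSD**: time-averaged per track with the last observation of each
  track excluded (track-ending artefacts), ensemble-averaged at the first
  four lag multiples, linear fit MSD = 4·D·τ + b.  The intercept
  reproduces the localization noise floor 4σ².
* **SQD fit**: single-frame squared displacements pooled over tracks;
  the empirical CDF on a 200-point quantile grid is fitted by
  Levenberg–Marquardt least squares to the exponential mixture
  P(x) = 1 − Σ fᵢ·e^(−x/(4DᵢΔt+4σ²)).  Scales are log-parameterized and
  fractions go through a softmax, so constraints hold by construction; a
  fast EM pass on the displacements supplies the optimizer's starting
  point (the quantile-grid least squares remains the estimator).  The
  localization term 4σ² is a **known input**: a single-lag CDF only
  identifies the combined scales, so σ cannot be fitted jointly with the
  Dᵢ; passing σ = 0 reproduces tools that omit the correction.  With
  `conditions` given, one set of coefficients is fitted globally and only
  the fractions are free per condition — the shared-coefficient
  convention for comparing strains.
* **Model selection** (up to three states): K+1 replaces K only when an
  extra-sum-of-squares F-test has p < 0.05 *and* BIC drops by more than
  5%.  Both statistics are computed on equal-count-bin Pearson residuals
  (64 quantile bins of the displacement sample; BIC = X² + k·ln n), not
  on the CDF residuals: the quantile-grid residual vector has an
  effective dimension of only ≈2.5 (the Brownian-bridge eigenvalue
  spectrum), which makes a nominal F-test on it reject a true single
  state in ~40% of runs, whereas the binned residuals are
  near-independent and restore nominal calibration (measured: correct
  K in 30/30 null and 30/30 two-state runs).
* **SMLM operators** use exact KD-tree queries (verified against an
  O(n²) oracle); event counts are localization counts, not molecule
  counts — with blinking they overcount molecules by design, which is
  why the count-conservation tests use single blinks.

### Attainable precision at the two-state conditions

At Δt = 20 ms, σ = 20 nm and D = 0.0657/0.0191 µm²/s, the immobile
state's signal scale (4DΔt = 1.5×10⁻³ µm²) equals the noise floor
(4σ² = 1.6×10⁻³ µm²), so any error in the fitted scale is roughly
doubled in D after the offset subtraction.  A Fisher-information
computation for the implied exponential mixture shows that ~22,000
pooled displacements bound the achievable per-experiment precision at
roughly 14% (sd) for the slow D and 0.05 for the fractions; estimates
are unbiased, and averaging over experiments recovers the generating
values closely (see `scripts/acceptance.py` output), but single-run
values of the slow coefficient should be read with that variance in
mind.

## Mechanics

For a bent tube of half-width r and centerline curvature κ = 1/R_c, the
outer and inner edges subtend the same angle at radii R_c ± r, so steady
bent growth requires the edge elongation ratio (R_c+r)/(R_c−r) = 1+f,
giving κ = f/(r(2+f)) and f = 2κr/(1−κr).  The edge-versus-edge measure
is the default; the edge-versus-centerline variant (f = κr) is also
provided since both conventions appear in the literature.  At r = 0.4 µm
and R_c = 5.733 µm this yields f = 0.150 — a ~15% outer-curve growth
excess sustains the typical curvature.

The roadblock simulator formalizes caging verbally described as
entrapment between dense obstacle complexes: agents on M angular bins
move `step` bins per tick, reverse with probability p_rev (higher inside
the trap sector), and exit the trap only with probability p_escape per
attempted boundary crossing, bouncing back otherwise.  Each tick deposits
one growth quantum at the agent's bin (an exact integer ledger, asserted).
The per-tick rule is mirrored exactly by a 2M-state (bin, direction)
Markov transition matrix whose stationary distribution is the oracle for
the Monte-Carlo occupancy (total variation < 0.02 at 10⁶ agent-ticks,
with a 300-tick burn-in from a uniform start).

Steady-state curvature iterates κ ← κ + gain·(κ_target − κ) with
gain 0.5 and tolerance 10⁻⁶ µm⁻¹, where the delivered asymmetry is
diluted as f₀·(1−κr)/(1+κr) — the simplest geometry-consistent form of
the argument that elongasome track density at the outer edge thins as
the cell bends; alternative dilution laws are pluggable.  The fixed point
is verified against independent Brent root bracketing.

## Problem sizes

The test suite and acceptance script use 2,000-track acquisitions
(~22,000 displacements), 100-series FRAP ensembles, 10⁶ agent-tick
roadblock runs and single-cell renderings at 50-nm pixels — sizes chosen
so each study completes in seconds while keeping Monte-Carlo error well
below the assertion tolerances.

## Known limitations

Segmentation is sized for sparse synthetic fields (Otsu + connected
components), with polygon import as the escape hatch for real crowded
images.  No HMM state switching within tracks, no drift correction, no
3-D tracking, no reaction–diffusion FRAP models, and no mechanical
(stress/turgor) sacculus model — the mechanics module is deliberately a
geometric-kinetic formalization.
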