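# Methods

## Model and procedure

PSMC reports, per EM round, a scaled mutation rate θ₀ and a step function
of relative population sizes λ_k over scaled time intervals t_k (units of
2·N₀ generations).  We convert to real units with the standard plotting
convention:

    N0        = θ0 / (4 · μ · s)          s = consensus bin size (bp)
    t_years,k = 2 · N0 · t_k · g          g = generation time (years)
    Ne,k      = N0 · λ_k

By default the final EM round is used (PSMC's reported estimate).  μ and g
are species-specific and must be supplied by the user; there are no
defaults.  The bin size defaults to 100 bp, the fq2psmcfa convention.

Missed heterozygotes at low coverage deflate θ₀ by the factor (1 − FNR),
where FNR is the false-negative rate for heterozygous sites.  The
correction inverts this: θ₀ → θ₀/(1 − FNR).  Because N₀ is linear in θ₀
and both the time and Ne coordinates are linear in N₀, the correction
multiplies every coordinate of the trajectory by 1/(1 − FNR).  This is the
only free parameter the method estimates.

### Curve comparison

Each trajectory is projected onto a shared vector of n logarithmically
spaced time points (default n = 60 spanning 10 kya – 1.5 Mya) by step
lookup — segment intervals are right-open [t_k, t_{k+1}), no
interpolation, preserving the piecewise-constant character of the
inference.  Points are compared in the plane x = log₁₀(years),
y = Ne / 10⁴ individuals, so both axes have comparable numeric ranges
(x ≈ 4–6.2, y ≈ O(1)).  y may optionally be log₁₀-transformed; the default
is raw scaled Ne.

Two metrics score a candidate against the reference: the undirected
Hausdorff distance (order-insensitive, worst-case local discrepancy) and
the discrete Fréchet distance (order-preserving; computed by the standard
dynamic program c(i,j) = max(d(i,j), min(c(i−1,j), c(i,j−1), c(i−1,j−1))),
filled iteratively).  Fréchet ≥ Hausdorff always holds for same-order
curves, and both are symmetric, translation-invariant and positively
homogeneous; the test suite verifies these properties and checks the DP
against an exhaustive enumeration of monotone couplings on short curves.
The sweep evaluates FNR candidates f_i = i·0.01 for i = 0…99 (generated by
index and rounded to 10 decimals, so decimal candidates are exact);
the optimum is the Fréchet argmin, with ties resolved toward the smallest
FNR (least correction).  SSE — Σ_i (y_P(i) − y_Q(i))² over grid points, in
(Ne/10⁴)² units — is reported at the optimum and at f = 0 as an
independent evaluation, summarized as log₁₀(SSE₀) − log₁₀(SSE_opt); it
never participates in selection.

### Calibration

Optimal FNR values across coverages form the regression set
(coverage → FNR).  Any sample with mean coverage ≥ 15× contributes FNR = 0
(false-negative losses are negligible at that depth; the threshold is
configurable), weighted equally with swept points.  Ordinary least squares
fits polynomials of degree 1–3 (Vandermonde design); R² = 1 − SS_res/SS_tot
about the mean observed FNR, with the degenerate convention R² = 1 when
SS_tot = 0 and the residuals also vanish (constant data fitted exactly),
else 0.  Degree selection is parsimonious: the lowest degree whose R² is
within `parsimony_tol` (default 0.005) of the best across degrees.
Predictions are clamped into the sweep domain [0, 0.99] — values outside
it are meaningless downstream — and coverages at or above the anchor with
a negative raw prediction report 0.

The regression is exposed as a scikit-learn estimator (`FNRCalibrator`),
fitted per individual; pooling across individuals is possible but not the
default, since the coverage–FNR law depends on population-specific
heterozygosity and demographic history and should not be transferred
between populations.

## Synthetic data generator

The generator emulates the study conditions end to end without sequencing
data.  Trajectories are piecewise-constant Ne histories (14 segments,
boundaries log-spaced from 5 kya to 2 Mya with a small seeded jitter so
boundaries never coincide with analysis-grid points) under four
archetypes: constant size, bottleneck (×0.2 between 50 and 250 kya),
expansion (ancestral size ×1/5), and zigzag (alternating ×3 / ×0.4
blocks), with baseline Ne = 10,000.

The coverage distortion is multiplicative: all coordinates shrink by
(1 − f(c)) with the ground-truth law f(c) = 0.6·(15 − c)²/15² for c < 15×
and f = 0 at or above 15× — quadratic, decreasing, consistent with the
anchor assumption, and spanning FNR ≈ 0 – 0.27 over the 5–14× range the
sweep covers.  Optional log-normal multiplicative noise (seeded) perturbs
segment Ne only, never times, keeping monotonicity intact.  The generator
can render any trajectory back into a syntactically valid `.psmc` file
(inverse of the scaling above, N₀ taken as the first segment's Ne), so
parser fixtures are self-generating.

What the model does *not* emulate: real downsampling reshapes curves
non-multiplicatively (the `-d 5` minimum-depth filter bites hardest near
5×, PSMC's time discretization interacts with the signal, and EM noise is
structured).  Passing round-trip tests therefore demonstrates that the
optimization machinery is exact and self-consistent under the stated bias
model, not that real 5× genomes are fully correctable.

## Numerical choices

- Candidate FNR grid by index with decimal rounding (no cumulative float
  drift; on-grid distortions are recovered exactly, off-grid ones to the
  grid resolution ±0.01).
- Hausdorff via `scipy.spatial.distance.directed_hausdorff` (both
  directions); an O(m·m′) brute-force scan is the test oracle.  At m = 60
  no nearest-neighbour acceleration is warranted.
- Fréchet DP fills the table iteratively (no recursion-depth limits);
  ties in the inner min do not affect the value.
- Grid-boundary rule: a grid time exactly equal to a segment start takes
  the newer segment (right-open intervals); times before the first
  segment start clamp to it.
- Degenerate inputs fail loudly: empty PSMC files, malformed records
  (with line numbers), non-monotone interval times, rank-deficient
  regression designs, fewer than three calibration points.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
at the protocol's own scale: 100-candidate sweeps on 60-point grids,
four demographic scenarios × twelve on-grid distortion levels for
round-trip recovery, ten swept coverages (5–14×) plus 15×/20× anchors for
calibration recovery, and 200 random short curve pairs for the
Fréchet-oracle cross-check.  The complete run takes well under a minute.

## Known limitations

- The multiplicative distortion is a first-order stand-in for real
  coverage bias; shape changes from depth filtering at ≤5× are out of
  scope.
- No uncertainty intervals on predicted FNR (none are defined for the
  procedure), and no bootstrap-replicate handling.
- Window choice is the analyst's responsibility: trajectories with sharp
  recent features can bias the optimum, and the recommended remedy is
  restricting the grid (e.g. starting at 50 kya) before optimizing, never
  automatic detection.
- Calibrations are population-specific by design; the CLI provides no
  cross-population transfer.
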