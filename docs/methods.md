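# Methods

This note records the models implemented in `canopy-complexity`, the
parameter choices that matter, and what the synthetic benchmarks do and do
not demonstrate.

## Box dimension

The box-counting dimension of a point cloud is estimated from the series
`N(r)` of occupied voxels under successive halving of a cubic grid.

Construction choices:

* **Initial box.** A cube with side equal to the largest componentwise
  extent, anchored at the cloud's minimum corner. A single side length is
  required for cubic voxels; anchoring at the data minimum makes the whole
  series — not just the slope — exactly translation invariant, and the
  index is exactly invariant under joint rescaling of coordinates and
  minimum voxel.
* **Binning.** Voxel index `floor((coord − min)/r)`, with points on the
  upper boundary clamped into the outermost voxel so no point is dropped.
* **Scales.** Every `r = r0/2^k ≥ min_voxel` is counted; halving stops at
  the last scale at or above the minimum (scales below it are excluded
  entirely, not down-weighted). At least 4 scales are required, else the
  computation raises rather than returning a meaningless slope.
* **Fit.** OLS of `ln N` on `ln(1/r)` over all scales except the first.
  The first scale is always `(r0, 1)` and carries no information about
  filling; dropping it follows the established practice for this index.
* **Bound.** Counts are non-decreasing and grow by at most 8× per halving,
  so every pairwise slope — and hence the OLS slope — lies in [0, 3]. The
  suite asserts this property on random clouds.

`min_voxel` defaults to 0.5 m: for field scans this is a guard against
occlusion and distance-dependent sampling artefacts, balanced against
keeping enough scales for the regression. For *synthetic lattice* fractals
the guard is irrelevant and the informative scale range is bounded below
by the lattice pitch instead: below the pitch the finite point set
saturates (`N` stops growing and the apparent dimension collapses toward
0), while far above it coarse boxes count like a solid. The Menger-sponge
benchmark therefore runs with `min_voxel = side/3^level` (0.185 m for a
level-4 sponge scaled to 15 m), which brackets the sponge's self-similar
regime and reproduces ln 20/ln 3 within 0.01; at the field default of
0.5 m only the five coarsest scales remain and the estimate rises to 2.86.
Degenerate inputs (all points coincident) raise an error: a one-scale
series leaves the regression undefined.

## Canopy entropy

Plane entropies are differential entropies of a kernel density estimate:
equal-weight isotropic Gaussian kernels, fixed bandwidth `h = 0.2 m`
(an agreed-upon constant for this index, not selected per cloud — unit
comparability across plots requires a fixed kernel).

Quadrature: the density is evaluated at the centers of a regular grid of
step `grid_step` (default `h/2 = 0.1 m`) covering the 2D bounding box
padded by `5h` per side, renormalized so the Riemann sum is exactly 1, and
summed as `−Σ p ln p ΔA` (cells below 1e-300 contribute 0). The padding
is set so the truncated kernel mass (~1e-7 at 5 standard deviations) is
far below the quadrature tolerance; tests verify the single-Gaussian
closed form `ln(2πe·h²)` to 1e-3, the uniform-square limit `ln(side²)` to
2%, stability of the result under grid refinement to 1e-3, and that the
pre-normalization mass deviates from 1 by under 1%. Because the grid is
anchored at the data minimum, entropies are translation invariant to
floating-point precision, and scaling coordinates together with `h` and
the grid step shifts each plane entropy by exactly `2 ln s`.

The separable form of the Gaussian kernel lets the full grid evaluation
factor into one matrix product per plane, so the estimate is exact (no
histogram binning) yet costs milliseconds for 10⁴-point clouds.

Entropy units: nats relative to the meter² reference density. CE grows
with plot extent by construction (a density over a larger support is
flatter), so CE values are comparable only between equal-sized plots; the
suite asserts this monotonicity on uniform clouds.

### Sampling-density bias (SDB)

Near surfaces return more laser hits than distant ones; for mobile scans
the dominant gradient is vertical. Screening and correction, in z only:

1. Cut the cloud into horizontal layers of `layer_width` (1 m), starting
   at the lowest point; the topmost point joins the last layer.
2. Per layer, compute the mean 3D distance of each point to its nearest
   neighbour *within the layer* (k-d tree; layers with fewer than 2 points
   carry no value and are excluded from the sequence).
3. Test the layer sequence for a monotone trend with the Mann–Kendall
   test, Hamed–Rao variant (below), at `alpha = 0.05`.
4. If trending, resample the *original* cloud to occupied-voxel centers,
   starting at a voxel equal to the largest per-layer mean NN distance
   and multiplying by `growth = 1.10` per round, until no trend remains.
   An iteration cap (50) turns non-convergence into an error carrying the
   full iteration log.

The 10% growth step is a reading of an ambiguous prescription ("voxel size
always increasing by 10"): a ×10 factor would blow past the target in one
step and +10 m is physically absurd, while +10% gives a fine-grained
search; the factor is exposed as a parameter. Sequences of fewer than 4
layers are declared test-inapplicable and left uncorrected — the test has
no power there, and erroring would make short canopies uncomputable.
Horizontal SDB (relevant mainly to stationary terrestrial scans) is a
documented limitation, not corrected.

### Mann–Kendall test, Hamed–Rao variant

`S = Σ_{i<j} sign(x_j − x_i)`; null variance with the standard tie
correction; variance multiplied by the Hamed–Rao factor
`1 + 2/(n(n−1)(n−2)) Σ (n−i)(n−i−1)(n−i−2) ρ_i` over the rank
autocorrelations `ρ_i` of the Sen-slope-detrended series that exceed the
two-sided normal bound `z_{1−α/2}/√n`; continuity-corrected z; two-sided
normal p. The implementation is cross-checked against brute-force pair
enumeration and Monte-Carlo null calibration (empirical size ∈ [0.01, 0.10]
at α = 0.05 for permuted sequences of 12 distinct values).

## Index comparison

* **Pearson r** with the t-transform p-value (scipy), for goodness of fit.
* **Range-ratio δ.** With no repeated measurements, the measurement-error
  SD of each index is assumed proportional to its observed range (equal
  signal-to-noise), so `δ = σ_Db/σ_CE = range(Db)/range(CE)`; for the
  benchmark ranges 1.99 and 8.12 this truncates to 0.24.
* **Deming regression.** Closed-form errors-in-variables slope with
  error-variance ratio `λ = σ_y²/σ_x² = 1/δ²`,

  `slope = [s_yy − λ s_xx + √((s_yy − λ s_xx)² + 4 λ s_xy²)] / (2 s_xy)`.

  The orientation of λ was fixed by the estimator's limits (λ→∞ must give
  OLS of y on x, λ→0 the inverse regression) and verified by simulation:
  with the generating error-SD ratio 0.245, only this orientation recovers
  the generating slope without bias. The fit is symmetric — swapping x
  and y while inverting δ inverts the line exactly (asserted to 1e-9) —
  and is validated against a numerical minimizer of the weighted
  orthogonal sum of squares. SEs are leave-one-out jackknife; CIs use the
  t quantile with n−2 df. Per-site fits reuse the pooled δ by default
  (one δ describes the whole campaign); a per-group policy is available.
  The per-site fits stand in for a spatial-dependence control model; no
  random-effects likelihood is implemented.
* **Runtime scaling.** `t = a·N^b` with no intercept (cost vanishes with
  cloud size), by nonlinear least squares initialized from the log-log
  OLS line, SEs from the Gauss–Newton covariance, R² on the original
  scale. Wall-clock timings recorded by the batch pipeline are inputs to
  this machinery but are hardware-bound and never asserted on.

## Synthetic data

The generators define the validation conditions:

* `generate_plane` / `generate_line` / `generate_uniform_cube`: bodies of
  analytic dimension 2 / 1 / 3 and, for dense uniform bodies, analytic
  entropy limits (`ln(side²)` per plane).
* `generate_menger_sponge`: the 20^level retained sub-cube centers of the
  recursive 3×3×3 construction, scaled to the plot cube; exact lattice,
  exactly 20 and 400 occupied cells at the side/3 and side/9 grids.
* `generate_biased_canopy`: uniform x, y over a 15 m square; z from a
  truncated exponential with rate `density_decay` (default 0.3 /m over
  20 m, 2×10⁵ points) so the expected per-layer count decays geometrically
  and the layer NN-distance sequence rises monotonically — strong enough
  that the MK screen must flag it. Rate 0 yields the uniform null slab
  used for false-positive calibration.
* `generate_paired_indices`: latent Db* uniform on [0.5, 2.5]; observed
  `db = Db* + N(0, 0.282²)`, `ce = 4.75·Db* − 1.07 + N(0, 1.15²)`. The
  noise SDs keep the error-SD ratio at 0.245 and put the observed
  correlation near 0.82, emulating a 170-plot field campaign; sites are
  assigned round-robin.

What the synthetic benchmarks do **not** show: real canopies are
surface-dominated, occluded and anisotropic, none of which the uniform or
exponential slabs emulate; passing the analytic-recovery tests validates
the estimators' correctness, not their ecological interpretation on field
data. Absolute runtimes and the field campaign's regression coefficients
depend on hardware and on the deposited scans and are out of scope here —
the simulation-based recovery tests check the machinery instead.

## Problem sizes

Default validation sizes were chosen so each check is statistically
decisive yet the whole suite runs in well under a minute of compute:
2×10⁵-point clouds for the bias machinery and cube bound, 10⁴ points for
entropy limits, 100 replicates of 170-plot campaigns for jackknife
coverage, 20 seeds for trend-test false positives.

## Known limitations

* SDB screening/correction in z only; horizontal bias is documented, not
  corrected.
* A non-significant MK p-value cannot *prove* absence of bias (it only
  fails to reject); low layer counts further reduce power, and clouds with
  fewer than 4 usable layers are never corrected.
* CE is plot-size dependent; cross-study comparison requires equal plot
  geometry.
* LAS/LAZ I/O requires the optional `laspy` dependency; without it the
  package reads and writes plain-text XYZ.
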