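# Methods

## Model and solver

The package solves the linear inverse problem of electrocardiographic
imaging: recover epicardial potentials `H_t` from body-surface
potentials `B_t = A H_t + ε` at each time instant, where `A` (N_B × N_H)
is a fixed lead-field (transfer) matrix. The estimator is zero-order
Tikhonov (ridge) regression,

    Ĥ_t(λ) = (AᵀA + λ²I)⁻¹ Aᵀ B_t ,

computed through the thin SVD `A = U Σ Vᵀ` as
`Ĥ_t = Σ_i [σ_i/(σ_i²+λ²)] (u_iᵀB_t) v_i` over the retained rank `r`.
The SVD is computed once per matrix and cached (`TransferModel`); all
selector objectives are then closed-form functions of the singular
values and the data projections `u_iᵀB_t`, so a whole beat of T instants
costs O(r) per (instant, λ) rather than a dense solve.

Assumptions inherited from the model: the torso is a time-invariant
homogeneous volume conductor, `A` is known exactly at reconstruction
time, and the relation is instantaneous (no temporal coupling — each
column of `B` is inverted independently).

### Numerical conventions

- **Numerical rank**: `r` = number of singular values above
  `rank_tol · σ_1`, with `rank_tol = 1e-12`. The search intervals reach
  singular values of order 1e-7, so near machine-precision retention is
  the intended regime; the threshold is exposed as an argument.
- **λ = 0** is the truncated pseudoinverse on the retained rank
  (filter factor `1/σ_i`), avoiding division by zero.
- **Sign convention**: each left singular vector is flipped so its
  largest-magnitude entry is non-negative, making serialized models
  reproducible across LAPACK builds.
- **Residual norm with rank deficiency**: `ρ(λ)²` includes the constant
  `‖b_⊥‖²`, the energy of `b` outside the retained left subspace,
  computed as `‖b‖² − Σ_{i≤r}(u_iᵀb)²` (clipped at 0).

## Selecting the regularization parameter

All five selectors evaluate their objective on a 200-point log-spaced
grid over a predefined interval and then refine locally: parabolic
interpolation in log λ for curve extrema (L-curve, CRESO), bounded
scalar minimization between the neighboring grid points (GCV, U-curve),
and bisection to 1e-6 relative accuracy for the zero-crossing root.
Results are clipped to the interval. The grid density is a package
choice; the refinement step makes the result insensitive to it.

- **Search interval**: `[σ_round(r/2), σ_1]` from the singular spectrum,
  with half-away-from-zero rounding of the 1-based index (r = 5 →
  index 3). GCV widens the lower bound to 1e-30 (its minimum often sits
  far below the spectrum midpoint); the U-curve widens the upper bound
  to 4.44 (kept as the conventional constant; its origin is not
  interpreted here).
- **L-curve**: curvature of `(log ρ, log η)` parameterized by `log λ`,
  with first and second derivatives in closed form from termwise
  differentiation of the filter-factor sums (validated against central
  differences in the tests). If the curvature is nowhere positive, no
  corner exists: the selector returns the log-scale midpoint with a
  fallback flag.
- **GCV**: `G(λ) = [Σ_{i≤r} λ⁴(u_iᵀb)²/(σ_i²+λ²)² + Σ_{i>r}(u_iᵀb)²] /
  [(N_B − r + Σ_{i≤r} λ²/(σ_i²+λ²))/N_B]²`. As λ → 0 on rank-deficient
  problems G flattens into a numerically constant plateau; the grid
  argmin inside the plateau is floating-point noise, so the selector
  takes the smallest λ attaining the grid minimum within 1e-12 relative
  before refining. An everywhere-flat objective (e.g. the 1×1 system)
  returns the interval lower bound with a flag.
- **CRESO**: `C = d/d(λ²)[λ²η² − ρ²]`, termwise:
  `C(x) = Σ σ_i²(u_iᵀb)²(σ_i² − 3x)/(σ_i² + x)³` with `x = λ²`. The
  selector returns the *last* (largest-λ) strict local maximum on the
  grid — the first local maximum is frequently a severely
  under-regularized value on experimental data. If no interior local
  maximum exists the selector delegates to the zero-crossing rule and
  flags the instant.
- **Zero-crossing**: first sign change (positive → non-positive) of
  `λ²η² − ρ²` scanning upward from the interval's lower bound; no sign
  change returns the upper bound with a flag so beat-level medians stay
  defined.
- **U-curve**: minimum of `1/ρ² + 1/η²`; grid points where either norm
  vanishes (exactly consistent data) are excluded.

**Per-beat aggregation.** Selectors run on every time sample of the
annotated beat span (from the start of the record through the end of
the repolarization window; trailing resting baseline is excluded), and
the beat is reconstructed at the *median* of the per-instant λ values
(even counts: mean of the two central order statistics). A single λ per
beat preserves temporal coherence of the reconstruction, which the
activation/recovery mapping requires. A `stride` option thins the
instants for speed but defaults to every sample.

All selector objectives are homogeneous in `b` (or corner-invariant),
so selections are invariant to rescaling of the data — asserted
numerically in the tests, along with determinism and the interval
contract.

## Synthetic data

The generator stands in for an instrumented-animal mapping study: one
paced beat per pacing site, unipolar epicardial electrograms with known
fiducials, torso potentials produced by a linear lead field.

- **Geometry**: two concentric Fibonacci-lattice spheres (heart radius
  25 mm, torso radius 120 mm by default), plus a rotated lattice of
  recording epicardial electrodes on the heart sphere mapped to their
  Euclidean-nearest mesh nodes (ties to the lowest index).
- **Transfer matrix**: `A[j,i] ∝ 1/(4π‖x_j − x_i‖)` row-normalized (an
  inverse-distance single-layer surrogate). The torso–heart gap
  low-passes high spatial frequencies, so the singular spectrum decays
  rapidly without tuning; at the default scale (200 nodes, 64
  electrodes) the retained condition number σ_1/σ_r exceeds 1e6, and it
  grows with mesh density while the electrode count limits the rank. A
  `spectral` mode builds `A = U diag(σ) Vᵀ` with a prescribed geometric
  spectrum for controlled unit-test instances.
- **Beats**: activation spreads isotropically from the pacing node at
  conduction velocity 0.8 mm/ms over chord (straight-line) distance —
  adequate on a convex sphere, a documented simplification of geodesic
  propagation. Recovery follows after an action-potential duration of
  200 ms plus a smooth nodal perturbation bounded by ±20 ms (the
  projection of the node's direction onto a random unit vector, so the
  recovery map is spatially smooth and recovery always follows
  activation). Each node's electrogram is
  `−a_dep·tanh((t−AT_i)/w_dep) + a_rep·tanh((t−RT_i)/w_rep)` with
  amplitudes 10 / 3 mV and widths 2 / 15 ms: the steepest negative and
  positive slopes sit exactly at AT_i and RT_i by construction, which
  is the contract the fiducial estimators are tested against.
- **Noise**: additive white Gaussian noise per electrode, scaled so the
  per-electrode SNR over the record equals the configured value
  (default 20 dB). Infinite SNR returns the clean projection, and
  `‖B_clean − A·H_true‖ = 0` exactly at generation time.
- **Corpus**: default desk scale is N_H = 200, N_B = 64, ~33 recording
  electrodes, 20 paced beats at distinct sites, 1 kHz sampling, 500 ms
  records; an experimental-scale corpus (~1700 nodes, ~200 electrodes,
  92 beats) is reachable through the same configuration. Every beat
  receives a child seed spawned from the master seed, making
  regeneration byte-identical.

### What the generator does *not* emulate

The transfer matrix used for reconstruction is the *same exact* matrix
that generated the data, and the noise is i.i.d. across electrodes.
Real studies have geometry/segmentation error, electrode-position
error, torso inhomogeneity and correlated residuals. This matters for
interpreting the selector comparison: GCV's notorious collapse to
λ ≈ 0 on experimental data is driven by such model mismatch, and under
this generator's clean conditions GCV is statistically well-founded and
selects a sensible λ, close to the L-curve's. Likewise the tanh
template gives every electrogram a large shared step (a time-varying
spatial mean) that the positive row-normalized kernel transmits at full
strength, which pushes the zero-crossing balance point toward larger λ
and makes electrogram CC tolerant of over-smoothing. Passing pipeline
tests therefore demonstrate internal consistency and parameter recovery
under known conditions — not that selector rankings on clean synthetic
data transfer to experimental recordings.

## Evaluation

Per electrode and beat, the recorded electrogram is compared with the
reconstruction at its nearest heart node:

1. **Alignment**: integer-lag cross-correlation over ±10 samples
   (±10 ms at 1 kHz); the reconstructed signal is shifted, overhang
   filled by edge replication; ties prefer the smallest |lag|, then the
   negative lag.
2. **Normalization**: min–max to [0, 1]; constant signals are flagged
   degenerate and excluded from aggregates (counted, never imputed).
3. **Metrics**: `RE = ‖y − x‖₂/‖x‖₂` on the aligned, normalized pair
   (the standard ECGI convention; the reference is the recorded
   signal) and Pearson CC on the aligned raw pair (CC is affine-
   invariant, so normalization order is immaterial).

Activation time is the steepest negative slope within the
depolarization window and recovery time the steepest positive slope
within the repolarization window (the standard convention for unipolar
electrograms), after a 3-sample moving average; the fiducial is placed
at the midpoint of the winning first-difference interval. AT/RT are
estimated on the *unaligned* signals — alignment would hide exactly the
timing errors these metrics measure — and compared across electrodes
per beat with CC and plain RE on the times in ms (no normalization: the
times already share units and origin). The exact fiducial algorithm
used with experimental recordings involves additional spatial-coherence
corrections; the operators here are exact on the generator's waveforms,
which is the testable contract.

## Experiments

- **Sweep**: each beat reconstructed at every λ of the fixed grid
  {0.001…0.009 step 0.001} ∪ {0.01…0.09 step 0.01} ∪ {0.1…1.0 step 0.1}
  (28 values; duplicates in custom grids are deduplicated with a
  warning); distributions summarized as median with quartiles, pooling
  electrode-beat pairs for electrogram metrics and beats for AT/RT
  metrics.
- **Method comparison**: per beat and selector, the per-beat median λ,
  reconstruction at it, and the evaluation report; selector fallbacks
  are recorded as flags, never dropped.
- **Fixed λ**: all beats reconstructed at one λ and paired per beat
  against each reference selector (the data behind an identity-line
  scatter). One λ per beat is used everywhere; per-instant
  reconstruction is intentionally not part of any report.

Analyses in the test suite and the acceptance script run at desk scale
(the default corpus, five master seeds for the pipeline-level checks),
chosen so the whole suite runs comfortably on one CPU; the
experimental-scale configuration exercises identical code paths.
Every CLI run writes a manifest (config hash, seed, package versions)
next to its outputs, and rerunning a pipeline with the same master seed
reproduces every CSV byte for byte.

## Known limitations

- Spherical geometry and the inverse-distance kernel are surrogates; no
  boundary-element forward model is included, and `A` is either given
  or generated.
- Chord-distance propagation and the two-ramp tanh electrogram are
  idealizations; no arrhythmic activity is simulated.
- Only zero-order Tikhonov is implemented (no first/second-order
  operators, no L1/elastic-net penalties), and only the five selectors
  above (no discrepancy principle or NCP).
- Heart and torso share one sampling rate.
- The evaluation maps electrodes to single nearest nodes; no spatial
  interpolation of potentials.
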