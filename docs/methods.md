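# Methods

## Model and assumptions

The package models one white-matter tract as a population of myelinated
axons with two ingredients:

1. **Radius law.** The axonal (inner) radius is Gamma-distributed,
   parameterised by mode *M* and scale *θ* so the shape is
   *k = M/θ + 1 > 1*. The mode is remarkably conserved across tracts and
   species, which motivates fixing *M* and reading tract differences off
   the tail scale *θ* (prevalence of large axons). Mean radius is
   *M + θ*; the fraction above *r*₀ is the regularised upper incomplete
   gamma Q(k, r₀/θ).
2. **Myelination law.** The per-axon g-ratio grows with radius as
   *g(r) = β·r^α* — an offset-free power law chosen because it makes the
   population averages analytic. α is restricted to [0, 0.5) so every
   gamma-function argument below stays positive; a soft warning (not an
   error) flags parameter sets whose g(r) exceeds 1 inside
   r ∈ [0.05, 3] μm.

Two observables follow:

- **Aggregate (MRI) g-ratio.** The voxel-level g-ratio is the ensemble
  average of g² weighted by fiber cross-sectional area (fiber radius
  *R = r/g(r)*): g_MRI² = E[r²]/E[r²/g²]. With the Gamma law this is
  β²θ^{2α}·Γ(k+2)/Γ(k+2−2α).
- **Conduction velocity.** Each axon conducts at *v = p·d/g* with *d*
  the inner diameter in μm and *p* (default 5.5, literature range
  5.5–6.0, (m/s)/μm) absorbing nodal and membrane properties. Equal
  contribution of all axons to the EEG-measured velocity gives
  V = (2p/β)·θ^{1−α}·Γ(k+1−α)/Γ(k); at p = 5.5 the leading constant is
  11.

Key structural facts the package exploits: g ∝ β and V ∝ 1/β, so the
product g·V is β-free and strictly increasing in θ; V is strictly
increasing in θ at fixed M (heavier tail → faster ensemble); at α = 0
the aggregate g-ratio collapses to β exactly.

All gamma-function ratios are evaluated as `exp` of `gammaln`
differences so that scales as small as θ = 1e−4 μm (shape ≈ 4000) stay
finite. Units are fixed at module boundaries: radii μm, velocities m/s
(1 mm/ms = 1 m/s, asserted in tests), times ms.

### Quadrature oracles

`quadrature_g_mri` / `quadrature_velocity` integrate the definitional
forms with adaptive quadrature on [0, q(1−1e−12)] (distribution
quantile), absolute tolerance 1e−12. The tail mass beyond the upper
limit is negligible relative to the 1e−6 relative agreement the tests
demand between oracle and closed form. These functions exist to validate
the closed forms, not to be fast.

## Calibration of (α, β)

The histological reference is g_REF(r) = 0.22·log10(2r) + 0.508 from
peripheral-nerve measurements. The logarithm is base 10: only that base
reproduces the published CNS offset (0.7 − [0.22·log10(1.8) + 0.508]
≈ 0.136 ≈ 0.14), whereas a natural log would give ≈ 0.06. Central
nervous system axons run at higher g; the additive offset is pinned by
the anchor point g = 0.7 at r = 0.9 μm.

The power law is fitted to the (possibly offset) curve by unweighted
least squares on a uniform radius grid. The reference data do not come
with a stated abscissa range, so the range is a genuine design choice;
we sample r ∈ [0.25, 1.5] μm (100 points), the radius span over which
the reference relationship is histologically supported, which
reproduces the published pairs within rounding — (α, β) ≈ (0.18, 0.57)
peripheral and (0.14, 0.71) with the CNS offset, both R² ≥ 0.99. Wider
ranges (e.g. [0.5, 3] μm) shift α down by ~0.02 while leaving β pinned
within ±0.02 of the curve value at r = 1 μm; this sensitivity is
exercised in the tests. Fit initial values (0.15, 0.6).

## Inversion

Two parameters are free (default θ and β; fixed α = 0.14, M = 0.40 μm,
p = 5.5). `estimate` minimises the stacked residuals
[gᵢ − ĝ] ⧺ [V − V̂] with scipy's bounded trust-region-reflective
least-squares, initial values θ = 0.10 μm, β = 0.70, bounds
θ ∈ [1e−4, 5], β ∈ [0.1, 1.5], M ∈ [0.01, 2], α ∈ [0, 0.45], step/residual
tolerance 1e−10. Residuals are unweighted: with two unknowns and an
attainable zero-residual point the optimum is the exact solution of
ĝ = mean(g), V̂ = V, so weighting cannot move it (an optional weight
vector exists for completeness).

`solve_two_equations` computes that exact solution directly and serves
as the deterministic oracle and the fast path for grid scans:

- free (θ, β) or (M, β): β cancels from g·V, leaving a 1-D
  strictly-monotone root problem solved by Brent's method; β follows
  from the g equation. No sign change across the bounds, or an implied β
  outside its bounds, raises a typed `IncompatibleObservablesError`
  rather than clipping.
- free (M, θ): 2-D root finding in (log M, log θ) (Powell hybrid,
  multi-start, with a vectorised coarse scan as a start generator).
  Log-space coordinates keep boundary-pushed solutions reachable: nodes
  just above the attainability boundary legitimately return M ≈ 1e−10 μm
  and below. Acceptance requires the log-residual below 1e−9.
- pairs involving α fall back to the bounded least-squares path with a
  residual-zero check.

Confidence intervals refit at both endpoints of the velocity CI (itself
[L/(IHTT+sd), L/(IHTT−sd)]); each parameter's interval is the [min, max]
envelope of the endpoint fits and the point fit. This is the natural
reading of error bars produced from a transfer-time CI; endpoint fit
failures degrade to a partial interval with a warning flag rather than
an exception.

## Simulation studies

Defaults reproduce the study conditions: per-sample g noise sd 0.03,
velocity noise sd 0.50 m/s, 700 g samples and 1 velocity sample per
repetition, 2,000 repetitions; cohort study with 15 subjects,
g ~ N(0.70, 0.05), V ~ N(10, 0.80) m/s. The evaluation grid (50×50 over
g ∈ [0.55, 0.85], V ∈ [5, 15] m/s) was chosen to contain both
literature crosses and the full plausibility band; the plausibility
windows are 0.05 < M < 0.9 μm and 0.01 < θ < 0.9 μm.

Definitions (the studies are reported without explicit formulas in the
literature, so these are package conventions): percent error =
sd(estimates)/true × 100; percent bias = (estimate − reference)/reference
× 100; the constant-inaccuracy study reports the mean of |percent bias|
over the plausible band. Noisy draws falling outside (0, 1) for g, below
0 for V, or into the incompatible region are redrawn rather than
clipped (preserving Gaussianity conditional on validity); redraw counts
are reported. Each repetition draws from a substream seeded by (seed,
repetition index), so enlarging the repetition count never reshuffles
earlier repetitions and every result is bit-reproducible from its spec.

Per-repetition fits go through the exact two-equation solve on the
sample means, which (see above) is the least-squares optimum whenever
the mean observables are compatible.

The constant-inaccuracy study perturbs one fixed constant by a relative
error and re-estimates the complementary pair: an α or β inaccuracy is
absorbed by (M, θ); an M inaccuracy by (θ, β). A 10% error in β is
catastrophic (order-100% biases) because β multiplies one observable
and divides the other — which is exactly why β is estimated rather than
fixed.

Measured at the defaults, the Monte-Carlo percent-sd of θ̂ at
(θ = 0.22, β = 0.71) is ≈ 13% with one velocity sample. This is fully
explained by linear error propagation: θ̂ solves the β-free product
equation A(θ)B(θ) = ḡ·V̄ whose log-log slope at θ = 0.22 is ≈ 0.37, so
the 5% relative velocity noise appears as ≈ 13% in θ̂. β̂ stays near 1%
once ≥ 100 g samples pin the g equation.

## Synthetic in-vivo cohort

`synth_cohort` emulates the measurement pipeline end to end: per-subject
mean g ~ N(0.70, 0.05) with 700 within-subject samples at sd 0.03, and a
velocity decomposed into its measured ingredients — tract length
~ N(150, 8) mm and transfer time ~ N(15, 0.85) ms, whose relative
dispersions combine to the ≈ N(10, 0.8) m/s velocity law used in the
simulation studies. What it does **not** emulate: spatial correlation of
g samples along streamlines, partial-volume and registration artifacts,
heteroscedastic EEG peak-latency noise, or between-tract differences.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to every real
acquisition artifact.

## Degenerate inputs and tie-breaks

- Peak detection takes the maximum of the current-density magnitude in
  the analysis window (default 0–300 ms), earliest sample on ties, no
  smoothing (band-pass filtering happens upstream in any EEG pipeline);
  a flat window or an ipsilateral peak preceding the contralateral one
  raises a typed error.
- The voxel map formula uses the square-root convention
  g = 1/sqrt(1 + MVF/AVF) — the standard area-based aggregate
  definition, and the only convention that yields g ≈ 0.7 at
  physiological MVF/AVF. Voxels with AVF = 0 and MVF > 0 are masked,
  not raised; MVF = AVF = 0 returns 1 by convention.
- θ → 0 drives the Gamma shape to infinity and the model to a
  single-radius population; the log-gamma evaluation keeps this limit
  finite and the tests pin it against the analytic degenerate forms.
- A velocity CI with lo = hi produces zero-width parameter intervals.

## Known limitations

- Exactly two free parameters: with two observables, estimating three
  or four is under-determined by construction.
- The velocity prefactor *p* is treated as universal across tracts and
  subjects; it trades off directly against β (only p/β is identified by
  V).
- The model is specific to the Gamma radius law and the offset-free
  power-law g-ratio; other laws lose the closed forms.
- The packaged cohort table stores per-subject summary statistics (mean
  ± sd of g), not the full per-streamline sample vectors; since the
  least-squares optimum depends on the samples only through their mean,
  fits from the summaries equal fits from homogeneous sample vectors.
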