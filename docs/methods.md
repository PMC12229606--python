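# Methods

This note documents the models, defaults, and numerical choices behind
`ismflux`, and what the synthetic-data tests do and do not establish about
real measurements.

## Optical model and MDFs

The molecule detection function `m_ij(r)` is the probability of detecting a
photon from an emitter at sample position `r` while the beam sits at orbit
position `i`, in detector element `j`. The package builds it from a
parametric scalar model:

- **Excitation**: vortex doughnut `Exc(ρ) ∝ (ρ²/w²)·exp(−2ρ²/w²)`, exactly
  zero on axis and radially symmetric, peaking on the ring `ρ = w/√2`.
  Default `w = 0.61·λ_exc/NA = 276.7 nm` (635 nm, NA 1.4), so the peak ring
  sits at ≈196 nm. The waist is exposed in `OpticsModel` for users who want
  to match a measured focus.
- **Detection**: isotropic Gaussian PSF with `σ_det = 0.21·λ_em/NA = 99 nm`
  (660 nm), integrated analytically (normal CDFs) over each element's
  square active area. Both profiles are separable/analytic, so the base map
  stack evaluates in closed form on the grid.
- **Descanned geometry**: detection shares the scanner, so the entire base
  map translates with the beam: `m_ij(r) = I_0j(r − δ_i)`. `MDFSet` stores
  the unshifted stack `I_0j` once and applies the orbit shift during
  interpolation — exact rather than an approximation of a materialized
  `N_c × N_d` stack, and ~30× smaller in memory at the default grid.
- **Normalization**: `Σ_j I_0j = 1` at the doughnut intensity maximum, so
  MDF values are per-photon detection probabilities relative to the
  brightest probe position.

This parametric stand-in replaces a full vectorial focus computation fitted
to a specific instrument. It reproduces the bound magnitudes that matter
(see below) but not instrument-specific features: aberrated doughnut zeros,
element-to-element sensitivity variations, or shift-vector anisotropy.
Measured MDFs can be imported instead (`prepare_measured_mdf`), with an
anisotropic x-rescale (fast-axis stretch correction, default 20% squeeze in
the measured path) and uniform+Gaussian smoothing (defaults 5 px / 2 px —
the original criterion is only "visually smooth", so both are config).

Grids are sample-plane nm, origin at the TCP center, pixel centers at
half-integer offsets. Default simulation grid: 2.5 nm pixels, 1000×1000.
Most analyses in the test suite use 400×400 (±500 nm): MDF values are local
point evaluations, so results at |r| ≲ 450 nm are identical on either grid;
the smaller grid is purely a runtime/memory choice.

## Estimator

The event likelihood is multinomial in the reduced counts `n_ij` with cell
probabilities mixing the MDFs with a uniform background at a fixed,
per-dataset SBR (10 for bound calculations, 3–3.3 for blinking data; never
estimated per event). The reported log-likelihood omits the count-only
multinomial constant, so likelihood *ratios* between candidate positions
are exact.

`localize_mle` is a deterministic brute-force search: a coarse lattice pass
(default 8 MDF pixels) over the search region, then three refinement passes
halving the step down to one pixel. Ties break toward the lowest x, then
lowest y. Rationale for not using a continuous optimizer: the likelihood is
non-smooth at the interpolation scale and nearly flat along the degenerate
directions of the doughnut zero; the lattice search is derivative-free,
reproducible, and is checked against exhaustive full-grid search on a toy
MDF set in the tests. The final estimate is quantized to the MDF pixel
(2.5 nm), which inflates an empirical spread σ by at most
`sqrt(σ² + s²/12)/σ` (≈3% at σ = 3 nm).

Interpolation is bilinear with clipping at zero; with finite SBR the
background term keeps every `p_ij > 0`, so the likelihood is always finite.
At infinite SBR a zero-probability cell with counts returns the
representable minimum and flags the result degenerate.

## Cramér-Rao bound

`F = N·Σ_ij (∇p_ij)(∇p_ij)ᵀ/p_ij` with gradients by central finite
differences of the interpolated probabilities (step = 1 MDF pixel,
validated against a 4× finer step to ≤2%). The scalar bound is the rms of
the per-axis bounds, `σ_CRB = sqrt(tr(F⁻¹)/2)`, matching the convention
used for measured spreads `σ = sqrt((σ_x²+σ_y²)/2)`; whether published
values use the rms or worst-axis convention is not always stated, and the
rms choice is recorded here as an assumption.

Measured magnitudes under the default model (L = 90 nm, N = 100, SBR 10):
σ_CRB ≈ 3.47 nm at the TCP center, ≈12.7 nm at 300 nm; log–log slope of
σ_CRB(center) vs L over 50–300 nm ≈ 0.97; maximum of the photon-yield-
scaled effective uncertainty over the FOV ≈ 6.6 nm. These are computed live
by the tests and `scripts/acceptance.py`, not asserted as constants.

One known divergence from expectation: collapsing the array to a virtual
single-element detector raises the bound dramatically *at* the TCP circle
(the circle-inversion ambiguity of a quadratic intensity zero) and far
outside (r ≈ 200–250 nm), but at 1.5× the TCP radius the exponential
envelope of the parametric doughnut still carries enough radial information
that the single/array ratio is only ≈1.6, not the order of magnitude a
sharper (aberrated or truncated) real doughnut zero exhibits there. The
corresponding acceptance test measures the ratio at that operating point
and is expected to fail under this PSF model; the qualitative content —
single-element blow-up outside the TCP, finite array bound everywhere in
the FOV — holds.

## Synthetic data

`simulate_trace` draws Poisson counts per (orbit, angle, element) dwell
from the MDF-derived rates. Conventions:

- **Brightness**: `rate` is signal photons per orbit for an emitter at the
  TCP center; elsewhere the yield follows `Σ m_ij(r)/Σ m_ij(0)`, emulating
  constant laser power. The center-to-ring yield ratio is ≈7 for L = 90.
- **Background**: time-homogeneous, uniform over all (i, j) cells — the
  same assumption the likelihood makes. Dead time, afterpulsing, and
  per-element dark-count maps are not modeled.
- **Blinking**: two-state renewal process with exponential sojourns,
  sampled at dwell midpoints; no photophysics beyond on/off.
- **Nanoruler defaults** (`nanoruler_tensor`): mean on-time 100 ms; mean
  off-time 1.9 s (one binding per ~2 s, matching the observed event rate of
  284 events in 9.6 min); 36 signal photons per orbit at the ruler centroid
  with SBR 3, so a mean-length binding clears the 2000-photon event filter
  at every site (~80% of event photons are signal); the armed docking site
  rotates every 0.5 s so successive events sample all sites. Ruler
  positions in tests sit 180–260 nm from the TCP center: the published
  per-event uncertainty (median 4.9 nm at ≥667 photons per segment)
  corresponds to that outer region in this PSF model, and sites closer to
  the doughnut zero receive too few photons under constant power to pass
  the 2000-photon filter — a real feature of the method, not an artifact.
  A site at 300 nm (FOV edge) acquires a ~5 nm inward bias from detector
  truncation, so rulers are kept inside ~260 nm.

What passing tests show: the estimator is efficient (spread within 25% of
σ_CRB) and unbiased inside the FOV under the model's own assumptions, and
the full pipeline separates 20 nm sites at realistic photon budgets. What
they do not show: robustness to drift (the instrument's active
stabilization replaced it), aberrated MDF mismatch, detector artifacts, or
multi-emitter events.

## Event pipeline

Per-orbit trace → two-Gaussian histogram fit → threshold at the mean of the
lower (background) component, per the literal published rule; an
intersection ("valley") alternative is available since thresholding at the
background *mean* deliberately over-segments and relies on the downstream
filters. Filters: ≥2000 photons, ≥5 orbits, per-orbit count std ≤
2.5·sqrt(mean per-orbit count) — the `N` in the Poisson rule is taken as
the mean photons per orbit within the event (the published wording is
ambiguous; recorded as an assumption). Events are split into three
equal-duration segments (remainder to the last), each localized
independently; `σ = sqrt(0.5(σ_x²+σ_y²))` over the three positions uses the
population convention (divide by 3), and the event is accepted iff
σ < σ_TH (8.25 nm default; 5 nm for the tighter ruler analysis). The
reported position is the mean of the three segments. Rendering uses
fixed-width Gaussian kernels (6 nm default); cluster uncertainty is
`sqrt((var_x+var_y)/2)` per user-supplied cluster (automatic clustering is
out of scope).

## Calibration

Reference route: per orbit angle, the bead's micro-image is localized
against the unshifted MDFs; descanned detection makes the apparent position
trace the orbit mirrored through the bead, so an algebraic (Kåsa) circle
fit plus one geometric refinement recovers radius and center. The starting
phase is estimated as the circular mean of `θ_i − dir·2πi/N_c` over all 32
angles (averaging out grid quantization); the rotation direction from the
sign of the median angular increment. The fit recovers the *executed*
orbit — if inertia attenuates the commanded radius, the attenuated value is
returned.

Self-calibration route: the event's counts are localized in 4 quadrants of
8 consecutive orbit angles (probabilities renormalized over the subset)
against MDF sets built for candidate L values (default grid 60–120 nm,
step 2 nm); the spread metric is the rms distance of the quadrant positions
from their centroid, minimized at the true L. Per-event calibration is the
default; pooling several events of one emitter sharpens the minimum and is
what the acceptance test does.

## Problem sizes and determinism

All simulations take explicit integer seeds and are bit-exact reproducible;
the estimator and the bound are deterministic. The test suite uses 400 px
grids, 200-repeat Monte-Carlo batches for efficiency checks, and two 180 s
(~94,000-orbit) synthetic acquisitions for the end-to-end ruler analysis —
sizes at which the medians and spreads being asserted are stable across
seeds.
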