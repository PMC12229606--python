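# ismflux

Single-molecule localization by orbital doughnut scanning with a small
descanned SPAD array detector (ISM-FLUX): a MINFLUX-class method whose
targeted coordinate pattern (TCP) is a fixed circle of diameter *L*, with the
detector array supplying the spatial information that keeps localization
unbiased and finite far outside the TCP.

The package is for microscopists and method developers who want to simulate,
analyze, or benchmark this class of measurement without the instrument: it
covers the molecule detection functions (MDFs), the position estimator, its
information-theoretic limits, a synthetic photon-trace generator, the
blinking-event analysis pipeline for DNA-PAINT data, and orbit calibration.

## Model

A doughnut-shaped excitation focus visits `N_c = 32` positions
`δ_i = (L/2)(cos θ_i, sin θ_i)` on a circle of diameter `L = 90 nm`
(1.92 ms per orbit). At each position the descanned 5×5 array (pitch 150 nm,
element size 100 nm in sample space) records a micro-image. An event reduces
to the count matrix `n_ij` (orbit position `i`, detector element `j`), which
conditional on the total photon number `N` is multinomial:

    L(r_E | {n_ij}) = N! / ∏ n_ij!  ·  ∏_ij  p_ij(r_E)^n_ij

    p_ij(r) = s/(s+1) · m_ij(r)/Σ m_ij(r)  +  1/(s+1) · 1/(N_c·N_d)

where `m_ij(r)` are the MDFs, and `s` is the signal-to-background ratio
(SBR) of a uniform background. The MDFs are built from a parametric scalar
model — excitation doughnut `Exc(ρ) ∝ (ρ²/w²)·exp(−2ρ²/w²)` with
`w = 0.61·λ_exc/NA`, detection PSF a Gaussian with `σ_det = 0.21·λ_em/NA`
integrated over each element's active area — or imported from measured
raster scans. The position estimate is the brute-force maximizer of the
log-likelihood on a coarse-to-fine grid; its precision limit is the
Cramér-Rao bound

    σ_CRB = sqrt( tr(F⁻¹) / 2 ),   F = N Σ_ij (∇p_ij)(∇p_ij)ᵀ / p_ij .

`docs/methods.md` documents the model assumptions, defaults, and numerical
choices in detail.

## Worked example

```python
import numpy as np
from ismflux import (BackgroundModel, DetectorGeometry, EventMatrix,
                     GridSpec, OpticsModel, OrbitGeometry, expected_counts,
                     localize_mle, sigma_crb, simulate_mdf)

optics = OpticsModel()                  # 635/660 nm, NA 1.4
detector = DetectorGeometry()           # 5x5, 150 nm pitch, 100 nm elements
orbit = OrbitGeometry()                 # L = 90 nm, 32 positions, 1.92 ms
mdf = simulate_mdf(optics, detector, orbit,
                   GridSpec(pixel_size=2.5, n_pixels=400))
bkg = BackgroundModel(sbr=10.0)

print(f"sigma_CRB at TCP center (N=100):  {sigma_crb(mdf, bkg, (0, 0), 100):.2f} nm")
print(f"sigma_CRB at 300 nm off-center:   {sigma_crb(mdf, bkg, (300, 0), 100):.2f} nm")

lam = expected_counts(mdf, r_E=(150.0, -80.0), rate=500.0, bkg_rate=50.0)
event = EventMatrix(np.random.default_rng(7).poisson(lam))
res = localize_mle(event, mdf, bkg)
print(f"true position (150.0, -80.0), N = {event.N} photons")
print(f"estimate      ({res.x:.1f}, {res.y:.1f})")
```

prints

```
sigma_CRB at TCP center (N=100):  3.47 nm
sigma_CRB at 300 nm off-center:   12.70 nm
true position (150.0, -80.0), N = 3407 photons
estimate      (147.5, -80.0)
```

The bound is a few nanometers at the TCP center and stays finite (~13 nm)
at the edge of the ~600 nm detector field of view — the array detector is
what keeps an emitter 150 nm *outside* the 45 nm TCP radius localizable to
a couple of nanometers at a few thousand photons.

A thin CLI mirrors the library (`ismflux mdf simulate`, `ismflux crb map`,
`ismflux simulate trace`, `ismflux localize`, `ismflux pipeline`,
`ismflux calibrate reference|self`); run `ismflux --help`.

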