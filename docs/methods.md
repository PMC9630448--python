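# Methods

## Model

Propagation-based phase contrast is modelled in the near-field, homogeneous
object regime.  Under the projection approximation a material of thickness
map T attenuates the incident intensity to I = I₀ exp(−µT) and imprints the
phase φ = −(2π/λ) δ T.  The linearised transport-of-intensity equation then
evolves the normalised intensity over a distance Δ as a multiplication of
its Fourier spectrum by 1 + (δΔ/µ) k⊥²; single-distance retrieval is the
matching division.  Two quantifications of k⊥² are implemented:

- **PM (continuous) kernel** — k⊥² = kx² + ky², the continuous-mathematics
  form;
- **GPM (discrete) kernel** — k⊥² = −(2/W²)[cos(W kx) + cos(W ky) − 2],
  the eigenvalues of the five-point discrete Laplacian on a grid of pixel
  size W, i.e. the form consistent with the DFT the algorithm actually uses.

Both agree to second order near DC; inside the Nyquist square the discrete
kernel is strictly smaller, so the GPM filter H = 1/(1 + (δΔ/µ)k⊥²)
suppresses high spatial frequencies less, and GPM-retrieved images are
sharper than PM-retrieved ones.  The per-frequency comparison statistics
are the ratio R = H_GPM/H_PM ≥ 1, the fractional difference D = R − 1 ≥ 0,
and, with a Gaussian detector CTF G of real-space FWHM Γ pixels, the
PSF-weighted difference D̄ = G·D.  D̄ keeps the *unblurred* H_PM in the
denominator, making D̄ exactly G·D; the alternative normalisation by the
blurred transfer function would instead reproduce D itself and carry no PSF
information.

**Frequency convention.**  All kernels use angular spatial frequencies
k = 2πn/(NW) (DFT index n, signed), so W·k spans [−π, π] and the cos(Wk)
kernel is parameterised naturally.  The Gaussian CTF is written in the same
convention: G = exp(−σ²(kx²+ky²)/2) with σ = Γ·W/(2√(2 ln 2)), the exact
transform of a unit-integral Gaussian PSF whose real-space FWHM is Γ pixels.
On even grids the single unpaired Nyquist sample is assigned +π/W; all
kernels are even in k, so only test bookkeeping depends on this.

**Units.**  Lengths are SI metres, energies keV, attenuation coefficients
1/m.  The dual-energy module works internally in cm and keV: the
Klein–Nishina cross section is in cm² per electron, projected electron
density in cm⁻², and the photoelectric map P in keV³/cm² (the amplitude of
the E⁻³ basis function such that P·E⁻³ contributes to ∫µ dz in 1/cm·cm).
Configuration files require explicit unit suffixes ("25 um", "24 keV") so a
bare number can never silently be in the wrong unit.

## Retrieval operations

`phase_retrieve` divides the spectrum of image/I₀ by 1 + (δΔ/µ)k⊥².  DC
gain is one, so the image mean is preserved exactly; the operation is
linear and shift-invariant.  Real-input FFTs are used (identical to the
complex transform for real data well below 1e−12).  Non-positive or
non-finite pixels are rejected by default; a `repair` flag clips them at
1e−12 of the image median instead.  No padding is applied by default — the
DFT's periodic boundary is part of the model — and a `pad` flag adds
symmetric extension for wraparound-sensitive measured data.

`beltran_retrieve` is the two-material variant: the identical filter with
coefficient (δ₂−δ₁)Δ/(µ₂−µ₁), reducing exactly to the single-material form
when material 1 is vacuum, and rejecting µ₁ = µ₂ as degenerate.

`dual_energy_decompose` inverts, per spatial frequency, the 2×2 system
that expresses −ln I at two energies in the photoelectric/Compton basis,
with the phase term χ k⊥² (χ = h²c²r_eΔ/2πE²) coupled to the electron
density through δ(E) = ρ_e h²c²r_e/(2πE²).  The kernel choice switches k⊥²
between the continuous and discrete forms.  Frequencies where |det| falls
below 1e−12 of its DC value are clamped (count reported); intensities are
clipped at 1e−12 of their median before the logarithm.  The total
Klein–Nishina cross section uses the standard closed form, verified in the
tests against direct angular integration of the differential cross section
and against the Thomson limit at low energy.

## Forward simulator

The disc-phantom protocol (defaults of `Fig2Params`):

| parameter | default | rationale |
| --- | --- | --- |
| detector grid | 2048×2048 px | reference protocol size; `scaled(2)` gives the 1024² half-scale variant used by the acceptance script |
| pixel size W | 25 µm | reference protocol |
| disc radius | 900.5 px | half-pixel offset avoids a row of exactly-on-edge pixels; scaled with the grid |
| thickness | 6 mm | reference protocol |
| material | water (δ = 3.993e−7, µ = 57.2 /m at 24 keV) | the protocol does not state optical constants; these are computed from ρ_e r_e λ²/2π and NIST attenuation data at 24 keV, the energy used in the matching experiments, with densities water 0.998 / PMMA 1.19 g/cm³ |
| upsampling | ×5 | propagation is evaluated on the fine grid so detector sampling is modelled by block averaging, and so retrieval on the detector grid is not the trivial algebraic inverse of the forward multiplication |
| pre-blur | 1.0 detector px | softens the pixelated rim; interpreted in detector pixels and applied on the upsampled grid (5 upsampled px), since "pixel" means detector pixel throughout |
| distance Δ | 4 mm | the reference protocol's stated value.  At these optics it produces a weak fringe (overshoot ≈0.6% of the edge step above background); `find_fringe_distance` provides the alternative operationalisation "smallest Δ with overshoot ≥ threshold×step" (≈8.9 mm at 5%) for users who prefer the fringe criterion.  Only δΔ/µ enters the filter |

Pipeline order: disc thickness → pre-blur (on the thickness map) →
projection approximation → TIE propagation with the continuous kernel on
the upsampled grid → ×5 block average to the detector grid → Gaussian
detector blur of FWHM Γ px → retrieval with each kernel.  Every blur uses
periodic boundaries, consistent with the DFT model, which makes flux
conservation exact.  Rebinning is block *mean* (not sum): on flat-field
normalised intensities the mean is the flux-consistent choice; it
multiplies W by n and divides the PSF-in-pixels by n.

There is no random stage anywhere in the simulation; reruns are
bit-identical.  `add_poisson_noise` exists for robustness experiments only
and takes an explicit generator.

**Linearity domain.**  The linearised TIE multiplies the spectrum by
1 + (δΔ/µ)k⊥², which can drive intensities negative when the product of
fringe curvature and δΔ/µ is large (a regime where real Fresnel propagation
diverges from the linearised operator anyway).  The CT rebinning experiment
therefore softens the cylinder rim by 4 native px before propagating, which
keeps the propagated intensity positive (minimum ≈0.56) at the
indirect-detector conditions (6.5 µm pixels, Δ = 2 m, PMMA); the helper
raises if parameters leave this domain.

## Resolution metrology

Resolution is measured at a circular edge: pixel values are averaged into
radial bins (default 0.25 px wide, with per-bin sample counts; angular arcs
measured from the top of the image, clockwise), the profile is
differentiated (central differences) to an LSF, and a Pearson VII peak
P(x) = A[1 + 4(x−x₀)²/Γ²·(2^{1/m}−1)]^{−m} is fitted.  This
parameterisation makes Γ *exactly* the FWHM — P(x₀ ± Γ/2) = A/2 identically
— and m interpolates Lorentzian (m=1) to Gaussian (m ≳ 10).  Fits are
initialised from the sample peak and half-max crossings with m = 2 and
restarted from m = 1 and 10 on non-convergence; m is bounded to [0.5, 50].
The improvement metric is Γ_I = (Γ_PM − Γ_GPM)/Γ_PM, normalised by Γ_PM
only, with first-order propagation of the two fit standard errors.

The 0.25 px default bin width suits FWHMs ≳ 2 px; for peaks near 1 px the
finite-difference LSF estimator adds ≈h²/3 of variance (h the bin width)
and the tests use bin widths ≤ σ/4, which keeps the bias below 1.5%.  In
the improvement *ratio* the residual estimator bias largely cancels because
it enters both FWHMs.

## CT

`fbp_reconstruct` is a pure-ramp (unapodised) filtered back projection:
the ramp's discrete frequency response is obtained by transforming its
sampled real-space kernel (¼ at 0, −1/(πn)² at odd lags), which keeps the
DC term of the discrete filter correct — a uniform disc reconstructs with
interior bias ~1e−4 and an edge response of ≈1.1 px FWHM.  Backprojection
uses linear interpolation on the detector axis; angles must be uniform over
[0°, 180°); the reconstruction grid equals the detector grid with the
rotation axis at the centred column (sub-pixel shifts via
`axis_shift_px`).  For upright cylinders the transverse Laplacian reduces
to the second derivative along the detector row, so TIE propagation and
retrieval are applied per projection row (`sinogram_propagate`,
`sinogram_retrieve`) — exact for this geometry, and the basis of the
rebinning experiment in `pipelines.rebin_ct_experiment`.

## What the simulations do and do not show

The simulator implements exactly the model the retrieval filters assume:
linearised TIE, homogeneous material, Gaussian PSF, noise-free detection.
Consequences worth keeping in mind:

- On a common grid, each retrieval kernel is the exact inverse of the
  matching forward kernel (verified to 1e−10); PM retrieval of
  continuous-kernel-propagated data recovers the contact image up to
  downsampling aliasing.  Measured Γ_I therefore quantifies the *relative
  sharpness* of the two retrievals under a realistic detector chain, not a
  fidelity difference — in projection space, once heavy rebinning pushes
  the physical blur below one (rebinned) pixel, both retrievals saturate at
  the sampling floor and their difference closes.  The rebinning experiment
  is accordingly run through the CT chain, whose ramp-filtered,
  interpolated reconstruction band-limits at the rebinned Nyquist the way
  the matching experiments were measured.
- Fresnel diffraction, partial coherence, polychromaticity, scintillator
  blur shapes and photon noise are out of scope; passing tests demonstrate
  the discrete-kernel mechanism and its PSF dependence, not detector
  performance on real beamline data.
- The simulation energy and optical constants are an assumption (24 keV
  tabulated values); the resolution-improvement results depend on them only
  through the dimensionless group δΔ/µW², which the transfer-function
  module exposes directly.

## Problem sizes

The acceptance script and tests run the disc protocol at the 1024²
half-scale grid (upsampled working grid 5120², a few seconds per
propagation), the exact-inversion check at 512², the dual-energy round trip
at 256² and the CT rebinning experiment at 1024 detector pixels × 900
angles.  The full 2048² protocol is available from the CLI
(`pbi fig2 --scale full`) and reproduces the same improvements within the
stated tolerance.
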