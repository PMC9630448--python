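# pbi — discrete-kernel phase retrieval for propagation-based X-ray imaging

Single-distance phase retrieval for propagation-based phase-contrast imaging
(PBI) converts the interference fringes that free-space propagation forms at
material boundaries back into a high-SNR map of the object's attenuation.
The standard tool is a Lorentzian Fourier filter derived from the transport
of intensity equation (TIE) for a homogeneous object:

    I_retrieved = DFT⁻¹ [ DFT(I/I₀) / (1 + (δΔ/µ) k⊥²) ]

with δ the refractive-index decrement, µ the linear attenuation coefficient
and Δ the propagation distance.  The classic filter (the "PM" kernel) uses
the continuous squared frequency k⊥² = kx² + ky², although the algorithm is
executed with *discrete* Fourier transforms on a pixel grid.  Rederiving the
filter with the discrete (five-point) Laplacian gives the generalised kernel

    k⊥²_GPM = −(2/W²) [cos(W kx) + cos(W ky) − 2]

(W the pixel size), which is smaller than kx² + ky² everywhere inside the
Nyquist square — the discrete filter suppresses high spatial frequencies
less, so the retrieved images are sharper, with the gain controlled by how
much high-frequency content survives the detector point-spread function
(PSF).  This package implements:

- both retrieval kernels, the transfer functions H = 1/(1 + (δΔ/µ)k⊥²),
  their ratio R = H_GPM/H_PM, the fractional difference D = R − 1 and the
  PSF-weighted difference D̄ = G·D for a Gaussian detector CTF G
  (`pbi.kernels`);
- a deterministic forward simulator: end-on cylinder phantoms, projection
  approximation, linearised-TIE propagation on an upsampled grid, detector
  downsampling, Gaussian PSF blur, pixel rebinning (`pbi.forward_sim`);
- circular-edge resolution metrology: azimuthally averaged edge profiles,
  differentiation to a line-spread function (LSF), Pearson VII fits whose
  Γ parameter is exactly the FWHM, and the improvement metric
  Γ_I = (Γ_PM − Γ_GPM)/Γ_PM (`pbi.metrology`);
- parallel-beam CT support: flat/dark correction, analytic disc sinograms,
  pure-ramp filtered back projection, per-projection retrieval and detector
  rebinning (`pbi.ct`);
- dual-energy Alvarez–Macovski decomposition of two PBI images into
  photoelectric and projected-electron-density maps, with either kernel in
  the phase coupling term (`pbi.spectral`);
- TIFF/YAML I/O with unit-suffixed configuration and a `pbi` command line
  (`pbi.io`, `pbi.config`, `pbi.cli`).

It is written for imaging scientists who want to quantify when the discrete
kernel is worth using: the answer depends almost entirely on the detector
PSF expressed in pixels.

## Worked example

Simulate the water disc phantom at half scale and measure the resolution
improvement of the discrete kernel for three detector PSF widths:

```sh
$ pbi fig2 --scale half --psf-fwhm 1 --psf-fwhm 2 --psf-fwhm 3
PSF 1 px: Gamma_PM 1.347 px, Gamma_GPM 1.289 px, improvement 4.27%
PSF 2 px: Gamma_PM 2.356 px, Gamma_GPM 2.335 px, improvement 0.87%
PSF 3 px: Gamma_PM 3.244 px, Gamma_GPM 3.238 px, improvement 0.20%
```

Each line reports the Pearson VII FWHM of the edge LSF after retrieval with
the continuous (PM) and discrete (GPM) kernels, and the fractional
improvement Γ_I in percent.  With a single-pixel PSF (direct, photon
counting detectors) the discrete kernel buys a few percent of resolution;
by a 3-pixel PSF (typical unbinned indirect detectors) the gain is gone,
because the PSF removes the high frequencies the two kernels disagree on.

The same measurement from Python:

```python
from pbi import pipelines
from pbi.forward_sim import Fig2Params

results = pipelines.fig2_resolution_sweep((1.0,), Fig2Params().scaled(2.0))
print(results[0].improvement)   # gamma_pm, gamma_gpm, improvement, uncertainty
```

Other entry points: `pbi transfer` tabulates the filter comparison curves as
CSV, `pbi retrieve` applies either kernel to a measured projection,
`pbi resolve` fits edge LSFs from TIFFs, `pbi ct` reconstructs a sinogram,
`pbi spectral` runs the dual-energy decomposition.

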