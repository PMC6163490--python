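# Methods

## Physical model and assumptions

The instrument modelled here is a lens-free Gabor in-line holographic
microscope: a quasi-monochromatic source (530 nm LED filtered to 532 nm
with a 10 nm bandpass) illuminates a thin transmissive sample ~80 mm from
the source and a few hundred micrometres from a bare CMOS sensor (1.67 µm
pixels, 3872 × 2764). Because the source-to-sample distance dwarfs the
sample-to-sensor distance, the illumination at the sample is treated as a
**unit plane wave** and the geometric magnification as exactly 1; the
source distance is carried in `OpticalConfig` for documentation only and
plays no role in propagation. Partial coherence (the finite filter
bandwidth and source size), vectorial diffraction, and refraction at the
cover glass are not modelled.

All propagation uses the scalar angular spectrum method on the discrete
FFT grid: `U(z) = IFT[FT(U)·H]`, `H(f) = exp(i2πz√(1/λ² − |f|²))` on the
propagating band and `H = 0` beyond `|f| = 1/λ`. The hard evanescent
cutoff makes back-propagation (negative z) stable; on band-limited fields
propagation is exactly unitary and forms a group in z, which the test
suite asserts at 1e−10 relative tolerance. Transforms are unpadded by
default (periodic boundary); `propagate(..., pad_factor=2)` zero-pads to
suppress circular wraparound at the cost of 4× the transform work. All
lengths are micrometres internally; unit conversion happens only at I/O.

## Pixel super-resolution

The stage shifts the sample over a k × k grid with spacing pitch/k
(k = 6 → 0.278 µm). With unit magnification each low-resolution frame is
an exact sample, on a sub-grid offset by the known stage shift, of the
high-resolution hologram correlated with the k × k pixel-aperture box.
Fusion is therefore deterministic shift-and-add: each frame is splatted
onto the up-sampled grid at its shift (bilinearly when a shift falls
between grid nodes) and normalized by per-pixel coverage. No shift
estimation is performed — the shifts are stage-commanded and known — and
the fused image equals the box-blurred truth to machine precision. The
optional deblur step divides by the box transfer function with a Wiener
regularizer (default 1e−3); since the box OTF has nulls at multiples of
1/pitch, deblur can only recover content below the first null, which is
why its accuracy contract (≤ 5e−2 relative) is stated for band-limited
images. Intensity, not amplitude, is super-resolved; the square root is
taken at the start of phase recovery.

## Autofocus

The sharpness score is the upper 99.9th percentile of the Sobel gradient
magnitude of the reconstructed amplitude — the strength of the sharpest
edge in the image. The field-wide mean gradient is *not* usable as a focus
score for in-line holograms: defocused twin/ring oscillations contribute
gradient over the whole field and can exceed the focused image's mean
(empirically the mean is minimized, not maximized, near focus for bead
scenes). The percentile form keeps the constant-image-zero, offset-
invariance and contrast-linearity properties while peaking decisively at
focus. Autofocus maximizes this score over sample-to-sensor distance with
an 11-point coarse pre-scan (which brackets the global peak and flags
multi-modality) followed by golden-section refinement to a 1 µm bracket.
On simulated bead scenes the result lands within ~0.3 µm of the true
focus; bar targets show a systematic few-µm bias from edge-diffraction
ringing, which is a property of the metric, not of the search.

## Multi-height phase recovery

Holograms at n ≥ 2 heights (≥ 3 recommended; default six heights 20 µm
apart) constrain the lost phase. The field is initialized at the first
(closest) height as √I with zero phase — the deterministic choice; a
seeded random-phase initialization is available as a flag. One iteration
sweeps forward through all heights and back, at each measured plane
replacing the calculated amplitude with the arithmetic mean of calculated
and measured amplitude, keeping the phase. Convergence is declared when
the normalized L2 change of the first-plane field between iterations falls
below `tol` (default 1e−4, capped at 50 iterations); the exact norm is a
package choice since only "a small value" is prescribed by convention.
Heights closer than 2 µm are rejected: the intensity difference between
such planes is too small to drive the update reliably. On noiseless
synthetic scenes the suite asserts that data fidelity does not degrade
after iteration 1 and that background twin-image energy falls below half
of the single-height zero-phase baseline (measured ratio ≈ 5–7%).

## Volume deconvolution

Back-propagating the recovered hologram to a uniform z ladder gives the
measured volume. Its model is `M = O ⊗ PSF` with `O` a sum of point
scatterers (no background term) and `PSF` the stacking operator's response
to a point, simulated with the same propagation kernel: a one-voxel
perturbation on a unit plane wave at the central plane (blocker `1 − δ` by
default, scatterer `1 + δ` optional), forward-propagated to the detector,
background-subtracted, back-propagated to every plane, peak-recentred, and
normalized so its total magnitude sums to 1 (a constant-preserving
kernel).

Because the object model is background-free, the volume handed to the
deconvolvers must be too: `build_measured_volume(..., background="dc")`
subtracts the hologram's complex mean (the unscattered reference) before
stacking. This matters in practice — feeding the raw |backprop| stack,
whose ~unit background has no counterpart in the PSF, makes the
multiplicative update amplify the mismatch and diverge within a few
iterations, while the scattered-field volume (sparse, nonnegative,
compact) is exactly the regime where Gold's method is well behaved. The
default `background="none"` keeps the plain stack used for display and
tomographic sectioning; the pipeline switches to `"dc"` for the
deconvolution stage.

Two deconvolvers are provided:

- **Wiener** (`β` default 0.001): single-pass regularized spectral
  division; exact to 1e−6 in the noiseless well-conditioned limit
  (asserted with β = 1e−12 on forward-convolved volumes).
- **Gold's method** (default, 20 iterations): `O⁽⁰⁾ = M`; each iteration
  re-blurs with the PSF, affinely rescales the re-blur's magnitude so its
  min and max match |M| (phases preserved in complex mode; the affine
  min-and-max reading was chosen over max-only rescaling and is isolated
  in `match_minmax` so it can be swapped), then applies
  `O ← O·M·conj(M⁽ᵏ⁾)/(|M⁽ᵏ⁾|² + β)`. The update preserves nonnegativity
  in amplitude mode. Residuals `‖|M⁽ᵏ⁾| − |M|‖/‖|M|‖` are recorded per
  iteration so late-stage over-fitting is observable; iteration counts
  above 200 trigger a warning rather than an error.

Convolution is circular via 3D FFTs with the PSF origin at index (0,0,0);
a padding flag doubles each dimension for linear convolution. Amplitude
mode (nonnegative real volumes) is the default; complex mode carries the
per-voxel phase through magnitude-only rescaling.

On the reference two-bead scene (1 µm beads at 700 and 760 µm, 256×256×25
volume, 7.5 µm steps) the Gold-deconvolved axial FWHM through each bead is
~7.9 µm versus ~9.8 µm for the plain stack, with out-of-focus background
energy reduced by more than six orders of magnitude — the package's
headline property, asserted as a strict inequality in the suite.

## Synthetic data

The simulator renders thin multi-plane scenes (each plane a complex
transmission grid, |t| ≤ 1) through the multi-slice model: multiply,
propagate to the next plane, repeat, then propagate to the detector and
take |U|². Detector emulation is ideal box integration over k × k blocks
plus optional additive Gaussian noise scaled to the mean intensity (white,
per the noise model the Wiener β guards against); quantization, dark
current and fill factor < 1 are not modelled. Sub-pixel shifts are applied
in the Fourier domain (exact for band-limited intensities) before binning.
Bead centres snap to pixel corners so a 1 µm bead spans exactly 4 pixels
at the 0.278 µm pitch; beads keep a 5-diameter minimum separation and are
assigned round-robin to the requested depth planes. Bar targets are
vertical three-bar groups with 1:1 duty cycle and recorded geometry.
Everything is deterministic per seed.

What passing tests on these scenes do **not** show: robustness to partial
coherence, stage-shift error, sensor nonlinearity, or dense phase-shifting
tissue — the simulator's objects are sparse, thin, and exactly known, so
the suite validates the algorithms' contracts, not clinical image quality.

## Problem sizes and numerical choices

Test and acceptance runs use 192–256 px lateral grids, 25-plane volumes,
and ≤ 20 Gold iterations — small enough for seconds-scale runs while
keeping every geometric parameter (wavelength, pitches, shift grid, height
spacing, β) at its reference value. Degenerate inputs are handled
explicitly: constant images score zero sharpness, a zero-width autofocus
bracket returns its endpoint, a constant-magnitude volume min/max-matches
to the reference maximum, and β = 0 Wiener division is refused whenever
the PSF spectrum has zeros.
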