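# holovol

3D reconstruction for lens-free digital in-line holographic microscopy
(DIHM).

A Gabor-geometry holographic microscope records, on a bare CMOS sensor, the
interference between a plane reference wave and the light scattered by a
thin sample a few hundred micrometres away. The recording is intensity
only, at the sensor's native 1.67 µm pitch, so two artifacts dominate naive
reconstructions: the **twin image** (the conjugate, defocused ghost caused
by phase loss) and **out-of-focus haze** when a 3D volume is assembled by
sectioning. `holovol` implements a two-step pipeline that addresses
under-sampling, phase loss, and axial blur in turn:

1. **Pixel super-resolution (PSR).** The stage steps the sample over a
   6 × 6 sub-pixel grid (spacing = pixel pitch / 6 = 0.278 µm); the 36
   shifted frames are fused by shift-and-add onto the up-sampled grid and
   the pixel-aperture box blur is removed by a regularized inverse filter.
2. **Multi-height phase recovery.** PSR holograms captured at ~6 detector
   heights (20 µm apart) over-determine the complex field. Starting from
   the measured amplitude and zero phase, the field is propagated between
   heights with the angular spectrum method
   `H(f) = exp(i2πz√(1/λ² − |f|²))`, averaging the calculated amplitude
   with the measured √intensity at every height (phase kept), until the
   first-plane field stops changing. Heights are refined by autofocus
   (Sobel sharp-edge score maximized by golden-section search).
3. **Volumetric deconvolution.** Back-propagating the recovered hologram to
   a ladder of depths gives a measured volume `M = O ⊗ PSF`, where `PSF`
   is the point-spread volume of the stacking operator, simulated from a
   point blocker with the same propagation kernel. `O` is recovered either
   by a regularized Wiener filter
   `O = IFT[FT(M)·conj(FT(PSF)) / (|FT(PSF)|² + β)]` or by Gold's
   multiplicative iteration
   `O⁽ᵏ⁾ = O⁽ᵏ⁻¹⁾·M·conj(M⁽ᵏ⁾)/(|M⁽ᵏ⁾|² + β)` with
   `M⁽ᵏ⁾ = O⁽ᵏ⁻¹⁾ ⊗ PSF` min/max-matched to `|M|` each iteration
   (β = 0.001). This confines each object axially and suppresses
   out-of-focus background.

No experimental raw data ship with the package; a forward simulator
(`holovol.simulate`) renders bead and bar-target scenes through the same
multi-slice angular-spectrum model, emulating box-integrating 1.67 µm
pixels, the sub-pixel shift grid, multiple heights, and Gaussian sensor
noise, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from holovol import (OpticalConfig, make_beads, build_measured_volume,
                     simulate_psf, gold_deconvolve)
from holovol.simulate import render_field

cfg = OpticalConfig()                      # 532 nm, 1.67 µm pixels, 6x grid
scene = make_beads(2, 1.0, [700.0, 760.0], seed=7,
                   shape=(256, 256), pitch=cfg.highres_pitch)
holo = render_field(scene, cfg, 860.0)     # detector 860 µm from z = 0
z = np.arange(640.0, 820.0 + 1e-9, 7.5)    # 25 planes
M = build_measured_volume(holo, z, mode="amplitude", background="dc")
psf = simulate_psf(cfg, (256, 256), z, source_kind="point-blocker")
O, residuals = gold_deconvolve(M, psf, beta=0.001, n_iter=20)
```

Measuring the axial full width at half maximum of the amplitude profile
through each bead (window-max per plane) gives, for this seed:

```
stacked back-propagation : 9.8 µm FWHM at both beads
Gold deconvolution       : 7.9 µm FWHM at both beads
background energy ratio  : ~3e-8 % of the stacked volume's
```

i.e. the deconvolved volume is axially tighter at both depths and the
out-of-focus haze between the beads is almost entirely removed, while both
beads stay at their true planes (700 and 760 µm).

The same stages are scriptable from the shell:

```bash
holovol pipeline --config examples/beads.yaml --seed 1 -o out/
holovol fov        # -> 29.85 mm^2 for the 3872 x 2764 sensor
```

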