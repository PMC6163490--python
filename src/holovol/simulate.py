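"""Forward model of the lens-free in-line acquisition.

Generates ground-truth scenes (sparse micro-beads, three-bar resolution
targets), renders their Gabor holograms by multi-slice angular-spectrum
propagation of a unit plane wave, and emulates the detector: box
integration over 1.67 um pixels, the 6 x 6 sub-pixel shift grid of the
motorized stage, multiple detector heights, and optional Gaussian sensor
noise.  Everything is deterministic under a fixed seed, so every pipeline
stage can be tested end-to-end without experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psr import LowResStack, grid_shifts
from .phase import MultiHeightSet
from .wave import ComplexField2D, OpticalConfig, propagate_array

__all__ = [
    "SceneSpec",
    "make_beads",
    "make_bar_target",
    "render_hologram",
    "render_field",
    "acquire_lowres_stack",
    "acquire_multiheight",
]


class SceneError(ValueError):
    """Raised for unrealisable scene requests."""


@dataclass
class SceneSpec:
    """A thin multi-plane transmissive object.

    ``planes`` maps each depth z (um, distance to the detector at the
    nominal first height) to a complex transmission grid with |t| <= 1.
    ``positions`` records ground-truth feature centres (per plane, in
    high-res pixels) for tests.
    """

    planes: list[tuple[float, np.ndarray]]
    pitch: float
    shape: tuple[int, int]
    noise_sigma: float = 0.0
    seed: int = 0
    positions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = []
        for z, t in self.planes:
            t = np.asarray(t, dtype=np.complex128)
            if t.shape != tuple(self.shape):
                raise SceneError(f"plane at z={z} has shape {t.shape}, expected {self.shape}")
            if np.any(np.abs(t) > 1.0 + 1e-9):
                raise SceneError(f"transmission at z={z} exceeds |t| = 1")
            norm.append((float(z), t))
        # sort by decreasing distance to the detector: light hits the
        # farthest plane first
        self.planes = sorted(norm, key=lambda p: -p[0])
        if self.noise_sigma < 0:
            raise SceneError("noise_sigma must be >= 0")


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, radius_px: float) -> np.ndarray:
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius_px**2


def make_beads(
    n: int,
    diameter: float,
    z_planes: list[float],
    seed: int,
    shape: tuple[int, int] = (256, 256),
    pitch: float = 1.67 / 6,
    phase_shift: float | None = None,
    noise_sigma: float = 0.0,
    margin: float = 0.15,
) -> SceneSpec:
    """Sparse micro-beads distributed round-robin over the given depths.

    Beads are opaque disks (or phase-shifting when ``phase_shift`` is a
    phase in radians) of the given diameter (um), placed at uniformly
    sampled lateral positions with minimum centre separation 5x the
    diameter, at least ``margin`` of the field away from the edges.  Bead
    centres snap to pixel corners, so a 1 um bead at the 0.278 um pitch
    spans 4 pixels across.  Deterministic per seed.
    """
    if n < 0:
        raise SceneError("n must be >= 0")
    if diameter <= 0:
        raise SceneError("diameter must be > 0")
    if not z_planes:
        raise SceneError("need at least one z plane")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    radius_px = 0.5 * diameter / pitch
    min_sep_px = 5.0 * diameter / pitch
    lo_y, hi_y = margin * ny, (1 - margin) * ny
    lo_x, hi_x = margin * nx, (1 - margin) * nx

    centres: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while len(centres) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SceneError(
                f"cannot pack {n} beads with separation {5 * diameter} um; "
                f"achieved {len(centres)}"
            )
        # snap to pixel corners (half-integer pixel-centre coordinates)
        cy = np.floor(rng.uniform(lo_y, hi_y)) - 0.5
        cx = np.floor(rng.uniform(lo_x, hi_x)) - 0.5
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep_px**2 for y, x in centres):
            centres.append((cy, cx))

    grids = {float(z): np.ones(shape, dtype=np.complex128) for z in z_planes}
    positions: dict[float, list[tuple[float, float]]] = {float(z): [] for z in z_planes}
    for i, (cy, cx) in enumerate(centres):
        z = float(z_planes[i % len(z_planes)])
        mask = _disk_mask(shape, cy, cx, radius_px)
        if phase_shift is None:
            grids[z][mask] = 0.0
        else:
            grids[z][mask] = np.exp(1j * phase_shift)
        positions[z].append((cy, cx))
    return SceneSpec(
        planes=[(z, g) for z, g in grids.items()],
        pitch=pitch,
        shape=shape,
        noise_sigma=noise_sigma,
        seed=seed,
        positions=positions,
    )


def make_bar_target(
    bar_widths: list[float],
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pitch: float = 1.67 / 6,
    z: float = 800.0,
    noise_sigma: float = 0.0,
) -> SceneSpec:
    """Binary three-bar resolution groups, one per requested width.

    Bars are vertical, opaque, with a 1:1 bar/gap duty cycle; groups are
    laid out left to right with known positions recorded for line-profile
    measurements.  Widths must be at least twice the grid pitch.
    """
    if not bar_widths:
        raise SceneError("need at least one bar width")
    for w in bar_widths:
        if w < 2 * pitch:
            raise SceneError(f"bar width {w} um is below the 2-pixel sampling limit")
    ny, nx = shape
    t = np.ones(shape, dtype=np.complex128)
    positions: dict[str, list] = {"groups": []}
    x0 = int(0.1 * nx)
    y0, y1 = int(0.25 * ny), int(0.75 * ny)
    for w in bar_widths:
        wpx = max(int(round(w / pitch)), 2)
        bars = []
        for b in range(3):
            xa = x0 + b * 2 * wpx
            if xa + wpx > int(0.95 * nx):
                raise SceneError("bar groups exceed the field; use fewer/narrower widths")
            t[y0:y1, xa : xa + wpx] = 0.0
            bars.append((xa, xa + wpx))
        positions["groups"].append({"width_um": float(w), "width_px": wpx, "bars": bars,
                                    "rows": (y0, y1)})
        x0 = bars[-1][1] + 3 * wpx
    return SceneSpec(
        planes=[(float(z), t)],
        pitch=pitch,
        shape=shape,
        noise_sigma=noise_sigma,
        seed=seed,
        positions=positions,
    )


def render_field(scene: SceneSpec, config: OpticalConfig, z_detector: float) -> ComplexField2D:
    """Noiseless complex field at the detector plane.

    Multi-slice model: a unit plane wave is multiplied by each plane's
    transmission in propagation order (farthest from the detector first)
    with angular-spectrum propagation between planes and to the detector.
    ``z_detector`` is the distance from the scene's z = 0 reference (the
    plane depths are distances to the nominal detector, so the detector at
    height z_detector sits z_detector beyond z = 0).
    """
    pitch = scene.pitch
    lam = config.wavelength
    u = np.ones(scene.shape, dtype=np.complex128)
    # plane depths are absolute plane-to-detector distances at this height
    depths = [d for d, _ in scene.planes]
    for d in depths:
        if d <= 0 or d > z_detector:
            raise SceneError(
                f"plane at depth {d} um lies beyond the detector at {z_detector} um"
            )
    prev: float | None = None
    for d, t in scene.planes:  # sorted farthest-first
        if prev is not None and prev > d:
            u = propagate_array(u, pitch, lam, prev - d)
        u = u * t
        prev = d
    u = propagate_array(u, pitch, lam, prev)
    return ComplexField2D(data=u, pitch=pitch, wavelength=lam, z_position=z_detector)


def render_hologram(
    scene: SceneSpec,
    config: OpticalConfig,
    z_detector: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Detector-plane intensity |U|^2 with optional Gaussian sensor noise.

    Noise standard deviation is ``scene.noise_sigma`` times the mean
    intensity; negative intensities are clipped.  Deterministic per seed.
    """
    field = render_field(scene, config, z_detector)
    intensity = field.intensity
    if scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        sigma = scene.noise_sigma * float(intensity.mean())
        intensity = intensity + rng.normal(0.0, sigma, size=intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)
    return intensity


def _fourier_shift(img: np.ndarray, dx_px: float, dy_px: float) -> np.ndarray:
    """Circularly shift an image by (dx, dy) pixels via the Fourier domain."""
    ny, nx = img.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    phase = np.exp(-2j * np.pi * (fx * dx_px + fy * dy_px))
    return np.fft.ifft2(np.fft.fft2(img) * phase).real


def acquire_lowres_stack(
    highres_intensity: np.ndarray,
    config: OpticalConfig,
    seed: int = 0,
    noise_sigma: float = 0.0,
    height_id: int = 0,
) -> LowResStack:
    """Emulate one full sub-pixel-shift acquisition at a single height.

    For each of the k^2 grid shifts, the high-resolution intensity is
    shifted laterally by that sub-pixel amount (Fourier shift, exact for
    band-limited images) and every k x k block is box-averaged to the
    detector pitch.  Shifts are recorded exactly; optional per-frame
    Gaussian noise uses the given seed.
    """
    hi = np.asarray(highres_intensity, dtype=np.float64)
    k = config.upsample_factor
    ny, nx = hi.shape
    if ny % k or nx % k:
        raise SceneError(
            f"high-res dims {hi.shape} not divisible by factor {k}; "
            f"crop to ({ny - ny % k}, {nx - nx % k})"
        )
    rng = np.random.default_rng(seed)
    s = config.pixel_pitch / k  # high-res pitch
    frames: list[np.ndarray] = []
    shifts = grid_shifts(k, config.pixel_pitch)
    for dx, dy in shifts:
        shifted = _fourier_shift(hi, dx / s, dy / s)
        binned = shifted.reshape(ny // k, k, nx // k, k).mean(axis=(1, 3))
        if noise_sigma > 0:
            binned = binned + rng.normal(0.0, noise_sigma * binned.mean(), binned.shape)
        np.clip(binned, 0.0, None, out=binned)
        frames.append(binned)
    return LowResStack(frames=frames, shifts=shifts, pitch=config.pixel_pitch,
                       height_id=height_id)


def acquire_multiheight(
    scene: SceneSpec,
    config: OpticalConfig,
    z_list: list[float],
    seed: int = 0,
    noise_sigma: float = 0.0,
    make_stacks: bool = True,
) -> tuple[list[LowResStack], MultiHeightSet, list[ComplexField2D]]:
    """Full multi-height acquisition of a scene.

    Renders the scene at each detector height in ``z_list`` (increasing
    sample-to-sensor distances, um), produces a sub-pixel-shifted
    low-resolution stack per height (requires grid dims divisible by the
    upsample factor; skipped with ``make_stacks=False``), and returns the
    stacks, the high-resolution intensity set (for pipelines that skip
    PSR), and the noiseless complex detector fields as ground truth.
    """
    z_list = [float(z) for z in z_list]
    if len(z_list) < 2:
        raise SceneError("need at least 2 heights")
    if any(b <= a for a, b in zip(z_list, z_list[1:])):
        raise SceneError("z_list must be strictly increasing")
    rng = np.random.default_rng(seed)
    stacks: list[LowResStack] = []
    highres: list[np.ndarray] = []
    truth: list[ComplexField2D] = []
    for hid, z in enumerate(z_list):
        # deeper detector positions: every scene plane recedes by the same
        # offset, so shift all depths by (z - z_list[0])
        offset = z - z_list[0]
        shifted_scene = SceneSpec(
            planes=[(d + offset, t) for d, t in scene.planes],
            pitch=scene.pitch,
            shape=scene.shape,
            noise_sigma=0.0,
            seed=scene.seed,
            positions=scene.positions,
        )
        fld = render_field(shifted_scene, config, z)
        truth.append(fld)
        intensity = fld.intensity
        sig = max(scene.noise_sigma, noise_sigma)
        if sig > 0:
            noisy = intensity + rng.normal(0.0, sig * intensity.mean(), intensity.shape)
            highres.append(np.clip(noisy, 0.0, None))
        else:
            highres.append(intensity)
        if make_stacks:
            stacks.append(
                acquire_lowres_stack(
                    intensity,
                    config,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise_sigma=sig,
                    height_id=hid,
                )
            )
    mh = MultiHeightSet(holograms=highres, z_nominal=z_list, pitch=scene.pitch)
    return stacks, mh, truth
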