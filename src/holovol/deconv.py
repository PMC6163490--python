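"""3D volumetric deconvolution of stacked holographic reconstructions.

Back-propagating a complex hologram to a ladder of depths gives a measured
volume M whose every plane is contaminated by the out-of-focus response of
objects at other depths.  Modelling M as the 3D convolution of the true
object distribution O with the point-spread volume PSF of the stacking
operator,

    M(r) = O(r) (x) PSF(r),

the object is recovered either by a regularized Wiener inverse filter

    O = IFT[ FT[M] conj(FT[PSF]) / (|FT[PSF]|^2 + beta) ],

or by Gold's multiplicative iteration

    O^(0) = M,
    M^(k) = O^(k-1) (x) PSF,
    O^(k) = O^(k-1) . M . conj(M^(k)) / (|M^(k)|^2 + beta),

with the magnitude of M^(k) affinely rescaled each iteration so its
minimum and maximum match those of |M|.  Gold's update preserves
nonnegativity in amplitude mode and sharpens the axial response of
point-like objects, suppressing the out-of-focus background.

The PSF volume is simulated with the same angular-spectrum kernel that
built M: a single-voxel scatterer (or blocker) on a unit plane wave at the
central depth, forward-propagated to the detector, background-subtracted,
and back-propagated to every depth of the measured volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .wave import OpticalConfig, propagate_array

__all__ = [
    "Volume3D",
    "PSFVolume",
    "build_measured_volume",
    "simulate_psf",
    "convolve3d",
    "wiener_deconvolve",
    "gold_deconvolve",
    "match_minmax",
]

#: Iteration count above which Gold's method is likely over-fitting.
GOLD_ITER_CAP = 200

_Z_UNIFORM_TOL = 1e-9


class InvalidVolume(ValueError):
    """Raised for inconsistent volume geometry."""


def _check_z(z_values: np.ndarray) -> None:
    if len(z_values) == 0:
        raise InvalidVolume("z_values may not be empty")
    dz = np.diff(z_values)
    if len(dz) and np.any(dz <= 0):
        raise InvalidVolume("z_values must be strictly increasing")
    if len(dz) and np.any(np.abs(dz - dz[0]) > _Z_UNIFORM_TOL):
        raise InvalidVolume("z_values must have a uniform step")


@dataclass
class Volume3D:
    """A (nz, ny, nx) stack with uniform z step.

    ``mode`` is ``"amplitude"`` (nonnegative real) or ``"complex"``
    (full complex field per voxel).
    """

    data: np.ndarray
    pitch_xy: float
    z_values: np.ndarray
    mode: str = "amplitude"

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=np.float64)
        if self.mode not in ("amplitude", "complex"):
            raise InvalidVolume(f"mode must be 'amplitude' or 'complex', got {self.mode!r}")
        dtype = np.complex128 if self.mode == "complex" else np.float64
        self.data = np.asarray(self.data, dtype=dtype)
        if self.data.ndim != 3:
            raise InvalidVolume(f"volume must be 3D, got ndim={self.data.ndim}")
        if self.data.shape[0] != len(self.z_values):
            raise InvalidVolume(
                f"{self.data.shape[0]} planes but {len(self.z_values)} z values"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidVolume("volume contains non-finite values")
        if self.mode == "amplitude" and np.any(self.data < 0):
            raise InvalidVolume("amplitude-mode volume must be nonnegative")
        _check_z(self.z_values)
        if self.pitch_xy <= 0:
            raise InvalidVolume(f"pitch_xy must be > 0, got {self.pitch_xy}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def z_step(self) -> float:
        return float(self.z_values[1] - self.z_values[0]) if len(self.z_values) > 1 else 0.0

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


class PSFVolume(Volume3D):
    """A point-spread volume: same layout as :class:`Volume3D`, with the
    total magnitude normalized to 1 and the peak centred on the grid."""


def build_measured_volume(
    hologram, z_values, mode: str = "amplitude", background: str = "none"
) -> Volume3D:
    """Stack back-propagations of a complex hologram into a measured volume.

    Plane ``i`` is the hologram back-propagated by ``z_values[i]`` (um,
    sample-to-sensor); amplitude mode stores |field|, complex mode the
    field itself.

    ``background="dc"`` subtracts the complex mean of the hologram (the
    unscattered reference wave) before stacking, leaving the scattered-
    field volume.  The object model behind the deconvolution is a sum of
    point scatterers with no background term, so this is the volume Gold's
    method should see; the default ``"none"`` keeps the plain stack used
    for display and tomographic sectioning.
    """
    z_values = np.asarray(z_values, dtype=np.float64)
    _check_z(z_values)
    if background not in ("none", "dc"):
        raise InvalidVolume(f"background must be 'none' or 'dc', got {background!r}")
    data = hologram.data
    if background == "dc":
        data = data - data.mean()
    planes = []
    for z in z_values:
        f = propagate_array(data, hologram.pitch, hologram.wavelength, -float(z))
        planes.append(np.abs(f) if mode == "amplitude" else f)
    return Volume3D(
        data=np.stack(planes), pitch_xy=hologram.pitch, z_values=z_values, mode=mode
    )


def simulate_psf(
    config: OpticalConfig,
    shape: tuple[int, int],
    z_values,
    source_kind: str = "point-blocker",
    mode: str = "amplitude",
    delta: float = 1.0,
) -> PSFVolume:
    """Simulate the point-spread volume of the stacking operator.

    A single-voxel perturbation of strength ``delta`` is placed on a unit
    plane wave at the central z plane (``point-scatterer``: transmission
    1 + delta at one pixel; ``point-blocker``: 1 - delta), forward-propagated
    to the detector (taken at the largest z), background-subtracted, and
    back-propagated to every plane of the target volume.  The stack is
    recentred so the peak sits at the grid centre and normalized so its
    total magnitude sums to 1 (a kernel that preserves constants under
    convolution).
    """
    z_values = np.asarray(z_values, dtype=np.float64)
    _check_z(z_values)
    if source_kind not in ("point-scatterer", "point-blocker"):
        raise InvalidVolume(
            f"source_kind must be 'point-scatterer' or 'point-blocker', got {source_kind!r}"
        )
    ny, nx = shape
    nz = len(z_values)
    pitch = config.highres_pitch
    lam = config.wavelength

    zc = float(z_values[nz // 2])
    t = np.ones((ny, nx), dtype=np.complex128)
    sign = 1.0 if source_kind == "point-scatterer" else -1.0
    t[ny // 2, nx // 2] += sign * delta

    det = propagate_array(t, pitch, lam, zc)
    background = propagate_array(np.ones((ny, nx), dtype=np.complex128), pitch, lam, zc)
    scattered = det - background

    planes = []
    for z in z_values:
        f = propagate_array(scattered, pitch, lam, -float(z))
        planes.append(np.abs(f) if mode == "amplitude" else f)
    vol = np.stack(planes)

    # recentre the peak of |PSF| on the grid centre
    mag = np.abs(vol)
    peak = np.unravel_index(int(np.argmax(mag)), mag.shape)
    centre = (nz // 2, ny // 2, nx // 2)
    vol = np.roll(vol, tuple(c - p for c, p in zip(centre, peak)), axis=(0, 1, 2))

    total = np.sum(np.abs(vol))
    if total == 0:
        raise InvalidVolume("degenerate PSF: zero scattered energy")
    vol = vol / total
    return PSFVolume(data=vol, pitch_xy=pitch, z_values=z_values, mode=mode)


def _kernel_spectrum(psf: Volume3D) -> np.ndarray:
    """3D FFT of the PSF with its centre voxel shifted to index (0,0,0)."""
    nz, ny, nx = psf.shape
    kern = np.roll(psf.data, (-(nz // 2), -(ny // 2), -(nx // 2)), axis=(0, 1, 2))
    return np.fft.fftn(kern)


def _check_compatible(a: Volume3D, b: Volume3D) -> None:
    if a.shape != b.shape:
        raise InvalidVolume(f"volume shapes differ: {a.shape} vs {b.shape}")
    if abs(a.pitch_xy - b.pitch_xy) > 1e-12 or abs(a.z_step - b.z_step) > _Z_UNIFORM_TOL:
        raise InvalidVolume("volumes must share pitch and z step")


def convolve3d(obj: Volume3D, psf: Volume3D, pad: bool = False) -> Volume3D:
    """Circular 3D convolution of an object volume with a PSF volume.

    With ``pad`` each dimension is zero-padded to twice its size to
    emulate linear convolution, then cropped back.
    """
    _check_compatible(obj, psf)
    if pad:
        nz, ny, nx = obj.shape
        po = np.zeros((2 * nz, 2 * ny, 2 * nx), dtype=np.complex128)
        pk = np.zeros_like(po)
        po[:nz, :ny, :nx] = obj.data
        pk[:nz, :ny, :nx] = psf.data
        # move the kernel centre voxel to index (0,0,0) of the padded grid;
        # at double size the circular product equals the linear convolution
        pk = np.roll(pk, (-(nz // 2), -(ny // 2), -(nx // 2)), axis=(0, 1, 2))
        out = np.fft.ifftn(np.fft.fftn(po) * np.fft.fftn(pk))[:nz, :ny, :nx]
    else:
        out = np.fft.ifftn(np.fft.fftn(obj.data) * _kernel_spectrum(psf))
    if obj.mode == "amplitude" and psf.mode == "amplitude":
        out = np.clip(out.real, 0.0, None)
        mode = "amplitude"
    else:
        mode = "complex"
    return Volume3D(data=out, pitch_xy=obj.pitch_xy, z_values=obj.z_values, mode=mode)


def wiener_deconvolve(measured: Volume3D, psf: Volume3D, beta: float = 0.001) -> Volume3D:
    """Regularized Wiener inverse filter.

    ``beta`` damps spectral components where the PSF transfers little
    energy; beta = 0 is the raw inverse and is refused when the PSF
    spectrum has zeros.
    """
    _check_compatible(measured, psf)
    if beta < 0:
        raise InvalidVolume(f"beta must be >= 0, got {beta}")
    S = _kernel_spectrum(psf)
    if beta == 0 and np.any(np.abs(S) < 1e-300):
        raise InvalidVolume(
            "PSF spectrum contains zeros; use a positive beta to regularize"
        )
    spec = np.fft.fftn(measured.data) * np.conj(S) / (np.abs(S) ** 2 + beta)
    out = np.fft.ifftn(spec)
    if measured.mode == "amplitude":
        out = out.real
        mode = "amplitude"
        out = np.clip(out, 0.0, None)
    else:
        mode = "complex"
    return Volume3D(data=out, pitch_xy=measured.pitch_xy, z_values=measured.z_values, mode=mode)


def match_minmax(volume: np.ndarray, reference_mag: np.ndarray) -> np.ndarray:
    """Affinely rescale |volume| so its min and max match the reference's.

    Phases are preserved for complex input.  Idempotent: matching an
    already-matched volume changes nothing.  A degenerate (constant-
    magnitude) volume is mapped to the reference maximum.
    """
    mag = np.abs(volume)
    lo, hi = float(mag.min()), float(mag.max())
    rlo, rhi = float(reference_mag.min()), float(reference_mag.max())
    if hi - lo < 1e-300:
        new_mag = np.full_like(mag, rhi)
    else:
        new_mag = rlo + (mag - lo) * (rhi - rlo) / (hi - lo)
    if np.iscomplexobj(volume):
        with np.errstate(invalid="ignore", divide="ignore"):
            phasor = np.where(mag > 0, volume / np.where(mag > 0, mag, 1.0), 1.0)
        return new_mag * phasor
    return new_mag


def gold_deconvolve(
    measured: Volume3D,
    psf: Volume3D,
    beta: float = 0.001,
    n_iter: int = 20,
) -> tuple[Volume3D, list[float]]:
    """Gold's multiplicative iterative deconvolution.

    Starting from the measured volume itself, each iteration re-blurs the
    current estimate with the PSF, affinely matches the min/max of the
    re-blurred magnitude to the measured one, and applies the regularized
    multiplicative update.  Returns the final estimate and the per-
    iteration data-fidelity residuals ``||M(k)| - |M|| / ||M||``.

    Too many iterations over-fit the data; a warning is issued above
    ``GOLD_ITER_CAP``.
    """
    _check_compatible(measured, psf)
    if n_iter < 1:
        raise InvalidVolume(f"n_iter must be >= 1, got {n_iter}")
    if beta <= 0:
        raise InvalidVolume(f"beta must be > 0 for Gold's method, got {beta}")
    if n_iter > GOLD_ITER_CAP:
        warnings.warn(
            f"n_iter={n_iter} exceeds {GOLD_ITER_CAP}; too many iterations "
            "over-fit the object",
            stacklevel=2,
        )
    M = measured.data
    M_mag = np.abs(M)
    M_norm = float(np.linalg.norm(M_mag))
    O = M.copy()
    residuals: list[float] = []
    for _ in range(n_iter):
        est = convolve3d(
            Volume3D(O, measured.pitch_xy, measured.z_values, measured.mode), psf
        )
        Mk = match_minmax(est.data, M_mag)
        residuals.append(float(np.linalg.norm(np.abs(Mk) - M_mag) / (M_norm + 1e-300)))
        O = O * M * np.conj(Mk) / (np.abs(Mk) ** 2 + beta)
        if measured.mode == "amplitude":
            O = np.clip(O.real, 0.0, None)
    out = Volume3D(O, measured.pitch_xy, measured.z_values, measured.mode)
    return out, residuals
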