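"""Scalar wave propagation by the angular spectrum method.

Free-space propagation of a monochromatic complex field over a distance
``z`` is computed by multiplying its 2D Fourier transform by the transfer
function

    H(fx, fy) = exp(i 2 pi z sqrt(1/lambda^2 - fx^2 - fy^2))

on the propagating band ``fx^2 + fy^2 <= 1/lambda^2`` and zero on the
evanescent components (hard cutoff, so back-propagation never amplifies
exponentially decaying waves).  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalConfig",
    "ComplexField2D",
    "transfer_function",
    "propagate",
    "propagate_array",
]


class InvalidConfiguration(ValueError):
    """Raised for non-physical optical parameters."""


@dataclass(frozen=True)
class OpticalConfig:
    """Physical acquisition geometry; the single source of truth for units.

    Parameters
    ----------
    wavelength:
        Illumination wavelength in um (green LED through a 532 nm filter).
    pixel_pitch:
        Detector pixel pitch in um.
    upsample_factor:
        Pixel super-resolution factor ``k``; the sub-pixel shift grid is
        ``k x k`` and the reconstructed pitch is ``pixel_pitch / k``.
    z_sample_to_sensor:
        Nominal sample-to-sensor distance in um.
    z_source_to_sample:
        Source-to-sample distance in um.  Large compared to the
        sample-to-sensor distance, so the illumination is treated as a unit
        plane wave and the geometric magnification is 1; kept for
        documentation and simulator realism only.
    refractive_index:
        Medium refractive index (air).
    """

    wavelength: float = 0.532
    pixel_pitch: float = 1.67
    upsample_factor: int = 6
    z_sample_to_sensor: float = 721.0
    z_source_to_sample: float = 80_000.0
    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise InvalidConfiguration(f"wavelength must be > 0, got {self.wavelength}")
        if self.pixel_pitch <= 0:
            raise InvalidConfiguration(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if int(self.upsample_factor) != self.upsample_factor or self.upsample_factor < 1:
            raise InvalidConfiguration(
                f"upsample_factor must be a positive integer, got {self.upsample_factor}"
            )
        if self.refractive_index <= 0:
            raise InvalidConfiguration("refractive_index must be > 0")

    @property
    def highres_pitch(self) -> float:
        """Reconstruction grid pitch in um (0.278 um at defaults)."""
        return self.pixel_pitch / self.upsample_factor

    def fov_mm2(self, sensor_dims: tuple[int, int]) -> float:
        """Field of view area in mm^2 for a sensor of (nx, ny) pixels."""
        nx, ny = sensor_dims
        if nx <= 0 or ny <= 0:
            raise InvalidConfiguration("sensor dims must be positive")
        return (nx * self.pixel_pitch) * (ny * self.pixel_pitch) * 1e-6


@dataclass
class ComplexField2D:
    """A complex wave amplitude sampled on a uniform grid.

    ``z_position`` tags the plane the field lives on, measured as distance
    from the sample plane toward the detector (um).
    """

    data: np.ndarray
    pitch: float
    wavelength: float
    z_position: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError(f"field data must be 2D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite values")
        if self.pitch <= 0:
            raise InvalidConfiguration(f"pitch must be > 0, got {self.pitch}")
        if self.wavelength <= 0:
            raise InvalidConfiguration(f"wavelength must be > 0, got {self.wavelength}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def energy(self) -> float:
        """Total power sum(|U|^2)."""
        return float(np.sum(np.abs(self.data) ** 2))


def transfer_function(
    shape: tuple[int, int], pitch: float, wavelength: float, z: float
) -> np.ndarray:
    """Angular-spectrum transfer function on the discrete FFT frequency grid.

    Parameters
    ----------
    shape:
        (ny, nx) grid dimensions.
    pitch:
        Grid pitch in um.
    wavelength:
        Wavelength in um.
    z:
        Signed propagation distance in um; negative back-propagates.

    Returns
    -------
    Complex (ny, nx) array, unit modulus on the propagating band and zero
    on evanescent components.
    """
    if pitch <= 0:
        raise InvalidConfiguration(f"pitch must be > 0, got {pitch}")
    if wavelength <= 0:
        raise InvalidConfiguration(f"wavelength must be > 0, got {wavelength}")
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise InvalidConfiguration(f"grid must be at least 2x2, got {shape}")
    fy = np.fft.fftfreq(ny, d=pitch)[:, None]
    fx = np.fft.fftfreq(nx, d=pitch)[None, :]
    arg = 1.0 / wavelength**2 - fx**2 - fy**2
    propagating = arg >= 0.0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    H = np.where(propagating, np.exp(2j * np.pi * z * kz), 0.0 + 0.0j)
    return H


def propagate_array(
    data: np.ndarray, pitch: float, wavelength: float, z: float, pad_factor: int = 1
) -> np.ndarray:
    """Propagate a raw complex array by ``z`` um; shape is preserved.

    ``pad_factor`` > 1 zero-pads each dimension by that factor before the
    transform to suppress circular wraparound, then crops back.  The default
    (1) is the exact periodic convention.
    """
    data = np.asarray(data, dtype=np.complex128)
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise InvalidConfiguration(f"pad_factor must be a positive integer, got {pad_factor}")
    ny, nx = data.shape
    if pad_factor > 1:
        py, px = ny * pad_factor, nx * pad_factor
        buf = np.zeros((py, px), dtype=np.complex128)
        oy, ox = (py - ny) // 2, (px - nx) // 2
        buf[oy : oy + ny, ox : ox + nx] = data
        H = transfer_function((py, px), pitch, wavelength, z)
        out = np.fft.ifft2(np.fft.fft2(buf) * H)
        return out[oy : oy + ny, ox : ox + nx]
    H = transfer_function((ny, nx), pitch, wavelength, z)
    return np.fft.ifft2(np.fft.fft2(data) * H)


def propagate(field: ComplexField2D, z: float, pad_factor: int = 1) -> ComplexField2D:
    """Propagate a :class:`ComplexField2D` by a signed distance ``z`` (um).

    Negative ``z`` back-propagates toward the source.  Returns a new field
    with the same shape and pitch and an updated ``z_position`` tag.
    """
    out = propagate_array(field.data, field.pitch, field.wavelength, z, pad_factor=pad_factor)
    return ComplexField2D(
        data=out,
        pitch=field.pitch,
        wavelength=field.wavelength,
        z_position=field.z_position + z,
    )


def bandlimit(data: np.ndarray, pitch: float, wavelength: float) -> np.ndarray:
    """Project an array onto the propagating band (evanescent mask at z=0).

    Useful for preparing fields on which propagation is exactly unitary.
    """
    H0 = transfer_function(np.asarray(data).shape, pitch, wavelength, 0.0)
    return np.fft.ifft2(np.fft.fft2(np.asarray(data, dtype=np.complex128)) * H0)
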