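"""Pixel super-resolution: fuse sub-pixel-shifted low-resolution frames.

The sensor under-samples the hologram at its 1.67 um pitch.  A motorized
stage steps the sample over a k x k rectangular grid with spacing
``pitch / k`` (0.278 um for k = 6); the k^2 low-resolution frames are
deterministic samples of the high-resolution hologram blurred by the pixel
aperture, and shift-and-add onto the up-sampled grid recovers that blurred
image exactly.  An optional regularized inverse filter then removes the
k x k box blur of the pixel aperture.

Because the stage shifts are known to sub-pixel accuracy, no shift
estimation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LowResStack", "grid_shifts", "synthesize_highres"]


class InvalidStack(ValueError):
    """Raised for inconsistent low-resolution stacks."""


@dataclass
class LowResStack:
    """N intensity frames with their known sub-pixel (dx, dy) stage shifts.

    ``shifts`` are sample-plane displacements in um (magnification is 1, so
    sample-plane and detector-plane shifts coincide).  ``pitch`` is the
    detector pixel pitch in um.
    """

    frames: list[np.ndarray]
    shifts: list[tuple[float, float]]
    pitch: float
    height_id: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise InvalidStack("stack needs at least one frame")
        if len(self.frames) != len(self.shifts):
            raise InvalidStack(
                f"{len(self.frames)} frames but {len(self.shifts)} shifts"
            )
        shape = np.asarray(self.frames[0]).shape
        frames = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=np.float64)
            if f.shape != shape:
                raise InvalidStack(f"frame {i} shape {f.shape} != {shape}")
            if np.any(f < 0):
                raise InvalidStack(f"frame {i} has negative intensities")
            frames.append(f)
        self.frames = frames
        self.shifts = [(float(dx), float(dy)) for dx, dy in self.shifts]
        if self.pitch <= 0:
            raise InvalidStack(f"pitch must be > 0, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


def grid_shifts(upsample_factor: int, pitch: float) -> list[tuple[float, float]]:
    """The k^2 stage shift vectors of a full acquisition, row-major.

    Spacing is ``pitch / k``; for k = 6 at 1.67 um pitch this is the
    0.278 um grid with 36 positions.
    """
    k = upsample_factor
    if int(k) != k or k < 1:
        raise InvalidStack(f"upsample_factor must be a positive integer, got {k}")
    if pitch <= 0:
        raise InvalidStack(f"pitch must be > 0, got {pitch}")
    s = pitch / k
    return [(i * s, j * s) for j in range(k) for i in range(k)]


def _box_otf(shape: tuple[int, int], k: int) -> np.ndarray:
    """FFT of the normalized k x k box kernel anchored at indices 0..k-1."""
    ny, nx = shape
    kern = np.zeros((ny, nx))
    kern[:k, :k] = 1.0 / k**2
    return np.fft.fft2(kern)


def synthesize_highres(
    stack: LowResStack,
    upsample_factor: int,
    deblur: bool = False,
    deblur_reg: float = 1e-3,
) -> np.ndarray:
    """Fuse a shifted low-resolution stack into one high-resolution image.

    Each frame with stage shift ``(dx, dy)`` samples the pixel-aperture-
    blurred high-resolution hologram on a sub-grid offset by that shift;
    the frames are splatted back onto the ``k * ny x k * nx`` grid
    (bilinearly, for shifts that fall between grid nodes) and normalized by
    per-pixel coverage.  With ``deblur`` the k x k box blur of the pixel
    aperture is removed by a Wiener-regularized inverse filter
    (regularizer ``deblur_reg``).

    Returns a nonnegative intensity grid at pitch ``stack.pitch / k``.
    """
    k = upsample_factor
    if int(k) != k or k < 1:
        raise InvalidStack(f"upsample_factor must be a positive integer, got {k}")
    k = int(k)
    ny, nx = stack.shape
    if k == 1 and len(stack.frames) == 1:
        return stack.frames[0].copy()
    Ny, Nx = ny * k, nx * k
    s = stack.pitch / k

    acc = np.zeros((Ny, Nx))
    cov = np.zeros((Ny, Nx))
    rows0 = np.arange(ny) * k
    cols0 = np.arange(nx) * k
    warned = False
    for frame, (dx, dy) in zip(stack.frames, stack.shifts):
        if not (0.0 <= dx < stack.pitch and 0.0 <= dy < stack.pitch):
            if not warned:
                warnings.warn(
                    "shift outside [0, pitch); reduced modulo the pixel pitch",
                    stacklevel=2,
                )
                warned = True
            dx %= stack.pitch
            dy %= stack.pitch
        # fractional grid-node position of this frame's sub-grid
        gx, gy = dx / s, dy / s
        ix, fx = int(np.floor(gx)), gx - np.floor(gx)
        iy, fy = int(np.floor(gy)), gy - np.floor(gy)
        # bilinear splat over the four surrounding nodes; collapses to a
        # single node when the shift sits exactly on the grid
        for ox, wxv in (((ix, 1.0 - fx),) if fx < 1e-9 else ((ix, 1.0 - fx), (ix + 1, fx))):
            for oy, wyv in (((iy, 1.0 - fy),) if fy < 1e-9 else ((iy, 1.0 - fy), (iy + 1, fy))):
                w = wxv * wyv
                r = (rows0[:, None] - oy) % Ny
                c = (cols0[None, :] - ox) % Nx
                np.add.at(acc, (r, c), w * frame)
                np.add.at(cov, (r, c), w)
    if np.any(cov == 0):
        raise InvalidStack(
            "incomplete shift coverage: some high-resolution pixels receive no data"
        )
    out = acc / cov
    if deblur:
        otf = _box_otf((Ny, Nx), k)
        spec = np.fft.fft2(out) * otf / (np.abs(otf) ** 2 + deblur_reg)
        out = np.fft.ifft2(spec).real
        np.clip(out, 0.0, None, out=out)
    return out
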