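"""Autofocus and multi-height iterative phase recovery.

An in-line hologram records intensity only; the lost phase produces the
defocused twin image in single-shot reconstructions.  Recording the
hologram at several sample-to-sensor distances over-determines the field:
iteratively propagating between the measured planes and pulling the
calculated amplitude toward the measured one (the phase is kept) converges
to a complex hologram whose reconstruction is largely twin-image free.

Focus distances are refined by maximizing a Sobel sharpness score with a
golden-section search, bracketed by a coarse pre-scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .wave import ComplexField2D, propagate, propagate_array

__all__ = [
    "MultiHeightSet",
    "RecoveryReport",
    "sharpness",
    "autofocus",
    "recover_phase",
    "single_height_reconstruction",
]

#: Minimum spacing between detector heights (um); sub-micron steps give
#: too little intensity transition for reliable recovery.
MIN_DZ = 2.0

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class InvalidHeights(ValueError):
    """Raised for unusable multi-height geometry."""


@dataclass
class MultiHeightSet:
    """Super-resolved hologram intensities at several detector heights.

    ``z_nominal`` are the stage's sample-to-sensor distances (um), strictly
    increasing with at least ``MIN_DZ`` separation; ``z_refined`` is filled
    in by :func:`autofocus` (or copied from nominal).
    """

    holograms: list[np.ndarray]
    z_nominal: list[float]
    pitch: float
    z_refined: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.holograms) != len(self.z_nominal):
            raise InvalidHeights(
                f"{len(self.holograms)} holograms but {len(self.z_nominal)} heights"
            )
        if len(self.holograms) < 2:
            raise InvalidHeights("phase recovery needs at least 2 heights (3+ recommended)")
        shape = np.asarray(self.holograms[0]).shape
        grids = []
        for i, h in enumerate(self.holograms):
            h = np.asarray(h, dtype=np.float64)
            if h.shape != shape:
                raise InvalidHeights(f"hologram {i} shape {h.shape} != {shape}")
            if np.any(h < 0) or not np.all(np.isfinite(h)):
                raise InvalidHeights(f"hologram {i} must be finite and nonnegative")
            grids.append(h)
        self.holograms = grids
        z = [float(v) for v in self.z_nominal]
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise InvalidHeights(f"z_nominal must be strictly increasing, got {z}")
        if np.any(dz < MIN_DZ):
            raise InvalidHeights(
                f"adjacent heights closer than {MIN_DZ} um make recovery unreliable: {z}"
            )
        self.z_nominal = z
        if self.pitch <= 0:
            raise InvalidHeights(f"pitch must be > 0, got {self.pitch}")

    @property
    def z(self) -> list[float]:
        """Refined heights if available, else nominal."""
        return self.z_refined if self.z_refined is not None else self.z_nominal


@dataclass
class RecoveryReport:
    iterations_run: int
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False


def sharpness(image: np.ndarray, percentile: float = 99.9) -> float:
    """Sobel sharp-edge score of an amplitude image.

    The score is the upper ``percentile`` of the Sobel gradient magnitude
    distribution: the strength of the sharpest edges in the image.  At the
    focus plane an absorbing object's boundary collapses into a one- to
    two-pixel transition whose gradient towers over the defocus ring
    oscillations, so this score peaks at focus; the field-wide *mean*
    gradient does not, because out-of-focus rings contribute gradient
    everywhere.  ``percentile=0`` degrades to the plain mean.

    Zero for a constant image; invariant to an additive offset and linear
    in the image contrast.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError(f"need a 2D image of at least 3x3, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    g = np.hypot(gx, gy)
    if percentile <= 0:
        return float(np.mean(g))
    return float(np.percentile(g, percentile))


def _focus_score(data: np.ndarray, pitch: float, wavelength: float, z: float) -> float:
    recon = propagate_array(data, pitch, wavelength, -z)
    return sharpness(np.abs(recon))


def autofocus(
    hologram: ComplexField2D | np.ndarray,
    z_lo: float,
    z_hi: float,
    tol: float = 1.0,
    pitch: float | None = None,
    wavelength: float | None = None,
    n_prescan: int = 11,
) -> float:
    """Find the focus distance by golden-section search on Sobel sharpness.

    The hologram is back-propagated over candidate distances in
    ``[z_lo, z_hi]`` and the distance maximizing the sharpness of the
    reconstructed amplitude is returned (bracket midpoint once the bracket
    is narrower than ``tol`` um).  A coarse pre-scan of ``n_prescan``
    points picks the initial bracket; a non-unimodal response triggers a
    non-fatal warning and the best bracket found is used.

    Raw intensity arrays are accepted if ``pitch`` and ``wavelength`` are
    given; the amplitude (square root of intensity) is reconstructed.
    """
    if isinstance(hologram, ComplexField2D):
        data, pitch, wavelength = hologram.data, hologram.pitch, hologram.wavelength
    else:
        if pitch is None or wavelength is None:
            raise ValueError("pitch and wavelength required for a raw intensity grid")
        data = np.sqrt(np.asarray(hologram, dtype=np.float64))
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if z_lo > z_hi:
        raise ValueError(f"need z_lo <= z_hi, got [{z_lo}, {z_hi}]")
    if z_lo == z_hi:
        return float(z_lo)

    zs = np.linspace(z_lo, z_hi, n_prescan)
    scores = np.array([_focus_score(data, pitch, wavelength, z) for z in zs])
    best = int(np.argmax(scores))
    # count interior local maxima to detect multi-modality
    interior = (scores[1:-1] > scores[:-2]) & (scores[1:-1] >= scores[2:])
    if int(np.sum(interior)) > 1:
        warnings.warn(
            "sharpness response is multi-modal over the search range; "
            "refining around the best pre-scan point",
            stacklevel=2,
        )
    a = zs[max(best - 1, 0)]
    b = zs[min(best + 1, n_prescan - 1)]

    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _focus_score(data, pitch, wavelength, c)
    fd = _focus_score(data, pitch, wavelength, d)
    while (b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = _focus_score(data, pitch, wavelength, c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = _focus_score(data, pitch, wavelength, d)
    return float(0.5 * (a + b))


_DEFAULT_WAVELENGTH = 0.532


def refine_heights(
    heights: MultiHeightSet,
    wavelength: float = _DEFAULT_WAVELENGTH,
    half_window: float = 10.0,
    tol: float = 0.5,
) -> MultiHeightSet:
    """Refine each nominal height by autofocus within +/- ``half_window`` um."""
    refined = [
        autofocus(
            h,
            z - half_window,
            z + half_window,
            tol=tol,
            pitch=heights.pitch,
            wavelength=wavelength,
        )
        for h, z in zip(heights.holograms, heights.z_nominal)
    ]
    heights.z_refined = refined
    return heights


def recover_phase(
    heights: MultiHeightSet,
    wavelength: float = _DEFAULT_WAVELENGTH,
    max_iter: int = 50,
    tol: float = 1e-4,
    init_phase: str = "zero",
    seed: int | None = None,
) -> tuple[ComplexField2D, RecoveryReport]:
    """Multi-height phase recovery; returns the complex hologram at the
    first (closest) height and a convergence report.

    The field is initialized at the first height with the measured
    amplitude (square root of intensity) and zero phase, then swept
    forward through the measured heights and back; at each height the
    calculated amplitude is replaced by the arithmetic mean of calculated
    and measured amplitude while the phase is kept.  One forward+backward
    sweep is one iteration; the loop stops when the normalized L2 change of
    the first-plane field drops below ``tol``.

    ``init_phase="random"`` (with ``seed``) starts from uniformly random
    phase instead, for reproducing random-initialization experiments.
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    if heights.z_refined is None:
        warnings.warn(
            "z_refined not populated; falling back to nominal heights", stacklevel=2
        )
    z = heights.z
    amps = [np.sqrt(h) for h in heights.holograms]
    pitch = heights.pitch

    if init_phase == "zero":
        u = amps[0].astype(np.complex128)
    elif init_phase == "random":
        rng = np.random.default_rng(seed)
        u = amps[0] * np.exp(2j * np.pi * rng.random(amps[0].shape))
    else:
        raise ValueError(f"init_phase must be 'zero' or 'random', got {init_phase!r}")

    n = len(z)
    report = RecoveryReport(iterations_run=0)
    prev_first = u.copy()
    norm0 = np.linalg.norm(prev_first)
    for _ in range(max_iter):
        # forward sweep to the farthest height
        for i in range(1, n):
            u = propagate_array(u, pitch, wavelength, z[i] - z[i - 1])
            u = _apply_amplitude(u, amps[i])
        # backward sweep to the first height
        for i in range(n - 2, -1, -1):
            u = propagate_array(u, pitch, wavelength, z[i] - z[i + 1])
            u = _apply_amplitude(u, amps[i])
        report.iterations_run += 1
        resid = float(np.linalg.norm(u - prev_first) / (norm0 + 1e-300))
        report.residual_history.append(resid)
        prev_first = u.copy()
        if resid < tol:
            report.converged = True
            break
    field_out = ComplexField2D(data=u, pitch=pitch, wavelength=wavelength, z_position=z[0])
    return field_out, report


def _apply_amplitude(u: np.ndarray, measured_amp: np.ndarray) -> np.ndarray:
    """Average the calculated amplitude with the measured one; keep phase."""
    amp = np.abs(u)
    target = 0.5 * (amp + measured_amp)
    # unit phasor; zero-amplitude pixels get phase 0
    with np.errstate(invalid="ignore", divide="ignore"):
        phasor = np.where(amp > 0, u / np.where(amp > 0, amp, 1.0), 1.0)
    return target * phasor


def single_height_reconstruction(
    intensity: np.ndarray, pitch: float, wavelength: float, z: float
) -> ComplexField2D:
    """Zero-phase single-shot baseline: sqrt(intensity) back-propagated by z.

    This is the reconstruction the twin image contaminates; used as the
    reference against which multi-height recovery is judged.
    """
    amp = np.sqrt(np.asarray(intensity, dtype=np.float64))
    out = propagate_array(amp.astype(np.complex128), pitch, wavelength, -z)
    return ComplexField2D(data=out, pitch=pitch, wavelength=wavelength, z_position=0.0)
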