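"""Sampled complex wavefronts and scalar free-space diffraction.

The carrier type is :class:`ComplexField`: a square 2-D complex array with a
physical sample pitch and a wavelength.  Propagation uses the exact
(non-paraxial) angular-spectrum transfer function

    H(fx, fy; z) = exp( i·2π·z·sqrt(1/λ² − fx² − fy²) )

applied on the FFT frequency grid, with evanescent components
(fx² + fy² > 1/λ²) set to zero.  Negative ``z`` back-propagates; the pitch is
unchanged by propagation.

Grid convention: pixel-centred coordinates with the origin at the array
centre pixel ``(n//2, n//2)``; spectra are handled in centred (DC-at-middle)
layout wherever they are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "ComplexField",
    "spatial_axes",
    "angular_spectrum_propagate",
    "tilted_plane_wave",
    "coma_phase",
]


@dataclass
class ComplexField:
    """A sampled 2-D complex wavefront on a uniform square grid.

    Attributes
    ----------
    values : (n, n) complex ndarray
    pitch : float
        Sample spacing in metres.
    wavelength : float
        Wavelength in metres.
    """

    values: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("field must be a square 2-D array")
        if self.values.shape[0] < 2:
            raise ValueError("field side must be at least 2 samples")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def power(self) -> float:
        """Total power Σ|values|²."""
        return float(np.sum(np.abs(self.values) ** 2))

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def with_values(self, values: np.ndarray) -> "ComplexField":
        return replace(self, values=values)

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


def spatial_axes(n: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Centred pixel coordinates (x, y) in metres; origin at pixel n//2."""
    c = np.arange(n) - n // 2
    return c * pitch, c * pitch


def _transfer_function(n: int, pitch: float, wavelength: float, z: float) -> np.ndarray:
    f = np.fft.fftfreq(n, d=pitch)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    fsq = fx * fx + fy * fy
    arg = 1.0 / wavelength**2 - fsq
    propagating = arg > 0
    kz = np.zeros_like(arg)
    kz[propagating] = 2.0 * np.pi * np.sqrt(arg[propagating])
    H = np.where(propagating, np.exp(1j * z * kz), 0.0)
    return H


def angular_spectrum_propagate(
    field: ComplexField,
    z: float,
    pad: int = 0,
    pad_mode: str = "edge",
) -> ComplexField:
    """Propagate a wavefront a signed distance ``z`` by the angular spectrum method.

    Parameters
    ----------
    field : ComplexField
    z : float
        Propagation distance in metres; negative values back-propagate.
    pad : int, optional
        Guard band in pixels added on every side before the FFT and cropped
        afterwards, to suppress periodic wrap-around of the FFT propagator.
    pad_mode : str, optional
        ``numpy.pad`` mode for the guard band (default replicates the edge,
        which continues a uniform background without creating an aperture).

    Notes
    -----
    Evanescent spectral components are truncated to zero, so power is
    conserved exactly only while all content propagates; with that condition
    ``propagate(z)`` followed by ``propagate(-z)`` is the identity and
    propagation distances compose additively.
    """
    v = field.values
    if pad:
        v = np.pad(v, pad, mode=pad_mode)
    if z == 0 and pad == 0:
        return field.copy()
    H = _transfer_function(v.shape[0], field.pitch, field.wavelength, z)
    out = np.fft.ifft2(np.fft.fft2(v) * H)
    if pad:
        out = out[pad:-pad, pad:-pad]
    return field.with_values(out)


def tilted_plane_wave(
    n: int,
    pitch: float,
    wavelength: float,
    fx: float,
    fy: float,
    amplitude: float = 1.0,
) -> ComplexField:
    """Unit-modulus plane wave ``A·exp(i·2π(fx·x + fy·y))`` on the centred grid.

    ``fx``, ``fy`` are transverse spatial frequencies in cycles/m and must be
    below the grid Nyquist frequency ``1/(2·pitch)``.
    """
    nyq = 1.0 / (2.0 * pitch)
    if abs(fx) >= nyq or abs(fy) >= nyq:
        raise ValueError(
            f"carrier ({fx:g}, {fy:g}) cycles/m at or beyond Nyquist {nyq:g}"
        )
    x, y = spatial_axes(n, pitch)
    X, Y = np.meshgrid(x, y, indexing="xy")
    return ComplexField(
        amplitude * np.exp(2j * np.pi * (fx * X + fy * Y)), pitch, wavelength
    )


def coma_phase(
    n: int,
    pitch: float,
    wavelength: float,
    coeff: float,
    axis: Literal["x", "y"] = "x",
) -> ComplexField:
    """Unit-amplitude field carrying a Zernike primary-coma phase.

    The phase is ``coeff · (3ρ³ − 2ρ) · cosθ`` (axis ``x``) or ``· sinθ``
    (axis ``y``), with the radial coordinate normalised to the half-diagonal
    of the grid so the polynomial argument stays within [0, 1] everywhere.
    ``coeff`` is in radians.  The polynomial is odd, so the phase is
    antisymmetric under point reflection through the centre.
    """
    x, y = spatial_axes(n, pitch)
    X, Y = np.meshgrid(x, y, indexing="xy")
    half_diag = np.hypot(x[0], y[0])  # corner pixel radius
    rho = np.hypot(X, Y) / half_diag
    theta = np.arctan2(Y, X)
    radial = 3.0 * rho**3 - 2.0 * rho
    trig = np.cos(theta) if axis == "x" else np.sin(theta)
    return ComplexField(np.exp(1j * coeff * radial * trig), pitch, wavelength)
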