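"""Optical geometry of a point-source lensless off-axis holographic microscope.

The instrument records a Fresnel diffraction pattern of a sample illuminated
by a divergent spherical wave: a point source sits a distance ``z1`` upstream
of the sample and the bare sensor a distance ``z2`` downstream.  A diffraction
grating upstream splits the illumination into laterally separated point
sources so that light passing a sample-free region of the multiplexed sample
plane acts as a tilted reference wave, imprinting a carrier fringe on the
recorded hologram (common-path off-axis geometry).

This module holds the closed-form system relations of that geometry:

* geometric magnification ``M = (z1 + z2) / z1`` of the recorded pattern,
* field of view side length ``L·p / M`` on the object plane,
* the diffraction-limited lateral resolution ``2·λ·z2 / (L·p)``,
* the lateral separation ``N·λ·f_FL`` of the grating's point-source replicas,

together with the Fresnel-scaling equivalence used throughout the package:
recording with a divergent source over (z1, z2) is equivalent to collimated
recording over ``z_eff = z1·z2/(z1+z2) = z2/M`` with the output magnified by
``M`` and sampled at the object-plane pitch ``p/M``.

All lengths are SI metres internally.  Configuration files may give values
with unit suffixes (``nm``, ``um``/``µm``, ``mm``, ``cm``, ``m``; grating
frequencies as ``lp/mm`` etc.); they are normalised on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from typing import Mapping, Optional

__all__ = [
    "GeometryError",
    "GeometryConfig",
    "magnification",
    "fov_side",
    "lateral_resolution",
    "source_separation",
    "effective_geometry",
    "parse_length",
    "parse_spatial_frequency",
    "default_geometry",
]


class GeometryError(ValueError):
    """Raised for physically invalid optical geometry."""


_LENGTH_UNITS = {
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
}

_VALUE_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]*)\s*$")


def parse_length(value) -> float:
    """Return a length in metres.

    Numbers pass through unchanged (assumed metres); strings may carry one of
    the unit suffixes ``nm um µm mm cm m``, e.g. ``"4.8 um"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _VALUE_RE.match(str(value))
    if not m:
        raise GeometryError(f"cannot parse length {value!r}")
    num, unit = m.groups()
    if unit == "":
        return float(num)
    try:
        return float(num) * _LENGTH_UNITS[unit]
    except KeyError:
        raise GeometryError(f"unknown length unit {unit!r} in {value!r}") from None


def parse_spatial_frequency(value) -> float:
    """Return a spatial frequency in line pairs (cycles) per metre.

    Accepts plain numbers (per metre) or strings such as ``"120 lp/mm"``,
    ``"120 /mm"`` or ``"120 cycles/mm"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _VALUE_RE.match(str(value))
    if not m:
        raise GeometryError(f"cannot parse spatial frequency {value!r}")
    num, unit = m.groups()
    if unit == "":
        return float(num)
    unit = unit.replace("lp/", "/").replace("cycles/", "/")
    if not unit.startswith("/"):
        raise GeometryError(f"unknown frequency unit in {value!r}")
    try:
        return float(num) / _LENGTH_UNITS[unit[1:]]
    except KeyError:
        raise GeometryError(f"unknown frequency unit in {value!r}") from None


def magnification(z1: float, z2: float) -> float:
    """Geometric magnification ``M = (z1 + z2)/z1`` of a point-source recording."""
    if z1 <= 0:
        raise GeometryError(f"source-to-sample distance z1 must be positive, got {z1}")
    if z2 < 0:
        raise GeometryError(f"sample-to-sensor distance z2 must be non-negative, got {z2}")
    return (z1 + z2) / z1


def fov_side(L: int, p: float, M: float) -> float:
    """Side length ``L·p/M`` of the object-plane field of view.

    The areal field of view is the square of this value.
    """
    if L < 1:
        raise GeometryError("sensor side must be at least 1 pixel")
    if p <= 0:
        raise GeometryError("pixel pitch must be positive")
    if M < 1:
        raise GeometryError("magnification below 1 is not a valid point-source geometry")
    return L * p / M


def lateral_resolution(wavelength: float, z2: float, L: int, p: float) -> float:
    """Diffraction-limited lateral resolution ``2·λ·z2/(L·p)``.

    Set by the numerical aperture the sensor area subtends at distance z2;
    linear in z2 and in λ.
    """
    if min(wavelength, z2, L, p) <= 0:
        raise GeometryError("all resolution parameters must be positive")
    return 2.0 * wavelength * z2 / (L * p)


def source_separation(N: float, wavelength: float, f_fl: float) -> float:
    """Lateral separation ``N·λ·f_FL`` of adjacent point-source replicas.

    ``N`` is the grating spatial frequency (line pairs per metre) and ``f_fl``
    the image focal length of the focusing lens behind the grating.
    """
    if N < 0 or wavelength < 0 or f_fl < 0:
        raise GeometryError("separation parameters must be non-negative")
    return N * wavelength * f_fl


@dataclass(frozen=True)
class GeometryConfig:
    """All optical and geometrical constants of one recording configuration.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength λ in metres.
    z1 : float
        Point source → sample distance in metres (> 0).
    z2 : float
        Sample → sensor distance in metres (≥ 0).
    sensor_pixels : int
        Pixels per side of the square sensor region of interest, L.
    pixel_pitch : float
        Sensor pixel pitch p in metres.
    grating_frequency : float, optional
        Spatial frequency N of the beam-splitting grating (line pairs/m).
    focal_length_fl : float, optional
        Image focal length of the focusing lens creating the point sources.
    focal_length_cl : float, optional
        Collimating-lens focal length (metadata only; not used numerically).
    """

    wavelength: float
    z1: float
    z2: float
    sensor_pixels: int = 1024
    pixel_pitch: float = 4.8e-6
    grating_frequency: Optional[float] = None
    focal_length_fl: Optional[float] = None
    focal_length_cl: Optional[float] = None

    def __post_init__(self):
        if self.wavelength <= 0:
            raise GeometryError("wavelength must be positive")
        if self.z1 <= 0:
            raise GeometryError("z1 must be positive")
        if self.z2 < 0:
            raise GeometryError("z2 must be non-negative")
        if int(self.sensor_pixels) < 2:
            raise GeometryError("sensor side must be at least 2 pixels")
        if self.pixel_pitch <= 0:
            raise GeometryError("pixel pitch must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def magnification(self) -> float:
        return magnification(self.z1, self.z2)

    @property
    def object_pitch(self) -> float:
        """Sample spacing p/M on the object plane."""
        return self.pixel_pitch / self.magnification

    @property
    def fov_side(self) -> float:
        return fov_side(self.sensor_pixels, self.pixel_pitch, self.magnification)

    @property
    def fov_side_um_rounded(self) -> int:
        """Field-of-view side rounded to the nearest micrometre, for display."""
        return int(round(self.fov_side * 1e6))

    @property
    def lateral_resolution(self) -> float:
        return lateral_resolution(
            self.wavelength, self.z2, self.sensor_pixels, self.pixel_pitch
        )

    @property
    def z_eff(self) -> float:
        """Equivalent collimated propagation distance z1·z2/(z1+z2) = z2/M."""
        return self.z1 * self.z2 / (self.z1 + self.z2)

    @property
    def source_separation(self) -> Optional[float]:
        if self.grating_frequency is None or self.focal_length_fl is None:
            return None
        return source_separation(
            self.grating_frequency, self.wavelength, self.focal_length_fl
        )

    # -- construction / serialisation ---------------------------------------

    @classmethod
    def from_mapping(cls, data: Mapping) -> "GeometryConfig":
        """Build from a flat key-value mapping, normalising unit suffixes."""
        kw = {}
        for key in ("wavelength", "z1", "z2", "pixel_pitch",
                    "focal_length_fl", "focal_length_cl"):
            if key in data and data[key] is not None:
                kw[key] = parse_length(data[key])
        if "sensor_pixels" in data:
            kw["sensor_pixels"] = int(data["sensor_pixels"])
        if data.get("grating_frequency") is not None:
            kw["grating_frequency"] = parse_spatial_frequency(data["grating_frequency"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensor_pixels"] = int(d["sensor_pixels"])
        return d


def effective_geometry(cfg: GeometryConfig) -> tuple[float, float]:
    """Equivalent collimated geometry (z_eff, object-plane pitch).

    A hologram recorded with a point source at distance ``z1`` before the
    sample and the sensor ``z2`` behind it equals, after rescaling by the
    magnification M, a collimated recording over ``z_eff = z1·z2/(z1+z2)``
    sampled at pitch ``p/M`` (Fresnel scaling).
    """
    return cfg.z_eff, cfg.object_pitch


def default_geometry(**overrides) -> GeometryConfig:
    """The reference bench configuration used throughout the package.

    515 nm laser, z1 = 1.0 mm, z2 = 10.0 mm (M = 11×), 1024² region of a
    4.8 µm-pitch CMOS sensor, 120 lp/mm grating focused by an 8.25 mm lens.
    """
    kw = dict(
        wavelength=515e-9,
        z1=1.0e-3,
        z2=10.0e-3,
        sensor_pixels=1024,
        pixel_pitch=4.8e-6,
        grating_frequency=120e3,
        focal_length_fl=8.25e-3,
        focal_length_cl=100e-3,
    )
    kw.update(overrides)
    return GeometryConfig(**kw)
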