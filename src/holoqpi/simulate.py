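"""Synthetic scenes and hologram recording for lensless off-axis holography.

Every generated object comes with machine-readable ground truth (a thickness
or phase map, or a per-cell parameter list), so reconstruction and feature
extraction can be validated end to end without external data.

Recording model
---------------
Divergent (point-source) illumination is simulated through the
Fresnel-scaling equivalence: the object transmittance is sampled on the
object-plane grid of pitch ``p_obj = p/M`` and propagated the effective
collimated distance ``z_eff = z2/M`` with the exact angular-spectrum
propagator.  The spatially multiplexed sample plane is emulated by splitting
the field into three horizontal bands: a blocked band (zero field), the
object band (centre), and an object-free reference band.  The propagated
object wave interferes with a tilted plane reference wave (optionally
carrying a parametric coma phase, mimicking the off-axis path through the
focusing lens); the recorded intensity is ``|O + R|²`` with optional Poisson
shot noise (parameterised by mean photons per pixel) and uniform
quantisation to 8 or 16 bits.

An in-line mode (no reference tilt; undiffracted unit background instead)
reproduces the twin-image-contaminated recordings of conventional lensless
in-line holography for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry import GeometryConfig, effective_geometry
from .wavefield import ComplexField, angular_spectrum_propagate, coma_phase, spatial_axes, tilted_plane_wave

__all__ = [
    "N_PMMA",
    "N_GLYCEROL_WATER",
    "N_CELL",
    "N_DMEM",
    "SceneError",
    "HologramFrame",
    "FlowCell",
    "FlowSpec",
    "object_band",
    "apply_multiplex",
    "sphere_transmittance",
    "usaf_bars",
    "adherent_blob",
    "generate_flow_cells",
    "flow_scene",
    "record_hologram",
    "blank_hologram",
    "DEFAULT_GUARD_FRACTION",
]

# Refractive-index constants used by the validation scenes.
N_PMMA = 1.494            # PMMA microspheres
N_GLYCEROL_WATER = 1.458  # 90/10 glycerol-water immersion medium
N_CELL = 1.3654           # mean integral RI of suspended pancreatic tumour cells
N_DMEM = 1.339            # DMEM culture medium

DEFAULT_GUARD_FRACTION = 8  # guard band = L // DEFAULT_GUARD_FRACTION pixels


class SceneError(ValueError):
    """Raised when a requested object does not fit the scene geometry."""


@dataclass
class HologramFrame:
    """A recorded (optionally quantised) intensity image with its geometry.

    ``intensity`` is non-negative; for quantised frames it holds the integer
    digital numbers as floats and ``full_scale`` records the physical
    intensity mapped to the top code, so reconstruction stays gain-aware.
    ``carrier`` is the fringe carrier in cycles per field (metadata; the
    reconstruction locates the carrier itself from the spectrum).
    """

    intensity: np.ndarray
    bits: int | Literal["float"]
    config: GeometryConfig
    carrier: tuple[float, float]
    frame_index: int = 0
    timestamp: Optional[float] = None
    full_scale: float = 1.0

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2-D array")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")
        if self.bits != "float":
            top = 2 ** int(self.bits) - 1
            if self.intensity.max(initial=0) > top:
                raise ValueError(f"quantised values exceed {top}")


# ---------------------------------------------------------------------------
# multiplexed sample-plane layout
# ---------------------------------------------------------------------------

def _band_rows(L: int) -> tuple[slice, slice, slice]:
    """Row slices of the blocked (x), object (o) and reference (r) bands."""
    a, b = L // 3, 2 * L // 3
    return slice(0, a), slice(a, b), slice(b, L)


def object_band(L: int) -> slice:
    """Rows of the object ('o') band: the central third of the field."""
    return _band_rows(L)[1]


def apply_multiplex(field: ComplexField) -> ComplexField:
    """Zero the blocked band of the multiplexed sample plane."""
    v = field.values.copy()
    v[_band_rows(field.n)[0], :] = 0.0
    return field.with_values(v)


def _grid(cfg: GeometryConfig, L: Optional[int] = None):
    L = int(L or cfg.sensor_pixels)
    p_obj = cfg.object_pitch
    x, y = spatial_axes(L, p_obj)
    X, Y = np.meshgrid(x, y, indexing="xy")
    return L, p_obj, X, Y


def _check_in_object_band(L: int, p_obj: float, center: tuple[float, float], half_extent: float):
    rows = object_band(L)
    y0 = (rows.start - L // 2) * p_obj
    y1 = (rows.stop - 1 - L // 2) * p_obj
    cy = center[1]
    if cy - half_extent < y0 or cy + half_extent > y1:
        raise SceneError("object does not fit inside the object band of the multiplexed field")


# ---------------------------------------------------------------------------
# objects
# ---------------------------------------------------------------------------

def sphere_transmittance(
    cfg: GeometryConfig,
    radius: float,
    delta_n: float,
    center: tuple[float, float] = (0.0, 0.0),
    L: Optional[int] = None,
) -> tuple[ComplexField, np.ndarray]:
    """Phase-only transmittance of a transparent sphere, with ground truth.

    A sphere of radius ``radius`` and refractive-index contrast ``delta_n``
    against the medium imprints the phase ``φ(x, y) = (2π·Δn/λ)·d(x, y)``
    with the chord thickness ``d = 2·sqrt(R² − r²)`` inside ``r ≤ R``.

    Returns the unit-amplitude transmittance and the thickness map in metres.
    """
    L, p_obj, X, Y = _grid(cfg, L)
    if radius < 2 * p_obj:
        raise SceneError("sphere radius below two object-plane pixels is unresolvable")
    _check_in_object_band(L, p_obj, center, radius)
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    thickness = 2.0 * np.sqrt(np.clip(radius**2 - r2, 0.0, None))
    phase = 2.0 * np.pi * delta_n / cfg.wavelength * thickness
    return ComplexField(np.exp(1j * phase), p_obj, cfg.wavelength), thickness


def usaf_bars(
    cfg: GeometryConfig,
    period: float,
    n_bars: int = 3,
    orientation: Literal["vertical", "horizontal"] = "vertical",
    center: tuple[float, float] = (0.0, 0.0),
    bar_length: Optional[float] = None,
    L: Optional[int] = None,
) -> tuple[ComplexField, np.ndarray]:
    """Binary three-bar amplitude target (opaque bars, duty cycle 1/2).

    ``period`` is the centre-to-centre bar spacing (bar width = period/2).
    Bars run along y for ``orientation='vertical'``.  Returns the {0, 1}
    amplitude transmittance and the bar mask (True on opaque bars).
    """
    L, p_obj, X, Y = _grid(cfg, L)
    if period < 2 * p_obj:
        raise SceneError("bar period below the object-plane Nyquist limit")
    if bar_length is None:
        bar_length = 2.5 * period * n_bars / 3  # 5:1-ish bar aspect as on test charts
    u = (X - center[0]) if orientation == "vertical" else (Y - center[1])
    v = (Y - center[1]) if orientation == "vertical" else (X - center[0])
    _check_in_object_band(L, p_obj, center,
                          max(bar_length / 2, n_bars * period / 2))
    bars = np.zeros((L, L), dtype=bool)
    for k in range(n_bars):
        c = (k - (n_bars - 1) / 2) * period
        bars |= (np.abs(u - c) <= period / 4 + 1e-12)
    bars &= np.abs(v) <= bar_length / 2
    t = np.where(bars, 0.0, 1.0)
    return ComplexField(t.astype(complex), p_obj, cfg.wavelength), bars


def adherent_blob(
    cfg: GeometryConfig,
    peak_phase: float,
    corr_len: float,
    seed: int = 0,
    L: Optional[int] = None,
) -> tuple[ComplexField, np.ndarray]:
    """Smooth random phase blob mimicking an adherent cell's optical thickness.

    Seeded white noise is low-pass filtered with a Gaussian of 1/e half-width
    ``corr_len``, confined to a soft circular support inside the object band,
    rectified to non-negative values and rescaled to ``peak_phase`` radians.
    Returns the unit-amplitude transmittance and the ground-truth phase map.
    """
    if peak_phase < 0:
        raise SceneError("peak phase must be non-negative")
    L, p_obj, X, Y = _grid(cfg, L)
    if peak_phase == 0:
        z = np.zeros((L, L))
        return ComplexField(np.ones((L, L), dtype=complex), p_obj, cfg.wavelength), z
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((L, L))
    # white noise through a Gaussian of std σ has autocorrelation
    # exp(−r²/4σ²): 1/e radius 2σ, so σ = corr_len/2
    sigma_px = corr_len / p_obj / 2.0
    smooth = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
    rows = object_band(L)
    support_r = 0.4 * (rows.stop - rows.start) * p_obj
    r = np.hypot(X, Y)
    envelope = np.clip(1.0 - (r / support_r) ** 2, 0.0, None)
    phase = np.clip(smooth, 0.0, None) * envelope
    m = phase.max()
    if m > 0:
        phase *= peak_phase / m
    return ComplexField(np.exp(1j * phase), p_obj, cfg.wavelength), phase


# ---------------------------------------------------------------------------
# flow scenes
# ---------------------------------------------------------------------------

@dataclass
class FlowCell:
    """Ground truth for one simulated suspended cell."""

    cell_id: int
    radius: float          # m
    integral_ri: float
    entry_frame: int
    x_entry: float         # m, object-plane coordinates at entry_frame
    y: float               # m

    def position(self, frame: int, velocity: float) -> tuple[float, float]:
        return self.x_entry + velocity * (frame - self.entry_frame), self.y


@dataclass
class FlowSpec:
    """Conditions of a simulated microfluidic flow recording.

    Defaults emulate hydrodynamically focused suspended tumour cells:
    near-spherical cells of radius 8.64 ± 0.4 µm and integral refractive
    index 1.366 ± 0.002 in medium of RI 1.339, travelling single-file along
    a lane centred in the object band.  ``velocity`` is in object-plane
    pixels per frame; ``arrival_rate`` is the mean number of new cells per
    frame before headway thinning (focused single-file flow forbids two
    cells closer than ``min_headway_radii`` mean radii along the lane).
    """

    n_frames: int = 200
    velocity: float = 10.0
    arrival_rate: float = 0.25
    radius_mean: float = 8.64e-6
    radius_std: float = 0.4e-6
    radius_clip: tuple[float, float] = (7.4e-6, 9.8e-6)
    ri_mean: float = 1.366
    ri_std: float = 0.002
    medium_ri: float = N_DMEM
    lane_jitter: float = 3.0e-6
    min_headway_radii: float = 3.0
    seed: int = 0


def generate_flow_cells(spec: FlowSpec, cfg: GeometryConfig,
                        L: Optional[int] = None) -> list[FlowCell]:
    """Draw the full ground-truth cell list for a flow recording.

    Arrivals are Poisson per frame, thinned so consecutive cells keep a
    minimum headway along the lane (hydrodynamic focusing produces
    single-file flow); radii and integral RIs are clipped Gaussians.
    """
    L = int(L or cfg.sensor_pixels)
    p_obj = cfg.object_pitch
    rng = np.random.default_rng([int(spec.seed), 0x5EED])
    cells: list[FlowCell] = []
    headway_frames = spec.min_headway_radii * spec.radius_mean / (spec.velocity * p_obj)
    last_entry = -np.inf
    x_entry = (-(L // 2)) * p_obj  # enters at the left field edge
    for t in range(spec.n_frames):
        for _ in range(rng.poisson(spec.arrival_rate)):
            if t - last_entry < headway_frames:
                continue
            radius = float(np.clip(rng.normal(spec.radius_mean, spec.radius_std),
                                   *spec.radius_clip))
            ri = float(rng.normal(spec.ri_mean, spec.ri_std))
            y = float(rng.uniform(-spec.lane_jitter, spec.lane_jitter))
            cells.append(FlowCell(len(cells), radius, ri, t, x_entry - radius, y))
            last_entry = t
    return cells


def flow_scene(
    spec: FlowSpec,
    cfg: GeometryConfig,
    frame: int,
    cells: Optional[Sequence[FlowCell]] = None,
    L: Optional[int] = None,
) -> tuple[ComplexField, list[dict]]:
    """Object transmittance of one flow frame plus per-cell ground truth.

    Returns the phase-only field (product of the in-frame cells'
    sphere transmittances) and a record per visible cell with its current
    position, true radius and RI, and an ``overlapping`` flag set when two
    cell disks intersect (for "clustered" tests).
    """
    if cells is None:
        cells = generate_flow_cells(spec, cfg, L=L)
    L = int(L or cfg.sensor_pixels)
    p_obj = cfg.object_pitch
    v = spec.velocity * p_obj
    half = (L // 2) * p_obj
    visible = []
    for c in cells:
        if c.entry_frame > frame:
            continue
        x, y = c.position(frame, v)
        if x - c.radius > half:
            continue
        visible.append((c, x, y))
    phase = np.zeros((L, L))
    truth = []
    Lg, p_obj, X, Y = _grid(cfg, L)
    for c, x, y in visible:
        r2 = (X - x) ** 2 + (Y - y) ** 2
        thickness = 2.0 * np.sqrt(np.clip(c.radius**2 - r2, 0.0, None))
        phase += 2.0 * np.pi * (c.integral_ri - spec.medium_ri) / cfg.wavelength * thickness
        overlap = any(
            np.hypot(x - x2, y - y2) < c.radius + c2.radius
            for c2, x2, y2 in visible if c2.cell_id != c.cell_id
        )
        truth.append(dict(cell_id=c.cell_id, frame=frame, x=x, y=y,
                          radius=c.radius, integral_ri=c.integral_ri,
                          overlapping=overlap))
    return ComplexField(np.exp(1j * phase), p_obj, cfg.wavelength), truth


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

def record_hologram(
    obj: ComplexField,
    cfg: GeometryConfig,
    carrier: Optional[tuple[float, float]] = None,
    coma_coeff: float = 0.0,
    photons: Optional[float] = None,
    bits: int | Literal["float"] = "float",
    seed: Optional[int] = None,
    inline: bool = False,
    reference_amplitude: float = 1.0,
    frame_index: int = 0,
    multiplex: bool = True,
    guard_band: Optional[int] = None,
) -> HologramFrame:
    """Record an off-axis (or in-line) hologram of an object transmittance.

    Parameters
    ----------
    obj : ComplexField
        Object transmittance sampled on the object-plane grid ``p/M``.
    carrier : (float, float), optional
        Reference-tilt carrier in cycles per field along (x, y).  The default
        ``(L/4, L/4)`` puts the cross-correlation sideband on the spectrum
        diagonal with a fringe period of ≈2.8 px, leaving a demodulation
        passband of half the carrier→DC distance — the regime of the
        near-Nyquist fringes a grating-based common-path bench produces.
    coma_coeff : float
        Zernike primary-coma coefficient (radians) applied to the reference
        wave, mimicking its off-axis path through the focusing lens.
    photons : float, optional
        Mean photons per pixel for Poisson shot noise; ``None`` (or inf)
        records noise-free.
    bits : 8, 16 or "float"
        Quantisation depth; full scale is the frame maximum.
    inline : bool
        Replace the tilted reference by an undiffracted unit background
        (conventional in-line lensless recording, twin image included).
    multiplex : bool
        Apply the blocked/object/reference band layout before propagation.
    guard_band : int, optional
        Zero-padding guard band in pixels used during propagation
        (default ``L // 8``), cropped afterwards.
    """
    L = obj.n
    z_eff, p_obj = effective_geometry(cfg)
    if abs(obj.pitch / p_obj - 1.0) > 1e-9:
        raise SceneError("object field pitch does not match the object-plane pitch p/M")
    if guard_band is None:
        guard_band = L // DEFAULT_GUARD_FRACTION
    field = apply_multiplex(obj) if multiplex else obj
    O = angular_spectrum_propagate(field, z_eff, pad=guard_band, pad_mode="edge")

    if inline:
        carrier = (0.0, 0.0)
        R = np.full((L, L), reference_amplitude, dtype=complex)
    else:
        if carrier is None:
            carrier = (L / 4.0, L / 4.0)
        fx = carrier[0] / (L * p_obj)
        fy = carrier[1] / (L * p_obj)
        if np.hypot(*carrier) < L / 8.0:
            warnings.warn(
                "carrier below L/8 cycles/field may not separate the "
                "cross-correlation sidebands from the autocorrelation term",
                stacklevel=2,
            )
        Rw = tilted_plane_wave(L, p_obj, cfg.wavelength, fx, fy, reference_amplitude)
        R = Rw.values
        if coma_coeff:
            R = R * coma_phase(L, p_obj, cfg.wavelength, coma_coeff).values

    I = np.abs(O.values + R) ** 2

    if photons is not None and np.isfinite(photons):
        rng = np.random.default_rng(None if seed is None else [int(seed), frame_index])
        mean = I.mean()
        I = rng.poisson(I * (photons / mean)).astype(float) * (mean / photons)

    full_scale = 1.0
    if bits != "float":
        top = 2 ** int(bits) - 1
        full_scale = float(I.max())
        I = np.round(I / full_scale * top)

    return HologramFrame(I, bits, cfg, tuple(carrier), frame_index, None, full_scale)


def blank_hologram(cfg: GeometryConfig, L: Optional[int] = None, **kwargs) -> HologramFrame:
    """Hologram of an empty (unit-transmittance) sample: the blank reference.

    Identical to :func:`record_hologram` with a unit object field; used by
    the reconstruction to divide out coma and static background.
    """
    L = int(L or cfg.sensor_pixels)
    unit = ComplexField(np.ones((L, L), dtype=complex), cfg.object_pitch, cfg.wavelength)
    return record_hologram(unit, cfg, **kwargs)
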