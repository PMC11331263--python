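"""Temporal phase-stability statistics of a quantitative-phase time series.

Given a stack of reconstructed phase maps φ(m, n, t) of a static (blank)
scene, the module computes

* the frame-mean drift  ``Δφ̄(t) = φ̄(t) − φ̄(0)`` over a region of interest,
* the per-pixel map     ``σt(m, n) = sqrt( (1/T)·Σ_t [φ(m,n,t) − φ(m,n,0)]² )``
  — the RMS of frame-0-referenced deviations with divisor T (population
  form), and
* its histogram and spatial mean σ̄t, the single-number stability figure.

The frame-0-referenced form is the default; a conventional temporal
standard deviation about the per-pixel temporal mean (divisor T−1) is
available as ``mode="temporal"``.  Note that for i.i.d. per-pixel noise of
standard deviation σ the frame-0-referenced statistic converges to σ·√2,
since each deviation is a difference of two independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "StabilityReport",
    "phase_drift",
    "pixel_std_map",
    "stability_summary",
    "analyze_stability",
    "centered_roi",
]


@dataclass
class StabilityReport:
    """Summary of a temporal phase-stability analysis."""

    drift: np.ndarray          # Δφ̄(t), rad, drift[0] == 0
    sigma_map: np.ndarray      # σt per pixel, rad
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    mean_sigma: float          # σ̄t, rad
    n_frames: int
    roi: tuple[int, int, int, int]  # (row, col, height, width)


def centered_roi(shape: tuple[int, int], size: int = 300) -> tuple[int, int, int, int]:
    """A size×size ROI centred in the frame, clipped to the frame bounds."""
    h = min(size, shape[0])
    w = min(size, shape[1])
    return ((shape[0] - h) // 2, (shape[1] - w) // 2, h, w)


def _stack_roi(stack, roi) -> np.ndarray:
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    if roi is None:
        roi = centered_roi(arr.shape[1:])
    r, c, h, w = roi
    if h < 1 or w < 1 or r < 0 or c < 0 or r + h > arr.shape[1] or c + w > arr.shape[2]:
        raise ValueError("ROI is empty or outside the frames")
    return arr[:, r : r + h, c : c + w]


def phase_drift(stack: Sequence[np.ndarray], roi=None) -> np.ndarray:
    """Frame-mean phase drift ``Δφ̄(t) = φ̄(t) − φ̄(0)`` over the ROI."""
    sub = _stack_roi(stack, roi)
    if sub.shape[0] < 2:
        raise ValueError("drift needs at least two frames")
    means = sub.mean(axis=(1, 2))
    return means - means[0]


def pixel_std_map(
    stack: Sequence[np.ndarray],
    roi=None,
    mode: Literal["first-frame", "temporal"] = "first-frame",
) -> np.ndarray:
    """Per-pixel temporal fluctuation map σt over the ROI.

    ``first-frame`` (default): RMS of deviations from frame 0, divisor T.
    ``temporal``: standard deviation about the temporal mean, divisor T−1.
    """
    sub = _stack_roi(stack, roi)
    T = sub.shape[0]
    if T < 2:
        raise ValueError("σt needs at least two frames")
    if mode == "first-frame":
        dev = sub - sub[0]
        return np.sqrt(np.mean(dev**2, axis=0))
    if mode == "temporal":
        return sub.std(axis=0, ddof=1)
    raise ValueError(f"unknown mode {mode!r}")


def stability_summary(
    sigma_map: np.ndarray,
    bins: int = 64,
    drift: Optional[np.ndarray] = None,
    roi: Optional[tuple[int, int, int, int]] = None,
    n_frames: int = 0,
) -> StabilityReport:
    """Histogram over [0, max σt] and the arithmetic mean σ̄t."""
    sigma_map = np.asarray(sigma_map, dtype=float)
    top = float(sigma_map.max())
    counts, edges = np.histogram(sigma_map, bins=bins, range=(0.0, top if top > 0 else 1.0))
    return StabilityReport(
        drift=np.zeros(0) if drift is None else np.asarray(drift, dtype=float),
        sigma_map=sigma_map,
        hist_edges=edges,
        hist_counts=counts,
        mean_sigma=float(sigma_map.mean()),
        n_frames=n_frames,
        roi=roi if roi is not None else (0, 0, *sigma_map.shape),
    )


def analyze_stability(
    stack: Sequence[np.ndarray],
    roi=None,
    bins: int = 64,
    mode: Literal["first-frame", "temporal"] = "first-frame",
) -> StabilityReport:
    """Drift, σt map and summary in one call."""
    arr = np.asarray(stack, dtype=float)
    if roi is None:
        roi = centered_roi(arr.shape[1:])
    drift = phase_drift(arr, roi)
    sigma = pixel_std_map(arr, roi, mode=mode)
    return stability_summary(sigma, bins=bins, drift=drift, roi=tuple(roi),
                             n_frames=arr.shape[0])
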