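"""File formats, run configuration and output manifests.

TIFF is the single raster interchange format: integer (8/16-bit) grayscale
for recorded holograms, 32-bit float for reconstructed phase, amplitude and
thickness maps, and two-page float32 for complex fields (real, imaginary).
Tables are CSV with a header row; every output directory receives a JSON
manifest listing each artifact with a content hash and the fully resolved
run configuration, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import GeometryConfig
from .wavefield import ComplexField

__all__ = [
    "FormatError",
    "read_image_stack",
    "write_stack",
    "save_field",
    "load_field",
    "RunConfig",
    "load_config",
    "save_config",
    "write_outputs",
]


class FormatError(ValueError):
    """An input file is not a supported grayscale TIFF."""


_SUPPORTED = {
    np.dtype("uint8"): 8,
    np.dtype("uint16"): 16,
    np.dtype("float32"): "float",
    np.dtype("float64"): "float",
}


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a single- or multi-page grayscale TIFF as a (frames, h, w) stack.

    Returns the stack and a metadata dict with the recorded bit depth and
    any JSON payload found in the image description.  RGB or unsupported
    sample formats raise :class:`FormatError` naming the offending property.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if not len(tf.pages):
                raise FormatError(f"{path}: no image pages (truncated file?)")
            spp = tf.pages[0].samplesperpixel
            if spp != 1:
                raise FormatError(
                    f"{path}: {spp} samples per pixel (colour image); "
                    "only grayscale is supported"
                )
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
    except (tifffile.TiffFileError, FileNotFoundError, OSError, IndexError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"{path}: empty image data (truncated file?)")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    if arr.dtype not in _SUPPORTED:
        raise FormatError(f"{path}: unsupported sample dtype {arr.dtype}")
    meta: dict[str, Any] = {"bits": _SUPPORTED[arr.dtype], "path": str(path)}
    if desc:
        try:
            meta.update(json.loads(desc))
        except (json.JSONDecodeError, TypeError):
            meta["description"] = desc
    return arr, meta


def write_stack(path, stack: np.ndarray, bits: int | str = "float",
                metadata: Optional[Mapping] = None) -> None:
    """Write a (frames, h, w) or (h, w) array as a multi-page grayscale TIFF."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if bits == 8:
        arr = arr.astype(np.uint8)
    elif bits == 16:
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.float32)
    desc = json.dumps(dict(metadata or {}))
    tifffile.imwrite(Path(path), arr, description=desc, photometric="minisblack")


def save_field(path, field: ComplexField, metadata: Optional[Mapping] = None) -> None:
    """Serialise a complex field as a two-page (real, imag) float32 TIFF."""
    meta = dict(metadata or {})
    meta.update(pitch=field.pitch, wavelength=field.wavelength, layout="real,imag")
    pages = np.stack([field.values.real, field.values.imag]).astype(np.float32)
    tifffile.imwrite(Path(path), pages, description=json.dumps(meta),
                     photometric="minisblack")


def load_field(path) -> ComplexField:
    """Read a complex field written by :func:`save_field`."""
    arr, meta = read_image_stack(path)
    if arr.shape[0] != 2:
        raise FormatError(f"{path}: complex field file must have exactly 2 pages")
    if "pitch" not in meta or "wavelength" not in meta:
        raise FormatError(f"{path}: missing pitch/wavelength metadata")
    return ComplexField(arr[0] + 1j * arr[1], float(meta["pitch"]),
                        float(meta["wavelength"]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully resolved settings of one simulation/reconstruction run."""

    geometry: GeometryConfig
    n_object: float = 1.3654
    n_medium: float = 1.339
    beta: float = 0.002
    filter_radius: Optional[float] = None   # cycles/m; None = auto
    amplitude_floor: float = 0.05
    focus: str | float = "fixed"            # "fixed" | "auto" | explicit metres
    unwrap: bool = True
    carrier: Optional[tuple[float, float]] = None  # cycles/field
    photons: Optional[float] = None
    bits: int | str = "float"
    coma: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d


def load_config(path) -> RunConfig:
    """Load a flat key-value (YAML) configuration file.

    Geometry keys (``wavelength``, ``z1``, ``z2``, ``sensor_pixels``,
    ``pixel_pitch``, ``grating_frequency``, ``focal_length_fl``) may carry
    unit suffixes; remaining keys map to :class:`RunConfig` fields.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: configuration must be a flat mapping")
    geo = GeometryConfig.from_mapping(data)
    kw = {}
    for key in ("n_object", "n_medium", "beta", "filter_radius",
                "amplitude_floor", "focus", "unwrap", "photons", "bits",
                "coma", "seed"):
        if key in data:
            kw[key] = data[key]
    if "carrier" in data and data["carrier"] is not None:
        cx, cy = (float(v) for v in str(data["carrier"]).split(","))
        kw["carrier"] = (cx, cy)
    return RunConfig(geometry=geo, **kw)


def save_config(path, cfg: RunConfig) -> None:
    flat = cfg.to_dict()
    geo = flat.pop("geometry")
    flat.update(geo)
    if flat.get("carrier") is not None:
        flat["carrier"] = ",".join(str(v) for v in flat["carrier"])
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    results: Mapping[str, Any],
    outdir,
    config: Optional[RunConfig] = None,
    overwrite: bool = False,
) -> dict:
    """Write a result set to a directory and return its manifest.

    2-D/3-D float arrays become 32-bit float TIFFs, DataFrames become CSVs,
    mappings become JSON files.  The manifest (also written as
    ``manifest.json``) lists every artifact with its SHA-256 content hash
    and the resolved configuration.  Existing files are refused unless
    ``overwrite`` is set; inputs are never mutated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            _refuse(p, overwrite)
            obj.to_csv(p, index=False)
        elif isinstance(obj, np.ndarray):
            p = outdir / f"{name}.tiff"
            _refuse(p, overwrite)
            write_stack(p, obj, bits="float")
        elif isinstance(obj, Mapping):
            p = outdir / f"{name}.json"
            _refuse(p, overwrite)
            p.write_text(json.dumps(_jsonable(obj), indent=2))
        else:
            raise TypeError(f"cannot serialise result {name!r} of type {type(obj)}")
        artifacts[name] = {"file": p.name, "sha256": _sha256(p)}
    manifest = {"artifacts": artifacts}
    if config is not None:
        manifest["config"] = config.to_dict()
    mp = outdir / "manifest.json"
    _refuse(mp, overwrite)
    mp.write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest


def _refuse(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
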