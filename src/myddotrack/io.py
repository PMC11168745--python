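"""Calibrated stack container, TIFF round-trip, tabular output and manifests.

Stacks are multi-page TIFFs in (t, z, y, x) order. When written by this
package the ImageJ-style metadata carries the calibration (pixel size, z
spacing, frame interval); arbitrary TIFFs are accepted as long as the missing
calibration is supplied explicitly. All tabular outputs are CSV with a fixed
float format so that rerunning a pipeline with the same config and seed
reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack4D",
    "write_stack",
    "load_stack",
    "write_table",
    "write_manifest",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.6g"


@dataclass
class ImageStack4D:
    """A calibrated (t, z, y, x) intensity stack."""

    data: np.ndarray
    pixel_size_xy: float  # um/px
    z_spacing: float      # um
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (t, z, y, x)")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        for name in ("pixel_size_xy", "z_spacing", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


def write_stack(stack: ImageStack4D, path: str | Path) -> None:
    """Write a calibrated stack as an ImageJ-compatible multi-page TIFF."""
    path = Path(path)
    data = stack.data
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / stack.pixel_size_xy, 1.0 / stack.pixel_size_xy),
        metadata={"axes": "TZYX", "spacing": stack.z_spacing,
                  "finterval": stack.frame_interval, "unit": "um"})


def load_stack(path: str | Path,
               pixel_size_xy: Optional[float] = None,
               z_spacing: Optional[float] = None,
               frame_interval: Optional[float] = None) -> ImageStack4D:
    """Load a TIFF as a calibrated 4D stack.

    Calibration is taken from ImageJ metadata when present; explicit arguments
    override it. A 3D (z, y, x) TIFF is accepted as a single-timepoint stack.
    Missing calibration raises a ``ValueError`` naming the flags to supply.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tif.imagej_metadata or {}
        res_px = None
        try:
            xres = tif.pages[0].tags["XResolution"].value
            if xres[0]:
                res_px = xres[1] / xres[0]
        except (KeyError, ZeroDivisionError, TypeError):
            pass

    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        if axes.startswith("T") and "Z" not in axes:
            data = data[:, None]
        else:
            data = data[None]
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with axes {axes!r} as (t,z,y,x)")

    px = pixel_size_xy if pixel_size_xy is not None else res_px
    dz = z_spacing if z_spacing is not None else meta.get("spacing")
    dt = frame_interval if frame_interval is not None else meta.get("finterval")
    missing = []
    if px is None:
        missing.append("--pixel-size-um")
    if dz is None:
        missing.append("--z-step-um")
    if dt is None:
        missing.append("--frame-interval-s")
    if missing:
        raise ValueError(
            "stack calibration missing from TIFF metadata; "
            f"supply {', '.join(missing)}")
    return ImageStack4D(data=data, pixel_size_xy=float(px),
                        z_spacing=float(dz), frame_interval=float(dt))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV output with a fixed float format (byte-stable across reruns)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config, seed: int,
                   inputs: dict[str, str | Path] | None = None,
                   extra: dict | None = None) -> dict:
    """Provenance manifest: config (and its hash), seed, input checksums.

    Deliberately carries no timestamp so reruns are byte-identical.
    """
    from . import __version__

    cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "package": "myddotrack",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": {name: _sha256(Path(p)) for name, p in (inputs or {}).items()},
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
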