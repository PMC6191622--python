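"""TIFF stack and YAML sidecar I/O.

Image series travel as multi-page 32-bit float TIFFs; every written
stack gets a YAML sidecar recording the configuration and seed that
produced it, so any stochastic run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Optional

import numpy as np
import tifffile
import yaml

from .scatter import ScatterConfig, ScatterKernel

__all__ = [
    "read_stack",
    "write_stack",
    "read_kernel",
    "write_kernel",
    "sidecar_path",
]


class StackFormatError(ValueError):
    """Raised for unreadable or inconsistent TIFF stacks."""


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".yaml")


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF as a float (n, h, w) array plus metadata.

    Pages are returned in file order; integer data converts to float
    exactly.  Mixed page shapes raise a format error.  Metadata from a
    YAML sidecar, if present, is merged in.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) != 1:
                raise StackFormatError(f"mixed page shapes in {path}: {shapes}")
            data = tif.asarray()
    except StackFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise StackFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    meta: dict[str, Any] = {
        "n_pages": data.shape[0],
        "shape": tuple(data.shape[1:]),
        "path": str(path),
    }
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta.update(yaml.safe_load(fh) or {})
    return data, meta


def write_stack(
    path: str | Path, series: np.ndarray, metadata: Optional[dict] = None
) -> Path:
    """Write a series as a multi-page float32 TIFF with a YAML sidecar."""
    series = np.asarray(series, dtype=np.float32)
    if series.ndim == 2:
        series = series[None]
    if series.ndim != 3 or series.shape[0] == 0:
        raise ValueError("series must be a nonempty (n, h, w) array")
    path = Path(path)
    tifffile.imwrite(path, series, photometric="minisblack")
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(_plain(metadata or {}), fh, sort_keys=False)
    return path


def write_kernel(path: str | Path, kernel: ScatterKernel) -> Path:
    """Persist a scattering kernel as a single-page float32 TIFF plus a
    sidecar with its generating configuration."""
    path = Path(path)
    tifffile.imwrite(path, kernel.values.astype(np.float32), photometric="minisblack")
    meta: dict[str, Any] = {"pixel_pitch": float(kernel.pixel_pitch)}
    if kernel.meta is not None:
        meta["config"] = dataclasses.asdict(kernel.meta)
        meta["seed"] = kernel.meta.seed
    meta["n_collected"] = int(kernel.n_collected)
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(_plain(meta), fh, sort_keys=False)
    return path


def read_kernel(path: str | Path) -> ScatterKernel:
    """Load a kernel TIFF and, when the sidecar allows, its configuration."""
    values = tifffile.imread(Path(path))
    if values.ndim != 2:
        raise StackFormatError("kernel TIFF must be single-page 2-D")
    pitch = 1.0
    cfg = None
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
        pitch = float(meta.get("pixel_pitch", 1.0))
        if "config" in meta:
            cfg = ScatterConfig(**meta["config"])
    return ScatterKernel(values=np.asarray(values, dtype=float), pixel_pitch=pitch, meta=cfg)


def _plain(obj: Any) -> Any:
    """Convert numpy scalars/arrays to YAML-safe built-ins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
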