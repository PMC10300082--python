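"""TIFF stack I/O with JSON metadata sidecars.

Arrays are indexed ``(frame/z, y, x)``, 0-based, matching the storage
order of multi-page TIFF.  Pixel size (nm) and dwell time (µs) travel in a
JSON sidecar next to the TIFF (same stem, ``.json`` suffix); stacks load
fine without one but carry ``pixel_size_known=False`` flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A non-negative grayscale image stack plus acquisition metadata."""

    data: np.ndarray                       # (frames, y, x) or (y, x)
    pixel_size: float | None = None        # nm / pixel
    dwell_time: float | None = None        # µs / pixel
    axes: str = "tyx"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def pixel_size_known(self) -> bool:
        return self.pixel_size is not None

    @property
    def dwell_time_known(self) -> bool:
        return self.dwell_time is not None


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF and its sidecar."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path}: RGB/multi-sample TIFF (samplesperpixel="
                f"{page.samplesperpixel}); only grayscale stacks are supported")
        data = tif.asarray()
    data = np.asarray(data, dtype=np.float64)
    meta: dict = {}
    pixel_size = dwell_time = None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        pixel_size = meta.get("pixel_size_nm")
        dwell_time = meta.get("dwell_time_us")
    return ImageStack(data, pixel_size=pixel_size, dwell_time=dwell_time,
                      metadata=meta)


def write_stack(path, stack: ImageStack | np.ndarray, **extra_meta) -> Path:
    """Write a stack as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    if not isinstance(stack, ImageStack):
        stack = ImageStack(np.asarray(stack))
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack")
    meta = dict(stack.metadata)
    meta.update(extra_meta)
    if stack.pixel_size is not None:
        meta["pixel_size_nm"] = stack.pixel_size
    if stack.dwell_time is not None:
        meta["dwell_time_us"] = stack.dwell_time
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
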