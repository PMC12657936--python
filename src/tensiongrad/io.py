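"""Reading and writing the pipeline's on-disk formats.

Lifetime images travel as 2-channel TIFFs (lifetime in ns, photon counts), the
layout confocal FLIM software exports; masks as 0/255 single-channel TIFFs;
traces and tables as CSV; ground truth and provenance as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .flim import LifetimeImage

__all__ = [
    "save_lifetime_image",
    "load_lifetime_image",
    "save_mask",
    "load_mask",
    "save_json",
    "load_json",
]


def save_lifetime_image(path: str | Path, img: LifetimeImage) -> None:
    """Write a lifetime image as a 2-channel float TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack([img.tau, img.photons.astype(np.float32)])  # NaN marks invalid
    tifffile.imwrite(path, stack.astype(np.float32))
    meta = {"pixel_size_um": img.pixel_size, "plane": img.plane, **img.meta}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_lifetime_image(path: str | Path, pixel_size: float | None = None) -> LifetimeImage:
    """Read a 2-channel (lifetime ns, photon counts) TIFF.

    Pixels with zero photons are marked invalid.  The pixel size comes from
    the JSON sidecar when present, else from the argument.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected a 2-channel (lifetime, counts) TIFF")
    tau = stack[0].astype(float)
    photons = stack[1].astype(np.int64)
    tau[photons <= 0] = np.nan
    meta, plane = {}, "bottom"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta.pop("pixel_size_um", pixel_size)
        plane = meta.pop("plane", plane)
    if pixel_size is None:
        raise ValueError("pixel size not in sidecar; pass pixel_size=")
    return LifetimeImage(tau=tau, photons=photons, pixel_size=pixel_size, plane=plane, meta=meta)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
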