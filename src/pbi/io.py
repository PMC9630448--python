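"""Grayscale TIFF reading/writing with provenance sidecars."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_image_stack", "write_image"]


def read_image_stack(path: str | Path) -> list[np.ndarray]:
    """Read a single- or multi-page grayscale TIFF as float64 images.

    Integer inputs map to their exact float values.  RGB(A) pages are
    rejected: quantitative retrieval is defined on single-channel data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        pages = [data]
    elif data.ndim == 3:
        if data.shape[-1] in (3, 4) and data.shape[-1] != data.shape[0]:
            raise ValueError(f"{path}: multi-channel (RGB) input is not supported")
        pages = list(data)
    else:
        raise ValueError(f"{path}: unsupported TIFF dimensionality {data.ndim}")
    out = []
    for page in pages:
        if page.ndim != 2:
            raise ValueError(f"{path}: multi-channel (RGB) input is not supported")
        out.append(np.asarray(page, dtype=np.float64))
    return out


def write_image(
    path: str | Path,
    image: np.ndarray,
    metadata: dict | None = None,
    allow_nan: bool = False,
) -> None:
    """Write a 32-bit float single-page TIFF plus a JSON provenance sidecar.

    The sidecar records the command line, the supplied metadata (geometry,
    kernel choice, ...) and a SHA-256 of the written pixel bytes, so any run
    can be reproduced and verified from its outputs alone.
    """
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if not allow_nan and not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values (pass allow_nan=True to force)")
    tifffile.imwrite(path, image)
    sidecar = {
        "command": sys.argv,
        "shape": list(image.shape),
        "dtype": "float32",
        "sha256": hashlib.sha256(image.tobytes()).hexdigest(),
        "metadata": metadata or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
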