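"""TIFF stack + JSON sidecar I/O for images and sequences."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError

__all__ = ["write_stack", "read_stack"]


def _sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_stack(path: str | Path, stack: np.ndarray,
                metadata: dict | None = None, dtype: str = "float32") -> None:
    """Write a (multi-page) TIFF with a JSON metadata sidecar.

    ``dtype`` may be ``float32`` (lossless for simulation output) or
    ``uint16`` (values outside [0, 65535] clamp with a warning).
    """
    arr = np.asarray(stack)
    if arr.size == 0:
        raise InvalidParameterError("refusing to write an empty stack")
    if dtype == "uint16":
        if arr.min() < 0 or arr.max() > 65535:
            warnings.warn("uint16 output clamps values outside [0, 65535]",
                          stacklevel=2)
        arr = np.clip(arr, 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        arr = arr.astype(np.float32)
    else:
        raise InvalidParameterError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(str(path), arr, photometric="minisblack")
    with open(_sidecar(path), "w") as fh:
        json.dump(metadata or {}, fh, indent=2)


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its sidecar metadata (defaults if missing)."""
    arr = tifffile.imread(str(path))
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
    else:
        warnings.warn(f"no metadata sidecar at {side}; using defaults",
                      stacklevel=2)
        meta = {}
    return arr, meta
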