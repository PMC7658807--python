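"""Shared readers/writers and the run manifest.

TIFF stacks are read with tifffile and never rescaled implicitly; the
stored dtype is recorded.  Multi-channel/RGB input is rejected with an
instruction to split channels — all analyses here are single-channel.
Every pipeline run writes a machine-readable manifest (input hashes,
parameters, seeds, package version) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile

from .architecture import ZStack
from .dynamics import TimeLapseStack

__all__ = ["load_stack", "save_stack", "load_mask", "sha256_file",
           "write_manifest"]


def _read_tiff(path: str | Path) -> tuple[np.ndarray, str]:
    arr = tifffile.imread(str(path))
    dtype = str(arr.dtype)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[0]:
        raise ValueError(
            f"{path}: looks like a multi-channel/RGB image "
            f"(shape {arr.shape}); split channels into separate grayscale "
            "TIFFs before analysis"
        )
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    return arr, dtype


def load_stack(path: str | Path, kind: str = "timelapse",
               frame_interval: float = 2.5, **metadata):
    """Load a grayscale TIFF as a time-lapse stack, z-stack, or image.

    ``kind``: 'timelapse' (multi-page, >= 2 frames), 'zstack' (>= 1
    slice), or 'image' (single page).  Pixel values are kept exactly as
    stored; the source dtype is recorded in the returned object's
    metadata where applicable.
    """
    arr, dtype = _read_tiff(path)
    if kind == "timelapse":
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError(f"{path}: a time-lapse needs >= 2 frames "
                             f"(got shape {arr.shape})")
        return TimeLapseStack(frames=arr, frame_interval=frame_interval,
                              **metadata)
    if kind == "zstack":
        return ZStack(slices=arr if arr.ndim == 3 else arr[None], **metadata)
    if kind == "image":
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-page image, "
                             f"got shape {arr.shape}")
        return arr
    raise ValueError(f"unknown kind {kind!r}")


def save_stack(path: str | Path, frames: np.ndarray) -> None:
    """Write frames as a multi-page TIFF (float32 for float input)."""
    arr = np.asarray(frames)
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask TIFF (nonzero = inside)."""
    arr, _ = _read_tiff(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be a single-page image")
    return arr > 0


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path: str | Path, command: str, params: dict,
                   inputs: list[str | Path], warnings: list[str] | None = None,
                   ) -> Path:
    """Write a JSON run manifest next to an output file.

    Records the subcommand, all parameters (including any seed), a
    sha256 of every input file, aggregated warnings, package version and
    a UTC timestamp; returns the manifest path.
    """
    from . import __version__

    manifest = {
        "command": command,
        "parameters": params,
        "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).is_file()},
        "warnings": warnings or [],
        "package_version": __version__,
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    mpath = Path(str(out_path) + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
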