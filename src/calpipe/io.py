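"""Reading and writing of the pipeline's standard file formats.

Channels travel as separate single-channel multi-page 16-bit grayscale
TIFFs; tables as CSV with 0-based frame indices and times in seconds.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import tifffile

from .simulator import TwoChannelMovie

__all__ = ["read_stack", "read_movie", "write_stack", "checksum"]

log = logging.getLogger("calpipe")


class FormatError(ValueError):
    """Input file has an unexpected shape or bit depth."""


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a T×H×W uint16 array.

    8-bit input is upcast with a logged warning; higher bit depths or
    multi-channel pages are rejected.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a T×H×W grayscale stack, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        log.warning("%s: 8-bit input upcast to 16-bit", path)
        arr = arr.astype(np.uint16)
    elif arr.dtype != np.uint16:
        raise FormatError(f"{path}: expected 8- or 16-bit grayscale, got dtype {arr.dtype}")
    return arr


def read_movie(red_path: str | Path, green_path: str | Path,
               frame_interval_s: float = 5.0) -> TwoChannelMovie:
    """Read and validate a two-channel movie from separate TIFF stacks."""
    red = read_stack(red_path)
    green = read_stack(green_path)
    if red.shape != green.shape:
        raise FormatError(
            f"channel dimensions differ: {red_path} is {red.shape}, "
            f"{green_path} is {green.shape}"
        )
    return TwoChannelMovie(red, green, frame_interval_s)


def write_stack(stack: np.ndarray, path: str | Path, dtype=np.uint16) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(stack)
    if dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def checksum(path: str | Path) -> str:
    """SHA-256 of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
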