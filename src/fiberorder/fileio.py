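"""TIFF/CSV/JSON reading and writing helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .orientation import Image2D


def read_frames(path: str | Path, pixel_size_um: float, channel: int | None = None) -> list[Image2D]:
    """Read a single- or multi-page grayscale TIFF as a list of frames."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # (frames, channels, r, c) or (frames, r, c, channels)
        if channel is None:
            channel = 0
        if arr.shape[1] <= 4:
            arr = arr[:, channel]
        else:
            arr = arr[..., channel]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret TIFF with shape {arr.shape}")
    return [Image2D(frame.astype(float), pixel_size_um) for frame in arr]


def write_image16(path: str | Path, frames: np.ndarray | list[np.ndarray]) -> None:
    """Write 16-bit grayscale TIFF (multi-page for a list of frames)."""
    stack = np.asarray(frames)
    if stack.ndim == 2:
        stack = stack[None]
    out = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), out)


def write_float32(path: str | Path, frames: np.ndarray | list[np.ndarray]) -> None:
    stack = np.asarray(frames, dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    tifffile.imwrite(str(path), stack)


def write_labels(path: str | Path, frames: np.ndarray | list[np.ndarray]) -> None:
    stack = np.asarray(frames)
    if stack.ndim == 2:
        stack = stack[None]
    tifffile.imwrite(str(path), stack.astype(np.int32))


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
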