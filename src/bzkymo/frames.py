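"""Reading and writing time-lapse frame stacks.

A recording is an ordered sequence of equally sized frames at a fixed frame
rate (0.4 frames/s in the study's acquisition).  ``t0_offset`` is the number
of seconds between completion of mixing the BZ medium and the first frame, so
sample timestamps ``t0_offset + i / frame_rate`` are measured from mixing --
the reference used for droplet lifetimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameStack", "read_frames", "write_frames"]

_FRAME_SUFFIXES = (".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class FrameStack:
    """Ordered image frames with timing metadata.

    ``frames`` has shape ``(n, height, width)`` (grayscale) or
    ``(n, height, width, channels)`` (colour); all frames share one geometry.
    """

    frames: np.ndarray
    frame_rate: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be (n, h, w[, c]), got shape {self.frames.shape}"
            )
        if len(self.frames) == 0:
            raise ValueError("a FrameStack needs at least one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return self.frames.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Per-frame times in seconds from completion of mixing."""
        return self.t0_offset + np.arange(len(self)) / self.frame_rate

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.frame_rate


def read_frames(
    path: str | Path, frame_rate: float = 0.4, t0_offset: float = 0.0
) -> FrameStack:
    """Read a directory of image frames into a :class:`FrameStack`.

    Files are taken in lexicographic order, which must equal temporal order
    (zero-padded frame numbers).  All frames must share one size and channel
    count; an empty directory or mixed geometries raise ``ValueError``.
    """
    path = Path(path)
    if not path.is_dir():
        raise ValueError(f"{path} is not a directory of frames")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not files:
        raise ValueError(f"no decodable image frames found in {path}")
    images = []
    shape = None
    for f in files:
        img = iio.imread(f)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"frame dimension mismatch: {files[0].name} is {shape}, "
                f"{f.name} is {img.shape}"
            )
        images.append(img)
    return FrameStack(np.stack(images), frame_rate=frame_rate, t0_offset=t0_offset)


def write_frames(
    stack: FrameStack | Sequence[np.ndarray],
    path: str | Path,
    *,
    prefix: str = "frame",
    fmt: str = "png",
) -> list[Path]:
    """Write frames as numbered images (``frame_000001.png`` ...)."""
    frames = stack.frames if isinstance(stack, FrameStack) else stack
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i, frame in enumerate(frames):
        arr = np.asarray(frame)
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        p = path / f"{prefix}_{i:06d}.{fmt}"
        iio.imwrite(p, arr)
        out.append(p)
    return out
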