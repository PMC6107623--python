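"""Kymograph (space-time plot) construction and per-droplet trace extraction.

The central analytic object of the workflow: for every video frame a strip of
``strip_width`` pixels (default 15) centred on the slot centreline is cropped,
blurred across the strip width, and the strips are placed side by side in
temporal order.  Travelling oxidation waves appear as oblique ridges; a
droplet's oscillation trace is the mean of a ``strip_width x height`` region
(default 15 x 5 px) of this image per frame.

Canonical orientation is time on x and position along the slot on y; plotting
helpers may transpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .frames import FrameStack
from .geometry import DropletROI, SlotLayout

__all__ = ["Kymograph", "build_kymograph", "extract_trace_values"]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass
class Kymograph:
    """Space-time intensity image for one slot.

    ``image`` has shape ``(length_px, n_frames * strip_width)``: row index is
    position along the slot centreline, column index is (strip-resolved) time.
    In collapsed mode (``strip_width == 1``) each frame contributes a single
    column.
    """

    image: np.ndarray
    strip_width: int
    channel: str
    slot_id: str
    frame_rate: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2-D")
        if self.image.shape[1] % self.strip_width:
            raise ValueError(
                "kymograph width must be a multiple of strip_width "
                f"({self.image.shape[1]} vs {self.strip_width})"
            )

    @property
    def n_frames(self) -> int:
        return self.image.shape[1] // self.strip_width

    @property
    def length_px(self) -> int:
        return self.image.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_frames) / self.frame_rate

    def collapsed(self) -> np.ndarray:
        """Per-frame image ``(length_px, n_frames)``, averaging strip columns."""
        if self.strip_width == 1:
            return self.image
        return self.image.reshape(
            self.length_px, self.n_frames, self.strip_width
        ).mean(axis=2)

    def save_npy(self, path: str | Path) -> None:
        np.save(Path(path), self.image)

    def to_png_array(self) -> np.ndarray:
        """8-bit rendering of the kymograph for visual inspection."""
        img = self.image
        lo, hi = float(img.min()), float(img.max())
        if hi <= lo:
            return np.zeros(img.shape, dtype=np.uint8)
        return np.clip((img - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)


def _select_channel(frames: np.ndarray, channel: str | int | None) -> np.ndarray:
    if frames.ndim == 3:  # grayscale input: single channel regardless of request
        return frames
    if channel is None:
        return frames.mean(axis=-1)
    idx = _CHANNELS[channel] if isinstance(channel, str) else int(channel)
    return frames[..., idx]


def build_kymograph(
    stack: FrameStack,
    slot: SlotLayout,
    strip_width: int = 15,
    channel: str | int | None = "blue",
    *,
    blur: str | int = "full",
    collapse: bool = False,
) -> Kymograph:
    """Compose a slot kymograph from a frame stack.

    A ``strip_width`` pixel wide strip centred on the slot centreline is
    cropped from every frame and blurred across the strip ("x-direction").
    ``blur='full'`` (default) averages over the whole strip, making the
    strip's columns identical; an integer gives a narrower box kernel.  With
    ``collapse=True`` each frame contributes one column instead of
    ``strip_width`` identical ones; trace extraction is unaffected by the
    choice.

    Odd strip widths centre exactly on the centreline; even widths take one
    extra pixel toward lower coordinates.
    """
    if strip_width < 1:
        raise ValueError("strip_width must be >= 1")
    frames = _select_channel(stack.frames, channel)
    n, h, w = frames.shape
    x0, y0 = slot.origin_xy
    half_lo = strip_width // 2 + (strip_width % 2 == 0)
    half_hi = strip_width - (strip_width // 2 + (strip_width % 2 == 0))
    c = slot.centre_across
    if slot.axis == (0, 1):
        lo, hi = c - half_lo, c + half_hi
        if lo < 0 or hi > w or y0 < 0 or y0 + slot.length_px > h:
            raise ValueError(
                f"slot {slot.slot_id!r}: {strip_width}-px strip at x={c} or length "
                f"{slot.length_px} does not fit a {h}x{w} frame"
            )
        strips = frames[:, y0 : y0 + slot.length_px, lo:hi]  # (n, L, sw)
    else:
        lo, hi = c - half_lo, c + half_hi
        if lo < 0 or hi > h or x0 < 0 or x0 + slot.length_px > w:
            raise ValueError(
                f"slot {slot.slot_id!r}: {strip_width}-px strip at y={c} or length "
                f"{slot.length_px} does not fit a {h}x{w} frame"
            )
        strips = frames[:, lo:hi, x0 : x0 + slot.length_px]  # (n, sw, L)
        strips = np.swapaxes(strips, 1, 2)  # (n, L, sw)

    strips = strips.astype(float)
    if blur == "full":
        blurred = np.repeat(
            strips.mean(axis=2, keepdims=True), strip_width, axis=2
        )
    else:
        k = int(blur)
        if not 1 <= k <= strip_width:
            raise ValueError("blur kernel must be in [1, strip_width]")
        blurred = uniform_filter1d(strips, size=k, axis=2, mode="nearest")

    if collapse:
        image = blurred.mean(axis=2).T  # (L, n)
        out_sw = 1
    else:
        # (n, L, sw) -> (L, n*sw) with frame strips side by side in time order
        image = np.transpose(blurred, (1, 0, 2)).reshape(slot.length_px, n * strip_width)
        out_sw = strip_width
    return Kymograph(
        image=image,
        strip_width=out_sw,
        channel=str(channel),
        slot_id=slot.slot_id,
        frame_rate=stack.frame_rate,
        t0_offset=stack.t0_offset,
    )


def extract_trace_values(
    kymo: Kymograph, roi: DropletROI, height: int = 5
) -> np.ndarray:
    """Raw per-frame intensity of one droplet.

    The value for frame ``i`` is the mean over the ``strip_width x height``
    region of the kymograph centred (along the slot) on ``roi.centre_y`` --
    with the study defaults a 15 x 5 px region per frame.  The region must lie
    inside the droplet span; if it crosses the droplet boundary a new
    ``centre_y`` must be chosen.
    """
    if height < 1:
        raise ValueError("height must be >= 1")
    half_lo = height // 2 + (height % 2 == 0)
    half_hi = height - half_lo
    lo, hi = roi.centre_y - half_lo, roi.centre_y + half_hi
    if lo < roi.span[0] or hi > roi.span[1]:
        raise ValueError(
            f"droplet {roi.droplet_id!r}: {height}-px trace strip at y={roi.centre_y} "
            f"crosses the droplet boundary {roi.span!r}; choose a centre_y at least "
            f"{half_lo} px inside the span"
        )
    if hi > kymo.length_px:
        raise ValueError("trace strip outside kymograph extent")
    region = kymo.image[lo:hi, :]
    return region.reshape(height, kymo.n_frames, kymo.strip_width).mean(axis=(0, 2))
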