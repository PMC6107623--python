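"""Slot templates, droplet regions of interest and pixel calibration.

Recordings of droplet arrays are made with the droplets sitting in laser-cut
slots of an acrylic template, so every droplet can be addressed by a fixed
region of interest instead of being re-detected in each frame.  This module
holds the layout description: each :class:`SlotLayout` is one slot (a straight
channel of known physical width), and each :class:`DropletROI` is one droplet's
half-open pixel span along the slot centreline.

Coordinates are 0-based.  Positions along a slot are measured in pixels from
the slot origin; droplet spans are half-open ``[start, end)`` intervals.  A
droplet's missing neighbour is ``None`` (open oil) or the reserved marker
:data:`WALL` when the droplet touches the end wall of the slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

__all__ = [
    "WALL",
    "LayoutError",
    "SlotLayout",
    "DropletROI",
    "pixel_scale",
    "load_layout",
    "save_layout",
    "validate_layout",
    "make_linear_layout",
]

#: Reserved neighbour marker for a droplet in contact with the slot end wall.
WALL = "wall"

_AXES = {(0, 1), (1, 0)}


class LayoutError(ValueError):
    """Raised when a layout file or layout objects violate an invariant."""


@dataclass(frozen=True)
class SlotLayout:
    """One straight template slot.

    Parameters
    ----------
    slot_id:
        Label for the slot.
    origin_xy:
        Pixel coordinates ``(x, y)`` of the start of the slot centreline in
        the video frame.
    axis:
        Unit vector of the slot direction in the image plane.  Only
        axis-aligned slots are supported: ``(0, 1)`` (vertical, position grows
        with image row) or ``(1, 0)`` (horizontal).
    length_px, width_px:
        Slot extent along and across the axis, in pixels.
    length_mm, width_mm:
        The corresponding physical sizes.  ``width_mm / width_px`` defines the
        pixel scale (the study geometry is 2.5 mm spanned by 108 px).
    incline_deg:
        Tilt of the dish; metadata only (droplets glide to the lower slot end,
        the layout records their final spans explicitly).
    """

    slot_id: str
    origin_xy: tuple[int, int]
    axis: tuple[int, int]
    length_px: int
    width_px: int
    width_mm: float = 2.5
    length_mm: float = 0.0
    incline_deg: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.axis) not in _AXES:
            raise LayoutError(
                f"slot {self.slot_id!r}: axis must be (0,1) or (1,0), got {self.axis!r}"
            )
        if self.width_px <= 0:
            raise LayoutError(f"slot {self.slot_id!r}: width_px must be > 0")
        if self.length_px <= 0:
            raise LayoutError(f"slot {self.slot_id!r}: length_px must be > 0")
        if self.width_mm <= 0:
            raise LayoutError(f"slot {self.slot_id!r}: width_mm must be > 0")
        object.__setattr__(self, "origin_xy", tuple(self.origin_xy))
        object.__setattr__(self, "axis", tuple(self.axis))

    @property
    def centre_across(self) -> int:
        """Pixel coordinate of the centreline across the slot axis."""
        x0, y0 = self.origin_xy
        return (x0 if self.axis == (0, 1) else y0) + self.width_px // 2


def pixel_scale(slot: SlotLayout) -> float:
    """Physical pixel scale of a slot in mm per pixel (``width_mm / width_px``)."""
    if slot.width_px <= 0:
        raise LayoutError(f"slot {slot.slot_id!r}: width_px must be > 0")
    return slot.width_mm / slot.width_px


@dataclass(frozen=True)
class DropletROI:
    """One droplet's region of interest within a slot.

    ``span`` is a half-open pixel interval along the slot centreline and
    ``centre_y`` is the along-slot pixel used for trace extraction (typically
    near the droplet centre and free of artifacts such as CO2 bubbles).
    ``neighbours`` is the ordered pair of adjacent droplets toward lower and
    higher positions; entries are droplet ids, :data:`WALL` or ``None``.
    """

    droplet_id: str
    slot_id: str
    span: tuple[int, int]
    centre_y: int
    neighbours: tuple[str | None, str | None] = (None, None)

    def __post_init__(self) -> None:
        start, end = self.span
        if not start < end:
            raise LayoutError(
                f"droplet {self.droplet_id!r}: span must be non-empty, got {self.span!r}"
            )
        if not start <= self.centre_y < end:
            raise LayoutError(
                f"droplet {self.droplet_id!r}: centre_y {self.centre_y} outside span {self.span!r}"
            )
        object.__setattr__(self, "span", (int(start), int(end)))
        object.__setattr__(self, "neighbours", tuple(self.neighbours))

    @property
    def width_px(self) -> int:
        return self.span[1] - self.span[0]


def validate_layout(slots: Sequence[SlotLayout], rois: Sequence[DropletROI]) -> None:
    """Check cross-object layout invariants.

    Raises :class:`LayoutError` if a droplet references an unknown slot, spans
    overlap within a slot, a span leaves the slot, or neighbour links are not
    symmetric.
    """
    slot_map = {s.slot_id: s for s in slots}
    if len(slot_map) != len(slots):
        raise LayoutError("duplicate slot_id in layout")
    roi_map = {r.droplet_id: r for r in rois}
    if len(roi_map) != len(rois):
        raise LayoutError("duplicate droplet_id in layout")

    by_slot: dict[str, list[DropletROI]] = {}
    for roi in rois:
        if roi.slot_id not in slot_map:
            raise LayoutError(
                f"droplet {roi.droplet_id!r}: unknown slot_id {roi.slot_id!r}"
            )
        slot = slot_map[roi.slot_id]
        if roi.span[0] < 0 or roi.span[1] > slot.length_px:
            raise LayoutError(
                f"droplet {roi.droplet_id!r}: span {roi.span!r} outside slot length "
                f"{slot.length_px}"
            )
        by_slot.setdefault(roi.slot_id, []).append(roi)

    for slot_id, group in by_slot.items():
        ordered = sorted(group, key=lambda r: r.span)
        for a, b in zip(ordered, ordered[1:]):
            if a.span[1] > b.span[0]:
                raise LayoutError(
                    f"slot {slot_id!r}: droplet spans overlap "
                    f"({a.droplet_id!r} {a.span!r} vs {b.droplet_id!r} {b.span!r})"
                )

    for roi in rois:
        for side, other in enumerate(roi.neighbours):
            if other is None or other == WALL:
                continue
            if other not in roi_map:
                raise LayoutError(
                    f"droplet {roi.droplet_id!r}: unknown neighbour {other!r}"
                )
            back = roi_map[other].neighbours[1 - side]
            if back != roi.droplet_id:
                raise LayoutError(
                    f"asymmetric neighbour link: {roi.droplet_id!r} lists {other!r} "
                    f"but {other!r} lists {back!r}"
                )


def _slot_to_dict(slot: SlotLayout) -> dict:
    return {
        "slot_id": slot.slot_id,
        "origin_xy": list(slot.origin_xy),
        "axis": list(slot.axis),
        "length_px": slot.length_px,
        "width_px": slot.width_px,
        "width_mm": slot.width_mm,
        "length_mm": slot.length_mm,
        "incline_deg": slot.incline_deg,
    }


def _roi_to_dict(roi: DropletROI) -> dict:
    return {
        "droplet_id": roi.droplet_id,
        "slot_id": roi.slot_id,
        "span": list(roi.span),
        "centre_y": roi.centre_y,
        "neighbours": list(roi.neighbours),
    }


_SLOT_FIELDS = {"slot_id", "origin_xy", "axis", "length_px", "width_px",
                "width_mm", "length_mm", "incline_deg"}
_ROI_FIELDS = {"droplet_id", "slot_id", "span", "centre_y", "neighbours"}


def load_layout(path: str | Path) -> tuple[list[SlotLayout], list[DropletROI]]:
    """Read a layout file (JSON with ``slots`` and ``droplets`` lists).

    Droplet spans are returned sorted along the slot axis.  Malformed entries
    raise :class:`LayoutError` naming the offending field; overlapping spans
    and asymmetric neighbour links raise as well.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LayoutError(f"layout file {path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "slots" not in doc:
        raise LayoutError(f"layout file {path}: missing top-level 'slots' list")

    slots: list[SlotLayout] = []
    for i, entry in enumerate(doc.get("slots", [])):
        unknown = set(entry) - _SLOT_FIELDS
        if unknown:
            raise LayoutError(f"slots[{i}]: unknown field(s) {sorted(unknown)}")
        try:
            slots.append(
                SlotLayout(
                    slot_id=entry["slot_id"],
                    origin_xy=tuple(entry["origin_xy"]),
                    axis=tuple(entry["axis"]),
                    length_px=int(entry["length_px"]),
                    width_px=int(entry["width_px"]),
                    width_mm=float(entry.get("width_mm", 2.5)),
                    length_mm=float(entry.get("length_mm", 0.0)),
                    incline_deg=float(entry.get("incline_deg", 0.5)),
                )
            )
        except KeyError as exc:
            raise LayoutError(f"slots[{i}]: missing field {exc.args[0]!r}") from exc

    rois: list[DropletROI] = []
    for i, entry in enumerate(doc.get("droplets", [])):
        unknown = set(entry) - _ROI_FIELDS
        if unknown:
            raise LayoutError(f"droplets[{i}]: unknown field(s) {sorted(unknown)}")
        try:
            rois.append(
                DropletROI(
                    droplet_id=entry["droplet_id"],
                    slot_id=entry["slot_id"],
                    span=tuple(entry["span"]),
                    centre_y=int(entry["centre_y"]),
                    neighbours=tuple(entry.get("neighbours", (None, None))),
                )
            )
        except KeyError as exc:
            raise LayoutError(f"droplets[{i}]: missing field {exc.args[0]!r}") from exc

    validate_layout(slots, rois)
    rois.sort(key=lambda r: (r.slot_id, r.span))
    return slots, rois


def save_layout(
    slots: Sequence[SlotLayout], rois: Sequence[DropletROI], path: str | Path
) -> None:
    """Write a layout file; ``load_layout(save_layout(...))`` round-trips."""
    validate_layout(slots, rois)
    doc = {
        "slots": [_slot_to_dict(s) for s in slots],
        "droplets": [_roi_to_dict(r) for r in rois],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def make_linear_layout(
    n_droplets: int,
    *,
    slot_id: str = "slot0",
    span_px: int = 108,
    width_px: int = 108,
    width_mm: float = 2.5,
    origin_xy: tuple[int, int] = (20, 20),
    axis: tuple[int, int] = (0, 1),
    extra_length_px: int = 0,
    incline_deg: float = 0.5,
    droplet_prefix: str = "d",
) -> tuple[SlotLayout, list[DropletROI]]:
    """Build a slot holding ``n_droplets`` equal contacting droplets.

    Droplets are stacked from the slot origin (the lower end, where gravity
    collects them): the first droplet touches the wall, the far side of the
    last droplet is open oil.  With the defaults each droplet spans 108 px of
    a 2.5 mm wide slot, the calibration of the study's recordings.
    """
    if n_droplets < 0:
        raise LayoutError("n_droplets must be >= 0")
    length = max(n_droplets * span_px + extra_length_px, span_px)
    scale = width_mm / width_px
    slot = SlotLayout(
        slot_id=slot_id,
        origin_xy=origin_xy,
        axis=axis,
        length_px=length,
        width_px=width_px,
        width_mm=width_mm,
        length_mm=length * scale,
        incline_deg=incline_deg,
    )
    ids = [f"{droplet_prefix}{i}" for i in range(n_droplets)]
    rois = []
    for i, did in enumerate(ids):
        lo = WALL if i == 0 else ids[i - 1]
        hi = ids[i + 1] if i + 1 < n_droplets else None
        start = i * span_px
        rois.append(
            DropletROI(
                droplet_id=did,
                slot_id=slot_id,
                span=(start, start + span_px),
                centre_y=start + span_px // 2,
                neighbours=(lo, hi),
            )
        )
    validate_layout([slot], rois)
    return slot, rois


def rescaled(slot: SlotLayout, factor: int) -> SlotLayout:
    """Uniformly rescale a slot's pixel and physical width (testing helper)."""
    return replace(
        slot, width_px=slot.width_px * factor, width_mm=slot.width_mm * factor
    )
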