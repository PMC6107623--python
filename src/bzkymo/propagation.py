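"""Wavefront tracking and interdroplet propagation analysis.

In a multi-droplet kymograph a travelling oxidation wave is an oblique bright
ridge.  This module binarises the kymograph into a space-time mask of
oxidised bands, links the per-column band segments into
:class:`WavefrontTrack` objects, and classifies what happens at every
droplet-droplet interface: a front either crosses (propagation), dies there
(blocked), annihilates against an opposing front, or runs out at a slot
boundary.  The study reads these events visually from space-time plots; the
rules here are an explicit, reproducible version of that reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .geometry import DropletROI, WALL
from .kymograph import Kymograph

__all__ = [
    "WavefrontTrack",
    "InterfaceStat",
    "PropagationReport",
    "binarize_fronts",
    "track_wavefronts",
    "classify_interfaces",
]


def binarize_fronts(
    kymo: Kymograph,
    *,
    threshold_frac: float = 0.5,
    baseline_window_s: float = 60.0,
    min_amplitude: float = 10.0,
) -> np.ndarray:
    """Boolean space-time mask of oxidised (high blue-channel) bands.

    Each spatial row is first corrected by its running-minimum baseline over
    ``baseline_window_s`` (adaptive per position, so slow photometric drift
    cannot flip the mask), then thresholded at ``threshold_frac`` of the
    99th-percentile corrected amplitude.  A degenerate kymograph whose
    corrected amplitude stays below ``min_amplitude`` intensity units yields
    an all-false mask.

    The mask is collapsed to one column per frame: shape
    ``(length_px, n_frames)``.
    """
    img = kymo.collapsed()
    window = max(3, int(round(baseline_window_s * kymo.frame_rate)))
    window = min(window, img.shape[1])
    if window >= 3:
        baseline = minimum_filter1d(img, size=window, axis=1, mode="nearest")
    else:
        baseline = np.min(img, axis=1, keepdims=True)
    corrected = img - baseline
    amp = float(corrected.max()) if corrected.size else 0.0
    if amp < min_amplitude:
        return np.zeros(img.shape, dtype=bool)
    return corrected >= threshold_frac * amp


@dataclass
class WavefrontTrack:
    """One travelling wavefront ridge in (time, position) space."""

    track_id: int
    times_s: np.ndarray
    positions_px: np.ndarray
    droplets_visited: list[str]
    crossings: list[dict]  # {"interface": "a|b", "time_s": t, "delay_s": d}
    termination: str  # boundary | annihilation | dissipation

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def direction(self) -> int:
        """+1 toward larger positions, -1 toward smaller, 0 stationary."""
        d = self.positions_px[-1] - self.positions_px[0]
        if abs(d) < 1.0:
            return 0
        return 1 if d > 0 else -1

    @property
    def t_start(self) -> float:
        return float(self.times_s[0])

    @property
    def t_end(self) -> float:
        return float(self.times_s[-1])

    @property
    def end_position(self) -> float:
        return float(self.positions_px[-1])


@dataclass
class InterfaceStat:
    interface: str  # "dropletA|dropletB"
    position_px: float
    propagated: int = 0
    blocked: int = 0

    @property
    def total(self) -> int:
        return self.propagated + self.blocked

    @property
    def coupled(self) -> bool | None:
        if self.total == 0:
            return None
        return self.propagated / self.total >= 0.5


@dataclass
class PropagationReport:
    """Per-interface propagation statistics, wave origins and annihilations."""

    interfaces: list[InterfaceStat]
    origins: list[dict]  # {"droplet_id", "time_s", "origin"}
    annihilations: list[tuple[float, float]]  # (time_s, position_px)
    coupled_fraction_threshold: float = 0.5

    def interface(self, name: str) -> InterfaceStat | None:
        for st in self.interfaces:
            if st.interface == name:
                return st
        return None

    def crossings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "interface": st.interface,
                    "position_px": st.position_px,
                    "propagated": st.propagated,
                    "blocked": st.blocked,
                }
                for st in self.interfaces
            ]
        )

    def as_dict(self) -> dict:
        return {
            "interfaces": [
                {
                    "interface": st.interface,
                    "position_px": st.position_px,
                    "propagated": st.propagated,
                    "blocked": st.blocked,
                    "coupled": st.coupled,
                }
                for st in self.interfaces
            ],
            "origins": self.origins,
            "annihilations": [list(a) for a in self.annihilations],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1) + "\n")


def _column_segments(col: np.ndarray, min_len: int = 2) -> list[tuple[int, int, float]]:
    """Maximal runs of True pixels: (start, end, centroid)."""
    idx = np.flatnonzero(col)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        lo, hi = int(idx[s]), int(idx[e])
        if hi - lo + 1 >= min_len:
            out.append((lo, hi, 0.5 * (lo + hi)))
    return out


class _LiveTrack:
    __slots__ = ("tid", "cols", "cents", "runs", "last_col", "annihilated", "anni_point")

    def __init__(self, tid: int, col: int, seg: tuple[int, int, float]):
        self.tid = tid
        self.cols = [col]
        self.cents = [seg[2]]
        self.runs = [(seg[0], seg[1])]
        self.last_col = col
        self.annihilated = False
        self.anni_point: tuple[float, float] | None = None

    def extend(self, col: int, seg: tuple[int, int, float]) -> None:
        self.cols.append(col)
        self.cents.append(seg[2])
        self.runs.append((seg[0], seg[1]))
        self.last_col = col


def track_wavefronts(
    mask: np.ndarray,
    times_s: np.ndarray,
    rois: Sequence[DropletROI],
    *,
    max_jump_px: float = 25.0,
    max_gap_frames: int = 2,
    min_track_frames: int = 3,
    interface_tol_px: float = 4.0,
) -> list[WavefrontTrack]:
    """Link per-column mask segments into wavefront tracks.

    Segments in consecutive (or near-consecutive, up to ``max_gap_frames``)
    columns are linked when their pixel runs overlap or their centroids lie
    within ``max_jump_px``.  A segment claimed by two tracks arriving from
    opposite directions terminates both as an annihilation; a track matching
    two segments continues with the nearer one and spawns a second track
    sharing the origin (a source emitting two opposite fronts).  Tracks
    shorter than ``min_track_frames`` columns are discarded as speckle.

    Crossings of droplet interfaces are recorded where a track's position
    passes an ROI boundary; the recorded delay is the dwell time of the front
    within ``interface_tol_px`` of the interface.
    """
    rois = sorted(rois, key=lambda r: r.span)
    times_s = np.asarray(times_s, dtype=float)
    n_pos, n_cols = mask.shape
    if n_cols != times_s.size:
        raise ValueError("mask column count must match times")

    live: list[_LiveTrack] = []
    done: list[_LiveTrack] = []
    next_id = 0

    for col in range(n_cols):
        segs = _column_segments(mask[:, col])
        # age out tracks not extended within the gap tolerance
        still_live = []
        for tr in live:
            if col - tr.last_col > max_gap_frames:
                done.append(tr)
            else:
                still_live.append(tr)
        live = still_live

        # greedy nearest assignment, each track claims at most one segment
        pairs: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(live):
            for si, (lo, hi, cent) in enumerate(segs):
                rlo, rhi = tr.runs[-1]
                overlap = not (hi < rlo - 1 or lo > rhi + 1)
                dist = abs(cent - tr.cents[-1])
                if overlap or dist <= max_jump_px:
                    pairs.append((dist, ti, si))
        pairs.sort()
        seg_claimers: dict[int, list[_LiveTrack]] = {}
        claimed: set[int] = set()
        for _dist, ti, si in pairs:
            if ti in claimed:
                continue
            claimed.add(ti)
            seg_claimers.setdefault(si, []).append(live[ti])

        ended: list[_LiveTrack] = []
        consumed_segs: set[int] = set()
        for si, claimers in seg_claimers.items():
            if len(claimers) >= 2:
                dirs = {
                    float(np.sign(tr.cents[-1] - tr.cents[0]))
                    for tr in claimers
                    if len(tr.cents) >= 2 and tr.cents[-1] != tr.cents[0]
                }
                if len(dirs) >= 2:
                    # opposite-direction fronts met: annihilation
                    t_meet = float(times_s[col])
                    x_meet = segs[si][2]
                    for tr in claimers:
                        tr.extend(col, segs[si])
                        tr.annihilated = True
                        tr.anni_point = (t_meet, x_meet)
                        ended.append(tr)
                else:
                    claimers[0].extend(col, segs[si])  # same direction: keep nearest
            else:
                claimers[0].extend(col, segs[si])
            consumed_segs.add(si)

        if ended:
            done.extend(ended)
            live = [tr for tr in live if tr not in ended]

        for si, seg in enumerate(segs):
            if si not in consumed_segs:
                live.append(_LiveTrack(next_id, col, seg))
                next_id += 1

    done.extend(live)

    # build WavefrontTrack objects
    interfaces: list[tuple[str, float]] = []
    for a, b in zip(rois, rois[1:]):
        if a.span[1] == b.span[0]:
            interfaces.append((f"{a.droplet_id}|{b.droplet_id}", float(a.span[1])))

    def droplet_of(pos: float) -> str | None:
        for r in rois:
            if r.span[0] <= pos < r.span[1]:
                return r.droplet_id
        return None

    tracks: list[WavefrontTrack] = []
    last_col_idx = n_cols - 1
    for tr in sorted(done, key=lambda t: (t.cols[0], t.tid)):
        if len(tr.cols) < min_track_frames:
            continue
        t_arr = times_s[np.asarray(tr.cols)]
        p_arr = np.asarray(tr.cents)
        visited: list[str] = []
        for p in p_arr:
            d = droplet_of(p)
            if d is not None and (not visited or visited[-1] != d):
                if d not in visited:
                    visited.append(d)
        crossings = []
        for name, bpos in interfaces:
            # a crossing requires genuine passage: samples on both sides of the
            # interface beyond a dead zone, so a front dying *at* the interface
            # (a block) is not mistaken for one
            below = p_arr <= bpos - interface_tol_px
            above = p_arr >= bpos + interface_tol_px
            if not (below.any() and above.any()):
                continue
            i_below = int(np.flatnonzero(below)[0])
            i_above = int(np.flatnonzero(above)[0])
            k = max(i_below, i_above)  # first sample on the far side
            t_cross = float(t_arr[k])
            near = np.abs(p_arr - bpos) <= max(
                interface_tol_px,
                abs(p_arr[min(k, len(p_arr) - 1)] - p_arr[max(k - 1, 0)]) / 2,
            )
            dwell = (
                float(near.sum() * (times_s[1] - times_s[0]))
                if times_s.size > 1
                else 0.0
            )
            crossings.append({"interface": name, "time_s": t_cross, "delay_s": dwell})
        if tr.annihilated:
            termination = "annihilation"
        elif tr.cols[-1] >= last_col_idx - 0:
            termination = "boundary"  # censored by end of recording
        elif p_arr[-1] <= rois[0].span[0] + interface_tol_px or p_arr[-1] >= rois[-1].span[1] - interface_tol_px:
            termination = "boundary"
        else:
            termination = "dissipation"
        tracks.append(
            WavefrontTrack(
                track_id=tr.tid,
                times_s=t_arr,
                positions_px=p_arr,
                droplets_visited=visited,
                crossings=sorted(crossings, key=lambda c: c["time_s"]),
                termination=termination,
            )
        )
    return tracks


def classify_interfaces(
    tracks: Sequence[WavefrontTrack],
    rois: Sequence[DropletROI],
    *,
    interface_tol_px: float = 6.0,
    delay_window_s: float = 25.0,
    coupled_fraction: float = 0.5,
) -> PropagationReport:
    """Classify every droplet interface from the tracked wavefronts.

    A front *propagates* across an interface when its track crosses it, or
    when its track ends at the interface and another track begins on the far
    side within ``delay_window_s`` (a crossing delay long enough to break the
    ridge into two tracks).  A front that ends at an interface with no such
    continuation is *blocked*.  An interface is called coupled when at least
    ``coupled_fraction`` of arriving fronts crossed.  Per-droplet wave
    origins are labelled from where each track first appears inside the
    droplet: at its top or bottom interface, at a slot wall, or in the
    interior (a self-excited wave).
    """
    rois = sorted(rois, key=lambda r: r.span)
    interfaces: list[InterfaceStat] = []
    iface_pos: dict[str, float] = {}
    for a, b in zip(rois, rois[1:]):
        if a.span[1] == b.span[0]:
            name = f"{a.droplet_id}|{b.droplet_id}"
            interfaces.append(InterfaceStat(interface=name, position_px=float(a.span[1])))
            iface_pos[name] = float(a.span[1])

    stats = {st.interface: st for st in interfaces}
    annihilations: list[tuple[float, float]] = []

    # direct crossings
    for tr in tracks:
        for c in tr.crossings:
            if c["interface"] in stats:
                stats[c["interface"]].propagated += 1

    # ends at an interface: bridged continuation or block
    for tr in tracks:
        if tr.termination == "annihilation":
            continue
        end_pos, end_t = tr.end_position, tr.t_end
        for name, bpos in iface_pos.items():
            if abs(end_pos - bpos) > interface_tol_px:
                continue
            if any(c["interface"] == name for c in tr.crossings):
                continue  # already crossed this interface
            if tr.termination == "boundary":
                continue  # censored by recording end / slot wall
            bridged = False
            for other in tracks:
                if other is tr:
                    continue
                gap = other.t_start - end_t
                if 0 <= gap <= delay_window_s and abs(
                    other.positions_px[0] - bpos
                ) <= 2 * interface_tol_px:
                    moving_on = (other.positions_px[0] - bpos) * tr.direction >= -interface_tol_px
                    if other.direction == tr.direction or moving_on:
                        bridged = True
                        break
            if bridged:
                stats[name].propagated += 1
            else:
                stats[name].blocked += 1

    # annihilation events (pairs share one endpoint)
    seen: set[tuple[float, float]] = set()
    for tr in tracks:
        if tr.termination == "annihilation":
            key = (round(tr.t_end, 3), round(tr.end_position, 1))
            if key not in seen:
                seen.add(key)
                annihilations.append((tr.t_end, tr.end_position))

    # per-droplet wave origins
    origins: list[dict] = []
    for tr in tracks:
        for did in tr.droplets_visited:
            roi = next(r for r in rois if r.droplet_id == did)
            inside = (tr.positions_px >= roi.span[0]) & (tr.positions_px < roi.span[1])
            if not inside.any():
                continue
            k = int(np.flatnonzero(inside)[0])
            pos, t0 = tr.positions_px[k], float(tr.times_s[k])
            if abs(pos - roi.span[0]) <= interface_tol_px:
                label = WALL if roi.neighbours[0] == WALL else "interface_top"
            elif abs(pos - roi.span[1]) <= interface_tol_px:
                label = WALL if roi.neighbours[1] == WALL else "interface_bottom"
            else:
                label = "interior"
            origins.append({"droplet_id": did, "time_s": t0, "origin": label})

    return PropagationReport(
        interfaces=interfaces,
        origins=sorted(origins, key=lambda o: (o["time_s"], o["droplet_id"])),
        annihilations=sorted(annihilations),
        coupled_fraction_threshold=coupled_fraction,
    )
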