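"""Synthetic droplet-array recordings with machine-readable ground truth.

The generator emulates, phenomenologically, what a camera sees of
ferroin-catalysed BZ droplets sitting in template slots: a red (reduced)
resting state, blue-channel intensity pulses as oxidation wavefronts pass,
the five lifecycle stages with their frequency/amplitude signatures,
interdroplet propagation with per-interface probabilities and delays, wave
annihilation, photometric noise and slow baseline drift.  No reaction
kinetics are integrated -- waves follow an explicit schedule -- which is
exactly what makes every pipeline stage testable: the schedule *is* the
ground truth.

Three levels of output are available, all deterministic for a given seed:

* :func:`simulate_fronts` -- an event-driven simulation of travelling
  wavefronts along a slot (droplet-resolution), producing ground truth:
  per-droplet wave times, per-interface crossings/blocks, annihilations and
  full front trajectories;
* :func:`simulate_traces` -- per-droplet intensity traces built from the
  simulated waves (asymmetric fast-rise/slow-decay pulses on a drifting,
  noisy baseline);
* :func:`render_kymograph` / :func:`render_frames` -- space-time images and
  full RGB frame stacks with the study's default calibration (108 px / 2.5 mm
  slots, 0.4 frames/s).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .frames import FrameStack
from .geometry import DropletROI, SlotLayout
from .kymograph import Kymograph
from .oscillation import IntensityTrace

__all__ = [
    "StageSpec",
    "LifecycleSchedule",
    "CouplingSpec",
    "NoiseConfig",
    "FrontRecord",
    "GroundTruth",
    "TraceSet",
    "schedule_wave_times",
    "simulate_fronts",
    "simulate_traces",
    "render_kymograph",
    "render_frames",
    "lifecycle_fixture",
]


@dataclass(frozen=True)
class StageSpec:
    """One oscillatory lifecycle stage.

    ``frequency_per_s`` is the wave frequency at the start of the stage;
    ``frequency_end_per_s`` (default: constant) lets the main stage decline
    slowly.  ``amplitude`` is the blue-channel pulse height in 8-bit intensity
    units.
    """

    duration_s: float
    frequency_per_s: float
    frequency_end_per_s: float | None = None
    amplitude: float = 80.0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("stage duration must be >= 0")
        if self.duration_s > 0 and self.frequency_per_s <= 0:
            raise ValueError("stage frequency must be > 0 where duration > 0")

    @property
    def f_end(self) -> float:
        return (
            self.frequency_per_s
            if self.frequency_end_per_s is None
            else self.frequency_end_per_s
        )

    def frequency_at(self, frac: float) -> float:
        return self.frequency_per_s + (self.f_end - self.frequency_per_s) * frac


@dataclass(frozen=True)
class LifecycleSchedule:
    """Per-droplet lifecycle: induction, initial, main and late stages.

    Defaults describe a typical malonic-acid BZ droplet: a short quiescent
    induction, ~3 min of fast low-amplitude initial waves (0.2 s^-1), a 1 h
    main stage at 0.04 s^-1 with full-amplitude waves, and a ~10 min late
    stage at roughly double the main frequency, after which the medium is
    exhausted.  ``final_state`` records whether the droplet ends reduced (red)
    or oxidised (blue); ``spiral_start_probability`` is the chance the droplet
    begins with spiral rather than planar waves (bookkeeping only -- wave
    geometry within a droplet is not rendered).  ``origin`` places the source
    of self-generated waves along the droplet span.
    """

    induction_s: float = 60.0
    initial: StageSpec = field(default_factory=lambda: StageSpec(180.0, 0.2, None, 24.0))
    main: StageSpec = field(default_factory=lambda: StageSpec(3600.0, 0.04, 0.04, 80.0))
    late: StageSpec = field(default_factory=lambda: StageSpec(600.0, 0.08, None, 80.0))
    final_state: str = "reduced"
    spiral_start_probability: float = 0.2
    origin: str = "centre"  # centre | low | high

    def __post_init__(self) -> None:
        if self.induction_s < 0:
            raise ValueError("induction_s must be >= 0")
        if self.final_state not in ("reduced", "oxidised"):
            raise ValueError("final_state must be 'reduced' or 'oxidised'")
        if self.origin not in ("centre", "low", "high"):
            raise ValueError("origin must be centre, low or high")
        if self.initial.duration_s > 0 and self.main.duration_s > 0:
            if not self.initial.frequency_per_s > self.main.frequency_per_s:
                raise ValueError("initial frequency must exceed main frequency")
        if self.late.duration_s > 0 and self.main.duration_s > 0:
            if not self.late.frequency_per_s > self.main.f_end:
                raise ValueError("late frequency must exceed the main end frequency")

    @property
    def total_s(self) -> float:
        return (
            self.induction_s
            + self.initial.duration_s
            + self.main.duration_s
            + self.late.duration_s
        )

    @classmethod
    def quiescent(cls) -> "LifecycleSchedule":
        """A droplet that never self-oscillates (excitable medium only)."""
        return cls(
            induction_s=0.0,
            initial=StageSpec(0.0, 1.0),
            main=StageSpec(0.0, 1.0),
            late=StageSpec(0.0, 1.0),
            spiral_start_probability=0.0,
        )


@dataclass(frozen=True)
class CouplingSpec:
    """Interdroplet coupling at one interface.

    An arriving wavefront crosses with ``propagation_probability`` after
    ``crossing_delay_s``; crossings within ``refractory_s`` of the previous
    one at the same interface are suppressed.
    """

    propagation_probability: float = 1.0
    crossing_delay_s: float = 2.5
    refractory_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.propagation_probability <= 1.0:
            raise ValueError("propagation_probability must be in [0, 1]")
        if self.crossing_delay_s < 0 or self.refractory_s < 0:
            raise ValueError("delay and refractory must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Photometric noise model.

    Additive Gaussian noise (``sigma_frac`` of the pulse amplitude), a slow
    sinusoidal baseline drift (``drift_amp_frac`` of the amplitude over
    ``drift_period_s``), and optionally a number of static bright spots
    emulating CO2 bubbles in rendered images.
    """

    sigma_frac: float = 0.02
    drift_amp_frac: float = 0.05
    drift_period_s: float = 1800.0
    n_artifacts: int = 0

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(sigma_frac=0.0, drift_amp_frac=0.0, n_artifacts=0)


def schedule_wave_times(
    schedule: LifecycleSchedule,
) -> tuple[list[tuple[float, float, float, str]], dict[str, tuple[float, float]]]:
    """Expand a schedule into wave emissions and stage boundaries.

    Returns ``(waves, stage_bounds)`` where each wave is
    ``(time_s, frequency_per_s, amplitude, stage)``.  A stage emits its first
    wave at the stage start and then every ``1/f(t)``; if a stage boundary
    falls within a quarter period of the previous wave the first wave is
    deferred by one period so stages never double-pulse.
    """
    waves: list[tuple[float, float, float, str]] = []
    bounds: dict[str, tuple[float, float]] = {}
    t_cursor = 0.0
    if schedule.induction_s > 0:
        bounds["induction"] = (0.0, schedule.induction_s)
    t_cursor = schedule.induction_s
    last_wave = -math.inf
    for name in ("initial", "main", "late"):
        stage: StageSpec = getattr(schedule, name)
        if stage.duration_s <= 0:
            continue
        start, end = t_cursor, t_cursor + stage.duration_s
        bounds[name] = (start, end)
        t = start
        f0 = stage.frequency_at(0.0)
        if t - last_wave < 0.25 / f0:
            t = start + 1.0 / f0
        while t < end - 1e-9:
            f = stage.frequency_at((t - start) / stage.duration_s)
            waves.append((t, f, stage.amplitude, name))
            last_wave = t
            t += 1.0 / f
        t_cursor = end
    bounds["exhausted"] = (t_cursor, math.inf)
    return waves, bounds


# ---------------------------------------------------------------------------
# front-level event simulation


@dataclass
class FrontRecord:
    """One travelling wavefront: piecewise-linear (time, position) segments."""

    front_id: int
    segments: list[tuple[float, float, float, float]]  # (t0, x0, t1, x1)
    droplets_visited: list[str]
    termination: str  # boundary | annihilation | blocked | recording_end
    frequency: float
    amplitude: float
    source_droplet: str

    def position_at(self, t: float) -> float | None:
        for t0, x0, t1, x1 in self.segments:
            if t0 - 1e-9 <= t <= t1 + 1e-9:
                if t1 <= t0:
                    return x1
                return x0 + (x1 - x0) * (t - t0) / (t1 - t0)
        return None

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][2]


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator scheduled."""

    wave_times: dict[str, list[float]]
    wave_freqs: dict[str, list[float]]
    wave_amps: dict[str, list[float]]
    stage_bounds: dict[str, dict[str, tuple[float, float]]]
    crossings: list[dict]  # {"interface": "a|b", "time_s": t, "delay_s": d}
    blocks: list[dict]  # {"interface": "a|b", "time_s": t}
    annihilations: list[tuple[float, float]]  # (time_s, position_px)
    fronts: list[FrontRecord]
    spiral_start: dict[str, bool]
    duration_s: float

    def crossings_at(self, interface: str) -> list[dict]:
        return [c for c in self.crossings if c["interface"] == interface]

    def blocks_at(self, interface: str) -> list[dict]:
        return [b for b in self.blocks if b["interface"] == interface]

    def as_dict(self) -> dict:
        return {
            "wave_times": self.wave_times,
            "wave_freqs": self.wave_freqs,
            "stage_bounds": {
                d: {
                    k: [v[0], v[1] if math.isfinite(v[1]) else self.duration_s]
                    for k, v in bounds.items()
                }
                for d, bounds in self.stage_bounds.items()
            },
            "crossings": self.crossings,
            "blocks": self.blocks,
            "annihilations": [list(a) for a in self.annihilations],
            "spiral_start": self.spiral_start,
            "duration_s": self.duration_s,
            "fronts": [
                {
                    "front_id": f.front_id,
                    "segments": [list(s) for s in f.segments],
                    "droplets_visited": f.droplets_visited,
                    "termination": f.termination,
                }
                for f in self.fronts
            ],
        }


class _Front:
    __slots__ = (
        "fid", "mode", "t_ref", "x_ref", "v", "droplet", "alive", "segments",
        "seg_t0", "seg_x0", "visited", "termination", "freq", "amp",
        "source", "pending_passes",
    )

    def __init__(self, fid, t, x, v, droplet, freq, amp, source):
        self.fid = fid
        self.mode = "moving"
        self.t_ref = t
        self.x_ref = x
        self.v = v
        self.droplet = droplet
        self.alive = True
        self.segments: list[tuple[float, float, float, float]] = []
        self.seg_t0, self.seg_x0 = t, x
        self.visited: list[int] = []
        self.termination = "recording_end"
        self.freq = freq
        self.amp = amp
        self.source = source
        self.pending_passes: list[tuple[int, float]] = []

    def position(self, t: float) -> float:
        if self.mode == "paused":
            return self.x_ref
        return self.x_ref + self.v * (t - self.t_ref)

    def close_segment(self, t: float, x: float) -> None:
        if t > self.seg_t0 or not self.segments:
            self.segments.append((self.seg_t0, self.seg_x0, t, x))
        self.seg_t0, self.seg_x0 = t, x


def _resolve_coupling(
    coupling: CouplingSpec | Mapping[str, CouplingSpec] | None, interface: str
) -> CouplingSpec:
    if coupling is None:
        return CouplingSpec()
    if isinstance(coupling, CouplingSpec):
        return coupling
    return coupling.get(interface, CouplingSpec())


def simulate_fronts(
    rois: Sequence[DropletROI],
    schedules: Mapping[str, LifecycleSchedule],
    *,
    coupling: CouplingSpec | Mapping[str, CouplingSpec] | None = None,
    seed: int = 0,
    duration_s: float | None = None,
    front_speed_px_per_s: float = 6.0,
) -> GroundTruth:
    """Event-driven simulation of wavefronts along one slot.

    Each droplet emits waves per its :class:`LifecycleSchedule`; fronts travel
    at constant speed, pause ``crossing_delay_s`` at interfaces they cross,
    die where a propagation draw fails (a block), annihilate pairwise when two
    opposing fronts meet inside a droplet, and terminate at slot ends or at
    the end of the recording.  Deterministic for a given seed: draws are
    consumed in event order, ties broken by insertion sequence.
    """
    rois = sorted(rois, key=lambda r: r.span)
    n = len(rois)
    ids = [r.droplet_id for r in rois]
    rng = np.random.default_rng(seed)

    if duration_s is None:
        duration_s = max(
            [schedules[i].total_s for i in ids if i in schedules] or [0.0]
        ) + 300.0

    wave_times: dict[str, list[float]] = {i: [] for i in ids}
    wave_freqs: dict[str, list[float]] = {i: [] for i in ids}
    wave_amps: dict[str, list[float]] = {i: [] for i in ids}
    stage_bounds: dict[str, dict[str, tuple[float, float]]] = {}
    crossings: list[dict] = []
    blocks: list[dict] = []
    annihilations: list[tuple[float, float]] = []
    spiral_start: dict[str, bool] = {}

    heap: list[tuple[float, int, str, tuple]] = []
    seq = 0

    def push(t: float, kind: str, data: tuple) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, data))
        seq += 1

    for idx, roi in enumerate(rois):
        sched = schedules.get(roi.droplet_id)
        if sched is None:
            sched = LifecycleSchedule.quiescent()
        spiral_start[roi.droplet_id] = bool(
            rng.random() < sched.spiral_start_probability
        )
        waves, bounds = schedule_wave_times(sched)
        stage_bounds[roi.droplet_id] = bounds
        for (t, f, a, _stage) in waves:
            if t <= duration_s:
                push(t, "spawn", (idx, f, a))

    fronts: list[_Front] = []
    active: dict[int, set[int]] = {i: set() for i in range(n)}
    last_cross: dict[str, float] = {}

    def interface_name(i: int, j: int) -> str:
        a, b = (i, j) if i < j else (j, i)
        return f"{ids[a]}|{ids[b]}"

    def start_in_droplet(front: _Front, idx: int, t: float, x: float) -> None:
        """Begin (or continue) traversal of droplet idx from position x."""
        roi = rois[idx]
        front.mode = "moving"
        front.t_ref, front.x_ref = t, x
        front.droplet = idx
        if idx not in front.visited:
            front.visited.append(idx)
        centre = roi.centre_y
        if (centre - x) * front.v > 0:
            t_pass = t + (centre - x) / front.v
            front.pending_passes.append((idx, t_pass))
        elif abs(centre - x) < 1e-9:
            front.pending_passes.append((idx, t))
        boundary = roi.span[1] if front.v > 0 else roi.span[0]
        t_exit = t + (boundary - x) / front.v
        push(t_exit, "arrive", (front.fid, boundary))
        # collision check against opposing fronts already in this droplet
        for gid in list(active[idx]):
            g = fronts[gid]
            if not g.alive or g.mode != "moving" or g.v * front.v >= 0:
                continue
            dv = front.v - g.v
            if dv == 0:
                continue
            t_meet = t + (g.position(t) - x) / dv
            if t_meet <= t + 1e-12:
                continue
            x_meet = front.position(t_meet)
            if rois[idx].span[0] - 1e-9 <= x_meet <= rois[idx].span[1] + 1e-9:
                push(t_meet, "meet", (front.fid, gid, x_meet))
        active[idx].add(front.fid)

    def kill(front: _Front, t: float, x: float, termination: str) -> None:
        front.close_segment(t, x)
        front.alive = False
        front.termination = termination
        active[front.droplet].discard(front.fid)
        front.pending_passes = [
            (d, tp) for (d, tp) in front.pending_passes if tp <= t + 1e-9
        ]

    while heap:
        t, _, kind, data = heapq.heappop(heap)
        if t > duration_s:
            break
        if kind == "spawn":
            idx, f, a = data
            roi = rois[idx]
            sched = schedules.get(roi.droplet_id) or LifecycleSchedule.quiescent()
            wave_times[roi.droplet_id].append(t)
            wave_freqs[roi.droplet_id].append(f)
            wave_amps[roi.droplet_id].append(a)
            if sched.origin == "centre":
                starts = [(roi.centre_y, +1.0), (roi.centre_y, -1.0)]
            elif sched.origin == "low":
                starts = [(float(roi.span[0]), +1.0)]
            else:
                starts = [(float(roi.span[1]) - 1e-9, -1.0)]
            for x0, direction in starts:
                front = _Front(
                    len(fronts), t, x0, direction * front_speed_px_per_s,
                    idx, f, a, roi.droplet_id,
                )
                fronts.append(front)
                start_in_droplet(front, idx, t, x0)
        elif kind == "arrive":
            fid, boundary = data
            front = fronts[fid]
            if not front.alive or front.mode != "moving":
                continue
            if abs(front.position(t) - boundary) > 1e-6:
                continue  # stale event from a previous traversal
            idx = front.droplet
            nbr = idx + (1 if front.v > 0 else -1)
            active[idx].discard(fid)
            if nbr < 0 or nbr >= n or rois[min(idx, nbr)].span[1] != rois[max(idx, nbr)].span[0]:
                kill(front, t, boundary, "boundary")
                continue
            iface = interface_name(idx, nbr)
            spec = _resolve_coupling(coupling, iface)
            refractory_hit = (
                spec.refractory_s > 0
                and iface in last_cross
                and t - last_cross[iface] < spec.refractory_s
            )
            if refractory_hit or rng.random() >= spec.propagation_probability:
                blocks.append({"interface": iface, "time_s": t})
                kill(front, t, boundary, "blocked")
                continue
            crossings.append(
                {"interface": iface, "time_s": t, "delay_s": spec.crossing_delay_s}
            )
            last_cross[iface] = t
            front.close_segment(t, boundary)
            if spec.crossing_delay_s > 0:
                front.mode = "paused"
                front.t_ref, front.x_ref = t, boundary
                front.close_segment(t + spec.crossing_delay_s, boundary)
                push(t + spec.crossing_delay_s, "resume", (fid, nbr, boundary))
            else:
                start_in_droplet(front, nbr, t, boundary)
        elif kind == "resume":
            fid, nbr, boundary = data
            front = fronts[fid]
            if not front.alive:
                continue
            start_in_droplet(front, nbr, t, boundary)
        elif kind == "meet":
            f1, f2, x_meet = data
            a, b = fronts[f1], fronts[f2]
            if not (a.alive and b.alive):
                continue
            if a.mode != "moving" or b.mode != "moving" or a.droplet != b.droplet:
                continue
            if abs(a.position(t) - x_meet) > 1e-6 or abs(b.position(t) - x_meet) > 1e-6:
                continue
            annihilations.append((t, x_meet))
            kill(a, t, x_meet, "annihilation")
            kill(b, t, x_meet, "annihilation")

    for front in fronts:
        if front.alive:
            front.close_segment(duration_s, front.position(duration_s))
            front.termination = "recording_end"

    # propagated waves register a pulse where the front passes a droplet centre
    for front in fronts:
        for idx, t_pass in front.pending_passes:
            did = ids[idx]
            if front.source != did and t_pass <= duration_s:
                wave_times[did].append(t_pass)
                wave_freqs[did].append(front.freq)
                wave_amps[did].append(front.amp)
    for did in ids:
        order = np.argsort(wave_times[did], kind="stable")
        wave_times[did] = [wave_times[did][k] for k in order]
        wave_freqs[did] = [wave_freqs[did][k] for k in order]
        wave_amps[did] = [wave_amps[did][k] for k in order]

    records = [
        FrontRecord(
            front_id=f.fid,
            segments=f.segments,
            droplets_visited=[ids[k] for k in f.visited],
            termination=f.termination,
            frequency=f.freq,
            amplitude=f.amp,
            source_droplet=f.source,
        )
        for f in fronts
    ]
    return GroundTruth(
        wave_times=wave_times,
        wave_freqs=wave_freqs,
        wave_amps=wave_amps,
        stage_bounds=stage_bounds,
        crossings=crossings,
        blocks=blocks,
        annihilations=annihilations,
        fronts=records,
        spiral_start=spiral_start,
        duration_s=duration_s,
    )


# ---------------------------------------------------------------------------
# traces


@dataclass
class TraceSet:
    """Per-droplet synthetic traces plus the ground truth that produced them."""

    time_s: np.ndarray
    traces: dict[str, np.ndarray]
    ground_truth: GroundTruth
    sample_rate_hz: float
    baseline_level: float

    def trace(self, droplet_id: str) -> IntensityTrace:
        return IntensityTrace(
            time_s=self.time_s,
            raw=self.traces[droplet_id],
            droplet_id=droplet_id,
        )


def _pulse_profile(
    t: np.ndarray, waves: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    """Superpose asymmetric wave pulses: linear rise over 10% of the period,
    linear decay over 40%.  Overlapping pulses combine by maximum (the
    indicator colour saturates; intensities do not stack)."""
    out = np.zeros_like(t)
    if not len(waves):
        return out
    dt = t[1] - t[0] if t.size > 1 else 1.0
    for t_k, f_k, a_k in waves:
        rise = 0.1 / f_k
        decay = 0.4 / f_k
        lo = np.searchsorted(t, t_k - rise)
        hi = np.searchsorted(t, t_k + decay, side="right")
        if hi <= lo:
            continue
        seg = t[lo:hi]
        pulse = np.interp(seg, [t_k - rise, t_k, t_k + decay], [0.0, a_k, 0.0])
        out[lo:hi] = np.maximum(out[lo:hi], pulse)
    return out


def simulate_traces(
    rois: Sequence[DropletROI],
    schedules: Mapping[str, LifecycleSchedule],
    *,
    coupling: CouplingSpec | Mapping[str, CouplingSpec] | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    sample_rate_hz: float = 2.0,
    duration_s: float | None = None,
    front_speed_px_per_s: float = 6.0,
    baseline_level: float = 60.0,
    ground_truth: GroundTruth | None = None,
) -> TraceSet:
    """Per-droplet intensity traces with full ground truth.

    Each trace is ``baseline + slow drift + one pulse per wave + noise``; wave
    times come from the front simulation, so coupled droplets pulse after the
    configured crossing delays.  Zero droplets give an empty trace set.
    Deterministic for a given seed.
    """
    noise = noise if noise is not None else NoiseConfig()
    if ground_truth is None:
        ground_truth = simulate_fronts(
            rois,
            schedules,
            coupling=coupling,
            seed=seed,
            duration_s=duration_s,
            front_speed_px_per_s=front_speed_px_per_s,
        )
    duration = ground_truth.duration_s
    t = np.arange(0.0, duration, 1.0 / sample_rate_hz)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    traces: dict[str, np.ndarray] = {}
    for roi in sorted(rois, key=lambda r: r.span):
        did = roi.droplet_id
        waves = list(
            zip(
                ground_truth.wave_times[did],
                ground_truth.wave_freqs[did],
                ground_truth.wave_amps[did],
            )
        )
        amp_scale = max([a for (_, _, a) in waves], default=80.0)
        y = np.full_like(t, baseline_level)
        if noise.drift_amp_frac > 0:
            y = y + noise.drift_amp_frac * amp_scale * np.sin(
                2 * np.pi * t / noise.drift_period_s
            )
        y = y + _pulse_profile(t, waves)
        sched = schedules.get(did)
        if sched is not None and sched.final_state == "oxidised" and waves:
            t_last = waves[-1][0]
            y[t >= t_last + 0.4 / waves[-1][1]] += 0.5 * amp_scale
        if noise.sigma_frac > 0:
            y = y + rng.normal(0.0, noise.sigma_frac * amp_scale, size=t.shape)
        traces[did] = y
    return TraceSet(
        time_s=t,
        traces=traces,
        ground_truth=ground_truth,
        sample_rate_hz=sample_rate_hz,
        baseline_level=baseline_level,
    )


# ---------------------------------------------------------------------------
# rendering


def _excitation_matrix(
    gt: GroundTruth,
    length_px: int,
    times: np.ndarray,
    *,
    amplitude: float,
    band_halfwidth_px: float,
) -> np.ndarray:
    """Rasterise front trajectories into an (length_px, n_frames) excitation map."""
    exc = np.zeros((length_px, times.size))
    y = np.arange(length_px)[:, None]
    for front in gt.fronts:
        scale = amplitude * (front.amplitude / 80.0)
        for t0, x0, t1, x1 in front.segments:
            lo = np.searchsorted(times, t0 - 1e-9)
            hi = np.searchsorted(times, t1 + 1e-9, side="right")
            if hi <= lo:
                continue
            seg_t = times[lo:hi]
            if t1 > t0:
                x = x0 + (x1 - x0) * (seg_t - t0) / (t1 - t0)
            else:
                x = np.full_like(seg_t, x1)
            profile = np.clip(1.0 - np.abs(y - x[None, :]) / band_halfwidth_px, 0, None)
            exc[:, lo:hi] = np.maximum(exc[:, lo:hi], scale * profile)
    return exc


def render_kymograph(
    gt: GroundTruth,
    slot: SlotLayout,
    *,
    frame_rate: float = 0.4,
    rest_level: float = 60.0,
    amplitude: float = 120.0,
    band_halfwidth_px: float = 7.0,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    t0_offset: float = 0.0,
) -> Kymograph:
    """Render front trajectories directly into a collapsed slot kymograph.

    The result is what :func:`bzkymo.kymograph.build_kymograph` would produce
    (collapsed mode) from a rendered frame stack, without materialising the
    frames -- convenient for long arrays.
    """
    noise = noise if noise is not None else NoiseConfig.none()
    n_cols = max(1, int(round(gt.duration_s * frame_rate)))
    times = t0_offset + np.arange(n_cols) / frame_rate
    image = np.full((slot.length_px, n_cols), rest_level)
    if noise.drift_amp_frac > 0:
        image = image + noise.drift_amp_frac * amplitude * np.sin(
            2 * np.pi * times / noise.drift_period_s
        )
    image = image + _excitation_matrix(
        gt, slot.length_px, times - t0_offset,
        amplitude=amplitude, band_halfwidth_px=band_halfwidth_px,
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    if noise.n_artifacts > 0:
        for _ in range(noise.n_artifacts):
            pos = int(rng.integers(0, slot.length_px))
            image[max(0, pos - 1) : pos + 2, :] += 0.6 * amplitude
    if noise.sigma_frac > 0:
        image = image + rng.normal(0.0, noise.sigma_frac * amplitude, size=image.shape)
    return Kymograph(
        image=image,
        strip_width=1,
        channel="blue",
        slot_id=slot.slot_id,
        frame_rate=frame_rate,
        t0_offset=t0_offset,
    )


def render_frames(
    gts: Mapping[str, GroundTruth] | GroundTruth,
    slots: Sequence[SlotLayout] | SlotLayout,
    *,
    frame_rate: float = 0.4,
    rest_blue: float = 60.0,
    rest_red: float = 175.0,
    amplitude: float = 120.0,
    band_halfwidth_px: float = 7.0,
    background: int = 25,
    margin_px: int = 10,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    t0_offset: float = 0.0,
) -> FrameStack:
    """Render RGB video frames of one or more slots.

    Droplets rest red-dominant (reduced ferroin); a passing oxidation front
    raises the blue channel and lowers the red one within its band.  The oil
    background is darker.  Frame geometry follows the slot origins; with the
    default layout a droplet is 108 px wide, the study's pixel calibration.
    """
    if isinstance(slots, SlotLayout):
        slots = [slots]
    if isinstance(gts, GroundTruth):
        gts = {slots[0].slot_id: gts}
    noise = noise if noise is not None else NoiseConfig.none()

    duration = max(gt.duration_s for gt in gts.values())
    n_frames = max(1, int(round(duration * frame_rate)))
    times = np.arange(n_frames) / frame_rate

    width = height = 0
    for slot in slots:
        x0, y0 = slot.origin_xy
        if slot.axis == (0, 1):
            width = max(width, x0 + slot.width_px)
            height = max(height, y0 + slot.length_px)
        else:
            width = max(width, x0 + slot.length_px)
            height = max(height, y0 + slot.width_px)
    width += margin_px
    height += margin_px

    frames = np.full((n_frames, height, width, 3), background, dtype=float)
    for slot in slots:
        gt = gts.get(slot.slot_id)
        if gt is None:
            continue
        exc = _excitation_matrix(
            gt, slot.length_px, times,
            amplitude=amplitude, band_halfwidth_px=band_halfwidth_px,
        )  # (L, n)
        x0, y0 = slot.origin_xy
        red = np.clip(rest_red - 0.6 * exc, 0, 255)
        green = np.full_like(exc, 45.0)
        blue = np.clip(rest_blue + exc, 0, 255)
        if slot.axis == (0, 1):
            sl = (slice(y0, y0 + slot.length_px), slice(x0, x0 + slot.width_px))
            for c, chan in enumerate((red, green, blue)):
                frames[:, sl[0], sl[1], c] = chan.T[:, :, None]
        else:
            sl = (slice(y0, y0 + slot.width_px), slice(x0, x0 + slot.length_px))
            for c, chan in enumerate((red, green, blue)):
                frames[:, sl[0], sl[1], c] = chan.T[:, None, :]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    if noise.sigma_frac > 0:
        frames += rng.normal(0.0, noise.sigma_frac * amplitude, size=frames.shape)
    frames = np.clip(frames, 0, 255).astype(np.uint8)
    return FrameStack(frames, frame_rate=frame_rate, t0_offset=t0_offset)


# ---------------------------------------------------------------------------
# packaged fixture


def lifecycle_fixture(
    *, noise: bool = False, sample_rate_hz: float = 0.4
) -> tuple[IntensityTrace, GroundTruth]:
    """Deterministic single-droplet trace emulating a typical MA BZ recording.

    The recording starts on clear oil (high intensity); the droplet is
    pipetted into the slot at 4.5 min and oscillates immediately (initial
    stage), the main stage runs from 7.5 min to 60 min, a late stage of about
    10 min follows, and the droplet is exhausted from 70 min.  Scheduled stage
    boundaries are returned as ground truth for segmentation tests.  Identical
    output across runs, with or without the (internally seeded) noise.
    """
    appear_s = 270.0  # 4.5 min
    schedule = LifecycleSchedule(
        induction_s=0.0,
        initial=StageSpec(180.0, 0.1, None, 24.0),
        main=StageSpec(3150.0, 0.04, 0.036, 80.0),
        late=StageSpec(600.0, 0.08, None, 70.0),
        spiral_start_probability=0.0,
    )
    waves, bounds = schedule_wave_times(schedule)
    waves = [(t + appear_s, f, a) for (t, f, a, _s) in waves]
    tail_s = 300.0
    duration = appear_s + schedule.total_s + tail_s
    t = np.arange(0.0, duration, 1.0 / sample_rate_hz)

    baseline = 60.0
    oil_level = 200.0
    y = np.full_like(t, baseline)
    y += 3.0 * np.sin(2 * np.pi * t / 1800.0)  # gentle photometric drift
    y += _pulse_profile(t, waves)
    y[t < appear_s] = oil_level
    if noise:
        rng = np.random.default_rng(123)
        y = y + rng.normal(0.0, 1.6, size=t.shape)

    stage_bounds = {"induction": (0.0, appear_s)}
    for name, (a, b) in bounds.items():
        if name == "induction":
            continue
        hi = duration if not math.isfinite(b) else b + appear_s
        stage_bounds[name] = (a + appear_s, hi)

    gt = GroundTruth(
        wave_times={"d0": [w[0] for w in waves]},
        wave_freqs={"d0": [w[1] for w in waves]},
        wave_amps={"d0": [w[2] for w in waves]},
        stage_bounds={"d0": stage_bounds},
        crossings=[],
        blocks=[],
        annihilations=[],
        fronts=[],
        spiral_start={"d0": False},
        duration_s=duration,
    )
    trace = IntensityTrace(time_s=t, raw=y, droplet_id="d0")
    return trace, gt
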