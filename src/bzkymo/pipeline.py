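"""End-to-end runs: generate synthetic datasets, analyse recordings.

`run_generate` writes a synthetic dataset (layout, ground truth, and frames /
kymographs / traces depending on the render mode); `run_pipeline` takes a
dataset or a directory of recorded frames plus a layout file and produces,
per droplet, the trace, peak train, lifecycle segmentation and wave-feature
summary, plus per-slot kymographs and (for multi-droplet slots) a
propagation report.  Every run writes a manifest with the full configuration
and seed, sufficient to reproduce it; outputs are deterministic for a given
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .frames import read_frames, write_frames
from .geometry import (
    DropletROI,
    SlotLayout,
    load_layout,
    make_linear_layout,
    save_layout,
)
from .kymograph import Kymograph, build_kymograph, extract_trace_values
from .oscillation import AnalysisConfig, IntensityTrace, analyze_trace
from .propagation import binarize_fronts, classify_interfaces, track_wavefronts
from .synth import (
    CouplingSpec,
    GroundTruth,
    LifecycleSchedule,
    NoiseConfig,
    StageSpec,
    render_frames,
    render_kymograph,
    simulate_fronts,
    simulate_traces,
)

__all__ = ["GenerateConfig", "RunConfig", "PipelineError", "run_generate", "run_pipeline"]


class PipelineError(RuntimeError):
    """A processing failure, annotated with slot/droplet identity and stage."""


def _package_version() -> str:
    try:
        return _pkg_version("bzkymo")
    except PackageNotFoundError:
        return "unknown"


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class GenerateConfig:
    """Configuration of a synthetic dataset.

    ``render`` selects the heaviest artifact written: ``"frames"`` (RGB frame
    stack, from which the analysis pipeline starts), ``"kymograph"`` (per-slot
    space-time arrays) or ``"traces"`` (per-droplet CSV traces only).
    ``source_only`` makes only the first droplet of each slot self-oscillate
    (the others are excitable but quiescent), the configuration used for
    controlled propagation experiments.
    """

    n_slots: int = 1
    n_droplets: int = 3
    span_px: int = 108
    width_px: int = 108
    width_mm: float = 2.5
    render: str = "traces"  # frames | kymograph | traces
    schedule: LifecycleSchedule = field(default_factory=LifecycleSchedule)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    source_only: bool = False
    seed: int = 0
    frame_rate: float = 0.4
    sample_rate_hz: float = 2.0
    duration_s: float | None = None
    front_speed_px_per_s: float = 6.0

    def __post_init__(self) -> None:
        if self.render not in ("frames", "kymograph", "traces"):
            raise ValueError(f"unknown render mode {self.render!r}")
        if self.n_slots < 1 or self.n_droplets < 0:
            raise ValueError("n_slots must be >= 1 and n_droplets >= 0")

    def as_dict(self) -> dict:
        return _to_jsonable(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerateConfig":
        d = dict(d)
        for key, typ in (("coupling", CouplingSpec), ("noise", NoiseConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "schedule" in d and isinstance(d["schedule"], dict):
            s = dict(d["schedule"])
            for st in ("initial", "main", "late"):
                if st in s and isinstance(s[st], dict):
                    s[st] = StageSpec(**s[st])
            d["schedule"] = LifecycleSchedule(**s)
        return cls(**d)


@dataclass
class RunConfig:
    """Configuration of an analysis run over a recording or dataset.

    ``input_dir`` is either a directory of numbered PNG/BMP frames, or a
    dataset directory produced by :func:`run_generate` (containing
    ``frames/``, ``kymographs/`` or ``traces/``).  All analysis thresholds
    live in ``analysis``; every field has a documented default and the config
    round-trips losslessly through JSON.
    """

    input_dir: str = ""
    layout_path: str = ""
    frame_rate: float = 0.4
    t0_offset: float = 0.0
    channel: str = "blue"
    strip_width: int = 15
    trace_height: int = 5
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    propagation_threshold_frac: float = 0.5
    propagation_delay_window_s: float = 25.0
    seed: int = 0
    plots: bool = True

    def as_dict(self) -> dict:
        d = _to_jsonable(self)
        d["analysis"] = self.analysis.as_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisConfig.from_dict(d["analysis"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1) + "\n")


def _write_manifest(outdir: Path, kind: str, config_dict: dict, seed: int) -> None:
    manifest = {
        "kind": kind,
        "package": "bzkymo",
        "version": _package_version(),
        "seed": seed,
        "config": config_dict,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def run_generate(config: GenerateConfig, outdir: str | Path) -> dict:
    """Write a synthetic dataset to ``outdir``; returns a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    slots: list[SlotLayout] = []
    rois: list[DropletROI] = []
    gts: dict[str, GroundTruth] = {}
    slot_rois: dict[str, list[DropletROI]] = {}
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(max(config.n_slots, 1))

    for s in range(config.n_slots):
        x_off = 20 + s * (config.width_px + 20)
        slot, sr = make_linear_layout(
            config.n_droplets,
            slot_id=f"slot{s}",
            span_px=config.span_px,
            width_px=config.width_px,
            width_mm=config.width_mm,
            origin_xy=(x_off, 20),
            droplet_prefix=f"s{s}d",
        )
        slots.append(slot)
        rois.extend(sr)
        slot_rois[slot.slot_id] = sr
        schedules = {}
        for i, roi in enumerate(sr):
            if config.source_only and i > 0:
                schedules[roi.droplet_id] = LifecycleSchedule.quiescent()
            else:
                schedules[roi.droplet_id] = config.schedule
        gts[slot.slot_id] = simulate_fronts(
            sr,
            schedules,
            coupling=config.coupling,
            seed=int(rng_seeds[s] % (2**31)),
            duration_s=config.duration_s,
            front_speed_px_per_s=config.front_speed_px_per_s,
        )

    save_layout(slots, rois, outdir / "layout.json")
    (outdir / "ground_truth.json").write_text(
        json.dumps({sid: gt.as_dict() for sid, gt in gts.items()}, indent=1) + "\n"
    )

    if config.render == "frames":
        stack = render_frames(
            gts, slots, frame_rate=config.frame_rate,
            noise=config.noise, seed=config.seed,
        )
        write_frames(stack, outdir / "frames")
    elif config.render == "kymograph":
        kdir = outdir / "kymographs"
        kdir.mkdir(exist_ok=True)
        for slot in slots:
            kymo = render_kymograph(
                gts[slot.slot_id], slot, frame_rate=config.frame_rate,
                noise=config.noise, seed=config.seed,
            )
            np.savez(
                kdir / f"{slot.slot_id}.npz",
                image=kymo.image,
                frame_rate=kymo.frame_rate,
                strip_width=kymo.strip_width,
                t0_offset=kymo.t0_offset,
            )
            iio.imwrite(kdir / f"{slot.slot_id}.png", kymo.to_png_array())
    elif config.render == "traces":
        tdir = outdir / "traces"
        tdir.mkdir(exist_ok=True)
        for slot in slots:
            sr = slot_rois[slot.slot_id]
            schedules = {
                roi.droplet_id: (
                    LifecycleSchedule.quiescent()
                    if config.source_only and i > 0
                    else config.schedule
                )
                for i, roi in enumerate(sr)
            }
            ts = simulate_traces(
                sr, schedules, noise=config.noise, seed=config.seed,
                sample_rate_hz=config.sample_rate_hz,
                ground_truth=gts[slot.slot_id],
            )
            for did in ts.traces:
                ts.trace(did).to_csv(tdir / f"{did}.csv")
    else:
        raise ValueError(f"unknown render mode {config.render!r}")

    _write_manifest(outdir, "generate", config.as_dict(), config.seed)
    return {
        "slots": [s.slot_id for s in slots],
        "droplets": [r.droplet_id for r in rois],
        "render": config.render,
    }


def _load_npz_kymograph(path: Path, slot_id: str) -> Kymograph:
    with np.load(path) as z:
        return Kymograph(
            image=z["image"],
            strip_width=int(z["strip_width"]),
            channel="blue",
            slot_id=slot_id,
            frame_rate=float(z["frame_rate"]),
            t0_offset=float(z["t0_offset"]),
        )


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Analyse a recording end to end; returns the per-droplet feature rows.

    Stages: read frames (or reuse rendered kymographs / traces), build one
    kymograph per slot, extract one trace per droplet, run the oscillation
    chain, and classify propagation on multi-droplet slots.  Stage failures
    are re-raised as :class:`PipelineError` naming the slot/droplet and stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_dir = Path(config.input_dir)

    layout_path = Path(config.layout_path) if config.layout_path else input_dir / "layout.json"
    slots, rois = load_layout(layout_path)
    rois_by_slot: dict[str, list[DropletROI]] = {}
    for roi in rois:
        rois_by_slot.setdefault(roi.slot_id, []).append(roi)

    kymos: dict[str, Kymograph] = {}
    traces: dict[str, IntensityTrace] = {}

    frames_dir = input_dir / "frames" if (input_dir / "frames").is_dir() else (
        input_dir if any(input_dir.glob("*.png")) or any(input_dir.glob("*.bmp")) else None
    )
    kymo_dir = input_dir / "kymographs"
    trace_dir = input_dir / "traces"

    if frames_dir is not None:
        try:
            stack = read_frames(frames_dir, config.frame_rate, config.t0_offset)
        except ValueError as exc:
            raise PipelineError(f"stage read_frames: {exc}") from exc
        for slot in slots:
            try:
                kymos[slot.slot_id] = build_kymograph(
                    stack, slot, strip_width=config.strip_width, channel=config.channel
                )
            except ValueError as exc:
                raise PipelineError(
                    f"stage build_kymograph, slot {slot.slot_id}: {exc}"
                ) from exc
    elif kymo_dir.is_dir():
        for slot in slots:
            path = kymo_dir / f"{slot.slot_id}.npz"
            if not path.exists():
                raise PipelineError(
                    f"stage load_kymograph, slot {slot.slot_id}: {path} missing"
                )
            kymos[slot.slot_id] = _load_npz_kymograph(path, slot.slot_id)
    elif trace_dir.is_dir():
        for roi in rois:
            path = trace_dir / f"{roi.droplet_id}.csv"
            if not path.exists():
                raise PipelineError(
                    f"stage load_trace, droplet {roi.droplet_id}: {path} missing"
                )
            traces[roi.droplet_id] = IntensityTrace.from_csv(path, roi.droplet_id)
    else:
        raise PipelineError(f"no frames, kymographs or traces found under {input_dir}")

    kdir = outdir / "kymographs"
    if kymos:
        kdir.mkdir(exist_ok=True)
        for sid, kymo in kymos.items():
            np.savez(
                kdir / f"{sid}.npz", image=kymo.image, frame_rate=kymo.frame_rate,
                strip_width=kymo.strip_width, t0_offset=kymo.t0_offset,
            )
            iio.imwrite(kdir / f"{sid}.png", kymo.to_png_array())
        for slot in slots:
            for roi in rois_by_slot.get(slot.slot_id, []):
                try:
                    values = extract_trace_values(
                        kymos[slot.slot_id], roi, height=config.trace_height
                    )
                except ValueError as exc:
                    raise PipelineError(
                        f"stage extract_trace, slot {slot.slot_id}, "
                        f"droplet {roi.droplet_id}: {exc}"
                    ) from exc
                kymo = kymos[slot.slot_id]
                traces[roi.droplet_id] = IntensityTrace(
                    time_s=kymo.timestamps, raw=values, droplet_id=roi.droplet_id
                )

    tdir = outdir / "traces"
    pdir = outdir / "peaks"
    tdir.mkdir(exist_ok=True)
    pdir.mkdir(exist_ok=True)
    feature_rows = []
    segment_rows = []
    for roi in rois:
        trace = traces.get(roi.droplet_id)
        if trace is None:
            continue
        try:
            result = analyze_trace(trace, config.analysis)
        except ValueError as exc:
            raise PipelineError(
                f"stage analyze_trace, droplet {roi.droplet_id}: {exc}"
            ) from exc
        result.trace.to_csv(tdir / f"{roi.droplet_id}.csv")
        result.peaks.to_csv(pdir / f"{roi.droplet_id}.csv")
        feature_rows.append(result.features.as_dict())
        for iv in result.segmentation.intervals:
            segment_rows.append(
                {
                    "droplet_id": roi.droplet_id,
                    "stage": iv.label,
                    "start_s": iv.start_s,
                    "end_s": iv.end_s,
                }
            )
        if config.plots:
            from .plotting import plot_trace_analysis

            plot_trace_analysis(result, outdir / f"trace_{roi.droplet_id}.png")

    pd.DataFrame(feature_rows).to_csv(
        outdir / "features.csv", index=False, float_format="%.6g"
    )
    pd.DataFrame(segment_rows).to_csv(
        outdir / "segments.csv", index=False, float_format="%.6g"
    )

    crossing_rows = []
    for slot in slots:
        sr = rois_by_slot.get(slot.slot_id, [])
        if len(sr) < 2 or slot.slot_id not in kymos:
            continue
        kymo = kymos[slot.slot_id]
        try:
            mask = binarize_fronts(kymo, threshold_frac=config.propagation_threshold_frac)
            tracks = track_wavefronts(mask, kymo.timestamps, sr)
            report = classify_interfaces(
                tracks, sr, delay_window_s=config.propagation_delay_window_s
            )
        except ValueError as exc:
            raise PipelineError(
                f"stage propagation, slot {slot.slot_id}: {exc}"
            ) from exc
        report.to_json(outdir / f"propagation_{slot.slot_id}.json")
        for st in report.interfaces:
            crossing_rows.append(
                {
                    "slot_id": slot.slot_id,
                    "interface": st.interface,
                    "propagated": st.propagated,
                    "blocked": st.blocked,
                }
            )
    if crossing_rows:
        pd.DataFrame(crossing_rows).to_csv(
            outdir / "crossings.csv", index=False, float_format="%.6g"
        )

    _write_manifest(outdir, "pipeline", config.as_dict(), config.seed)
    return {"features": feature_rows, "n_droplets": len(feature_rows)}
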