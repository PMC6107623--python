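"""Oscillation-trace analysis: filtering, baseline, peaks, lifecycle, features.

A droplet's blue-channel intensity trace oscillates once per oxidation wave.
The processing chain mirrors the study workflow:

1. low-pass filter the raw trace (zero-phase box smoothing);
2. subtract a baseline formed by the running minimum over a one-period-wide
   window, so slow drift is absorbed and the corrected trace is >= 0;
3. detect peaks (one per wavefront) and the troughs between them;
4. per-oscillation frequency = 1 / peak-to-peak interval, assigned to the
   later peak;
5. segment the lifecycle into induction / initial / main / late / exhausted
   stages from the frequency series;
6. summarise the five wave features: lifetime, median frequency, wave count,
   median amplitude, and median trough-to-trough wave area.

Timestamps are seconds from completion of mixing, so the lifetime is simply
the start time of the exhausted stage.  Medians use the lower-of-two
convention for even counts, making every summary value an observed one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "IntensityTrace",
    "PeakTrain",
    "PeriodInterval",
    "PeriodSegmentation",
    "WaveFeatureSummary",
    "AnalysisConfig",
    "SegmentationConfig",
    "AnalysisResult",
    "lowpass",
    "estimate_period",
    "subtract_baseline",
    "detect_peaks",
    "instantaneous_frequency",
    "segment_periods",
    "peak_area",
    "summarize_features",
    "analyze_trace",
    "low_median",
    "load_curation",
]

STAGES = ("induction", "initial", "main", "late", "exhausted")


def low_median(values: Sequence[float] | np.ndarray) -> float:
    """Median with the lower-of-two convention for even counts.

    Deterministic and always equal to an observed value; ``nan`` for empty
    input.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        return math.nan
    return float(arr[(arr.size - 1) // 2])


# ---------------------------------------------------------------------------
# containers


@dataclass
class IntensityTrace:
    """One droplet's intensity trace and its processed companions."""

    time_s: np.ndarray
    raw: np.ndarray
    filtered: np.ndarray | None = None
    baseline: np.ndarray | None = None
    corrected: np.ndarray | None = None
    droplet_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.time_s.shape != self.raw.shape:
            raise ValueError("time_s and raw must have equal length")
        for name in ("filtered", "baseline", "corrected"):
            val = getattr(self, name)
            if val is not None and np.asarray(val).shape != self.raw.shape:
                raise ValueError(f"{name} must match raw length")

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def dt(self) -> float:
        if len(self.time_s) < 2:
            return math.nan
        return float(self.time_s[1] - self.time_s[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {"frame": np.arange(len(self)), "time_s": self.time_s,
                "intensity": self.raw}
        for name, col in (("filtered", self.filtered), ("baseline", self.baseline),
                          ("corrected", self.corrected)):
            if col is not None:
                cols[name] = col
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path, droplet_id: str = "") -> "IntensityTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            raw=df["intensity"].to_numpy(),
            filtered=df["filtered"].to_numpy() if "filtered" in df else None,
            baseline=df["baseline"].to_numpy() if "baseline" in df else None,
            corrected=df["corrected"].to_numpy() if "corrected" in df else None,
            droplet_id=droplet_id,
        )


@dataclass
class PeakTrain:
    """Detected peaks (wavefronts) and the troughs between them."""

    peak_indices: np.ndarray
    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_indices: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_indices", "trough_indices"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("peak_times", "peak_values", "trough_times", "trough_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if len(self.trough_times) != max(len(self.peak_times) - 1, 0):
            raise ValueError("expected one trough between each pair of peaks")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": np.concatenate([self.peak_times, self.trough_times]),
                "value": np.concatenate([self.peak_values, self.trough_values]),
                "kind": ["peak"] * self.n_peaks + ["trough"] * len(self.trough_times),
            }
        ).sort_values("time_s", kind="stable", ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


@dataclass(frozen=True)
class PeriodInterval:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PeriodSegmentation:
    """Contiguous lifecycle intervals in canonical stage order."""

    intervals: list[PeriodInterval]

    def __post_init__(self) -> None:
        order = [STAGES.index(iv.label) for iv in self.intervals]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError("intervals must appear once each, in stage order")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if not math.isclose(a.end_s, b.start_s, abs_tol=1e-9):
                raise ValueError("intervals must be contiguous")

    def interval(self, label: str) -> PeriodInterval | None:
        for iv in self.intervals:
            if iv.label == label:
                return iv
        return None

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    @property
    def exhausted_start_s(self) -> float | None:
        iv = self.interval("exhausted")
        return iv.start_s if iv is not None else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.labels,
                "start_s": [iv.start_s for iv in self.intervals],
                "end_s": [iv.end_s for iv in self.intervals],
            }
        )


@dataclass
class WaveFeatureSummary:
    """The five per-droplet wave features.

    ``lifetime_s`` runs from completion of mixing to the start of the
    exhausted state; ``median_frequency_per_s`` is the median of all
    per-oscillation frequencies over the lifetime; ``wave_count`` is the peak
    count over the lifetime; ``median_amplitude`` is the median
    baseline-corrected peak height; ``median_area`` (arbitrary units) is the
    median trough-to-trough integral of a wave on the corrected trace.
    Medians that are undefined (no oscillations) are ``None``.
    """

    lifetime_s: float
    median_frequency_per_s: float | None
    wave_count: int
    median_amplitude: float | None
    median_area: float | None
    droplet_id: str = ""

    def as_dict(self) -> dict:
        return {
            "droplet_id": self.droplet_id,
            "lifetime_s": self.lifetime_s,
            "median_frequency_per_s": self.median_frequency_per_s,
            "wave_count": self.wave_count,
            "median_amplitude": self.median_amplitude,
            "median_area": self.median_area,
        }


# ---------------------------------------------------------------------------
# processing steps


def lowpass(values: np.ndarray, window: int) -> np.ndarray:
    """Zero-phase box smoothing with an odd ``window`` of samples.

    ``window`` is forced odd (rounded up) so the kernel is symmetric and the
    filter is zero-phase; edges are handled by edge replication, so a constant
    trace passes through unchanged.  ``window <= 1`` is the identity.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("lowpass needs at least 3 samples")
    if window <= 1:
        return x.copy()
    if window % 2 == 0:
        window += 1
    if window > x.size:
        raise ValueError(
            f"smoothing window ({window}) longer than trace ({x.size} samples)"
        )
    return uniform_filter1d(x, size=window, mode="nearest")


def estimate_period(
    values: np.ndarray,
    dt: float,
    *,
    min_lag_s: float | None = None,
    min_prominence: float = 0.05,
) -> float | None:
    """Dominant oscillation period from the autocorrelation function.

    Returns the lag of the first prominent autocorrelation maximum, or
    ``None`` ("no-period") for traces without oscillatory structure; callers
    fall back to a configured default period.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        return None
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :] / denom
    min_lag = 2 if min_lag_s is None else max(2, int(round(min_lag_s / dt)))
    if ac.size <= min_lag + 1:
        return None
    peaks, props = find_peaks(ac[min_lag:], prominence=min_prominence)
    peaks = peaks[ac[min_lag:][peaks] > 0.05]
    if peaks.size == 0:
        return None
    return float((peaks[0] + min_lag) * dt)


def subtract_baseline(
    filtered: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Running-minimum baseline over a centred window, and the corrected trace.

    ``baseline[t]`` is the minimum of the filtered trace over a window of
    ``window`` samples centred at ``t`` (truncated at the edges), nominally
    one oscillation period wide.  ``corrected = filtered - baseline`` is
    non-negative everywhere because the window always contains ``t`` itself.
    """
    x = np.asarray(filtered, dtype=float)
    if window < 3:
        raise ValueError("baseline window must be >= 3 samples")
    if window > x.size:
        raise ValueError(
            f"baseline window ({window}) longer than trace ({x.size} samples)"
        )
    baseline = minimum_filter1d(x, size=window, mode="nearest")
    return baseline, x - baseline


def load_curation(path: str | Path) -> list[dict]:
    """Read a manual peak-curation sidecar.

    The sidecar is a JSON list of edits, applied after automatic detection:
    ``{"action": "add", "time_s": t}`` inserts a peak at the nearest sample;
    ``{"action": "remove", "time_s": t, "tolerance_s": tol}`` removes the
    detected peak nearest ``t`` within ``tol`` seconds.
    """
    edits = json.loads(Path(path).read_text())
    if not isinstance(edits, list):
        raise ValueError("curation sidecar must be a JSON list of edits")
    for e in edits:
        if e.get("action") not in ("add", "remove") or "time_s" not in e:
            raise ValueError(f"malformed curation edit: {e!r}")
    return edits


def _troughs_between(values: np.ndarray, peak_idx: np.ndarray) -> np.ndarray:
    troughs = []
    for a, b in zip(peak_idx, peak_idx[1:]):
        seg = values[a : b + 1]
        troughs.append(a + int(np.argmin(seg)))
    return np.asarray(troughs, dtype=int)


def detect_peaks(
    corrected: np.ndarray,
    time_s: np.ndarray,
    *,
    prominence: float | None = None,
    prominence_frac: float = 0.2,
    period_hint_s: float | None = None,
    distance_frac: float = 0.5,
    min_distance_s: float | None = None,
    curation: Sequence[dict] | None = None,
    refine_times: bool = True,
) -> PeakTrain:
    """Detect oscillation peaks and interleaved troughs on a corrected trace.

    Peaks are local maxima with prominence at least ``prominence`` (by default
    ``prominence_frac`` of the 90th-percentile corrected amplitude).  A
    minimum peak separation of ``distance_frac * period_hint_s`` (or
    ``min_distance_s``) is enforced when a period hint is supplied; without
    one, prominence alone discriminates, which keeps the fast low-amplitude
    waves of the initial stage.  Troughs are the minima between consecutive
    surviving peaks.  Curation edits are applied last; an empty train is a
    valid result.
    """
    x = np.asarray(corrected, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if x.shape != t.shape:
        raise ValueError("corrected and time_s must share a length")
    if prominence is None:
        scale = float(np.percentile(x, 90)) if x.size else 0.0
        prominence = prominence_frac * scale
    prominence = max(prominence, 1e-12)

    distance = None
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    if min_distance_s is not None:
        distance = max(1, int(round(min_distance_s / dt)))
    elif period_hint_s is not None:
        distance = max(1, int(round(distance_frac * period_hint_s / dt)))

    peak_idx, _ = find_peaks(x, prominence=prominence, distance=distance)
    peak_idx = list(peak_idx)

    for edit in curation or ():
        if edit["action"] == "add":
            idx = int(np.argmin(np.abs(t - edit["time_s"])))
            if idx not in peak_idx:
                peak_idx.append(idx)
        else:
            tol = float(edit.get("tolerance_s", 2 * dt))
            if not peak_idx:
                continue
            times = t[np.asarray(peak_idx)]
            j = int(np.argmin(np.abs(times - edit["time_s"])))
            if abs(times[j] - edit["time_s"]) <= tol:
                peak_idx.pop(j)
    peak_idx = np.asarray(sorted(set(peak_idx)), dtype=int)

    peak_times = t[peak_idx].astype(float)
    if refine_times and peak_idx.size:
        # parabolic vertex through the apex sample and its neighbours gives
        # sub-sample peak times, removing the half-sample quantisation of
        # peak-to-peak intervals
        for k, i in enumerate(peak_idx):
            if 0 < i < x.size - 1:
                denom = x[i - 1] - 2 * x[i] + x[i + 1]
                if denom < 0:
                    shift = 0.5 * (x[i - 1] - x[i + 1]) / denom
                    peak_times[k] = t[i] + np.clip(shift, -0.5, 0.5) * dt
        if np.any(np.diff(peak_times) <= 0):  # degenerate; keep grid times
            peak_times = t[peak_idx].astype(float)

    trough_idx = _troughs_between(x, peak_idx)
    return PeakTrain(
        peak_indices=peak_idx,
        peak_times=peak_times,
        peak_values=x[peak_idx],
        trough_indices=trough_idx,
        trough_times=t[trough_idx],
        trough_values=x[trough_idx],
    )


def instantaneous_frequency(
    peak_times: np.ndarray | PeakTrain,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-oscillation frequency series.

    The frequency at a given time is the inverse of the peak-to-peak time
    difference, assigned to the later peak of each consecutive pair.  Fewer
    than two peaks give empty arrays.
    """
    if isinstance(peak_times, PeakTrain):
        peak_times = peak_times.peak_times
    pt = np.asarray(peak_times, dtype=float)
    if pt.size < 2:
        return np.empty(0), np.empty(0)
    dts = np.diff(pt)
    return pt[1:], 1.0 / dts


@dataclass
class SegmentationConfig:
    """Thresholds for lifecycle segmentation (all stage rules configurable).

    ``initial_drop_frac``: the main stage starts at the first oscillation whose
    frequency falls below this fraction of the running initial-stage median
    (the "rapid decrease in frequency").  ``late_rise_frac``: the late stage
    starts when a ``late_window``-oscillation rolling median frequency exceeds
    this fraction of the trailing main-stage median (the "sudden increase").
    ``exhausted_margin_periods``: the exhausted state starts this many final
    periods after the last peak (capped at the trace end).
    """

    initial_drop_frac: float = 0.6
    late_rise_frac: float = 1.5
    late_window: int = 3
    trailing_main_window: int = 10
    exhausted_margin_periods: float = 3.0


def segment_periods(
    peak_times: np.ndarray | PeakTrain,
    *,
    t_start: float,
    t_end: float,
    config: SegmentationConfig | None = None,
) -> PeriodSegmentation:
    """Segment a trace extent into lifecycle stages from its peak times.

    Induction runs from the trace start to the first peak; the initial stage
    ends at the frequency drop; the main stage ends at the sustained frequency
    up-step; the exhausted state begins a refractory margin after the final
    peak.  Stages that do not occur are absent; with no peaks at all the
    segmentation is induction followed by a (possibly empty) exhausted state.
    """
    cfg = config or SegmentationConfig()
    if isinstance(peak_times, PeakTrain):
        peak_times = peak_times.peak_times
    pt = np.asarray(peak_times, dtype=float)

    if pt.size == 0:
        return PeriodSegmentation(
            [
                PeriodInterval("induction", t_start, t_end),
                PeriodInterval("exhausted", t_end, t_end),
            ]
        )

    freqs = 1.0 / np.diff(pt)  # freqs[j] belongs to interval (pt[j], pt[j+1])
    m = freqs.size

    # initial -> main: first interval whose frequency is below the running
    # median of the intervals before it.
    main_j: int | None = None
    for j in range(1, m):
        med = low_median(freqs[:j])
        if freqs[j] < cfg.initial_drop_frac * med:
            main_j = j
            break

    # main -> late: rolling median over `late_window` intervals exceeds the
    # trailing main-stage median.
    late_j: int | None = None
    if main_j is not None:
        w = cfg.late_window
        for j in range(main_j + w, m):
            # the reference is the *recent* main frequency: the main stage may
            # itself decline slowly, so the sudden late up-step is judged
            # against the last few main oscillations, not the whole stage
            lo = max(main_j, j - w + 1 - cfg.trailing_main_window)
            trailing = freqs[lo : j - w + 1]
            if trailing.size < 1:
                continue
            threshold = cfg.late_rise_frac * low_median(trailing)
            rolling = low_median(freqs[j - w + 1 : j + 1])
            if rolling > threshold:
                # boundary at the start of the first interval in the window
                # that is individually fast (the window may begin with the
                # main->late transition interval, still at main frequency)
                late_j = j - w + 1
                for k in range(j - w + 1, j + 1):
                    if freqs[k] > threshold:
                        late_j = k
                        break
                break

    if m:
        last_period = 1.0 / freqs[-1]
        exhausted_start = min(
            t_end, pt[-1] + cfg.exhausted_margin_periods * last_period
        )
    else:  # a single peak: no period information, exhaust right after it
        exhausted_start = min(t_end, pt[-1])

    # ordered stage start times; a stage that never begins is simply absent
    starts: list[tuple[str, float]] = [("induction", t_start), ("initial", pt[0])]
    if main_j is not None:
        starts.append(("main", pt[main_j]))
        if late_j is not None:
            starts.append(("late", pt[late_j]))
    starts.append(("exhausted", exhausted_start))

    intervals: list[PeriodInterval] = []
    for (label, s), (_, e) in zip(starts, starts[1:]):
        s = min(max(s, t_start), t_end)
        e = min(max(e, s), t_end)
        intervals.append(PeriodInterval(label, s, e))
    intervals.append(PeriodInterval("exhausted", intervals[-1].end_s, t_end))
    return PeriodSegmentation(intervals)


def peak_area(
    corrected: np.ndarray,
    time_s: np.ndarray,
    left_trough_idx: int,
    right_trough_idx: int,
) -> float:
    """Trough-to-trough trapezoidal integral of one wave (arbitrary units)."""
    if not 0 <= left_trough_idx < right_trough_idx < len(corrected):
        raise ValueError("flanking trough indices out of order or range")
    sl = slice(left_trough_idx, right_trough_idx + 1)
    return float(np.trapezoid(corrected[sl], np.asarray(time_s)[sl]))


def summarize_features(
    trace: IntensityTrace,
    peaks: PeakTrain,
    segmentation: PeriodSegmentation,
    droplet_id: str | None = None,
) -> WaveFeatureSummary:
    """Compute the five wave features over the droplet lifetime.

    The lifetime ends at the start of the exhausted state; peaks after it (by
    construction there are none) are excluded.  Waves without both flanking
    troughs (the first and last peak) are excluded from area statistics.
    """
    exhausted = segmentation.exhausted_start_s
    lifetime = exhausted if exhausted is not None else float(trace.time_s[-1])

    in_life = peaks.peak_times <= lifetime + 1e-9
    times = peaks.peak_times[in_life]
    values = peaks.peak_values[in_life]
    wave_count = int(times.size)

    _, freqs = instantaneous_frequency(times)
    median_freq = low_median(freqs) if freqs.size else None

    median_amp = low_median(values) if values.size else None

    areas = []
    corrected = trace.corrected if trace.corrected is not None else trace.raw
    for k in range(1, max(wave_count - 1, 0)):
        areas.append(
            peak_area(
                corrected,
                trace.time_s,
                int(peaks.trough_indices[k - 1]),
                int(peaks.trough_indices[k]),
            )
        )
    median_area = low_median(areas) if areas else None

    def _none_if_nan(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

    return WaveFeatureSummary(
        lifetime_s=float(lifetime),
        median_frequency_per_s=_none_if_nan(median_freq),
        wave_count=wave_count,
        median_amplitude=_none_if_nan(median_amp),
        median_area=_none_if_nan(median_area),
        droplet_id=droplet_id if droplet_id is not None else trace.droplet_id,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class AnalysisConfig:
    """End-to-end trace analysis settings with documented defaults.

    ``smooth_width_s`` sets the zero-phase box filter width in seconds (1.5 s
    default: wide enough to suppress photometric noise, narrow enough to keep
    the fast initial-stage waves).  The baseline window defaults to one
    estimated oscillation period (``default_period_s`` when no period can be
    estimated).  Peak selection is prominence-based
    (``prominence_frac`` of the 90th-percentile corrected amplitude); a
    period-scaled minimum separation can be enabled via
    ``use_period_distance``.
    """

    smooth_width_s: float = 1.5
    smooth_window: int | None = None
    baseline_window_s: float | None = None
    default_period_s: float = 25.0
    prominence: float | None = None
    prominence_frac: float = 0.2
    use_period_distance: bool = False
    distance_frac: float = 0.5
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    curation: list[dict] | None = None

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "smooth_width_s", "smooth_window", "baseline_window_s",
                "default_period_s", "prominence", "prominence_frac",
                "use_period_distance", "distance_frac",
            )
        }
        d["segmentation"] = vars(self.segmentation).copy()
        d["curation"] = self.curation
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        cfg = cls(**d)
        if seg:
            cfg.segmentation = SegmentationConfig(**seg)
        return cfg


@dataclass
class AnalysisResult:
    trace: IntensityTrace
    peaks: PeakTrain
    segmentation: PeriodSegmentation
    features: WaveFeatureSummary
    period_s: float


def analyze_trace(
    trace: IntensityTrace, config: AnalysisConfig | None = None
) -> AnalysisResult:
    """Run the full single-trace chain: filter, baseline, peaks, stages, features."""
    cfg = config or AnalysisConfig()
    dt = trace.dt
    if not math.isfinite(dt) or dt <= 0:
        raise ValueError("trace needs uniformly increasing timestamps")

    window = cfg.smooth_window
    if window is None:
        window = max(1, int(round(cfg.smooth_width_s / dt)))
    filtered = lowpass(trace.raw, window) if window > 1 else trace.raw.astype(float)

    period = estimate_period(filtered, dt)
    if period is None:
        period = cfg.default_period_s

    base_window_s = cfg.baseline_window_s if cfg.baseline_window_s else period
    base_window = max(3, int(round(base_window_s / dt)))
    base_window = min(base_window, len(trace))
    baseline, corrected = subtract_baseline(filtered, base_window)

    trace.filtered = filtered
    trace.baseline = baseline
    trace.corrected = corrected

    peaks = detect_peaks(
        corrected,
        trace.time_s,
        prominence=cfg.prominence,
        prominence_frac=cfg.prominence_frac,
        period_hint_s=period if cfg.use_period_distance else None,
        distance_frac=cfg.distance_frac,
        curation=cfg.curation,
    )
    segmentation = segment_periods(
        peaks,
        t_start=float(trace.time_s[0]),
        t_end=float(trace.time_s[-1]),
        config=cfg.segmentation,
    )
    features = summarize_features(trace, peaks, segmentation)
    return AnalysisResult(trace, peaks, segmentation, features, period)
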