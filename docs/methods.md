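# Methods

This note documents the models, defaults and numerical choices behind
`bzkymo`, and what the synthetic benchmark does and does not establish about
real recordings.

## Coordinate and time conventions

Pixel coordinates are 0-based; droplet spans are half-open `[start, end)`
intervals along the slot centreline. Only axis-aligned slots are supported
(the template fixes the dish, so slots are vertical or horizontal in the
frame). Timestamps are seconds from completion of mixing the BZ medium:
frame `i` is at `t0_offset + i / frame_rate`, where `t0_offset` is the delay
between mixing and the first frame. With this convention the droplet
lifetime is simply the start time of the exhausted stage. The default
calibration is the acquisition geometry of the template recordings: 108 px
per 2.5 mm slot width (23.1 µm/px) and 0.4 frames/s.

## Kymograph construction

For each frame a strip of `strip_width` px (default 15) centred on the slot
centreline is cropped and blurred across the strip; the strips are placed
side by side in temporal order. The blur kernel is not prescribed by the
workflow this reproduces, so the default is the simplest faithful reading —
the mean over the full strip width, which makes the strip's columns
identical — with an integer box-kernel option for narrower blurs. Odd strip
widths centre exactly on the centreline; even widths take one extra pixel
toward lower coordinates. A collapsed mode (one column per frame) is
provided for compact plots and for tracking; because the trace is a region
mean, the two modes are analytically equivalent for all quantitative
outputs. The droplet trace is the mean of a `strip_width × height` region
(default 15 × 5 px) per frame, positioned at a `centre_y` chosen inside the
droplet and away from artifacts.

## Trace processing

**Low-pass filter.** A zero-phase box average with width given in seconds
(`smooth_width_s`, default 1.5 s; forced odd in samples; edge replication,
so constants pass unchanged). The width is deliberately *not* tied to the
estimated dominant period: a lifecycle trace spans a ~5× frequency range,
and a filter sized from the (main-stage-dominated) autocorrelation estimate
would erase the fast, low-amplitude initial-stage waves. A period-scaled
width remains available through `smooth_window`.

**Period estimate.** The lag of the first prominent autocorrelation maximum
(prominence ≥ 0.05 of the zero-lag value). Traces without oscillatory
structure return "no period" and callers fall back to `default_period_s`
(25 s, the main-stage period at 0.04 s⁻¹).

**Baseline.** The running minimum of the filtered trace over a centred
window one estimated period wide, truncated at the edges. Because the
window always contains its centre sample, `corrected = filtered − baseline`
is non-negative everywhere; slow drift and step changes (e.g. the bright
oil before a droplet is pipetted) are absorbed. For a sampled sinusoid
`C + A·sin` whose grid hits the minimum and whose every truncated window
contains a minimum sample, the baseline is exactly `C − A` (a closed form
used in the tests).

**Peaks and troughs.** Local maxima of the corrected trace with topographic
prominence at least 20 % of the 90th-percentile corrected amplitude
(`prominence_frac`), troughs being the minima between consecutive peaks.
A minimum-separation rule (0.5 × period hint) is implemented but off by
default for the same reason as the filter width: it would prune the
initial-stage waves. Prominence alone discriminates cleanly at the default
noise level. Peak times are refined to sub-sample resolution by a parabolic
fit through the apex and its two neighbours (clipped to ±half a sample),
which removes the half-sample quantisation of peak-to-peak intervals;
without it, median-frequency errors are bounded by one sample per interval
(±2.5 % at 2 Hz sampling of a 25 s period) rather than the ~0.3 % achieved.
A curation sidecar (JSON list of `add`/`remove` edits with time and
tolerance) is applied after detection, mirroring manual verification of
peak assignments; the tests exercise it, the defaults need none.

**Per-oscillation frequency.** `1/Δt` for each consecutive peak pair,
assigned to the later peak.

**Medians.** All feature medians use the lower-of-two convention for even
counts: deterministic, and always an observed value.

## Lifecycle segmentation

Stage rules operate on the per-oscillation frequency series only:

* **induction** — trace start to first detected peak;
* **initial → main** — at the first oscillation whose frequency falls below
  60 % of the running median of the preceding oscillations (the rapid
  frequency decrease out of the initial stage); the boundary is the earlier
  peak of that interval;
* **main → late** — when a 3-oscillation rolling median exceeds 150 % of
  the median of the trailing main-stage oscillations (the sudden frequency
  increase). The trailing reference uses the last 10 main oscillations, not
  the whole stage: the main stage itself declines slowly, and a whole-stage
  median would overstate the recent frequency and can miss a genuine
  up-step. Within the triggering window the boundary is placed at the start
  of the first individually fast interval, i.e. at the first late-stage
  peak;
* **exhausted** — three final periods after the last peak (capped at the
  trace end).

All thresholds are configurable (`SegmentationConfig`). A trace with no
peaks segments as induction followed by a zero-length exhausted marker. A
trace that never leaves its first frequency regime is labelled initial
throughout — the rules never invent a main stage.

On the default synthetic lifecycle these rules recover the main-stage
boundaries to within one oscillation period and every scheduled wave
(see `tests/test_acceptance.py`).

## Wavefront tracking and interface classification

The kymograph is binarised by subtracting, per spatial row, a running-minimum
baseline over time (60 s window), then thresholding at 50 % of the maximum
corrected amplitude; a kymograph whose corrected amplitude stays below 10
intensity units is treated as degenerate (empty mask). Row-wise baselining
makes the mask immune to slow photometric drift and to static bright
artifacts such as CO₂ bubbles.

Per-column runs of mask pixels are linked into tracks when consecutive runs
overlap or their centroids lie within 25 px (gaps up to 2 frames are
bridged); tracks shorter than 3 frames are discarded as speckle. A run
claimed by two tracks of opposite direction terminates both as an
**annihilation**; a track splitting into two runs spawns a second track
sharing the origin (a source emitting opposite fronts). A **crossing** of a
droplet interface requires samples beyond a ±4 px dead zone on *both* sides
— a front that dies at the interface is a **block**, not a crossing. A
track ending at an interface is still counted as propagated if another
track begins just across it within the configured delay window (one
oscillation period by default), covering crossing delays long enough to
break the ridge. Per-droplet wave origins are labelled from where a track
first appears in the droplet: top interface, bottom interface, slot wall,
or interior. Terminations partition into boundary (slot end or end of
recording), annihilation, and dissipation.

## The synthetic generator

The generator is phenomenological: no reaction kinetics are integrated.
Waves follow an explicit per-droplet `LifecycleSchedule`, and that schedule
*is* the ground truth. Defaults describe a typical malonic-acid droplet and
are used unchanged throughout the tests:

| parameter | default | meaning |
|---|---|---|
| induction | 60 s | quiescent period after mixing |
| initial stage | 180 s, 0.2 s⁻¹, amplitude 24 | fast low-amplitude waves |
| main stage | 3600 s, 0.04 s⁻¹, amplitude 80 | the stage relevant for propagation |
| late stage | 600 s, 0.08 s⁻¹, amplitude 80 | sudden frequency doubling |
| pulse shape | rise 10 %, decay 40 % of period | asymmetric sawtooth-like wave |
| noise | σ = 2 % of amplitude | additive Gaussian, per sample |
| drift | 5 % of amplitude, 30 min period | slow sinusoidal baseline |
| trace sampling | 2 Hz | trace-level studies |
| rendering | 0.4 frames/s, 108 px droplets | video-level studies |
| front speed | 6 px/s | wavefront traversal of a droplet |
| coupling | p = 1, delay 2.5 s, refractory 0 s | per-interface crossing |

Amplitudes are 8-bit blue-channel intensity units. Each stage emits its
first wave at the stage start and then every `1/f(t)` (the main stage may
decline linearly in frequency); a stage whose start falls within a quarter
period of the previous wave defers its first wave by one period, so stage
boundaries never double-pulse. Wavefronts are simulated event-driven along
the slot: fronts travel at constant speed, pause for the crossing delay at
interfaces they pass (rendered as a stationary band, which keeps a
propagating wave one connected space-time ridge), die where a Bernoulli
propagation draw fails, and annihilate pairwise when opposing fronts meet.
Every draw is consumed in deterministic event order, so identical seeds give
bit-identical traces, frames and ground truth.

The fraction of droplets flagged as starting with spiral waves (default
20 %) is bookkeeping only: wave geometry inside a droplet is not rendered —
fronts are 1-D bands along the slot — and no spiral/planar/circular
classification is attempted. This is sufficient for every implemented
operation, which consume scalar traces and 1-D front positions.

**What passing tests show, and what they do not.** The generator reproduces
the features the pipeline measures: stage-structured pulse trains,
amplitude and frequency contrasts between stages, drift, additive noise,
interdroplet delays, blocks, and annihilations. It does not reproduce
within-droplet wave geometry, droplet fusion, bubble artifacts in motion,
exposure changes, or frequency jitter between consecutive waves. Recovery
results on synthetic data therefore validate the algorithmic chain, not the
photometric robustness margins on laboratory video.

## Problem sizes

Test and acceptance runs use desk-scale versions of the study conditions:
single-droplet lifecycles of 60–90 simulated minutes sampled at 2 Hz,
20-droplet arrays with 40 px droplet spans at 0.4 frames/s, and a packaged
deterministic reference trace of 75 minutes at 0.4 Hz. The acceptance
script's headline figure — the number of waves counted in a segmented 1 h
main stage at 0.04 s⁻¹ — is recomputed from scratch on each run.

## Known limitations

* Slots must be axis-aligned in the frame; arbitrary slot angles are not
  supported.
* Droplet spans are inputs (from the layout file or the generator); there
  is no automatic droplet detection from images.
* Junction/maze topologies are analysed slot-by-slot; tracking assumes a
  linear slot.
* Segmentation assumes the initial stage is sampled well enough to resolve
  its waves; at 0.4 frames/s an initial frequency above ~0.1 s⁻¹ aliases
  and the initial/main boundary degrades accordingly (trace-level studies
  default to 2 Hz for this reason).
* A refractory collision at a paused (mid-crossing) front is not modelled;
  opposing fronts are resolved only while both are moving.
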