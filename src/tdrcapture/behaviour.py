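"""Capture-point, baseline, and movement-bout extraction from depth traces.

The algorithm converts a raw depth trace into a per-animal capture summary
in five stages:

1. a steady-state baseline depth is averaged over a 1-min window ending at
   the capture point and re-established at the end of every 30-min block
   (and after movement bouts that span a large tidal depth change);
2. the absolute deviation of every sample from its covering baseline is
   computed;
3. a movement threshold per baseline segment is the chosen fraction of the
   effective gangion extension plus the baseline window's standard
   deviation (the s.d. term absorbs surface swell);
4. maximal runs of samples meeting or exceeding the threshold are movement
   bouts; sub-threshold gaps longer than the cessation gap terminate a
   bout, shorter gaps are bridged and counted as movement;
5. samples beyond the haul-up point are excluded.

Capture onset is the first sustained supra-threshold deviation from the
trailing 1-min baseline at the most sensitive configured fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trace import DepthTrace, GearConfig

__all__ = [
    "BaselineSegment",
    "MovementBout",
    "CapturePoint",
    "CaptureSummary",
    "AnalysisResult",
    "detect_capture_point",
    "detect_haul_time",
    "build_baseline_schedule",
    "refine_schedule_for_bouts",
    "deviation_series",
    "movement_threshold",
    "detect_bouts",
    "summarize_capture",
    "analyze_trace",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineSegment:
    """One stretch of the capture with a fixed reference depth."""

    start_s: float
    end_s: float
    baseline_depth_m: float
    baseline_sd_m: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment end must exceed start")
        if self.baseline_sd_m < 0:
            raise ValueError("baseline s.d. must be >= 0")


@dataclass(frozen=True)
class MovementBout:
    """A maximal supra-threshold interval at one threshold fraction."""

    start_s: float
    end_s: float
    peak_deviation_m: float
    threshold_fraction: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class CapturePoint:
    time_s: float
    depth_m: float


@dataclass(frozen=True)
class CaptureSummary:
    """Per-animal capture metrics (one output-table row)."""

    device_id: str
    capture_time_s: float
    capture_depth_m: float
    haul_time_s: float
    capture_duration_min: float
    movement_min: dict[float, float]
    movement_pct: dict[float, float]

    def to_row(self) -> dict:
        row = {
            "device_id": self.device_id,
            "capture_time_s": self.capture_time_s,
            "capture_depth_m": self.capture_depth_m,
            "haul_time_s": self.haul_time_s,
            "capture_duration_min": self.capture_duration_min,
        }
        for frac in sorted(self.movement_min):
            key = f"{int(round(frac * 100))}"
            row[f"movement_min_{key}"] = self.movement_min[frac]
            row[f"movement_pct_{key}"] = self.movement_pct[frac]
        return row


@dataclass(frozen=True)
class AnalysisResult:
    """Full output of :func:`analyze_trace`."""

    summary: CaptureSummary | None
    capture: CapturePoint | None
    haul_time_s: float | None
    schedule: list[BaselineSegment] = field(default_factory=list)
    bouts: dict[float, list[MovementBout]] = field(default_factory=dict)

    @property
    def captured(self) -> bool:
        return self.summary is not None


def _trailing_stats(depths: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample s.d. of the w samples strictly before each index.

    Entries for indices < w are NaN.
    """
    n = depths.size
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    if n <= w:
        return mean, sd
    c1 = np.concatenate(([0.0], np.cumsum(depths)))
    c2 = np.concatenate(([0.0], np.cumsum(depths**2)))
    s1 = c1[w:n] - c1[: n - w]
    s2 = c2[w:n] - c2[: n - w]
    m = s1 / w
    var = np.maximum(s2 / w - m**2, 0.0) * (w / (w - 1))
    mean[w:] = m
    sd[w:] = np.sqrt(var)
    return mean, sd


def _window_stats(trace: DepthTrace, start_s: float, end_s: float) -> tuple[float, float]:
    """Mean and sample s.d. of depths with start_s <= t < end_s."""
    sel = (trace.times >= start_s) & (trace.times < end_s)
    vals = trace.depths[sel]
    if vals.size < 2:
        raise ValueError(f"baseline window [{start_s}, {end_s}) has < 2 samples")
    return float(vals.mean()), float(vals.std(ddof=1))


def detect_capture_point(
    trace: DepthTrace, gear: GearConfig
) -> CapturePoint | None:
    """Locate the onset of capture, or return None if nothing is hooked.

    The onset is the first sample whose absolute deviation from the
    trailing 1-min baseline meets or exceeds the detection threshold
    (most sensitive fraction of the effective extension plus the trailing
    window's s.d.) for at least ``gear.capture_min_run`` consecutive
    samples.
    """
    dt = trace.sample_interval_s
    w = max(2, int(round(gear.baseline_window_s / dt)))
    if len(trace) < 2 * w:
        raise ValueError("trace shorter than twice the baseline window")
    mean, sd = _trailing_stats(trace.depths, w)
    thr = gear.detection_fraction * gear.effective_extension_m + sd
    # the run condition is judged against the baseline frozen at the
    # candidate onset: the trailing window right before the capture point
    # (letting the window slide into the excursion inflates the s.d. and
    # breaks genuine onsets)
    need = gear.capture_min_run
    n = len(trace)
    sustained = np.ones(n - need + 1, dtype=bool)
    sustained[:w] = False
    for shift in range(need):
        seg = trace.depths[shift : n - need + 1 + shift]
        sustained &= np.abs(seg - mean[: n - need + 1]) >= thr[: n - need + 1]
    hits = np.nonzero(sustained)[0]
    if hits.size == 0:
        return None
    a = int(hits[0])
    return CapturePoint(time_s=float(trace.times[a]), depth_m=float(mean[a]))


def detect_haul_time(
    trace: DepthTrace,
    capture: CapturePoint,
    gear: GearConfig,
    *,
    surface_depth_m: float = 1.0,
) -> float:
    """Auto-detect the haul-up point after capture.

    Finds the first excursion to shallower than ``surface_depth_m`` after
    the capture point and backtracks to the last sample still within the
    detection threshold of its trailing baseline — i.e. the start of the
    final ascent to the surface. Falls back to the end of the trace when
    the gear is never brought to the surface on record.
    """
    dt = trace.sample_interval_s
    w = max(2, int(round(gear.baseline_window_s / dt)))
    i0 = trace.index_at(capture.time_s)
    shallow = np.nonzero(trace.depths[i0:] < surface_depth_m)[0]
    if shallow.size == 0:
        return float(trace.times[-1] + dt)
    j = i0 + int(shallow[0])
    mean, sd = _trailing_stats(trace.depths, w)
    dev = np.abs(trace.depths - mean)
    thr = gear.detection_fraction * gear.effective_extension_m + sd
    in_band = np.nonzero(dev[i0:j] <= thr[i0:j])[0]
    if in_band.size == 0:
        return float(trace.times[j])
    k = i0 + int(in_band[-1])
    return float(trace.times[k] + dt)


def build_baseline_schedule(
    trace: DepthTrace,
    capture_time_s: float,
    haul_time_s: float,
    gear: GearConfig,
) -> list[BaselineSegment]:
    """Tile [capture, haul) with baseline segments.

    The first baseline averages the 1-min window ending at the capture
    point; a fresh baseline is struck from the trailing 1-min window at
    the end of every 30-min block. A sample exactly on a block boundary
    belongs to the later segment.
    """
    if capture_time_s < gear.baseline_window_s + trace.times[0]:
        raise ValueError("capture point too early for a pre-capture baseline window")
    if haul_time_s <= capture_time_s:
        raise ValueError("haul time must exceed capture time")
    segments: list[BaselineSegment] = []
    start = capture_time_s
    while start < haul_time_s:
        end = min(start + gear.baseline_recalc_interval_s, haul_time_s)
        m, s = _window_stats(trace, start - gear.baseline_window_s, start)
        segments.append(BaselineSegment(start, end, m, s))
        start = end
    _check_tiling(segments, capture_time_s, haul_time_s)
    return segments


def _check_tiling(
    segments: list[BaselineSegment], start_s: float, end_s: float
) -> None:
    if not segments:
        raise ValueError("empty baseline schedule")
    if segments[0].start_s != start_s or segments[-1].end_s != end_s:
        raise ValueError("baseline schedule does not span [capture, haul)")
    for a, b in zip(segments, segments[1:]):
        if a.end_s != b.start_s:
            raise ValueError(
                f"baseline schedule gap/overlap at {a.end_s} vs {b.start_s}"
            )


def refine_schedule_for_bouts(
    trace: DepthTrace,
    schedule: list[BaselineSegment],
    bouts: list[MovementBout],
    gear: GearConfig,
) -> list[BaselineSegment]:
    """Insert mid-capture baseline recalculations after tide-spanning bouts.

    A bout spans a significant tidal depth change when the mean depth over
    the 1-min window after it differs from the 1-min window before it by
    more than ``tidal_shift_sigma`` times the covering baseline s.d.; the
    baseline from the bout's end onward (until the next boundary) becomes
    the average of those two window means.
    """
    if not bouts:
        return schedule
    w = gear.baseline_window_s
    capture_s, haul_s = schedule[0].start_s, schedule[-1].end_s
    boundaries = [(seg.start_s, seg.baseline_depth_m, seg.baseline_sd_m) for seg in schedule]
    # merge bouts separated by less than one baseline window into movement
    # periods, so the 1-min windows flanking a period are movement-free
    periods: list[list[float]] = []
    for bout in sorted(bouts, key=lambda b: b.start_s):
        if periods and bout.start_s - periods[-1][1] < w:
            periods[-1][1] = max(periods[-1][1], bout.end_s)
        else:
            periods.append([bout.start_s, bout.end_s])
    extra: list[tuple[float, float, float]] = []
    for start, end in periods:
        if start - w < trace.times[0] or end + w > haul_s:
            continue
        before_m, before_s = _window_stats(trace, start - w, start)
        after_m, after_s = _window_stats(trace, end, end + w)
        seg = _covering_segment(schedule, start)
        if abs(after_m - before_m) > gear.tidal_shift_sigma * max(seg.baseline_sd_m, 1e-9):
            log.debug(
                "tidal shift across movement period at %.0f s: %.3f m; "
                "recalculating baseline",
                start,
                after_m - before_m,
            )
            extra.append((end, (before_m + after_m) / 2, (before_s + after_s) / 2))
    if not extra:
        return schedule
    merged = sorted(boundaries + extra)
    segments = []
    for i, (start, m, s) in enumerate(merged):
        end = merged[i + 1][0] if i + 1 < len(merged) else haul_s
        if end > start:
            segments.append(BaselineSegment(start, end, m, s))
    _check_tiling(segments, capture_s, haul_s)
    return segments


def _covering_segment(schedule: list[BaselineSegment], t: float) -> BaselineSegment:
    for seg in schedule:
        if seg.start_s <= t < seg.end_s:
            return seg
    raise ValueError(f"time {t} s not covered by baseline schedule")


def deviation_series(
    trace: DepthTrace, schedule: list[BaselineSegment]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample absolute deviation from the covering baseline.

    Returns ``(indices, deviations)`` for samples inside
    [capture, haul); samples beyond the haul point are excluded.
    """
    starts = np.array([seg.start_s for seg in schedule])
    base = np.array([seg.baseline_depth_m for seg in schedule])
    lo, hi = schedule[0].start_s, schedule[-1].end_s
    idx = np.nonzero((trace.times >= lo) & (trace.times < hi))[0]
    which = np.searchsorted(starts, trace.times[idx], side="right") - 1
    if np.any(which < 0):
        raise ValueError("sample not covered by any baseline segment")
    dev = np.abs(trace.depths[idx] - base[which])
    return idx, dev


def movement_threshold(
    segment: BaselineSegment, fraction: float, gear: GearConfig
) -> float:
    """Threshold (m) above which deviation counts as movement.

    fraction × effective extension, plus the baseline s.d. to absorb
    swell-driven depth noise.
    """
    if fraction not in gear.threshold_fractions:
        raise ValueError(
            f"fraction {fraction} not in configured {gear.threshold_fractions}"
        )
    return fraction * gear.effective_extension_m + segment.baseline_sd_m


def detect_bouts(
    trace: DepthTrace,
    indices: np.ndarray,
    deviations: np.ndarray,
    schedule: list[BaselineSegment],
    fraction: float,
    gear: GearConfig,
) -> list[MovementBout]:
    """Movement bouts at one threshold fraction.

    A bout is a maximal run of samples whose deviation meets or exceeds
    the covering segment's threshold; sub-threshold gaps of at most the
    cessation gap are bridged (gap samples count as movement), longer
    gaps end the bout.
    """
    if indices.size != deviations.size:
        raise ValueError("indices and deviations misaligned")
    if indices.size == 0:
        return []
    dt = trace.sample_interval_s
    starts = np.array([seg.start_s for seg in schedule])
    thr_by_seg = np.array(
        [movement_threshold(seg, fraction, gear) for seg in schedule]
    )
    which = np.searchsorted(starts, trace.times[indices], side="right") - 1
    supra = deviations >= thr_by_seg[which]

    runs = _supra_runs(supra)
    merged: list[list[int]] = []
    for a, b in runs:  # half-open sample runs [a, b)
        if merged and (a - merged[-1][1]) * dt <= gear.cessation_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    bouts = []
    for a, b in merged:
        i0, i1 = indices[a], indices[b - 1]
        bouts.append(
            MovementBout(
                start_s=float(trace.times[i0]),
                end_s=float(trace.times[i1] + dt),
                peak_deviation_m=float(deviations[a:b].max()),
                threshold_fraction=fraction,
            )
        )
    return bouts


def _supra_runs(supra: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [start, stop) pairs."""
    padded = np.concatenate(([False], supra, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def summarize_capture(
    device_id: str,
    capture: CapturePoint,
    haul_time_s: float,
    bouts_by_fraction: dict[float, list[MovementBout]],
) -> CaptureSummary:
    """Collapse bouts into per-animal duration and movement metrics."""
    if haul_time_s <= capture.time_s:
        raise ValueError("haul time must exceed capture time")
    duration_min = (haul_time_s - capture.time_s) / 60.0
    movement_min: dict[float, float] = {}
    movement_pct: dict[float, float] = {}
    for frac, bouts in bouts_by_fraction.items():
        for b in bouts:
            if b.start_s < capture.time_s or b.end_s > haul_time_s:
                raise ValueError("bout outside [capture, haul]")
        total_min = sum(b.duration_s for b in bouts) / 60.0
        movement_min[frac] = total_min
        movement_pct[frac] = 100.0 * total_min / duration_min
    return CaptureSummary(
        device_id=device_id,
        capture_time_s=capture.time_s,
        capture_depth_m=capture.depth_m,
        haul_time_s=haul_time_s,
        capture_duration_min=duration_min,
        movement_min=movement_min,
        movement_pct=movement_pct,
    )


def analyze_trace(
    trace: DepthTrace,
    gear: GearConfig | None = None,
    *,
    haul_time_s: float | None = None,
    refine_tidal: bool = True,
) -> AnalysisResult:
    """Run the full capture-behaviour extraction on one trace.

    Returns a result with ``summary=None`` when no capture is detected.
    When ``haul_time_s`` is not supplied it is auto-detected as the start
    of the final ascent to the surface.
    """
    gear = gear or GearConfig()
    capture = detect_capture_point(trace, gear)
    if capture is None:
        log.info("%s: no capture detected", trace.device_id)
        return AnalysisResult(summary=None, capture=None, haul_time_s=None)
    if haul_time_s is None:
        haul_time_s = detect_haul_time(trace, capture, gear)
    schedule = build_baseline_schedule(trace, capture.time_s, haul_time_s, gear)
    idx, dev = deviation_series(trace, schedule)
    if refine_tidal:
        probe = detect_bouts(trace, idx, dev, schedule, gear.detection_fraction, gear)
        refined = refine_schedule_for_bouts(trace, schedule, probe, gear)
        if refined is not schedule:
            schedule = refined
            idx, dev = deviation_series(trace, schedule)
    bouts = {
        frac: detect_bouts(trace, idx, dev, schedule, frac, gear)
        for frac in gear.threshold_fractions
    }
    summary = summarize_capture(trace.device_id, capture, haul_time_s, bouts)
    log.info(
        "%s: capture at %.0f s, duration %.1f min",
        trace.device_id,
        capture.time_s,
        summary.capture_duration_min,
    )
    return AnalysisResult(
        summary=summary,
        capture=capture,
        haul_time_s=haul_time_s,
        schedule=schedule,
        bouts=bouts,
    )
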