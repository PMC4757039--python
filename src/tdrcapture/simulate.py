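"""Seeded depth-trace simulator with known ground truth.

Traces are built as: set depth + tidal sinusoid + i.i.d. Gaussian swell
noise, with surface-ward excursions superimposed during movement bouts, a
sharp-onset struggle at the capture point, and a monotone haul-up ramp to
the surface at the end. The simulator records everything a recovery test
needs: the true capture time, haul time, bout intervals, and the true
fraction of capture time the noiseless excursion spends at or above each
detection level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .trace import DepthTrace, GearConfig

__all__ = [
    "BoutSpec",
    "TraceScenario",
    "TraceGroundTruth",
    "simulate_trace",
    "simulate_cohort",
    "CohortRanges",
]


@dataclass(frozen=True)
class BoutSpec:
    """One movement bout: a half-sine excursion toward the surface."""

    start_s: float
    duration_s: float
    amplitude_m: float


@dataclass(frozen=True)
class TraceScenario:
    """Parameters for one simulated trace.

    When ``bouts`` is None a bout schedule is drawn: bout count is Poisson
    with the given hourly rate over the capture interval, durations are
    log-normal, amplitudes uniform over ``bout_amplitude_range`` (never
    above the effective gangion extension), and bouts are kept at least
    ``min_separation_s`` apart so the cessation rule cannot merge distinct
    bouts.
    """

    set_depth_m: float = 8.0
    tide_amplitude_m: float = 0.15
    tide_period_min: float = 745.0
    tide_phase_rad: float = 0.0
    swell_sd_m: float = 0.05
    capture_time_s: float = 600.0
    haul_time_s: float = 10200.0
    soak_duration_min: float = 200.0
    sample_interval_s: float = 2.0
    struggle_duration_s: float = 30.0
    struggle_amplitude_m: float = 0.60
    bout_rate_per_h: float = 6.0
    bout_duration_log_mean: float = np.log(40.0)
    bout_duration_log_sd: float = 0.35
    # amplitudes well above the 50%-extension level keep excursion edges
    # steep; near-level amplitudes make noise chatter dominate bout edges
    bout_amplitude_range: tuple[float, float] = (0.50, 0.60)
    min_separation_s: float = 12.0
    #: bout-free stretch before haul so haul detection sees a clean plateau
    haul_buffer_s: float = 90.0
    haul_ramp_rate_m_per_s: float = 0.25
    bouts: tuple[BoutSpec, ...] | None = None
    device_id: str = "sim"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.capture_time_s >= self.haul_time_s:
            raise ValueError("capture must precede haul")
        if self.haul_time_s > self.soak_duration_min * 60.0:
            raise ValueError("haul must occur within the soak")
        if self.swell_sd_m < 0 or self.tide_amplitude_m < 0:
            raise ValueError("noise scales must be >= 0")
        for name in (
            "set_depth_m",
            "tide_period_min",
            "sample_interval_s",
            "struggle_duration_s",
            "haul_ramp_rate_m_per_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.bout_amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("bout amplitude range must be ordered and positive")


@dataclass(frozen=True)
class TraceGroundTruth:
    """Simulator-known truth used as the recovery-test oracle."""

    capture_time_s: float
    haul_time_s: float
    bout_intervals: tuple[tuple[float, float, float], ...]  # (start, end, amplitude)
    movement_pct: dict[float, float]  # threshold fraction -> true % time moving
    occupancy_pct: float  # raw bout-interval occupancy, % of capture time

    @property
    def capture_duration_min(self) -> float:
        return (self.haul_time_s - self.capture_time_s) / 60.0

    def to_json(self) -> str:
        d = asdict(self)
        d["movement_pct"] = {str(k): v for k, v in self.movement_pct.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TraceGroundTruth":
        d = json.loads(text)
        d["movement_pct"] = {float(k): v for k, v in d["movement_pct"].items()}
        d["bout_intervals"] = tuple(tuple(b) for b in d["bout_intervals"])
        return cls(**d)


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _draw_bouts(
    scenario: TraceScenario, gear: GearConfig, rng: np.random.Generator
) -> list[BoutSpec]:
    dt = scenario.sample_interval_s
    lo = scenario.capture_time_s + scenario.struggle_duration_s + scenario.min_separation_s
    hi = scenario.haul_time_s - max(scenario.min_separation_s, scenario.haul_buffer_s)
    window_h = max(hi - lo, 0.0) / 3600.0
    n = rng.poisson(scenario.bout_rate_per_h * window_h)
    amp_lo, amp_hi = scenario.bout_amplitude_range
    amp_hi = min(amp_hi, gear.effective_extension_m)
    taken: list[tuple[float, float]] = [
        (scenario.capture_time_s, scenario.capture_time_s + scenario.struggle_duration_s)
    ]
    # keep bouts clear of the trailing 1-min windows used for the 30-min
    # baseline recalculations; a bout inside one would corrupt the baseline
    boundary = scenario.capture_time_s + gear.baseline_recalc_interval_s
    while boundary < scenario.haul_time_s:
        taken.append((boundary - gear.baseline_window_s, boundary))
        boundary += gear.baseline_recalc_interval_s
    bouts: list[BoutSpec] = []
    for _ in range(n):
        dur = _snap(float(rng.lognormal(scenario.bout_duration_log_mean, scenario.bout_duration_log_sd)), dt)
        dur = max(dur, 2 * dt)
        amp = float(rng.uniform(amp_lo, amp_hi))
        for _attempt in range(100):  # redraw start on conflict; drop after 100 tries
            start = _snap(float(rng.uniform(lo, hi - dur)), dt)
            if start < lo or start + dur > hi:
                continue
            sep = scenario.min_separation_s
            if all(start + dur + sep <= a or b + sep <= start for a, b in taken):
                taken.append((start, start + dur))
                bouts.append(BoutSpec(start, dur, amp))
                break
    bouts.sort(key=lambda b: b.start_s)
    return bouts


def _excursion_profile(
    times: np.ndarray, scenario: TraceScenario, bouts: list[BoutSpec]
) -> np.ndarray:
    """Noise-free surface-ward excursion (m) at each sample."""
    exc = np.zeros_like(times)
    # capture struggle: instant onset, flat top, so the onset is a single
    # well-defined sample (half-sine onsets would smear it by seconds)
    u = times - scenario.capture_time_s
    mask = (u >= 0) & (u < scenario.struggle_duration_s)
    exc[mask] = np.maximum(exc[mask], scenario.struggle_amplitude_m)
    for b in bouts:
        u = (times - b.start_s) / b.duration_s
        mask = (u >= 0) & (u < 1)
        exc[mask] = np.maximum(exc[mask], b.amplitude_m * np.sin(np.pi * u[mask]))
    return exc


def simulate_trace(
    scenario: TraceScenario,
    gear: GearConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DepthTrace, TraceGroundTruth]:
    """Generate one trace plus its ground truth.

    The true per-fraction movement percentage is the fraction of capture
    time the noiseless excursion spends at or above
    ``fraction × effective_extension + swell_sd`` — the level the detector
    will operate at once the baseline s.d. has absorbed the swell.
    """
    gear = gear or GearConfig()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if scenario.struggle_amplitude_m > gear.effective_extension_m + 1e-9:
        raise ValueError("struggle amplitude exceeds effective gangion extension")
    dt = scenario.sample_interval_s
    n = int(round(scenario.soak_duration_min * 60.0 / dt))
    times = dt * np.arange(n)
    capture_s = _snap(scenario.capture_time_s, dt)
    haul_s = _snap(scenario.haul_time_s, dt)
    scenario = _replace_times(scenario, capture_s, haul_s)

    if scenario.bouts is not None:
        bouts = sorted(scenario.bouts, key=lambda b: b.start_s)
        for b in bouts:
            if b.amplitude_m > gear.effective_extension_m + 1e-9:
                raise ValueError("bout amplitude exceeds effective gangion extension")
            if b.start_s < capture_s or b.start_s + b.duration_s > haul_s:
                raise ValueError("bout outside [capture, haul]")
    else:
        bouts = _draw_bouts(scenario, gear, rng)

    omega = 2 * np.pi / (scenario.tide_period_min * 60.0)
    tide = scenario.tide_amplitude_m * np.sin(omega * times + scenario.tide_phase_rad)
    exc = _excursion_profile(times, scenario, bouts)
    depth = scenario.set_depth_m + tide - exc

    # monotone haul ramp from the noiseless depth at haul time to the surface
    i_haul = int(round(haul_s / dt))
    if i_haul < n:
        base = depth[i_haul]
        ramp = base - scenario.haul_ramp_rate_m_per_s * (times[i_haul:] - haul_s)
        depth[i_haul:] = np.maximum(ramp, 0.0)

    if scenario.swell_sd_m > 0:
        depth = depth + rng.normal(0.0, scenario.swell_sd_m, size=n)
    depth = np.maximum(depth, 0.0)

    trace = DepthTrace(
        times=times,
        depths=depth,
        device_id=scenario.device_id,
        sample_interval_s=dt,
    )

    in_capture = (times >= capture_s) & (times < haul_s)
    n_capture = int(in_capture.sum())
    movement_pct = {}
    for frac in gear.threshold_fractions:
        level = frac * gear.effective_extension_m + scenario.swell_sd_m
        movement_pct[frac] = 100.0 * float((exc[in_capture] >= level).sum()) / n_capture
    intervals = [(capture_s, capture_s + scenario.struggle_duration_s, scenario.struggle_amplitude_m)]
    intervals += [(b.start_s, b.start_s + b.duration_s, b.amplitude_m) for b in bouts]
    occupied = sum(e - s for s, e, _ in intervals)
    truth = TraceGroundTruth(
        capture_time_s=capture_s,
        haul_time_s=haul_s,
        bout_intervals=tuple(intervals),
        movement_pct=movement_pct,
        occupancy_pct=100.0 * occupied / (haul_s - capture_s),
    )
    return trace, truth


def _replace_times(s: TraceScenario, capture_s: float, haul_s: float) -> TraceScenario:
    if capture_s == s.capture_time_s and haul_s == s.haul_time_s:
        return s
    d = asdict(s)
    d["capture_time_s"] = capture_s
    d["haul_time_s"] = haul_s
    if d["bouts"] is not None:
        d["bouts"] = tuple(BoutSpec(**b) for b in d["bouts"])
    if d["bout_amplitude_range"] is not None:
        d["bout_amplitude_range"] = tuple(d["bout_amplitude_range"])
    return TraceScenario(**d)


@dataclass(frozen=True)
class CohortRanges:
    """Uniform draw ranges for a cohort of scenarios."""

    set_depth_m: tuple[float, float] = (3.5, 22.7)
    capture_time_s: tuple[float, float] = (300.0, 1200.0)
    capture_duration_min: tuple[float, float] = (30.0, 220.0)
    post_haul_slack_s: tuple[float, float] = (300.0, 900.0)
    tide_amplitude_m: tuple[float, float] = (0.05, 0.25)
    swell_sd_m: float = 0.05
    bout_rate_per_h: float = 6.0


def simulate_cohort(
    n: int,
    seed: int | None = None,
    gear: GearConfig | None = None,
    ranges: CohortRanges | None = None,
    **scenario_overrides,
) -> list[tuple[DepthTrace, TraceGroundTruth]]:
    """Draw ``n`` independent scenarios and simulate each one.

    Reproducible: the same seed yields an identical cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gear = gear or GearConfig()
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        capture = float(rng.uniform(*ranges.capture_time_s))
        duration = float(rng.uniform(*ranges.capture_duration_min)) * 60.0
        haul = capture + duration
        soak_min = (haul + float(rng.uniform(*ranges.post_haul_slack_s))) / 60.0
        params = dict(
            set_depth_m=float(rng.uniform(*ranges.set_depth_m)),
            tide_amplitude_m=float(rng.uniform(*ranges.tide_amplitude_m)),
            tide_phase_rad=float(rng.uniform(0, 2 * np.pi)),
            swell_sd_m=ranges.swell_sd_m,
            bout_rate_per_h=ranges.bout_rate_per_h,
            capture_time_s=capture,
            haul_time_s=haul,
            soak_duration_min=soak_min,
            device_id=f"sim{i:03d}",
        )
        params.update(scenario_overrides)
        out.append(simulate_trace(TraceScenario(**params), gear=gear, rng=rng))
    return out
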