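"""Depth-trace container, gear geometry, and delimited-text I/O.

A trace is a uniformly sampled depth series (metres, positive downward)
recorded by an archival depth logger mounted on a longline gangion. Gear
geometry determines the maximum vertical excursion the logger can register
from a hooked animal: the gangion length minus the mounting offset of the
device from the hook eye ("effective extension").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrace",
    "GearConfig",
    "TraceReadError",
    "read_trace",
    "write_trace",
]

#: relative tolerance on grid uniformity (fraction of the sample interval)
_GRID_RTOL = 1e-3
#: depths in (-_NEG_CLIP, 0) are treated as surface measurement noise
_NEG_CLIP = 0.5


class TraceReadError(ValueError):
    """Raised when a trace file violates the reader preconditions."""


@dataclass(frozen=True)
class GearConfig:
    """Longline gear geometry and detection thresholds.

    ``effective_extension_m`` is the vertical range available to a hooked
    animal as seen by the depth logger: gangion length minus the device's
    offset from the hook eye.
    """

    gangion_length_m: float = 0.70
    tdr_offset_m: float = 0.10
    threshold_fractions: tuple[float, ...] = (0.5, 1.0)
    baseline_window_s: float = 60.0
    baseline_recalc_interval_s: float = 1800.0
    cessation_gap_s: float = 4.0
    #: shortest supra-threshold run (samples) accepted as a capture onset
    capture_min_run: int = 3
    #: sigma multiple of baseline s.d. flagging a tidal shift across a bout
    tidal_shift_sigma: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.tdr_offset_m < self.gangion_length_m:
            raise ValueError("require 0 < tdr_offset_m < gangion_length_m")
        if not self.threshold_fractions:
            raise ValueError("at least one threshold fraction required")
        for f in self.threshold_fractions:
            if not 0 < f <= 1:
                raise ValueError(f"threshold fraction {f} not in (0, 1]")
        for name in ("baseline_window_s", "baseline_recalc_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cessation_gap_s < 0:
            raise ValueError("cessation_gap_s must be >= 0")
        if self.capture_min_run < 1:
            raise ValueError("capture_min_run must be >= 1")

    @property
    def effective_extension_m(self) -> float:
        return self.gangion_length_m - self.tdr_offset_m

    @property
    def detection_fraction(self) -> float:
        """Most sensitive configured fraction; used for capture detection."""
        return min(self.threshold_fractions)

    @classmethod
    def from_dict(cls, d: dict) -> "GearConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown gear config keys: {sorted(unknown)}")
        if "threshold_fractions" in d:
            d = {**d, "threshold_fractions": tuple(d["threshold_fractions"])}
        return cls(**d)


@dataclass(frozen=True)
class DepthTrace:
    """Uniformly sampled depth series for one hook.

    Parameters
    ----------
    times
        Seconds since trace start, strictly increasing on a constant grid.
    depths
        Depth in metres, positive downward, finite and non-negative.
    device_id
        Identifier of the recording device.
    sample_interval_s
        Grid step in seconds.
    """

    times: np.ndarray
    depths: np.ndarray
    device_id: str = "tdr"
    sample_interval_s: float = 2.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "depths", d)
        if t.ndim != 1 or d.ndim != 1 or t.shape != d.shape:
            raise ValueError("times and depths must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trace must contain at least 2 samples")
        dt = np.diff(t)
        step = self.sample_interval_s
        if step <= 0:
            raise ValueError("sample_interval_s must be > 0")
        if np.any(np.abs(dt - step) > _GRID_RTOL * step):
            i = int(np.argmax(np.abs(dt - step) > _GRID_RTOL * step))
            raise ValueError(
                f"non-uniform time grid at sample {i + 1}: "
                f"step {dt[i]:.6g} s, expected {step:.6g} s"
            )
        if not np.all(np.isfinite(d)):
            i = int(np.argmax(~np.isfinite(d)))
            raise ValueError(f"non-finite depth at sample {i}")
        if np.any(d < 0):
            raise ValueError("depths must be >= 0 (positive-down convention)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0] + self.sample_interval_s)

    def index_at(self, time_s: float) -> int:
        """Index of the sample whose interval [t_i, t_i + dt) covers time_s."""
        i = int(np.floor((time_s - self.times[0]) / self.sample_interval_s))
        if not 0 <= i < len(self):
            raise IndexError(f"time {time_s} s outside trace")
        return i


def _parse_times(raw: pd.Series, path: str) -> np.ndarray:
    """Accept either numeric seconds or ISO-8601 timestamps."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    try:
        stamps = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = int(numeric.isna().idxmax())
        raise TraceReadError(
            f"{path}: time column row {bad + 1} is neither numeric seconds "
            f"nor an ISO-8601 timestamp ({raw.iloc[bad]!r})"
        ) from exc
    return (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy(dtype=float)


def read_trace(
    path,
    *,
    delimiter: str = ",",
    time_column: str = "time",
    depth_column: str = "depth",
    device_id: str | None = None,
    flip_sign: bool = False,
    resample: bool = False,
    max_missing_frac: float = 0.01,
) -> DepthTrace:
    """Read a delimited-text depth trace.

    The file must carry a header row with ``time`` and ``depth`` columns;
    time is either seconds (numeric) or ISO-8601 timestamps. The grid must
    be uniform; set ``resample=True`` to linearly interpolate small gaps
    (up to ``max_missing_frac`` of the grid) onto the nominal grid instead
    of rejecting them.

    Raises
    ------
    TraceReadError
        On missing columns, non-monotone time, or too many missing samples;
        the message names the first offending data row (1-based).
    """
    path = str(path)
    df = pd.read_csv(path, delimiter=delimiter)
    for col in (time_column, depth_column):
        if col not in df.columns:
            raise TraceReadError(f"{path}: missing required column {col!r}")
    times = _parse_times(df[time_column], path)
    depths = pd.to_numeric(df[depth_column], errors="coerce").to_numpy(dtype=float)

    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2  # 1-based data row of the offender
        kind = "duplicated" if diffs[np.argmax(diffs <= 0)] == 0 else "non-monotone"
        raise TraceReadError(f"{path}: {kind} timestamp at data row {row}")

    step = float(np.median(diffs))
    n_expected = int(round((times[-1] - times[0]) / step)) + 1
    n_missing = (n_expected - len(times)) + int(np.isnan(depths).sum())
    if n_missing > 0:
        if n_missing / n_expected > max_missing_frac:
            off = np.abs(diffs - step) > _GRID_RTOL * step
            row = (int(np.argmax(off)) + 2) if off.any() else int(np.isnan(depths).argmax()) + 1
            raise TraceReadError(
                f"{path}: {n_missing}/{n_expected} samples missing "
                f"(> {max_missing_frac:.0%}); first gap near data row {row}"
            )
        if not resample:
            off = np.abs(diffs - step) > _GRID_RTOL * step
            row = (int(np.argmax(off)) + 2) if off.any() else int(np.isnan(depths).argmax()) + 1
            raise TraceReadError(
                f"{path}: non-uniform grid near data row {row}; "
                "pass resample=True to interpolate"
            )
        grid = times[0] + step * np.arange(n_expected)
        ok = ~np.isnan(depths)
        depths = np.interp(grid, times[ok], depths[ok])
        times = grid

    if flip_sign:
        depths = -depths
    if np.median(depths) < 0:
        raise TraceReadError(
            f"{path}: depths are predominantly negative; expected positive-down "
            "metres (pass flip_sign=True for positive-up input)"
        )
    small_neg = (depths < 0) & (depths > -_NEG_CLIP)
    if small_neg.any():
        warnings.warn(
            f"{path}: clipped {int(small_neg.sum())} slightly negative depths to 0",
            stacklevel=2,
        )
        depths = np.where(small_neg, 0.0, depths)

    if device_id is None:
        if "device_id" in df.columns:
            device_id = str(df["device_id"].iloc[0])
        else:
            device_id = path.rsplit("/", 1)[-1].removesuffix(".csv")
    return DepthTrace(
        times=times - times[0],
        depths=depths,
        device_id=device_id,
        sample_interval_s=step,
    )


def write_trace(trace: DepthTrace, path, *, delimiter: str = ",") -> None:
    """Write a trace in the dialect :func:`read_trace` consumes."""
    pd.DataFrame({"time": trace.times, "depth": trace.depths}).to_csv(
        path, sep=delimiter, index=False, float_format="%.6g"
    )
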