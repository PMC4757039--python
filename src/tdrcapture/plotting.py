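"""Single figure: depth trace with baselines and detected bouts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .behaviour import AnalysisResult
from .trace import DepthTrace

__all__ = ["plot_trace"]


def plot_trace(trace: DepthTrace, result: AnalysisResult, path) -> None:
    """Save a trace figure with baseline segments and movement bouts."""
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(trace.times / 60.0, trace.depths, lw=0.5, color="0.3", label="depth")
    for seg in result.schedule:
        ax.hlines(
            seg.baseline_depth_m,
            seg.start_s / 60.0,
            seg.end_s / 60.0,
            color="tab:blue",
            lw=1.5,
        )
    for frac, color in ((0.5, "tab:orange"), (1.0, "tab:red")):
        for bout in result.bouts.get(frac, []):
            ax.axvspan(
                bout.start_s / 60.0, bout.end_s / 60.0, color=color, alpha=0.25
            )
    if result.capture is not None:
        ax.axvline(result.capture.time_s / 60.0, color="k", ls="--", lw=1)
    if result.haul_time_s is not None:
        ax.axvline(result.haul_time_s / 60.0, color="k", ls=":", lw=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("depth (m)")
    ax.invert_yaxis()
    ax.set_title(trace.device_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
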