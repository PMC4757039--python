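import numpy as np
import pytest

from tdrcapture import DepthTrace, GearConfig


@pytest.fixture
def gear() -> GearConfig:
    return GearConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def flat_trace(
    depth: float = 8.0,
    n: int = 900,
    dt: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    device_id: str = "flat",
) -> DepthTrace:
    """Constant-depth trace with optional Gaussian noise."""
    r = np.random.default_rng(seed)
    depths = np.full(n, depth)
    if noise_sd > 0:
        depths = depths + r.normal(0, noise_sd, n)
    return DepthTrace(
        times=dt * np.arange(n),
        depths=np.maximum(depths, 0.0),
        device_id=device_id,
        sample_interval_s=dt,
    )


@pytest.fixture
def flat():
    return flat_trace


def brute_force_bouts(
    times: np.ndarray,
    deviations: np.ndarray,
    thresholds: np.ndarray,
    dt: float,
    cessation_gap_s: float,
) -> list[tuple[float, float]]:
    """Independent per-sample reference for bout detection.

    Walks every sample, labels supra-threshold points (>=), and merges
    consecutive supra samples whose sub-threshold gap is at most the
    cessation gap. Returns (start_s, end_s) pairs with end exclusive.
    """
    bouts: list[list[float]] = []
    last_supra_t = None
    for i in range(len(deviations)):
        if deviations[i] >= thresholds[i]:
            t = float(times[i])
            if last_supra_t is not None and (t - (last_supra_t + dt)) <= cessation_gap_s:
                bouts[-1][1] = t + dt
            else:
                bouts.append([t, t + dt])
            last_supra_t = t
    return [(a, b) for a, b in bouts]
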