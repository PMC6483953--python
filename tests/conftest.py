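import numpy as np
import pytest

from edahab.eda import EdaTrace, ScrEvent
from edahab.synthetic import ScrGenParams


@pytest.fixture
def clean_params():
    """Generator parameters for deterministic, noise-free traces."""
    return ScrGenParams(
        noise_sd_uS=0.0, drift_uS_per_s=0.0, latency_jitter_s=0.0, response_prob=1.0
    )


def brute_force_scr_events(
    trace: EdaTrace,
    backward_window_s: float = 4.0,
    bend_eps_uS_per_s: float = 0.001,
    min_amplitude_uS: float = 0.0,
):
    """Independent SCR-detection oracle: an explicit per-sample scan over
    strict local maxima/minima with the same pairing rule as the detector
    (minimum-value trough in the backward window, latest tie, bends only
    when no trough exists)."""
    x = trace.values_uS
    n = x.size
    dt = 1.0 / trace.rate_hz
    deriv = np.gradient(x, dt)
    maxima = [i for i in range(1, n - 1) if x[i - 1] < x[i] and x[i] > x[i + 1]]
    minima = [i for i in range(1, n - 1) if x[i - 1] > x[i] and x[i] < x[i + 1]]
    window_n = int(round(backward_window_s * trace.rate_hz))
    events = []
    for p in maxima:
        lo = max(0, p - window_n)
        cands = [i for i in minima if lo <= i < p]
        if not cands:
            cands = [i for i in range(lo, p) if abs(deriv[i]) < bend_eps_uS_per_s]
        if not cands:
            continue
        vmin = min(x[i] for i in cands)
        best = max(i for i in cands if x[i] == vmin)
        amp = x[p] - x[best]
        if amp <= 0 or amp < min_amplitude_uS:
            continue
        events.append(
            ScrEvent(trace.start_s + best * dt, trace.start_s + p * dt, float(amp))
        )
    return events


def brute_force_trials_to_habituation(present: list[bool]) -> tuple[int, bool]:
    """Independent habituation oracle: try every candidate score directly."""
    n = len(present)
    for t in range(n - 1):
        if not present[t] and not present[t + 1]:
            return t, False
    return n, True
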