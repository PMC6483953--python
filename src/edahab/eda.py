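"""Skin-conductance trace filtering and SCR peak/trough detection.

The detector mirrors the classic first-derivative algorithm used by
laboratory EDA scoring software: the filtered signal is scanned for peaks
(first-derivative sign changes from positive to negative); for each peak the
algorithm searches backward, within a fixed interval, for the trough or
"bend" that marks the response onset, and the SCR amplitude is the
peak-minus-trough conductance difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import ParameterError

__all__ = [
    "EdaTrace",
    "ScrEvent",
    "lowpass_butterworth",
    "first_derivative",
    "detect_scr_events",
]


@dataclass(frozen=True)
class EdaTrace:
    """Uniformly sampled skin-conductance time series.

    Parameters
    ----------
    values_uS : array of conductance samples in microsiemens.
    rate_hz : sampling rate in samples per second.
    start_s : time of the first sample (seconds).
    """

    values_uS: np.ndarray
    rate_hz: float
    start_s: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values_uS, dtype=float)
        object.__setattr__(self, "values_uS", values)
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")
        if values.ndim != 1 or values.size < 2:
            raise ParameterError("trace must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(values)):
            raise ParameterError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.values_uS.size

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.rate_hz

    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class ScrEvent:
    """One detected skin conductance response: a trough/peak pair.

    ``trough_time_s`` is the response onset (preceding trough or bend),
    ``peak_time_s`` the response maximum; ``amplitude_uS`` is the
    conductance difference between them and is strictly positive.
    """

    trough_time_s: float
    peak_time_s: float
    amplitude_uS: float

    def __post_init__(self):
        if not self.trough_time_s < self.peak_time_s:
            raise ParameterError("trough must precede peak")
        if self.amplitude_uS <= 0:
            raise ParameterError("amplitude must be positive")


def lowpass_butterworth(
    trace: EdaTrace,
    cutoff_hz: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
) -> EdaTrace:
    """Low-pass Butterworth filter (default 10 Hz, 4th order).

    By default the filter is applied forward and backward (zero-phase) so
    detected event times are not delayed by the filter's group delay; the
    effective magnitude response is then the square of the single-pass
    response.  ``zero_phase=False`` gives the causal single-pass filter.
    """
    nyquist = trace.rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=trace.rate_hz, output="sos")
    if zero_phase:
        filtered = _signal.sosfiltfilt(sos, trace.values_uS)
    else:
        # seed the filter state with the first sample so a DC trace passes through
        zi = _signal.sosfilt_zi(sos) * trace.values_uS[0]
        filtered, _ = _signal.sosfilt(sos, trace.values_uS, zi=zi)
    return EdaTrace(filtered, trace.rate_hz, trace.start_s)


def first_derivative(trace: EdaTrace) -> np.ndarray:
    """First derivative of the trace in µS/s.

    Central differences on interior samples, one-sided at the ends; exact on
    linear signals.
    """
    if trace.n_samples < 3:
        raise ParameterError("need at least 3 samples for a derivative")
    return np.gradient(trace.values_uS, 1.0 / trace.rate_hz)


def detect_scr_events(
    trace: EdaTrace,
    backward_window_s: float = 4.0,
    bend_eps_uS_per_s: float = 0.001,
    min_amplitude_uS: float = 0.0,
) -> list[ScrEvent]:
    """Detect SCR peak/trough pairs on an (already low-pass filtered) trace.

    A peak is a sample where the discrete first derivative changes sign from
    positive to negative.  For each peak the algorithm searches backward over
    ``backward_window_s`` seconds for troughs (sign change negative to
    positive) and, when no trough exists in the window, for bends — samples
    whose derivative magnitude is below ``bend_eps_uS_per_s``.  The trough is
    the candidate with minimal conductance (ties broken toward the latest,
    i.e. the one closest to the rise); peaks with no candidate in the window
    are dropped.  Amplitude is peak minus trough and must be positive;
    ``min_amplitude_uS`` lets callers discard sub-threshold pairs early
    (the default 0 keeps every pair).

    Returns events sorted by peak time.  A flat trace yields an empty list.
    """
    if backward_window_s <= 0:
        raise ParameterError("backward_window_s must be positive")
    x = trace.values_uS
    n = x.size
    if n < 3:
        return []
    d = np.diff(x)  # d[i] = x[i+1] - x[i]
    rising = d > 0
    falling = d < 0
    # sample i is a peak when d[i-1] > 0 and d[i] < 0, a trough when reversed
    peak_idx = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    trough_idx = np.flatnonzero(falling[:-1] & rising[1:]) + 1
    if peak_idx.size == 0:
        return []
    deriv = first_derivative(trace)
    bend_mask = np.abs(deriv) < bend_eps_uS_per_s
    window_n = int(round(backward_window_s * trace.rate_hz))
    dt = 1.0 / trace.rate_hz

    events: list[ScrEvent] = []
    for p in peak_idx:
        lo = max(0, p - window_n)
        i0, i1 = np.searchsorted(trough_idx, [lo, p])
        cands = trough_idx[i0:i1]
        if cands.size == 0:
            cands = np.flatnonzero(bend_mask[lo:p]) + lo
        if cands.size == 0:
            continue
        vals = x[cands]
        best = cands[vals == vals.min()][-1]  # latest among minimal-value ties
        amp = x[p] - x[best]
        if amp <= 0 or amp < min_amplitude_uS:
            continue
        events.append(
            ScrEvent(
                trough_time_s=trace.start_s + best * dt,
                peak_time_s=trace.start_s + p * dt,
                amplitude_uS=float(amp),
            )
        )
    return events
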