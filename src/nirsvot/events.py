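"""Event segmentation within occlusion–reperfusion cycles.

Locates, on baseline-normalized series, the start/peak/end of the deoxy- and
reoxygenation curves (10% amplitude threshold), the hyperemia spike after
deflation, the zero-crossing preceding the spike, and the 63%-decay time
after it.  All event times are linearly interpolated between samples, and
ties at equal extrema break to the earliest time.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurveBounds",
    "SpikeResult",
    "detect_curve_bounds",
    "find_spike",
    "zero_crossing_before",
    "decay63_after",
    "DEFAULT_BOUND_THRESHOLD",
    "DEFAULT_DECAY_FRACTION",
    "DEFAULT_SPIKE_HORIZON_S",
]

DEFAULT_BOUND_THRESHOLD = 0.10
DEFAULT_DECAY_FRACTION = 0.63
#: The hyperemia spike is searched within this many seconds of deflation.
DEFAULT_SPIKE_HORIZON_S = 120.0

#: Peak deviations below this are treated as "no event" (flat series).
NOISE_FLOOR = 1e-9


@dataclass(frozen=True)
class CurveBounds:
    """10%-threshold bounds of a deoxy-/reoxygenation curve."""

    start: float
    peak_time: float
    peak_value: float  # signed deviation from the reference level
    end: float
    flag: str = "ok"   # ok | no_event | no_return


@dataclass(frozen=True)
class SpikeResult:
    time: float
    value: float
    flag: str = "ok"   # ok | no_hyperemia


def _window_slice(time: np.ndarray, t_start: float, t_end: float) -> slice:
    i0 = int(np.searchsorted(time, t_start - 1e-9))
    i1 = int(np.searchsorted(time, t_end - 1e-9))
    return slice(i0, i1)


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def detect_curve_bounds(
    time: np.ndarray,
    series: np.ndarray,
    window: tuple[float, float],
    threshold: float = DEFAULT_BOUND_THRESHOLD,
    ref_value: float | None = None,
    noise_floor: float = NOISE_FLOOR,
) -> CurveBounds:
    """Start, peak and end of the dominant excursion within a window.

    The peak is the sample of largest absolute deviation from the local
    pre-event level ``ref_value`` (default: the series value at the window
    start).  The start is the last time before the peak at which the
    absolute deviation is <= ``threshold`` of the peak deviation, the end
    the first such time after it; both are interpolated.  A window whose
    peak deviation is below ``noise_floor`` yields a ``no_event`` result; a
    curve that never returns below threshold ends at the window end
    (``no_return``).  The result is invariant to positive rescaling.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sl = _window_slice(time, *window)
    t = time[sl]
    x = series[sl]
    if t.size < 2:
        raise ValueError("window contains fewer than 2 samples")
    if ref_value is None:
        ref_value = float(x[0])
    dev = x - ref_value
    absdev = np.abs(dev)
    ipk = int(np.argmax(absdev))  # argmax takes the earliest of equal peaks
    peak = float(absdev[ipk])
    if peak < noise_floor:
        return CurveBounds(float(t[0]), float(t[0]), 0.0, float(t[-1]), "no_event")
    level = threshold * peak

    # start: last crossing of |dev| up through `level` before the peak
    start = float(t[0])
    below = np.flatnonzero(absdev[: ipk + 1] <= level)
    if below.size:
        i = int(below[-1])
        if i < ipk:
            start = _interp_crossing(t[i], t[i + 1], absdev[i], absdev[i + 1], level)
        else:
            start = float(t[i])

    # end: first crossing of |dev| down through `level` after the peak
    flag = "ok"
    below_after = np.flatnonzero(absdev[ipk:] <= level)
    if below_after.size:
        j = ipk + int(below_after[0])
        end = _interp_crossing(t[j - 1], t[j], absdev[j - 1], absdev[j], level) if j > ipk else float(t[j])
    else:
        end = float(t[-1])
        flag = "no_return"

    return CurveBounds(start, float(t[ipk]), float(dev[ipk]), end, flag)


def find_spike(
    time: np.ndarray,
    series: np.ndarray,
    reperfusion_window: tuple[float, float],
    horizon_s: float = DEFAULT_SPIKE_HORIZON_S,
    min_amplitude: float = 0.0,
) -> SpikeResult:
    """Hyperemia spike: the maximum within the first ``horizon_s`` of reperfusion.

    A maximum of the normalized series at or below ``min_amplitude`` means
    no detectable overshoot of baseline — legal for venous-only pressures —
    and is flagged ``no_hyperemia``.  A positive ``min_amplitude``
    (typically the baseline noise scale) keeps the downstream spike-relative
    crossings well conditioned: their times are meaningless on a near-flat
    trace.  Equal maxima break to the earlier time.
    """
    t0, t1 = reperfusion_window
    sl = _window_slice(time, t0, min(t1, t0 + horizon_s))
    t = time[sl]
    x = series[sl]
    if t.size == 0:
        raise ValueError("empty reperfusion window")
    ipk = int(np.argmax(x))
    value = float(x[ipk])
    flag = "ok" if value > max(min_amplitude, 0.0) else "no_hyperemia"
    return SpikeResult(float(t[ipk]), value, flag)


def zero_crossing_before(
    time: np.ndarray,
    series: np.ndarray,
    spike_time: float,
    window_start: float,
) -> tuple[float, str]:
    """Time of the sign change nearest to the spike on its left.

    Linear interpolation between the bracketing samples.  If the series
    never changes sign in ``[window_start, spike_time]`` the window start is
    returned with a ``no_crossing`` flag (and a warning).
    """
    i0 = int(np.searchsorted(time, window_start - 1e-9))
    i1 = int(np.searchsorted(time, spike_time + 1e-9))
    x = series[i0:i1]
    t = time[i0:i1]
    if t.size < 2:
        return float(window_start), "no_crossing"
    sign = np.sign(x)
    # treat exact zeros as crossings at the sample itself
    change = np.flatnonzero((sign[:-1] * sign[1:] < 0) | (sign[:-1] == 0))
    if change.size == 0:
        if sign[-1] == 0:
            return float(t[-1]), "ok"
        warnings.warn(
            "no zero-crossing before hyperemia spike; using window start",
            stacklevel=2,
        )
        return float(window_start), "no_crossing"
    i = int(change[-1])  # nearest crossing on the left of the spike
    if sign[i] == 0:
        return float(t[i]), "ok"
    return _interp_crossing(t[i], t[i + 1], x[i], x[i + 1], 0.0), "ok"


def decay63_after(
    time: np.ndarray,
    series: np.ndarray,
    spike_time: float,
    spike_value: float,
    phase_end: float,
    fraction: float = DEFAULT_DECAY_FRACTION,
) -> tuple[float, str]:
    """First time after the spike at which ``fraction`` of its amplitude is lost.

    I.e. the first crossing below ``(1 − fraction) * spike_value``
    (interpolated).  If the threshold is never reached before ``phase_end``
    that time is returned with a ``no_decay`` flag.
    """
    if spike_value <= 0:
        raise ValueError("decay63_after requires a positive spike value")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    level = (1.0 - fraction) * spike_value
    i0 = int(np.searchsorted(time, spike_time + 1e-9))
    i1 = int(np.searchsorted(time, phase_end - 1e-9))
    x = series[i0:i1]
    t = time[i0:i1]
    below = np.flatnonzero(x <= level)
    if below.size == 0:
        return float(phase_end), "no_decay"
    j = int(below[0])
    if j == 0:
        return float(t[0]), "ok"
    return _interp_crossing(t[j - 1], t[j], x[j - 1], x[j], level), "ok"
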