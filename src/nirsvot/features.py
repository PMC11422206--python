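"""Per-cycle hemodynamic features and per-session averaging.

For every occlusion+reperfusion cycle and channel the module computes the
extrema, signed occlusion AUC (trapezoid on the baseline-normalized signal),
63% time constant, and 30-s deoxy-/reoxygenation slopes; on the tissue
saturation index it additionally quantifies post-occlusive reactive
hyperemia (spike value, AUC from the pre-spike zero-crossing to the 63%
post-spike decay, and the 63% rise time).  The three cycles of a session
are averaged, skipping flagged cycles, into one value per parameter.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import events
from .protocol import ProtocolSchedule
from .recording import NIRSRecording

__all__ = [
    "CycleFeatures",
    "SessionSummary",
    "phase_extrema",
    "occlusion_auc",
    "porh_auc",
    "time_constant_63",
    "slope_30s",
    "average_cycles",
    "compute_abi",
    "extract_cycle_features",
    "extract_session_features",
    "DEFAULT_CHANNELS",
    "TAU_CHANNELS",
    "SLOPE_WINDOW_S",
]

log = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("tsi", "o2hb", "hhb", "dhb")
#: Channels for which the occlusion time constant is reported by default:
#: TSI on its downward deviation, HHb on its upward one.
TAU_CHANNELS = ("tsi", "hhb")
SLOPE_WINDOW_S = 30.0
#: PORH metrics are reported on the saturation channel.
PORH_CHANNEL = "tsi"
#: Minimum TSI overshoot (%) counted as a detectable hyperemia spike —
#: below the ~0.5% baseline noise of the device class, spike-relative
#: crossing times are ill conditioned.
PORH_MIN_SPIKE = 0.2


def _slice(time: np.ndarray, t0: float, t1: float, closed: bool = False) -> slice:
    """Samples with t0 <= t < t1 (or <= t1 when ``closed``)."""
    i0 = int(np.searchsorted(time, t0 - 1e-9))
    i1 = int(np.searchsorted(time, t1 + (1e-9 if closed else -1e-9)))
    return slice(i0, i1)


def phase_extrema(
    time: np.ndarray, series: np.ndarray, window: tuple[float, float]
) -> tuple[float, float, float, float]:
    """(min, max, t_min, t_max) of the series restricted to the window."""
    sl = _slice(time, *window, closed=True)
    x = series[sl]
    t = time[sl]
    if x.size == 0:
        raise ValueError(f"empty window {window}")
    imin = int(np.argmin(x))
    imax = int(np.argmax(x))
    return float(x[imin]), float(x[imax]), float(t[imin]), float(t[imax])


def occlusion_auc(
    time: np.ndarray, series: np.ndarray, window: tuple[float, float]
) -> float:
    """Signed trapezoidal integral of the normalized signal over the window.

    Negative for the deoxygenation of TSI/O2Hb, positive for HHb.  The
    closing boundary sample is included so the integral spans the full
    window duration.
    """
    sl = _slice(time, *window, closed=True)
    if sl.stop - sl.start < 2:
        raise ValueError("window shorter than 2 samples")
    return float(np.trapezoid(series[sl], time[sl]))


def porh_auc(
    time: np.ndarray, series: np.ndarray, t_start: float, t_end: float
) -> float:
    """Trapezoidal integral between two (possibly inter-sample) times."""
    if t_end < t_start:
        raise ValueError("inverted integration bounds")
    if t_end == t_start:
        return 0.0
    inner = _slice(time, t_start, t_end, closed=False)
    # interpolated endpoint ordinates make the bounds exact
    ts = np.concatenate(([t_start], time[inner], [t_end]))
    ys = np.concatenate(
        ([np.interp(t_start, time, series)], series[inner], [np.interp(t_end, time, series)])
    )
    keep = np.concatenate(([True], np.diff(ts) > 1e-12))
    return float(np.trapezoid(ys[keep], ts[keep]))


def time_constant_63(
    time: np.ndarray,
    series: np.ndarray,
    window: tuple[float, float],
    fraction: float = 0.63,
) -> tuple[float, str]:
    """Time from the window start until 63% of the extreme deviation.

    The extreme deviation is the largest |value| of the normalized series in
    the window (downward for TSI, upward for HHb — the sign is taken from
    the data).  The crossing is linearly interpolated.  Returns
    ``(tau, flag)``; a near-zero extreme deviation is flagged.
    """
    sl = _slice(time, *window, closed=True)
    x = series[sl]
    t = time[sl]
    if x.size < 2:
        raise ValueError("window shorter than 2 samples")
    ipk = int(np.argmax(np.abs(x)))
    extreme = x[ipk]
    if abs(extreme) < events.NOISE_FLOOR:
        return math.nan, "no_event"
    level = fraction * extreme
    if extreme > 0:
        hit = np.flatnonzero(x >= level)
    else:
        hit = np.flatnonzero(x <= level)
    j = int(hit[0])
    if j == 0:
        return 0.0, "ok"
    t_cross = events._interp_crossing(t[j - 1], t[j], x[j - 1], x[j], level)
    return float(t_cross - window[0]), "ok"


def slope_30s(
    time: np.ndarray,
    series: np.ndarray,
    curve_start_time: float,
    window_s: float = SLOPE_WINDOW_S,
) -> tuple[float, str]:
    """OLS slope of the series over the first 30 s of a curve.

    Flagged (NaN) when fewer than ``window_s`` seconds of data follow the
    curve start.
    """
    if curve_start_time + window_s > time[-1] + 1e-9:
        return math.nan, "insufficient_data"
    sl = _slice(time, curve_start_time, curve_start_time + window_s, closed=True)
    t = time[sl]
    x = series[sl]
    if t.size < 3:
        return math.nan, "insufficient_data"
    slope = np.polyfit(t, x, 1)[0]
    return float(slope), "ok"


def compute_abi(ankle_sbps, brachial_sbps) -> float:
    """Ankle–brachial index: highest ankle over highest brachial pressure."""
    ankle = list(ankle_sbps)
    brachial = list(brachial_sbps)
    if not ankle or not brachial:
        raise ValueError("pressure lists must be non-empty")
    if min(ankle) <= 0 or min(brachial) <= 0:
        raise ValueError("pressures must be positive")
    return max(ankle) / max(brachial)


@dataclass
class CycleFeatures:
    """All extracted parameters of one occlusion+reperfusion cycle."""

    cycle: int
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def ok(self, name: str) -> bool:
        v = self.values.get(name)
        return v is not None and np.isfinite(v) and self.flags.get(name, "ok") == "ok"


@dataclass
class SessionSummary:
    """Cycle-averaged parameters of one subject-session."""

    subject_id: str
    group: str
    session: str
    values: dict[str, float]
    counts: dict[str, int]

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "group": self.group, "session": self.session}
        row.update(self.values)
        row["n_cycles"] = min(self.counts.values()) if self.counts else 0
        return row


def extract_cycle_features(
    rec: NIRSRecording,
    schedule: ProtocolSchedule,
    cycle_index: int,
    channels=DEFAULT_CHANNELS,
    threshold: float = events.DEFAULT_BOUND_THRESHOLD,
    decay_fraction: float = events.DEFAULT_DECAY_FRACTION,
    spike_horizon_s: float = events.DEFAULT_SPIKE_HORIZON_S,
) -> CycleFeatures:
    """Extract every reported parameter for one cycle of a normalized recording.

    The deoxygenation-curve search starts ``cuff_ramp_s`` after inflation;
    the reoxygenation curve is referenced to the occlusion-end level and
    searched from deflation onward.
    """
    if not rec.normalized:
        raise ValueError("recording must be baseline-normalized first")
    occ, rep = schedule.cycles()[cycle_index]
    ramp = schedule.cuff_ramp_s
    t = rec.time
    cf = CycleFeatures(cycle=cycle_index + 1)

    for ch in channels:
        x = rec.channel(ch)
        lo, hi, _, _ = phase_extrema(t, x, (occ.t_start, rep.t_end))
        cf.values[f"{ch}_min"] = lo
        cf.values[f"{ch}_max"] = hi
        cf.values[f"{ch}_auc"] = occlusion_auc(t, x, (occ.t_start, occ.t_end))

        # deoxygenation curve: referenced to the pre-inflation level,
        # searched after the cuff ramp
        ref_deoxy = float(np.interp(occ.t_start, t, x))
        deoxy = events.detect_curve_bounds(
            t, x, (occ.t_start + ramp, occ.t_end), threshold, ref_value=ref_deoxy
        )
        sl_d, fl = slope_30s(t, x, deoxy.start)
        cf.values[f"{ch}_slope_deoxy"] = sl_d
        # "no_return" just means the curve plateaus inside the window — the
        # slope at its start is still well defined
        cf.flags[f"{ch}_slope_deoxy"] = fl if deoxy.flag != "no_event" else deoxy.flag

        # reoxygenation curve: referenced to the occlusion-end level
        ref_reoxy = float(np.interp(rep.t_start, t, x))
        reoxy = events.detect_curve_bounds(
            t, x, (rep.t_start, rep.t_end), threshold, ref_value=ref_reoxy
        )
        sl_r, fl = slope_30s(t, x, reoxy.start)
        cf.values[f"{ch}_slope_reoxy"] = sl_r
        cf.flags[f"{ch}_slope_reoxy"] = fl if reoxy.flag != "no_event" else reoxy.flag

        if ch in TAU_CHANNELS:
            tau, fl = time_constant_63(t, x, (occ.t_start, occ.t_end))
            cf.values[f"{ch}_tau"] = tau
            cf.flags[f"{ch}_tau"] = fl

        if ch == PORH_CHANNEL:
            spike = events.find_spike(
                t, x, (rep.t_start, rep.t_end), spike_horizon_s,
                min_amplitude=PORH_MIN_SPIKE,
            )
            if spike.flag != "ok":
                for name in ("tsi_max_porh", "tsi_auc_porh", "tsi_tau_porh"):
                    cf.values[name] = math.nan
                    cf.flags[name] = "no_hyperemia"
            else:
                cf.values["tsi_max_porh"] = spike.value
                cf.flags["tsi_max_porh"] = "ok"
                zc, zc_flag = events.zero_crossing_before(t, x, spike.time, rep.t_start)
                d63, d_flag = events.decay63_after(
                    t, x, spike.time, spike.value, rep.t_end, decay_fraction
                )
                cf.values["tsi_auc_porh"] = porh_auc(t, x, zc, d63)
                cf.flags["tsi_auc_porh"] = (
                    "ok" if zc_flag == "ok" and d_flag == "ok" else f"{zc_flag}/{d_flag}"
                )
                # PORH rise time: reoxy start to 63% of the spike amplitude
                # above the occlusion-end level
                amp = spike.value - ref_reoxy
                level = ref_reoxy + decay_fraction * amp
                sl2 = _slice(t, reoxy.start, spike.time, closed=True)
                hit = np.flatnonzero(x[sl2] >= level)
                if hit.size and amp > 0:
                    j = sl2.start + int(hit[0])
                    if j == sl2.start:
                        t63 = t[j]
                    else:
                        t63 = events._interp_crossing(
                            t[j - 1], t[j], x[j - 1], x[j], level
                        )
                    cf.values["tsi_tau_porh"] = float(t63 - reoxy.start)
                    cf.flags["tsi_tau_porh"] = "ok"
                else:
                    cf.values["tsi_tau_porh"] = math.nan
                    cf.flags["tsi_tau_porh"] = "no_rise"
                cf.values["tsi_zero_cross"] = zc
                cf.values["tsi_decay63"] = d63
    return cf


def average_cycles(
    cycles: list[CycleFeatures],
    subject_id: str = "",
    group: str = "",
    session: str = "",
) -> SessionSummary:
    """Arithmetic mean per parameter over the non-flagged cycles.

    A parameter flagged (or NaN) in every cycle becomes a missing value and
    is logged; the count of contributing cycles is kept per parameter.
    """
    if not cycles:
        raise ValueError("no cycles to average")
    names: list[str] = []
    for c in cycles:
        for k in c.values:
            if k not in names:
                names.append(k)
    values: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name in names:
        good = [c.values[name] for c in cycles if name in c.values and c.ok(name)]
        counts[name] = len(good)
        if good:
            values[name] = float(np.mean(good))
        else:
            values[name] = math.nan
            log.info(
                "%s %s: parameter %r flagged in all cycles; reported missing",
                subject_id, session, name,
            )
    return SessionSummary(subject_id, group, session, values, counts)


def extract_session_features(
    rec: NIRSRecording,
    schedule: ProtocolSchedule,
    subject_id: str = "",
    group: str = "",
    session: str = "",
    channels=DEFAULT_CHANNELS,
    threshold: float = events.DEFAULT_BOUND_THRESHOLD,
    decay_fraction: float = events.DEFAULT_DECAY_FRACTION,
    spike_horizon_s: float = events.DEFAULT_SPIKE_HORIZON_S,
) -> tuple[SessionSummary, list[CycleFeatures]]:
    """All cycles of one normalized recording, plus their average."""
    cycles = [
        extract_cycle_features(rec, schedule, k, channels,
                               threshold, decay_fraction, spike_horizon_s)
        for k in range(len(schedule.cycles()))
    ]
    return average_cycles(cycles, subject_id, group, session), cycles
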