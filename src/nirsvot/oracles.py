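"""Continuous-time reference values for the feature-extraction pipeline.

Given the noise-free analytic channel model of a simulated session, this
module computes every reported parameter by root-finding, quadrature and
dense evaluation of the closed-form curves — never touching the sampled,
filtered extraction path.  Agreement between the two routes validates the
discrete pipeline against the generative ground truth.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .features import SLOPE_WINDOW_S, TAU_CHANNELS, DEFAULT_CHANNELS, PORH_MIN_SPIKE
from .simulate import AnalyticChannels

__all__ = ["oracle_cycle_features", "compare_cycle_to_oracle"]

#: Parameter-name suffixes holding event times (seconds) rather than values.
TIME_SUFFIXES = ("_tau", "tau_porh", "zero_cross", "decay63")

_DENSE_DT = 0.01  # s; dense-grid resolution for extrema/bracketing


def _scalar(f):
    return lambda t: float(f(np.array([t]))[0])


def _bracketed_root(f, grid_t, grid_y, level, sign_from_below=True):
    """First grid interval crossing `level`, refined with brentq."""
    if sign_from_below:
        hit = np.flatnonzero(grid_y >= level)
    else:
        hit = np.flatnonzero(grid_y <= level)
    if hit.size == 0:
        return None
    j = int(hit[0])
    if j == 0:
        return float(grid_t[0])
    g = lambda t: f(t) - level
    a, b = grid_t[j - 1], grid_t[j]
    if g(a) * g(b) > 0:
        return float(b)
    return float(brentq(g, a, b, xtol=1e-6))


def oracle_cycle_features(
    model: AnalyticChannels,
    cycle_index: int,
    channels=DEFAULT_CHANNELS,
    threshold: float = 0.10,
    decay_fraction: float = 0.63,
    spike_horizon_s: float = 120.0,
) -> dict[str, float]:
    """Reference parameter values for one cycle of the analytic model.

    Returns the same parameter names as the discrete extractor, plus the
    PORH boundary times ``tsi_zero_cross`` / ``tsi_decay63``.  Parameters
    whose defining event does not exist (e.g. PORH at venous-only pressure)
    are returned as NaN.
    """
    cyc = model.cycles[cycle_index]
    ramp = model.schedule.cuff_ramp_s
    out: dict[str, float] = {}

    t_occ = np.arange(cyc.t0, cyc.t1 + _DENSE_DT / 2, _DENSE_DT)
    t_rep = np.arange(cyc.t1, cyc.t2 + _DENSE_DT / 2, _DENSE_DT)
    t_cycle = np.arange(cyc.t0, cyc.t2 + _DENSE_DT / 2, _DENSE_DT)

    for ch in channels:
        f_vec = model.delta(ch)
        f = _scalar(f_vec)
        y_occ = f_vec(t_occ)
        y_rep = f_vec(t_rep)
        y_cycle = f_vec(t_cycle)

        out[f"{ch}_min"] = float(np.min(y_cycle))
        out[f"{ch}_max"] = float(np.max(y_cycle))
        out[f"{ch}_auc"] = quad(
            f, cyc.t0, cyc.t1, points=[cyc.t0 + ramp], limit=200
        )[0]

        # deoxygenation curve start at the 10% threshold (search after ramp)
        mask = t_occ >= cyc.t0 + ramp - 1e-9
        dev = np.abs(y_occ[mask] - f(cyc.t0))
        peak = float(np.max(dev))
        if peak > 1e-9:
            ref = f(cyc.t0)
            g = lambda t: abs(f(t) - ref)
            start = _bracketed_root(
                g, t_occ[mask], dev, threshold * peak, sign_from_below=True
            )
            out[f"{ch}_slope_deoxy"] = _dense_ols_slope(f_vec, start, SLOPE_WINDOW_S)
            out[f"{ch}_slope_deoxy_sens"] = _slope_sensitivity(f_vec, start)
        else:
            out[f"{ch}_slope_deoxy"] = math.nan
            out[f"{ch}_slope_deoxy_sens"] = math.nan

        # reoxygenation curve start, referenced to the occlusion-end level
        ref_r = f(cyc.t1)
        dev_r = np.abs(y_rep - ref_r)
        peak_r = float(np.max(dev_r))
        if peak_r > 1e-9:
            ipk = int(np.argmax(dev_r))
            g = lambda t: abs(f(t) - ref_r)
            start_r = _bracketed_root(
                g, t_rep[: ipk + 1], dev_r[: ipk + 1], threshold * peak_r
            )
            out[f"{ch}_slope_reoxy"] = _dense_ols_slope(f_vec, start_r, SLOPE_WINDOW_S)
            out[f"{ch}_slope_reoxy_sens"] = _slope_sensitivity(f_vec, start_r)
        else:
            start_r = None
            out[f"{ch}_slope_reoxy"] = math.nan
            out[f"{ch}_slope_reoxy_sens"] = math.nan

        if ch in TAU_CHANNELS:
            ipk = int(np.argmax(np.abs(y_occ)))
            extreme = y_occ[ipk]
            if abs(extreme) > 1e-9:
                level = decay_fraction * extreme
                tau = _bracketed_root(
                    f, t_occ, y_occ, level, sign_from_below=extreme > 0
                )
                out[f"{ch}_tau"] = tau - cyc.t0
            else:
                out[f"{ch}_tau"] = math.nan

        if ch == "tsi":
            horizon = t_rep <= cyc.t1 + spike_horizon_s + 1e-9
            isp = int(np.argmax(y_rep[horizon]))
            spike_t = float(t_rep[horizon][isp])
            # parabolic refinement of the smooth spike apex
            spike_t = _refine_max(f, spike_t, _DENSE_DT)
            spike_v = f(spike_t)
            if spike_v <= PORH_MIN_SPIKE:
                for name in ("tsi_max_porh", "tsi_auc_porh", "tsi_tau_porh",
                             "tsi_zero_cross", "tsi_decay63"):
                    out[name] = math.nan
                continue
            out["tsi_max_porh"] = spike_v
            pre = t_rep <= spike_t
            zc = _bracketed_root(f, t_rep[pre], y_rep[pre], 0.0, sign_from_below=True)
            zc = cyc.t1 if zc is None else zc
            post = t_rep >= spike_t
            d63 = _bracketed_root(
                f, t_rep[post], y_rep[post], (1 - decay_fraction) * spike_v,
                sign_from_below=False,
            )
            d63 = cyc.t2 if d63 is None else d63
            out["tsi_zero_cross"] = zc
            out["tsi_decay63"] = d63
            out["tsi_auc_porh"] = quad(f, zc, d63, limit=200)[0]
            # rise time from reoxy start to 63% of the spike amplitude
            if start_r is not None:
                amp = spike_v - ref_r
                level = ref_r + decay_fraction * amp
                seg = (t_rep >= start_r) & (t_rep <= spike_t)
                t63 = _bracketed_root(f, t_rep[seg], y_rep[seg], level)
                out["tsi_tau_porh"] = (t63 - start_r) if t63 is not None else math.nan
            else:
                out["tsi_tau_porh"] = math.nan
    return out


def _dense_ols_slope(f_vec, start: float, window_s: float) -> float:
    t = np.arange(start, start + window_s + 1e-9, 0.005)
    y = f_vec(t)
    return float(np.polyfit(t, y, 1)[0])


def _slope_sensitivity(f_vec, start: float, dt: float = 0.1) -> float:
    """Slope change produced by shifting the window start by one sample."""
    s0 = _dense_ols_slope(f_vec, start, SLOPE_WINDOW_S)
    return max(
        abs(_dense_ols_slope(f_vec, start + dt, SLOPE_WINDOW_S) - s0),
        abs(_dense_ols_slope(f_vec, start - dt, SLOPE_WINDOW_S) - s0),
    )


def compare_cycle_to_oracle(
    pipeline_values: dict[str, float],
    oracle_values: dict[str, float],
    amplitude_scale: float,
) -> dict[str, float]:
    """Summarize pipeline-vs-oracle discrepancies for one cycle.

    Returns the largest time error (s), the largest relative value error
    (extrema and AUCs, with ``amplitude_scale`` as the floor for near-zero
    parameters), the largest slope error expressed as a multiple of its
    allowance max(0.1% of the oracle slope, the one-sample-shift
    sensitivity), and the number of event-flag mismatches.
    """
    max_time = 0.0
    max_value_rel = 0.0
    max_slope_ratio = 0.0
    flag_mismatches = 0
    for name, ov in oracle_values.items():
        if name.endswith("_sens"):
            continue
        pv = pipeline_values.get(name, math.nan)
        o_nan, p_nan = not np.isfinite(ov), not np.isfinite(pv)
        if o_nan and p_nan:
            continue
        if o_nan != p_nan:
            flag_mismatches += 1
            continue
        d = abs(pv - ov)
        if name.endswith(TIME_SUFFIXES):
            max_time = max(max_time, d)
        elif "slope" in name:
            sens = oracle_values.get(f"{name}_sens", 0.0)
            allowance = max(1e-3 * abs(ov), sens)
            if allowance > 0:
                max_slope_ratio = max(max_slope_ratio, d / allowance)
        else:
            max_value_rel = max(max_value_rel, d / max(abs(ov), amplitude_scale))
    return {
        "max_time_error_s": max_time,
        "max_value_rel_error": max_value_rel,
        "max_slope_error_ratio": max_slope_ratio,
        "flag_mismatches": flag_mismatches,
    }


def _refine_max(f, t0: float, dt: float) -> float:
    ya, yb, yc = f(t0 - dt), f(t0), f(t0 + dt)
    denom = ya - 2 * yb + yc
    if denom >= 0 or abs(denom) < 1e-15:
        return t0
    return t0 + 0.5 * dt * (ya - yc) / denom
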