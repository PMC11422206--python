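"""Signal conditioning for muscle-oximetry traces.

Pipeline order used throughout the package: zero-phase low-pass filtering of
every channel, then baseline normalization (subtraction of the mean over the
central-baseline window), after which all signals are deviations from rest.
"""
from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .recording import NIRSRecording, ALL_CHANNELS

__all__ = [
    "FormatError",
    "read_nirs_csv",
    "write_nirs_csv",
    "lowpass_zero_phase",
    "normalize_to_baseline",
    "compute_tsi",
    "compute_delta_hb",
    "DEFAULT_FILTER_ORDER",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_BASELINE_WINDOW",
]

log = logging.getLogger(__name__)

DEFAULT_FILTER_ORDER = 10
DEFAULT_CUTOFF_HZ = 0.8
#: Central ten minutes of the 15-min baseline, [150 s, 750 s).
DEFAULT_BASELINE_WINDOW = (150.0, 750.0)

#: Longest gap (s) repaired by linear interpolation before filtering.
MAX_GAP_S = 0.5


class FormatError(ValueError):
    """Malformed input file (missing column, non-numeric cell, empty)."""


def read_nirs_csv(
    path,
    column_map: dict[str, str] | None = None,
    sampling_rate: float = 10.0,
    sep: str | None = None,
) -> NIRSRecording:
    """Read a delimited-text recording into an :class:`NIRSRecording`.

    ``column_map`` maps canonical names (``time``, ``o2hb``, ``hhb``,
    ``tsi``) to the file's column headers.  A missing ``tsi`` column is
    derived from the concentration channels via :func:`compute_tsi` (the
    choice is logged).  Non-uniform time grids are resampled to
    ``sampling_rate`` by linear interpolation with a warning; gaps up to
    ``MAX_GAP_S`` are repaired, longer gaps fail the recording.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if sep is None:
        sep = _sniff_delimiter(path)
    try:
        # round_trip parsing keeps write->read lossless at double precision
        df = pd.read_csv(path, sep=sep, comment="#",
                         float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"{path}: unreadable file ({exc})") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    cmap = {"time": "time_s", "o2hb": "o2hb", "hhb": "hhb", "tsi": "tsi"}
    if column_map:
        cmap.update(column_map)

    def col(name: str, required: bool = True) -> np.ndarray | None:
        src = cmap[name]
        if src not in df.columns:
            if required:
                raise FormatError(f"{path}: missing column {src!r} (for {name!r})")
            return None
        vals = pd.to_numeric(df[src], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals) & df[src].notna().to_numpy())
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric value in column {src!r}, row {bad[0] + 2}"
            )
        return vals

    time = col("time")
    o2hb = col("o2hb")
    hhb = col("hhb")
    tsi = col("tsi", required=False)
    derived_tsi = tsi is None
    if derived_tsi:
        log.info("%s: no TSI column; deriving TSI from concentration channels", path)
        tsi = compute_tsi(o2hb, hhb)

    dt_nom = 1.0 / sampling_rate
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    if np.max(np.abs(dt - dt_nom)) > 1e-6:
        if np.max(dt) > MAX_GAP_S + dt_nom / 2:
            raise FormatError(
                f"{path}: gap of {np.max(dt):.2f} s exceeds the "
                f"{MAX_GAP_S} s interpolation limit"
            )
        warnings.warn(
            f"{path}: non-uniform time grid; resampling to {sampling_rate} Hz "
            "by linear interpolation",
            stacklevel=2,
        )
        grid = time[0] + dt_nom * np.arange(int(round((time[-1] - time[0]) / dt_nom)) + 1)
        o2hb = np.interp(grid, time, o2hb)
        hhb = np.interp(grid, time, hhb)
        tsi = np.interp(grid, time, tsi)
        time = grid

    # flagged (NaN) samples: repair short gaps only
    for arr, name in ((o2hb, "o2hb"), (hhb, "hhb"), (tsi, "tsi")):
        nan = ~np.isfinite(arr)
        if nan.any():
            runs = _nan_run_lengths(nan)
            if runs.max() * dt_nom > MAX_GAP_S:
                raise FormatError(
                    f"{path}: missing-data gap in {name!r} longer than {MAX_GAP_S} s"
                )
            arr[nan] = np.interp(time[nan], time[~nan], arr[~nan])

    return NIRSRecording(
        time=time,
        o2hb=o2hb,
        hhb=hhb,
        tsi=tsi,
        sampling_rate=sampling_rate,
        meta={"source": str(path), "tsi_derived": derived_tsi},
    )


def _sniff_delimiter(path: Path) -> str:
    """First non-comment line decides between comma and tab."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty file")


def _nan_run_lengths(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.array([0])
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return edges[1::2] - edges[::2]


def write_nirs_csv(rec: NIRSRecording, path, provenance: dict | None = None) -> None:
    """Write a recording as CSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    lines = [f"# nirsvot recording; sampling_rate_hz={rec.sampling_rate:g}"]
    if rec.normalized and rec.baseline_window is not None:
        lines.append(
            f"# normalized=1; baseline_window_s="
            f"[{rec.baseline_window[0]:g},{rec.baseline_window[1]:g})"
        )
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        # %.17g round-trips doubles exactly, so write->read is lossless
        rec.to_frame().to_csv(fh, index=False, lineterminator="\n",
                              float_format="%.17g")


def lowpass_zero_phase(
    rec: NIRSRecording,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> NIRSRecording:
    """Zero-phase low-pass Butterworth smoothing of every channel.

    The filter of the given ``order`` is applied forward and backward
    (``sosfiltfilt``), so the net magnitude response is the squared
    Butterworth response and the group delay is zero.  DC gain is exactly 1.
    Odd-reflection padding of 3x the filter length controls edge transients;
    records shorter than that padding are rejected.
    """
    if not rec.sampling_rate > 2 * cutoff_hz:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = butter(order, cutoff_hz, btype="low", fs=rec.sampling_rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(rec) <= padlen:
        raise ValueError(
            f"record of {len(rec)} samples too short for filter padding ({padlen})"
        )
    out = {}
    for name, sig in rec.channels():
        out[name] = sosfiltfilt(sos, sig, padtype="odd", padlen=padlen)
    meta = dict(rec.meta)
    meta["filter"] = {"order": order, "cutoff_hz": cutoff_hz, "zero_phase": True}
    return rec.copy_with(o2hb=out["o2hb"], hhb=out["hhb"], tsi=out["tsi"], meta=meta)


def normalize_to_baseline(
    rec: NIRSRecording, window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
) -> NIRSRecording:
    """Express every channel as the deviation from its baseline-window mean.

    The window is half-open ``[t_start, t_end)``.  Normalizing an already
    normalized recording is a contract error, not an idempotent no-op.
    """
    if rec.normalized:
        raise ValueError("recording is already normalized")
    t0, t1 = window
    if t0 < rec.time[0] - 1e-9 or t1 > rec.time[-1] + 1.0 / rec.sampling_rate + 1e-9:
        raise ValueError(f"baseline window [{t0}, {t1}) outside recording")
    sl = rec.window_slice(t0, t1)
    out = {name: sig - sig[sl].mean() for name, sig in rec.channels()}
    return rec.copy_with(
        o2hb=out["o2hb"],
        hhb=out["hhb"],
        tsi=out["tsi"],
        normalized=True,
        baseline_window=(float(t0), float(t1)),
    )


def compute_tsi(o2hb: np.ndarray, hhb: np.ndarray) -> np.ndarray:
    """Tissue saturation index 100*O2Hb/(O2Hb+HHb) in percent.

    Requires absolute (pre-normalization) pools.  Samples with a zero
    denominator are flagged as NaN rather than raising.
    """
    o2hb = np.asarray(o2hb, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if o2hb.shape != hhb.shape:
        raise ValueError("o2hb and hhb must have the same shape")
    denom = o2hb + hhb
    with np.errstate(divide="ignore", invalid="ignore"):
        tsi = np.where(denom != 0, 100.0 * o2hb / denom, np.nan)
    return tsi


def compute_delta_hb(o2hb: np.ndarray, hhb: np.ndarray) -> np.ndarray:
    """Hemoglobin difference O2Hb − HHb (elementwise)."""
    o2hb = np.asarray(o2hb, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if o2hb.shape != hhb.shape:
        raise ValueError("o2hb and hhb must have the same shape")
    return o2hb - hhb
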