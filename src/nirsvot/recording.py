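"""In-memory container for a multichannel muscle-oximetry recording."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["NIRSRecording", "CONCENTRATION_CHANNELS", "ALL_CHANNELS"]

#: Hemoglobin-concentration channels (device units); TSI is a saturation in %.
CONCENTRATION_CHANNELS = ("o2hb", "hhb")
ALL_CHANNELS = ("o2hb", "hhb", "tsi")


@dataclass
class NIRSRecording:
    """Uniformly sampled oxy-/deoxyhemoglobin and tissue-saturation traces.

    ``o2hb`` and ``hhb`` are concentration changes in opaque device units;
    ``tsi`` is the tissue saturation index in percent (absolute before
    normalization, deviation from baseline after).  ``time`` is seconds from
    recording start on a uniform grid at ``sampling_rate`` Hz.
    """

    time: np.ndarray
    o2hb: np.ndarray
    hhb: np.ndarray
    tsi: np.ndarray
    sampling_rate: float = 10.0
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2hb = np.asarray(self.o2hb, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        self.tsi = np.asarray(self.tsi, dtype=float)
        n = self.time.size
        for name in ("o2hb", "hhb", "tsi"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length != time length")
        if n < 2:
            raise ValueError("recording needs at least 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-6:
            raise ValueError("time grid is not uniform at the declared rate")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def dhb(self) -> np.ndarray:
        """Hemoglobin difference O2Hb − HHb, an index of oxygenated blood."""
        return self.o2hb - self.hhb

    def channel(self, name: str) -> np.ndarray:
        if name == "dhb":
            return self.dhb
        if name in ALL_CHANNELS:
            return getattr(self, name)
        raise KeyError(name)

    def channels(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in ALL_CHANNELS:
            yield name, getattr(self, name)

    def copy_with(self, **kwargs) -> "NIRSRecording":
        return replace(self, **kwargs)

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Index slice of samples with t_start <= t < t_end (half-open)."""
        i0 = int(np.searchsorted(self.time, t_start - 1e-9))
        i1 = int(np.searchsorted(self.time, t_end - 1e-9))
        if i1 <= i0:
            raise ValueError(f"window [{t_start}, {t_end}) contains no samples")
        return slice(i0, i1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "o2hb": self.o2hb, "hhb": self.hhb, "tsi": self.tsi}
        )
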