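"""Vascular occlusion test protocol: phase schedule and cuff-pressure rules.

The default protocol is a 15-min supine baseline followed by three 7-min
cuff occlusions of the upper arm interleaved with reperfusion phases of
10, 10 and 20 min.  Phases are half-open intervals ``[t_start, t_end)`` in
seconds from recording start, so they partition the session exactly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Phase",
    "ProtocolSchedule",
    "PressureRule",
    "build_schedule",
    "DEFAULT_BASELINE_S",
    "DEFAULT_OCCLUSION_S",
    "DEFAULT_REPERFUSION_S",
    "DEFAULT_CUFF_RAMP_S",
]

DEFAULT_BASELINE_S = 900.0
DEFAULT_OCCLUSION_S = 420.0
DEFAULT_REPERFUSION_S = (600.0, 600.0, 1200.0)
#: Manual sphygmomanometer inflation/deflation takes a few seconds; modelled
#: and segmented as a linear ramp of this duration.
DEFAULT_CUFF_RAMP_S = 6.0


class ScheduleError(ValueError):
    """Raised for ill-formed protocol schedules."""


@dataclass(frozen=True)
class Phase:
    """One protocol phase as a half-open interval [t_start, t_end)."""

    label: str
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ScheduleError(
                f"phase {self.label!r} has non-positive duration "
                f"({self.t_start}..{self.t_end})"
            )


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered, contiguous phases plus the cuff inflation/deflation ramp."""

    phases: tuple[Phase, ...]
    cuff_ramp_s: float = DEFAULT_CUFF_RAMP_S

    def __post_init__(self) -> None:
        if not self.phases:
            raise ScheduleError("schedule has no phases")
        if self.cuff_ramp_s < 0:
            raise ScheduleError("cuff_ramp_s must be >= 0")
        prev_end = self.phases[0].t_start
        for ph in self.phases:
            if abs(ph.t_start - prev_end) > 1e-9:
                raise ScheduleError(
                    f"phases must be contiguous and non-overlapping; "
                    f"{ph.label!r} starts at {ph.t_start}, previous ended at {prev_end}"
                )
            prev_end = ph.t_end

    @property
    def t_start(self) -> float:
        return self.phases[0].t_start

    @property
    def t_end(self) -> float:
        return self.phases[-1].t_end

    @property
    def total_duration(self) -> float:
        return self.t_end - self.t_start

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(label)

    @property
    def occlusions(self) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.label.startswith("O"))

    @property
    def reperfusions(self) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.label.startswith("R"))

    def cycles(self) -> tuple[tuple[Phase, Phase], ...]:
        """(occlusion, reperfusion) pairs in protocol order."""
        occ, rep = self.occlusions, self.reperfusions
        if len(occ) != len(rep):
            raise ScheduleError("unequal number of occlusion and reperfusion phases")
        return tuple(zip(occ, rep))


def build_schedule(
    baseline_s: float = DEFAULT_BASELINE_S,
    occlusion_s: float = DEFAULT_OCCLUSION_S,
    reperfusion_s: Sequence[float] = DEFAULT_REPERFUSION_S,
    cuff_ramp_s: float = DEFAULT_CUFF_RAMP_S,
    n_cycles: int | None = None,
) -> ProtocolSchedule:
    """Build the occlusion–reperfusion schedule.

    Defaults give baseline(900) + 3x[occlusion(420) + reperfusion(600/600/1200)]
    = 4560 s total.  ``baseline_s = 0`` with ``n_cycles = 0`` is rejected;
    a baseline-only schedule is obtained with ``n_cycles = 0``.
    """
    if n_cycles is None:
        n_cycles = len(reperfusion_s)
    if n_cycles != len(reperfusion_s):
        raise ScheduleError("need one reperfusion duration per cycle")
    phases: list[Phase] = []
    t = 0.0
    if baseline_s > 0:
        phases.append(Phase("baseline", t, t + baseline_s))
        t += baseline_s
    elif baseline_s < 0:
        raise ScheduleError("negative baseline duration")
    for k in range(n_cycles):
        phases.append(Phase(f"O{k + 1}", t, t + occlusion_s))
        t += occlusion_s
        phases.append(Phase(f"R{k + 1}", t, t + reperfusion_s[k]))
        t += reperfusion_s[k]
    return ProtocolSchedule(tuple(phases), cuff_ramp_s=cuff_ramp_s)


_RULE_RE = re.compile(r"^\s*SBP\s*([+-])\s*(\d+(?:\.\d+)?)\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class PressureRule:
    """Cuff-pressure assignment: absolute mmHg, or an offset over systolic BP.

    The string forms ``"50"``, ``"250"`` (absolute) and ``"SBP+50"``
    (individualized) mirror the three occlusion-pressure groups of a VOT
    study design: venous-only, individualized suprasystolic, high absolute.
    """

    absolute: float | None = None
    sbp_offset: float | None = None

    def __post_init__(self) -> None:
        if (self.absolute is None) == (self.sbp_offset is None):
            raise ValueError("specify exactly one of absolute / sbp_offset")
        if self.absolute is not None and self.absolute < 0:
            raise ValueError("absolute pressure must be >= 0")

    @classmethod
    def parse(cls, text: str | float | int) -> "PressureRule":
        if isinstance(text, (int, float)):
            return cls(absolute=float(text))
        m = _RULE_RE.match(text)
        if m:
            sign = 1.0 if m.group(1) == "+" else -1.0
            return cls(sbp_offset=sign * float(m.group(2)))
        try:
            return cls(absolute=float(text))
        except ValueError:
            raise ValueError(f"unrecognized pressure rule {text!r}") from None

    def resolve(self, sbp: float) -> float:
        """Cuff pressure (mmHg) for a subject with systolic pressure ``sbp``."""
        if self.absolute is not None:
            return self.absolute
        return sbp + float(self.sbp_offset)

    def __str__(self) -> str:
        if self.absolute is not None:
            return f"{self.absolute:g}"
        sign = "+" if self.sbp_offset >= 0 else "-"
        return f"SBP{sign}{abs(self.sbp_offset):g}"
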