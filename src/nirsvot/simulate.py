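"""Synthetic occlusion–reperfusion NIRS generator with known ground truth.

The generator emulates the phenomenology of a cuff vascular occlusion test on
the forearm: during an occlusion, deoxyhemoglobin rises exponentially toward
a plateau while oxyhemoglobin mirrors it downward; on deflation both recover
exponentially, and (for suprasystolic pressures) the oxygenation channels
transiently overshoot the baseline — post-occlusive reactive hyperemia.

Model in brief (all shapes are the package's own modelling choices):

* Occlusion completeness ``c`` interpolates smoothly between venous-only and
  complete arterial occlusion as a logistic in (cuff pressure − SBP).
* Per cycle, the HHb deviation is ``A*(1 − exp(−t/τ_deoxy))`` with amplitude
  ``A = a_ven + c*a_art``; O2Hb mirrors it with negative sign.  Cuff
  inflation is a linear amplitude ramp.
* Reperfusion decays the plateau deviation with ``τ_reoxy``; the hyperemic
  overshoot is an alpha function ``(t/t_p)*exp(1 − t/t_p)`` added to the
  O2Hb pool, its amplitude calibrated (closed-form 1-D solve) so the net
  post-deflation TSI spike above baseline equals ``h_amp*c``.
* TSI is always computed from the absolute hemoglobin pools via the
  saturation formula, so it stays within [0, 100] and the derived-channel
  operation reproduces it exactly.
* Additive white Gaussian noise and a slow linear drift act on the raw
  concentration channels (and therefore propagate into TSI).

The continuous-time model is exposed as :class:`AnalyticChannels` so that
downstream feature extraction can be checked against root-finding /
quadrature oracles that never touch the sampled pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .preprocess import compute_tsi, write_nirs_csv
from .protocol import PressureRule, ProtocolSchedule, build_schedule
from .recording import NIRSRecording

__all__ = [
    "SimulationParams",
    "GroupSpec",
    "GroundTruth",
    "AnalyticChannels",
    "CohortDataset",
    "occlusion_completeness",
    "simulate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic and noise parameters of one simulated session.

    Defaults emulate a young healthy forearm at suprasystolic pressure:
    baseline TSI 65%, HHb occlusion plateau ~30 device units, occlusion
    kinetics slow (τ_deoxy 160 s, giving a 63% rise time near 140 s over a
    7-min occlusion), fast reperfusion (τ_reoxy 20 s) with a ~10% TSI
    hyperemic overshoot peaking ~25 s after deflation.  ``noise_sd`` is set
    so the raw baseline TSI standard deviation is about 0.5%.
    """

    sbp: float = 118.0            # systolic blood pressure, mmHg
    cuff_pressure: float = 250.0  # mmHg
    baseline_tsi: float = 65.0    # %
    a_art: float = 22.0           # arterial-occlusion HHb amplitude, device units
    a_ven: float = 8.0            # venous-occlusion HHb amplitude
    k_sigmoid: float = 10.0       # pressure-transition width, mmHg
    tau_deoxy: float = 160.0      # s
    tau_reoxy: float = 20.0       # s
    h_amp: float = 10.0           # hyperemic TSI overshoot amplitude, %
    t_peak: float = 25.0          # overshoot time-to-peak, s
    noise_sd: float = 0.68        # per-channel white noise SD, device units
    drift_slope: float = 1e-4     # linear drift, device units per s
    total_pool: float = 100.0     # o2hb+hhb baseline pool, device units
    sampling_rate: float = 10.0   # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_sigmoid", "tau_deoxy", "tau_reoxy", "t_peak"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("a_ven", "h_amp", "noise_sd", "cuff_pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.a_art <= 0:
            raise ValueError("a_art must be > 0")
        if not 0 < self.baseline_tsi < 100:
            raise ValueError("baseline_tsi must be in (0, 100)")
        if self.sampling_rate <= 0 or self.total_pool <= 0:
            raise ValueError("sampling_rate and total_pool must be > 0")

    @property
    def o2hb_pool(self) -> float:
        return self.total_pool * self.baseline_tsi / 100.0

    @property
    def hhb_pool(self) -> float:
        return self.total_pool * (100.0 - self.baseline_tsi) / 100.0


def occlusion_completeness(cuff_pressure: float, sbp: float, k_sigmoid: float) -> float:
    """Fraction of arterial occlusion achieved at a given cuff pressure.

    Logistic in (P − SBP): 0 well below systolic pressure (venous-only
    compression), 0.5 at P = SBP, → 1 for strongly suprasystolic pressures.
    """
    if not k_sigmoid > 0:
        raise ValueError("k_sigmoid must be strictly positive")
    x = (float(cuff_pressure) - float(sbp)) / float(k_sigmoid)
    # guard exp overflow far in the tails
    if x < -50:
        return math.exp(x) / (1.0 + math.exp(x)) if x > -700 else 0.0
    return 1.0 / (1.0 + math.exp(-x))


def _ramp_time(x: np.ndarray, ramp: float) -> np.ndarray:
    """Effective elapsed time under a linear cuff-deflation ramp.

    Integral of the ramp weight min(x/ramp, 1): x²/(2·ramp) during the ramp,
    x − ramp/2 afterwards.  Keeps the reperfusion recovery C¹-smooth at
    deflation (flow, hence washout, resumes gradually as the cuff releases).
    """
    if ramp <= 0:
        return x
    return np.where(x < ramp, x * x / (2.0 * ramp), x - ramp / 2.0)


@dataclass(frozen=True)
class _Cycle:
    t0: float      # occlusion start
    t1: float      # deflation / reperfusion start
    t2: float      # reperfusion end
    amp_hhb: float  # HHb deviation amplitude A
    plateau: float  # deviation reached at deflation, D = A*(1-exp(-T/τ))


class AnalyticChannels:
    """Noise- and drift-free continuous-time channel model of one session.

    Channel deviations (from baseline) are piecewise closed forms of time,
    evaluable at arbitrary ``t`` — the independent reference for every
    sampled, filtered, threshold-based quantity the pipeline extracts.
    """

    def __init__(self, params: SimulationParams, schedule: ProtocolSchedule,
                 amplitude_factor: float = 1.0):
        self.params = params
        self.schedule = schedule
        self.completeness = occlusion_completeness(
            params.cuff_pressure, params.sbp, params.k_sigmoid
        )
        self.amplitude_factor = float(amplitude_factor)
        self.amp_hhb = (params.a_ven + self.completeness * params.a_art) * self.amplitude_factor
        self.cycles: tuple[_Cycle, ...] = tuple(
            _Cycle(
                occ.t_start,
                occ.t_end,
                rep.t_end,
                self.amp_hhb,
                self.amp_hhb * (1.0 - math.exp(-occ.duration / params.tau_deoxy)),
            )
            for occ, rep in schedule.cycles()
        )
        self.overshoot_o2hb = self._calibrate_overshoot()

    def _calibrate_overshoot(self) -> float:
        """O2Hb overshoot amplitude giving a net TSI spike of h_amp * c.

        The hyperemic overshoot rides on the still-recovering occlusion
        deviation, so the raw alpha-function amplitude undershoots the
        intended spike; a bracketed 1-D solve on the closed-form model makes
        ``h_amp`` mean the net post-deflation TSI maximum above baseline.
        """
        from scipy.optimize import brentq

        p = self.params
        target = p.h_amp * self.completeness * self.amplitude_factor
        if not self.cycles or target < 1e-9:
            return 0.0
        cyc = self.cycles[0]
        t = np.arange(cyc.t1, min(cyc.t2, cyc.t1 + 6.0 * p.t_peak), 0.05)

        def net_spike(amp: float) -> float:
            self.overshoot_o2hb = amp
            return float(np.max(self.delta_tsi(t)))

        # saturation-formula sensitivity at baseline bounds the search
        o0, h0 = p.o2hb_pool, p.hhb_pool
        lin = target * (o0 + h0) ** 2 / (100.0 * h0)
        lo, hi = 0.0, 4.0 * lin + 1.0
        while net_spike(hi) < target:
            hi *= 2.0
            if hi > 1e4:
                raise RuntimeError("overshoot calibration failed to bracket")
        amp = brentq(lambda a: net_spike(a) - target, lo, hi, xtol=1e-9)
        self.overshoot_o2hb = amp
        return amp

    # -- deviations from baseline ------------------------------------------
    def delta_hhb(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        p = self.params
        ramp = self.schedule.cuff_ramp_s
        for c in self.cycles:
            occ = (t >= c.t0) & (t < c.t1)
            if occ.any():
                x = t[occ] - c.t0
                r = np.clip(x / ramp, 0.0, 1.0) if ramp > 0 else 1.0
                out[occ] = c.amp_hhb * r * (1.0 - np.exp(-x / p.tau_deoxy))
            rep = (t >= c.t1) & (t < c.t2)
            if rep.any():
                x = t[rep] - c.t1
                out[rep] = c.plateau * np.exp(-_ramp_time(x, ramp) / p.tau_reoxy)
        return out

    def _overshoot(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        tp = self.params.t_peak
        ramp = self.schedule.cuff_ramp_s
        for c in self.cycles:
            rep = (t >= c.t1) & (t < c.t2)
            if rep.any():
                x = t[rep] - c.t1
                w = np.clip(x / ramp, 0.0, 1.0) if ramp > 0 else 1.0
                out[rep] = self.overshoot_o2hb * w * (x / tp) * np.exp(1.0 - x / tp)
        return out

    def delta_o2hb(self, t) -> np.ndarray:
        return -self.delta_hhb(t) + self._overshoot(t)

    def delta_dhb(self, t) -> np.ndarray:
        return self.delta_o2hb(t) - self.delta_hhb(t)

    def tsi_abs(self, t) -> np.ndarray:
        p = self.params
        o = p.o2hb_pool + self.delta_o2hb(t)
        h = p.hhb_pool + self.delta_hhb(t)
        return 100.0 * o / (o + h)

    def delta_tsi(self, t) -> np.ndarray:
        return self.tsi_abs(t) - self.params.baseline_tsi

    def delta(self, channel: str) -> Callable[[np.ndarray], np.ndarray]:
        return {
            "o2hb": self.delta_o2hb,
            "hhb": self.delta_hhb,
            "tsi": self.delta_tsi,
            "dhb": self.delta_dhb,
        }[channel]


@dataclass
class GroundTruth:
    """True per-session generative quantities for downstream validation."""

    completeness: float
    amp_hhb: float
    plateau_hhb: float
    tau_deoxy: float
    tau_reoxy: float
    overshoot_tsi: float  # nominal TSI overshoot amplitude h_amp * c * factor
    t_peak: float
    amplitude_factor: float
    analytic: AnalyticChannels = field(repr=False)

    def as_row(self) -> dict:
        return {
            "completeness": self.completeness,
            "amp_hhb": self.amp_hhb,
            "plateau_hhb": self.plateau_hhb,
            "tau_deoxy": self.tau_deoxy,
            "tau_reoxy": self.tau_reoxy,
            "overshoot_tsi": self.overshoot_tsi,
            "t_peak": self.t_peak,
            "amplitude_factor": self.amplitude_factor,
        }


def simulate_session(
    params: SimulationParams,
    schedule: ProtocolSchedule | None = None,
    amplitude_factor: float = 1.0,
) -> tuple[NIRSRecording, GroundTruth]:
    """Simulate one subject-session recording plus its ground truth.

    The emitted ``o2hb``/``hhb`` channels are absolute hemoglobin pools
    (baseline pool + deviation + drift + noise) and ``tsi`` is the
    saturation formula applied to them, so the recording round-trips through
    the derived-channel operation exactly.  Same seed → identical output.
    """
    if schedule is None:
        schedule = build_schedule()
    model = AnalyticChannels(params, schedule, amplitude_factor)
    fs = params.sampling_rate
    n = int(round(schedule.total_duration * fs))
    t = schedule.t_start + np.arange(n) / fs

    rng = np.random.default_rng(params.seed)
    drift = params.drift_slope * (t - t[0])
    o2hb = params.o2hb_pool + model.delta_o2hb(t) + drift
    hhb = params.hhb_pool + model.delta_hhb(t) + drift
    if params.noise_sd > 0:
        o2hb = o2hb + rng.normal(0.0, params.noise_sd, n)
        hhb = hhb + rng.normal(0.0, params.noise_sd, n)
    tsi = compute_tsi(o2hb, hhb)

    rec = NIRSRecording(
        time=t, o2hb=o2hb, hhb=hhb, tsi=tsi, sampling_rate=fs,
        meta={"simulated": True, "seed": params.seed},
    )
    truth = GroundTruth(
        completeness=model.completeness,
        amp_hhb=model.amp_hhb,
        plateau_hhb=model.cycles[0].plateau if model.cycles else 0.0,
        tau_deoxy=params.tau_deoxy,
        tau_reoxy=params.tau_reoxy,
        overshoot_tsi=params.h_amp * model.completeness * amplitude_factor,
        t_peak=params.t_peak,
        amplitude_factor=amplitude_factor,
        analytic=model,
    )
    return rec, truth


@dataclass(frozen=True)
class GroupSpec:
    """One pressure group: label, cuff-pressure rule, number of subjects."""

    label: str
    pressure_rule: PressureRule | str | float
    n: int

    def rule(self) -> PressureRule:
        if isinstance(self.pressure_rule, PressureRule):
            return self.pressure_rule
        return PressureRule.parse(self.pressure_rule)


def default_group_specs(n_per_group: int | Sequence[int] = (9, 14, 12)) -> list[GroupSpec]:
    """The three-group VOT design: 50 mmHg, SBP+50 mmHg, 250 mmHg."""
    if isinstance(n_per_group, int):
        ns = (n_per_group,) * 3
    else:
        ns = tuple(n_per_group)
    return [
        GroupSpec("G1", "50", ns[0]),
        GroupSpec("G2", "SBP+50", ns[1]),
        GroupSpec("G3", "250", ns[2]),
    ]


@dataclass
class SessionRecord:
    subject_id: str
    group: str
    session: str
    sbp: float
    cuff_pressure: float
    amplitude_factor: float
    recording: NIRSRecording
    truth: GroundTruth


@dataclass
class CohortDataset:
    """All simulated subject-sessions plus manifest and ground-truth tables."""

    sessions: list[SessionRecord]
    schedule: ProtocolSchedule
    params: SimulationParams
    seed: int

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "session": s.session,
                "sbp": s.sbp,
                "cuff_pressure": s.cuff_pressure,
                "file": f"{s.subject_id}_{s.session}.csv",
            }
            for s in self.sessions
        ]
        return pd.DataFrame(rows)

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "session": s.session,
                "sbp": s.sbp,
                "cuff_pressure": s.cuff_pressure,
            }
            row.update(s.truth.as_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = {"seed": self.seed, "simulated": 1}
        for s in self.sessions:
            write_nirs_csv(s.recording, outdir / f"{s.subject_id}_{s.session}.csv", prov)
        self.manifest().to_csv(outdir / "manifest.csv", index=False)
        self.ground_truth_table().to_csv(outdir / "ground_truth.csv", index=False)


#: Between-subject and between-session coefficients of variation of the
#: hemodynamic response amplitude; chosen to mimic the spread of reported
#: group summaries (amplitude CVs of 10–20%).
SUBJECT_AMPLITUDE_CV = 0.12
SESSION_AMPLITUDE_CV = 0.05
SBP_MEAN = 118.0
SBP_SD = 9.0


def simulate_cohort(
    group_specs: Sequence[GroupSpec] | None = None,
    params: SimulationParams | None = None,
    schedule: ProtocolSchedule | None = None,
    n_sessions: int = 2,
    seed: int = 0,
    sbp_mean: float = SBP_MEAN,
    sbp_sd: float = SBP_SD,
) -> CohortDataset:
    """Simulate a multi-group, multi-session cohort.

    Each subject draws a systolic pressure from Normal(``sbp_mean``,
    ``sbp_sd``) and a response-amplitude factor; each session adds an
    independent amplitude offset, emulating between-visit variability.
    Cuff pressure is resolved per group rule (absolute or SBP-relative).
    """
    if group_specs is None:
        group_specs = default_group_specs()
    if not group_specs:
        raise ValueError("group_specs must be non-empty")
    for gs in group_specs:
        if gs.n < 1:
            raise ValueError(f"group {gs.label!r} has n < 1")
    if params is None:
        params = SimulationParams()
    if schedule is None:
        schedule = build_schedule()

    rng = np.random.default_rng(seed)
    sessions: list[SessionRecord] = []
    for gs in group_specs:
        rule = gs.rule()
        for i in range(gs.n):
            subject_id = f"{gs.label}_{i + 1:02d}"
            sbp = float(rng.normal(sbp_mean, sbp_sd))
            cuff = rule.resolve(sbp)
            subj_factor = max(0.3, float(rng.normal(1.0, SUBJECT_AMPLITUDE_CV)))
            for s in range(n_sessions):
                sess_factor = max(0.3, float(rng.normal(1.0, SESSION_AMPLITUDE_CV)))
                factor = subj_factor * sess_factor
                sess_seed = int(rng.integers(0, 2**31 - 1))
                p = replace(params, sbp=sbp, cuff_pressure=cuff, seed=sess_seed)
                rec, truth = simulate_session(p, schedule, amplitude_factor=factor)
                sessions.append(
                    SessionRecord(
                        subject_id=subject_id,
                        group=gs.label,
                        session=f"S{s + 1}",
                        sbp=sbp,
                        cuff_pressure=cuff,
                        amplitude_factor=factor,
                        recording=rec,
                        truth=truth,
                    )
                )
    return CohortDataset(sessions=sessions, schedule=schedule, params=params, seed=seed)
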