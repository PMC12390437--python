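"""Digital twin of the slaughter line.

Discrete-time replica of an electrical water-bath stunning line with four
processing stages — reception, stunning, cutting, plucking — plus an idle
state, indexed 0–4.  A bird enters reception immediately, then advances to
the next stage after the dwell time of the stage it is in; with the default
dwells (2, 7, 1, 1) s the index traverses 0 → 4 within a 10 s run (the
final 1 s is dwell in plucking).  The 7 s stunning dwell reflects the
typical 7 ± 0.6 s shock duration on a real line.

During the stunning stage a positional PID controller regulates the applied
voltage toward a weight-dependent setpoint (heavier birds need more voltage;
the mapping is an affine function clamped to the configured safe range), and
the real-time EEG threshold monitor classifies the bird as stunned / not
stunned.  Each simulation tick emits a :class:`~stunwatch.datamodel.TwinEvent`;
the resulting JSON-Lines stream is the file-level stand-in for a live
telemetry feed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datamodel import EEGTrace, TwinEvent
from .eeg import DEFAULT_THRESHOLD_MV

__all__ = [
    "ConveyorConfig",
    "PIDState",
    "SetpointMap",
    "TwinConfig",
    "stage_at",
    "simulate_conveyor",
    "pid_step",
    "voltage_setpoint",
    "run_twin",
]


@dataclass(frozen=True)
class ConveyorConfig:
    """Stage dwell times (s), simulation step and total duration.

    ``delays`` are the dwell times of reception, stunning, cutting and
    plucking, in that order.
    """

    delays: tuple[float, float, float, float] = (2.0, 7.0, 1.0, 1.0)
    dt: float = 0.1
    duration: float = 10.0

    def __post_init__(self) -> None:
        if len(self.delays) != 4:
            raise ValueError("exactly four stage delays are required")
        if any(d <= 0 for d in self.delays):
            raise ValueError("all stage delays must be > 0 s")
        if self.dt <= 0:
            raise ValueError("dt must be > 0 s")
        if self.duration <= 0:
            raise ValueError("duration must be > 0 s")
        if self.dt > min(self.delays):
            raise ValueError(
                f"dt = {self.dt} s exceeds the smallest stage delay "
                f"{min(self.delays)} s; a stage would be skipped"
            )


def stage_at(t: float, delays: Sequence[float]) -> int:
    """Stage index at time ``t``: 0 (idle) at t ≤ 0, else 1–4.

    Stage k+1 is entered once the cumulative dwell of the first k stages has
    elapsed; the plucking dwell is time spent in the final stage.
    """
    if t <= 0:
        return 0
    boundaries = np.cumsum(delays[:3])
    return 1 + int(np.searchsorted(boundaries, t, side="right"))


def simulate_conveyor(cfg: ConveyorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Time series ``(t, stage_index)`` of one bird traversing the line.

    The index starts at 0, is non-decreasing, and reaches 4 iff the duration
    covers the dwells of the first three stages.
    """
    t = np.arange(0.0, cfg.duration + cfg.dt / 2, cfg.dt)
    stages = np.array([stage_at(ti, cfg.delays) for ti in t], dtype=int)
    return t, stages


@dataclass(frozen=True)
class PIDState:
    """Positional PID controller state with output clamping and anti-windup.

    ``kp`` is dimensionless, ``ki`` has units 1/s, ``kd`` has units s.  The
    integral term is frozen whenever the output saturates at the clamp
    (clamping anti-windup), which prevents integral build-up during long
    saturated transients.
    """

    kp: float
    ki: float = 0.0
    kd: float = 0.0
    integral: float = 0.0
    prev_error: float = 0.0
    out_min: float = 0.0
    out_max: float = 160.0

    def __post_init__(self) -> None:
        if not self.out_min < self.out_max:
            raise ValueError("out_min must be < out_max")


def pid_step(
    state: PIDState, setpoint: float, measured: float, dt: float
) -> tuple[PIDState, float]:
    """One controller update; returns the new state and the clamped output.

    out = kp·e + ki·∫e dt + kd·de/dt, clamped to [out_min, out_max];
    derivative acts on the error.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0 s")
    error = setpoint - measured
    integral = state.integral + error * dt
    derivative = (error - state.prev_error) / dt
    raw = state.kp * error + state.ki * integral + state.kd * derivative
    out = min(max(raw, state.out_min), state.out_max)
    if raw != out:
        integral = state.integral  # saturated: freeze the integral
    return replace(state, integral=integral, prev_error=error), out


@dataclass(frozen=True)
class SetpointMap:
    """Affine weight → stunning-voltage map with a safe-range clamp.

    setpoint(weight) = a·weight + b, clamped to [vmin, vmax].  The default
    range 80–160 V spans voltages observed in practice on the line; the
    slope/offset are site calibration, not science.
    """

    a: float = 0.0
    b: float = 100.0
    vmin: float = 80.0
    vmax: float = 160.0

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")


def voltage_setpoint(weight: float, spmap: SetpointMap) -> float:
    """Weight-dependent voltage setpoint (V), clamped to the safe range."""
    if weight <= 0:
        raise ValueError(f"weight must be > 0 kg, got {weight}")
    return min(max(spmap.a * weight + spmap.b, spmap.vmin), spmap.vmax)


@dataclass(frozen=True)
class TwinConfig:
    """Full twin configuration: conveyor + controller + setpoint + monitor."""

    conveyor: ConveyorConfig = field(default_factory=ConveyorConfig)
    pid: PIDState = field(default_factory=lambda: PIDState(
        kp=2.0, ki=1.0, kd=0.0, out_min=0.0, out_max=160.0))
    setpoint: SetpointMap = field(default_factory=SetpointMap)
    threshold_mv: float = DEFAULT_THRESHOLD_MV
    #: time constant (s) of the first-order voltage actuator
    actuator_tau: float = 0.5
    #: spacing (s) between successive birds entering the line
    entry_interval: float | None = None


def _monitor_flag(trace: EEGTrace, t_local: float, threshold: float) -> bool | None:
    """Stunned verdict from the most recent EEG sample at local time t."""
    idx = int(np.searchsorted(trace.t, t_local, side="right")) - 1
    if idx < 0 or idx >= len(trace):
        return None
    return bool(trace.v[idx] <= threshold)


def run_twin(
    cfg: TwinConfig,
    birds: Sequence[tuple[str, float, EEGTrace]],
) -> list[TwinEvent]:
    """Simulate the line for a sequence of birds and emit the event stream.

    ``birds`` is a list of (bird_id, weight kg, EEG trace).  Birds enter the
    line one per shackle at ``entry_interval`` spacing (default: the full
    traversal time, so at most one bird is on the line at a time).  Events
    are emitted every tick while a bird is on the line, time-ordered; during
    the stunning stage the voltage is the PID command tracking the bird's
    weight-dependent setpoint and ``stunned_flag`` is the threshold-monitor
    verdict, otherwise the voltage is 0 and the flag is None.
    """
    conveyor = cfg.conveyor
    traversal = float(sum(conveyor.delays))
    interval = cfg.entry_interval if cfg.entry_interval is not None else traversal
    events: list[TwinEvent] = []

    for i, (bird_id, weight, trace) in enumerate(birds):
        t_entry = i * interval
        setpt = voltage_setpoint(weight, cfg.setpoint)
        pid = cfg.pid
        applied = 0.0  # actuator (plant) voltage, first-order lag of the command
        n_ticks = int(round(conveyor.duration / conveyor.dt))
        for k in range(n_ticks + 1):
            t_local = k * conveyor.dt
            stage = stage_at(t_local, conveyor.delays)
            if stage == 2:  # stunning
                pid, command = pid_step(pid, setpt, applied, conveyor.dt)
                applied += conveyor.dt / cfg.actuator_tau * (command - applied)
                flag = _monitor_flag(trace, t_local, cfg.threshold_mv)
                voltage = command
            else:
                voltage = 0.0
                flag = None
            events.append(
                TwinEvent(
                    t=t_entry + t_local,
                    bird_id=bird_id,
                    stage_index=stage,
                    voltage=voltage,
                    stunned_flag=flag,
                )
            )
    events.sort(key=lambda e: e.t)
    return events
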