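"""Stimulus model: from valve schedule to transcription-factor activity.

Hyperosmotic medium is delivered to the imaging chamber by switching a
valve.  The activity ``u(t)`` of the stress-responsive transcription
factor is modeled as the valve indicator, shifted by the fluid transport
delay from valve to chamber, and smoothed by a first-order lag that
stands in for the diffusion-limited medium exchange and the upstream
signaling chain.  ``u`` is normalized to [0, 1]; the absolute stimulus
scale is absorbed into the transcription rate ``k_m``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ShockSchedule", "InputSignal", "build_input", "ScheduleError"]


class ScheduleError(ValueError):
    """Raised for malformed shock schedules."""


@dataclass(frozen=True)
class ShockSchedule:
    """Ordered on-intervals of the osmotic-shock valve.

    Parameters
    ----------
    intervals
        Sequence of ``(start_min, end_min)`` pairs during which the valve
        delivers hyperosmotic medium.  Must be sorted, non-overlapping,
        with ``start < end``, and lie within ``[0, duration_min]``.
    duration_min
        Total experiment length in minutes.
    """

    intervals: tuple[tuple[float, float], ...]
    duration_min: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", tuple((float(a), float(b)) for a, b in self.intervals)
        )
        if not np.isfinite(self.duration_min) or self.duration_min <= 0:
            raise ScheduleError(f"duration_min must be positive, got {self.duration_min}")
        prev_end = 0.0
        for start, end in self.intervals:
            if not (np.isfinite(start) and np.isfinite(end)):
                raise ScheduleError("non-finite interval bound")
            if start >= end:
                raise ScheduleError(f"interval ({start}, {end}) has start >= end")
            if start < prev_end:
                raise ScheduleError("intervals must be sorted and non-overlapping")
            if start < 0 or end > self.duration_min:
                raise ScheduleError(
                    f"interval ({start}, {end}) outside [0, {self.duration_min}]"
                )
            prev_end = end

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intervals": [[a, b] for a, b in self.intervals],
            "duration_min": self.duration_min,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ShockSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            intervals=tuple((a, b) for a, b in payload["intervals"]),
            duration_min=payload["duration_min"],
        )


@dataclass(frozen=True)
class InputSignal:
    """Transcription-factor activity on a time grid.

    ``values[i]`` holds ``u(t)`` on the half-open interval
    ``[grid_times[i], grid_times[i+1])``; the final value extends to the
    last grid time.  Values lie in [0, 1].
    """

    grid_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.grid_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("grid_times and values must be 1-D with equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("grid_times must be strictly increasing")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("input values must lie in [0, 1]")
        object.__setattr__(self, "grid_times", t)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def duration_min(self) -> float:
        return float(self.grid_times[-1])

    def at(self, times: np.ndarray) -> np.ndarray:
        """Piecewise-constant evaluation of u at arbitrary times."""
        idx = np.searchsorted(self.grid_times, np.asarray(times, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        return self.values[idx]

    def integral(self) -> float:
        """∫ u dt over the grid span (piecewise-constant quadrature)."""
        dt = np.diff(self.grid_times)
        return float(np.sum(self.values[:-1] * dt))


def build_input(
    schedule: ShockSchedule,
    transport_delay_min: float = 2.0,
    lag_min: float = 2.0,
    grid_step_min: float = 0.5,
) -> InputSignal:
    """Build the activity signal u(t) from a valve schedule.

    The valve indicator is shifted by ``transport_delay_min`` (fluid
    transit from valve to chamber, ~2 min in the experimental setup) and
    passed through a first-order lag with time constant ``lag_min``:

        du/dt = (v(t - delay) - u) / lag,   u(0) = 0.

    ``lag_min = 0`` gives the pure shifted indicator.  The result is
    discretized piecewise-constant on a uniform grid covering
    ``[0, duration_min]``; the lag ODE is integrated exactly on each grid
    step (the shifted indicator is constant there once grid breakpoints
    include the shifted interval edges — enforced by snapping edges to
    the grid via left-closed sampling of the indicator at step starts).

    Returns
    -------
    InputSignal with values in [0, 1].
    """
    if not isinstance(schedule, ShockSchedule):
        raise ScheduleError("schedule must be a ShockSchedule")
    if grid_step_min <= 0 or not np.isfinite(grid_step_min):
        raise ValueError(f"grid_step_min must be positive, got {grid_step_min}")
    if transport_delay_min < 0 or lag_min < 0:
        raise ValueError("transport_delay_min and lag_min must be non-negative")

    n_steps = int(np.ceil(schedule.duration_min / grid_step_min))
    grid = np.linspace(0.0, n_steps * grid_step_min, n_steps + 1)

    # shifted valve indicator, sampled at step midpoints to decide each
    # step's drive value (half-open convention: a step belongs to an
    # interval iff its start time does)
    starts = grid[:-1]
    v = np.zeros(n_steps)
    for a, b in schedule.intervals:
        v[(starts >= a + transport_delay_min) & (starts < b + transport_delay_min)] = 1.0

    if lag_min == 0.0:
        u = v
    else:
        u = np.empty(n_steps)
        decay = np.exp(-grid_step_min / lag_min)
        state = 0.0
        for i in range(n_steps):
            u[i] = state
            state = v[i] + (state - v[i]) * decay
    # value on the last (degenerate) grid point repeats the final step
    return InputSignal(grid_times=grid, values=np.append(u, u[-1] if n_steps else 0.0))


def default_schedule(
    n_shocks: int = 8,
    shock_min: float = 8.0,
    period_min: float = 60.0,
    first_start_min: float = 30.0,
    duration_min: float = 600.0,
) -> ShockSchedule:
    """Periodic shock train mimicking the repeated-shock experiments:
    8-min hyperosmotic pulses every hour starting at t = 30 min, over a
    10-h run."""
    intervals = []
    for k in range(n_shocks):
        a = first_start_min + k * period_min
        b = a + shock_min
        if b <= duration_min:
            intervals.append((a, b))
    return ShockSchedule(intervals=tuple(intervals), duration_min=duration_min)
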