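"""Stimulation protocols: timed current injections, optionally repeated.

A protocol is a list of events.  Each event injects a depolarizing
current of a given amplitude (ms^-1 on the dimensionless voltage scale)
for a given duration, optionally repeated at a fixed basic cycle length
(BCL).  In tissue an event carries a spatial region (a boolean mask over
the grid); in a space-clamped cell the region is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = ["StimulusEvent", "StimulusProtocol"]


@dataclass
class StimulusEvent:
    """One (possibly repeated) stimulus.

    ``region`` is ``None`` (whole cell / whole domain) or a boolean
    array matching the tissue grid shape.
    """

    start: float  # ms
    amplitude: float  # ms^-1, depolarizing
    duration: float = 1.0  # ms
    bcl: Optional[float] = None  # ms, None = single pulse
    n_beats: int = 1
    region: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.n_beats > 1:
            if self.bcl is None:
                raise ValueError("repeated stimulus requires a BCL")
            if self.bcl <= self.duration:
                raise ValueError("BCL must exceed the stimulus duration")

    def pulses(self) -> Iterator[tuple[float, float, float]]:
        """Yield (t_on, t_off, amplitude) for every repetition."""
        period = self.bcl if self.bcl is not None else 0.0
        for k in range(self.n_beats):
            t_on = self.start + k * period
            yield (t_on, t_on + self.duration, self.amplitude)


@dataclass
class StimulusProtocol:
    events: list[StimulusEvent] = field(default_factory=list)

    @classmethod
    def pacing(cls, amplitude: float, bcl: float, n_beats: int,
               duration: float = 1.0, start: float = 0.0,
               region: Optional[np.ndarray] = None) -> "StimulusProtocol":
        """Fixed-rate pacing train, the workhorse protocol."""
        return cls([StimulusEvent(start=start, amplitude=amplitude,
                                  duration=duration, bcl=bcl,
                                  n_beats=n_beats, region=region)])

    @classmethod
    def single(cls, amplitude: float, duration: float = 1.0,
               start: float = 0.0,
               region: Optional[np.ndarray] = None) -> "StimulusProtocol":
        return cls([StimulusEvent(start=start, amplitude=amplitude,
                                  duration=duration, region=region)])

    def add(self, event: StimulusEvent) -> None:
        self.events.append(event)

    def end_time(self) -> float:
        t = 0.0
        for ev in self.events:
            for _, t_off, _ in ev.pulses():
                t = max(t, t_off)
        return t

    def waveform(self, dt: float, n_steps: int) -> np.ndarray:
        """Per-step summed stimulus amplitude, ignoring regions.

        Step ``i`` covers the interval [i*dt, (i+1)*dt); a pulse active
        on [t_on, t_off) contributes to all steps it covers, so a 1-ms
        pulse at dt = 0.01 ms injects exactly amplitude x 1 ms of charge.
        """
        out = np.zeros(n_steps)
        for ev in self.events:
            for t_on, t_off, amp in ev.pulses():
                i0 = int(np.ceil(t_on / dt - 1e-9))
                i1 = int(np.ceil(t_off / dt - 1e-9))
                if i0 < n_steps:
                    out[i0:min(i1, n_steps)] += amp
        return out
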