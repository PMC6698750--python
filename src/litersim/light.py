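"""Time-dependent light inputs u(t) in LPA grayscale units (0-4095).

Three illumination regimes are supported, matching the experiments the
circuits were characterised with: constant intensity, a single pulse of
given duration starting at t = 0, and periodic duty-cycle stimulation with
a default period of 1 h.  All programs are piecewise constant; the engines
integrate segment by segment so light switches are handled exactly, never
smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAYSCALE_MAX = 4095.0

#: Default terminal measurement times (h), mirroring the experimental
#: protocol: 72 h for the feedback circuits, 24 h for the open-loop benchmark.
DEFAULT_T_END = {"liter1": 72.0, "liter2": 72.0, "open_loop": 24.0}


@dataclass(frozen=True)
class LightProgram:
    """Piecewise-constant light input.

    Use the constructors :meth:`constant`, :meth:`single_pulse` and
    :meth:`duty_cycle` rather than the raw dataclass.

    Attributes
    ----------
    kind : {"constant", "single_pulse", "duty_cycle"}
    intensity : float
        Grayscale setting in [0, 4095] while the light is on.
    pulse_duration : float
        Pulse length in **minutes** (single_pulse only).
    period : float
        Stimulus period in hours (duty_cycle only; default 1 h).
    duty_fraction : float
        Fraction of each period with light on, in [0, 1].
    total_duration : float
        Program horizon in hours.
    """

    kind: str
    intensity: float
    total_duration: float = 72.0
    pulse_duration: float = 0.0
    period: float = 1.0
    duty_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "single_pulse", "duty_cycle"):
            raise ValueError(f"unknown light program kind {self.kind!r}")
        if not (0.0 <= self.intensity <= GRAYSCALE_MAX):
            raise ValueError(f"intensity must be in [0, {GRAYSCALE_MAX:g}] g.s., got {self.intensity}")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be > 0")
        if self.kind == "single_pulse" and self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0 minutes")
        if self.kind == "duty_cycle":
            if not (0.0 <= self.duty_fraction <= 1.0):
                raise ValueError("duty_fraction must lie in [0, 1]")
            if self.period <= 0:
                raise ValueError("period must be > 0 hours")

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, intensity: float, total_duration: float = 72.0) -> "LightProgram":
        return cls("constant", intensity, total_duration)

    @classmethod
    def single_pulse(cls, intensity: float, pulse_duration_min: float,
                     total_duration: float = 72.0) -> "LightProgram":
        """Single pulse of ``pulse_duration_min`` minutes starting at t = 0."""
        return cls("single_pulse", intensity, total_duration,
                   pulse_duration=pulse_duration_min)

    @classmethod
    def duty_cycle(cls, intensity: float, duty_fraction: float, period: float = 1.0,
                   total_duration: float = 72.0) -> "LightProgram":
        """Light on for the first ``duty_fraction`` of each ``period`` hours."""
        return cls("duty_cycle", intensity, total_duration,
                   period=period, duty_fraction=duty_fraction)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, t: float) -> float:
        """u(t) in grayscale units; t in hours, t >= 0."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        if self.kind == "constant":
            return self.intensity
        if self.kind == "single_pulse":
            return self.intensity if t < self.pulse_duration / 60.0 else 0.0
        phase = t % self.period
        return self.intensity if phase < self.duty_fraction * self.period else 0.0

    def switch_times(self, t_end: float | None = None) -> np.ndarray:
        """Interior light switch points in (0, t_end), sorted."""
        t_end = self.total_duration if t_end is None else t_end
        if self.kind == "constant":
            return np.empty(0)
        if self.kind == "single_pulse":
            t_off = self.pulse_duration / 60.0
            return np.array([t_off]) if 0 < t_off < t_end else np.empty(0)
        if self.duty_fraction in (0.0, 1.0):
            return np.empty(0)
        edges = []
        k = 0
        while k * self.period < t_end:
            on_end = k * self.period + self.duty_fraction * self.period
            if 0 < on_end < t_end:
                edges.append(on_end)
            nxt = (k + 1) * self.period
            if 0 < nxt < t_end:
                edges.append(nxt)
            k += 1
        return np.array(sorted(edges))

    def segments(self, t_end: float | None = None) -> list[tuple[float, float, float]]:
        """Decompose [0, t_end] into (t0, t1, u) intervals of constant light."""
        t_end = self.total_duration if t_end is None else t_end
        edges = np.concatenate([[0.0], self.switch_times(t_end), [t_end]])
        # sample at the midpoint: edges can fall a rounding error off a switch
        return [
            (float(a), float(b), self.evaluate(float(a + b) / 2.0))
            for a, b in zip(edges[:-1], edges[1:])
            if b > a
        ]

    def time_average(self) -> float:
        """Exact average of u(t) over [0, total_duration]."""
        total = sum((b - a) * u for a, b, u in self.segments())
        return total / self.total_duration

    def schedule_table(self):
        """Switch-time table as a DataFrame (t_start, t_end, intensity) for audit."""
        import pandas as pd

        return pd.DataFrame(self.segments(), columns=["t_start", "t_end", "intensity"])
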