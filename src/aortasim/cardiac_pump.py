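"""Ventricular drive: piston volume-time curve and aortic root flow.

The linear pump ejects the stroke volume during systole through a one-way
aortic valve; diastolic refill is routed through the reservoir and never
appears as aortic flow, so the root flow is non-negative and integrates to
exactly one stroke volume per beat.  The ejection template is a half-sine
occupying a fixed fraction (0.35) of the beat: the piston drive profile
scales with the pulsation period, as it does when the pump period is the
controlled quantity.  At the standard 75 beats/min the ejection lasts 0.28 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SYSTOLIC_FRACTION_DEFAULT = 0.35


@dataclass(frozen=True)
class CardiacProfile:
    """Heart rate (beats/min), stroke volume (mL) and ejection shape."""

    hr: float = 75.0
    sv: float = 70.0
    systolic_fraction: float = SYSTOLIC_FRACTION_DEFAULT
    shape: str = "half_sine"

    def __post_init__(self) -> None:
        if self.hr <= 0 or self.sv <= 0:
            raise ValueError("HR and SV must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic fraction must lie strictly in (0, 1)")
        if self.shape != "half_sine":
            raise ValueError(f"unknown ejection shape {self.shape!r}")

    @property
    def period(self) -> float:
        """Beat period, 60/HR seconds."""
        return 60.0 / self.hr

    @property
    def systolic_duration(self) -> float:
        """Ejection time in seconds, systolic_fraction x period."""
        return self.systolic_fraction * self.period

    @property
    def mean_flow(self) -> float:
        """Cycle-averaged aortic flow, mL/s."""
        return self.sv * self.hr / 60.0

    @property
    def peak_flow(self) -> float:
        """Peak ejection flow of the half-sine template, mL/s."""
        return math.pi * self.sv / (2.0 * self.systolic_duration)


def volume_curve(profile: CardiacProfile, t):
    """Cumulative ejected volume (mL) at time(s) t >= 0.

    Periodic staircase: rises by exactly SV during each systole and is flat
    in diastole.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    beats = np.floor(t / profile.period)
    tau = t - beats * profile.period
    ts = profile.systolic_duration
    within = np.where(
        tau < ts,
        profile.sv * 0.5 * (1.0 - np.cos(np.pi * np.minimum(tau, ts) / ts)),
        profile.sv,
    )
    out = beats * profile.sv + within
    return float(out) if out.ndim == 0 else out


def flow_rate(profile: CardiacProfile, t):
    """Aortic root flow (mL/s) at time(s) t >= 0; zero throughout diastole."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = np.mod(t, profile.period)
    ts = profile.systolic_duration
    q = np.where(tau < ts, profile.peak_flow * np.sin(np.pi * np.minimum(tau, ts) / ts), 0.0)
    return float(q) if q.ndim == 0 else q
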