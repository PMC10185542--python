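"""Simulator core: forward/reflected wave superposition on a delay line.

The artificial aorta is modelled as a single lossless conduit from the
aortic root to the aortic bifurcation (AB), travelled at the Moens-Korteweg
speed of the current wall state.  The forward pressure wave launched at the
root is the characteristic-impedance image of the pulsatile ejection flow,
Zc.(Q - Qbar), riding on the ripple of a two-element Windkessel
(drainage resistance R, compliance C) that sets the diastolic decay.  At the
AB the wave meets the peripheral constriction and reflects with
Gamma = (R_refl - Zc_AB)/(R_refl + Zc_AB); during diastole the closed aortic
valve re-reflects returning waves at the root (coefficient Gamma_root, zero
while the valve is open).  The pressure at a sensor is the mean level
(reservoir offset plus mean flow times drainage resistance) plus the delayed
forward and backward wave trains.

The peripheral ball valves appear as a drainage resistance in the
DC/Windkessel path (the two iliac branches and reservoir plumbing in
parallel) following the orifice law R(o) = R_ref.((1 - o_ref)/(1 - o))^2
anchored at the 15% standard occlusion.  The wave reflector is the aortic
bifurcation junction itself -- the anatomical reflection site -- whose
impedance is set by the local geometry and is therefore independent of the
valve setting 74 mm further downstream.

Everything is deterministic; optional measurement noise takes an explicit
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, lfilter

from . import vessel_geometry
from .cardiac_pump import CardiacProfile, flow_rate
from .units import impedance_si_to_clinical
from .vessel_geometry import AortaGeometry, diameter_at
from .wall_material import (
    ChamberPressures,
    D_EFF_DEFAULT_M,
    FLUID_DENSITY_KG_M3,
    WallMaterial,
    effective_modulus,
    moens_pwv,
)

OCCLUSION_REF = 0.15

# Frozen calibration of the standard configuration (see calibration.py).
R_TOTAL_REF_DEFAULT = 0.15  # mmHg.s/mL, DC/Windkessel drainage resistance at 15%
REFLECTION_RESISTANCE_REF_DEFAULT = 3.6147334  # mmHg.s/mL, AB junction impedance
WINDKESSEL_COMPLIANCE_DEFAULT = 4.2126302  # mL/mmHg (diastolic decay time constant ~0.6 s)
FORWARD_WAVE_SCALE_DEFAULT = 0.9829190  # dimensionless gain on Zc.(Q - Qbar)
IVP_OFFSET_DEFAULT = 86.0837295  # mmHg reservoir pressurization

ROOT_REFLECTION_DEFAULT = 0.2
VALVE_TRANSITION_S = 0.02  # finite opening/closure time of the soft valve
TERMINAL_SMOOTHING_DEFAULT_S = 0.03  # compliant-junction reflection memory  # finite opening/closure time of the soft valve


class SimulationError(RuntimeError):
    """Unstable or non-physical simulator configuration."""


class PTTError(RuntimeError):
    """Transit time could not be measured (no feet, or non-causal ordering)."""


def terminal_resistance(
    occlusion_ratio: float, r_ref: float, occlusion_ref: float = OCCLUSION_REF
) -> float:
    """Orifice-law resistance, anchored to ``r_ref`` at the reference occlusion.

    R(o) = r_ref . ((1 - o_ref)/(1 - o))^2; monotone increasing in o and
    unbounded as the valve closes completely.
    """
    if not 0.0 <= occlusion_ratio < 1.0:
        raise ValueError("occlusion ratio must lie in [0, 1); full closure is unbounded")
    if r_ref <= 0:
        raise ValueError("reference resistance must be positive")
    return r_ref * ((1.0 - occlusion_ref) / (1.0 - occlusion_ratio)) ** 2


def characteristic_impedance(diameter: float, pwv: float, rho: float) -> float:
    """Zc = rho.c/A for a travelling wave, in mmHg.s/mL."""
    if diameter <= 0 or pwv <= 0 or rho <= 0:
        raise ValueError("diameter, wave speed and density must be positive")
    area = math.pi * (diameter / 2.0) ** 2
    return impedance_si_to_clinical(rho * pwv / area)


def reflection_coefficient(zc: float, r_terminal: float) -> float:
    """Gamma = (R - Zc)/(R + Zc); 0 for a matched load, -> 1 for a closed end."""
    if zc <= 0:
        raise ValueError("characteristic impedance must be positive")
    if r_terminal < 0:
        raise ValueError("terminal resistance must be non-negative")
    if math.isinf(r_terminal):
        return 1.0
    return (r_terminal - zc) / (r_terminal + zc)


@dataclass(frozen=True)
class PeripheralLoad:
    """Peripheral ball-valve setting and the lumped terminal parameters."""

    occlusion_ratio: float = OCCLUSION_REF
    r_total_ref: float = R_TOTAL_REF_DEFAULT
    windkessel_compliance: float = WINDKESSEL_COMPLIANCE_DEFAULT
    reflection_resistance_ref: float = REFLECTION_RESISTANCE_REF_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 <= self.occlusion_ratio < 1.0:
            raise ValueError("occlusion ratio must lie in [0, 1)")
        if self.windkessel_compliance <= 0:
            raise ValueError("Windkessel compliance must be positive")

    @property
    def terminal_resistance(self) -> float:
        """Drainage (DC/Windkessel) resistance at the current occlusion, mmHg.s/mL."""
        return terminal_resistance(self.occlusion_ratio, self.r_total_ref)

    @property
    def reflection_resistance(self) -> float:
        """Junction impedance seen by the wave at the AB, mmHg.s/mL.

        The AB is the anatomical reflection site; its impedance is geometric
        and does not vary with the downstream valve setting.
        """
        return self.reflection_resistance_ref


@dataclass(frozen=True)
class SimulationSettings:
    sample_rate: float = 1000.0
    terminal_smoothing_s: float = TERMINAL_SMOOTHING_DEFAULT_S
    n_beats: int = 12
    n_transient: int = 9
    n_reflections: int = 30
    root_reflection_coefficient: float = ROOT_REFLECTION_DEFAULT
    forward_wave_scale: float = FORWARD_WAVE_SCALE_DEFAULT
    effective_diameter: float = D_EFF_DEFAULT_M
    fluid_density: float = FLUID_DENSITY_KG_M3

    def __post_init__(self) -> None:
        if self.sample_rate < 200.0:
            raise ValueError("sample rate must be >= 200 Hz to resolve 30 Hz content")
        if self.n_beats < 3 or not 0 < self.n_transient < self.n_beats:
            raise ValueError("need n_beats >= 3 with at least one retained beat")
        if not 0.0 <= self.root_reflection_coefficient < 1.0:
            raise ValueError("root reflection coefficient must lie in [0, 1)")
        if self.n_reflections < 1:
            raise ValueError("need at least one reflection pass")


@dataclass
class PressureWaveform:
    """Uniformly sampled pressure (mmHg) at one sensor position."""

    samples: np.ndarray
    sample_rate: float
    sensor_position: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise SimulationError("waveform contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class PTTMeasurement:
    """Foot-to-foot transit over a known distance."""

    distance: float
    dt: float

    @property
    def pwv(self) -> float:
        return self.distance / self.dt


def _delayed(x: np.ndarray, t: np.ndarray, delay: float) -> np.ndarray:
    """x(t - delay) by linear interpolation; zero before the record starts."""
    return np.interp(t - delay, t, x, left=0.0)


def simulate(
    geometry: AortaGeometry,
    material: WallMaterial,
    profile: CardiacProfile,
    load: PeripheralLoad,
    pressures: ChamberPressures,
    settings: SimulationSettings = SimulationSettings(),
    sensor_positions: Sequence[float] | None = None,
    noise_mmhg: float = 0.0,
    seed: int | None = None,
) -> list[PressureWaveform]:
    """Run the simulator and return one waveform per sensor position.

    The first ``n_transient`` beats are discarded; the returned records are
    the remaining beats, periodic to well under 0.1 mmHg.  With IVP = EVP
    (TP = 0) changing both together only shifts every waveform by a constant.
    """
    if sensor_positions is None:
        sensor_positions = geometry.sensor_positions

    tp = pressures.tp
    h = geometry.wall_thickness
    rho = settings.fluid_density
    d_eff = settings.effective_diameter
    E = effective_modulus(material, tp, d_eff, h)
    c = moens_pwv(E, h, rho, d_eff, material.poisson_ratio)

    fs = settings.sample_rate
    T = profile.period
    n = int(round(settings.n_beats * T * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    q = flow_rate(profile, t)
    q_bar = profile.mean_flow

    # Two-element Windkessel ripple (exact exponential stepping via lfilter).
    r_wk = load.terminal_resistance
    tau = r_wk * load.windkessel_compliance
    alpha = math.exp(-dt / tau)
    ripple = lfilter([1.0 - alpha], [1.0, -alpha], r_wk * (q - q_bar))

    # Forward wave launched at the root.
    zc_root = characteristic_impedance(diameter_at(geometry, 0.0), c, rho)
    forward = ripple + settings.forward_wave_scale * zc_root * (q - q_bar)

    s_r = geometry.reflection_position
    zc_ab = characteristic_impedance(diameter_at(geometry, s_r), c, rho)
    gamma = reflection_coefficient(zc_ab, load.reflection_resistance)
    gamma_root = settings.root_reflection_coefficient
    if abs(gamma * gamma_root) >= 1.0 - 1e-9:
        raise SimulationError(
            f"unstable reflections: |Gamma.Gamma_root| = {abs(gamma * gamma_root):.3f} >= 1"
        )

    # Valve gating: the root re-reflects only while the valve is closed.
    # The soft valve opens/closes over a finite transition, so the gate is a
    # raised-cosine ramp rather than a hard switch (a hard switch would launch
    # step echoes that never occur in the hardware).
    phase = np.mod(t, T)
    w = min(VALVE_TRANSITION_S, 0.25 * (T - profile.systolic_duration))
    closing = np.clip((phase - profile.systolic_duration) / w, 0.0, 1.0)
    opening = np.clip((T - phase) / w, 0.0, 1.0)
    gate = (
        0.5 * (1.0 - np.cos(np.pi * closing)) * 0.5 * (1.0 - np.cos(np.pi * opening))
    ) * gamma_root

    # Compliant termination: the junction reflects with a one-pole memory
    # (time constant terminal_smoothing_s), dispersing the reflected wave the
    # way a compliant load does.  Zero time constant reflects instantly.
    if settings.terminal_smoothing_s > 0.0:
        beta = math.exp(-dt / settings.terminal_smoothing_s)
        smooth = lambda x: lfilter([1.0 - beta], [1.0, -beta], x)  # noqa: E731
    else:
        smooth = lambda x: x  # noqa: E731

    t_rt = 2.0 * s_r / c
    scale = max(np.max(np.abs(forward)), 1e-12)
    g = forward
    contributions = [forward]
    reflected_at_ab = []
    for _ in range(settings.n_reflections):
        refl = smooth(_delayed(g, t, t_rt))
        g = gate * gamma * refl
        contributions.append(g)
        if np.max(np.abs(g)) < 1e-9 * scale:
            break
    f_root = np.sum(contributions, axis=0)

    level = pressures.ivp_offset + q_bar * r_wk
    k0 = int(round(settings.n_transient * T * fs))
    rng = np.random.default_rng(seed) if noise_mmhg > 0.0 else None

    out = []
    backward_at_ab = gamma * smooth(_delayed(f_root, t, s_r / c))
    for s in sensor_positions:
        s_eff = min(s, s_r)  # distal branch sensors see the bifurcation pressure
        p = (
            level
            + _delayed(f_root, t, s_eff / c)
            + _delayed(backward_at_ab, t, (s_r - s_eff) / c)
        )
        samples = p[k0:]
        if rng is not None:
            samples = samples + rng.normal(0.0, noise_mmhg, size=samples.shape)
        out.append(PressureWaveform(samples, fs, s, t0=k0 * dt))
    return out


def analytic_wave_speed(
    material: WallMaterial,
    pressures: ChamberPressures,
    geometry: AortaGeometry | None = None,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """The Moens-Korteweg speed the simulator uses internally (m/s)."""
    geometry = geometry or vessel_geometry.build_standard_aorta()
    E = effective_modulus(
        material, pressures.tp, settings.effective_diameter, geometry.wall_thickness
    )
    return moens_pwv(
        E,
        geometry.wall_thickness,
        settings.fluid_density,
        settings.effective_diameter,
        material.poisson_ratio,
    )


def detect_feet(samples: np.ndarray, sample_rate: float) -> np.ndarray:
    """Indices of per-beat feet (the lowest point before each upstroke).

    Beats are delimited by the systolic peaks (prominence at half the signal
    range); each foot is the global minimum between consecutive peaks.
    """
    x = np.asarray(samples, dtype=float)
    rng = np.ptp(x)
    if rng <= 1e-9:
        raise PTTError("flat signal: no beats detectable")
    peaks, _ = find_peaks(x, prominence=0.5 * rng)
    if len(peaks) < 2:
        raise PTTError("fewer than two beats detected")
    feet = [int(lo + np.argmin(x[lo:hi])) for lo, hi in zip(peaks[:-1], peaks[1:])]
    return np.asarray(feet, dtype=int)


def measure_ptt(
    waveform_a: PressureWaveform, waveform_b: PressureWaveform, distance: float
) -> PTTMeasurement:
    """Foot-to-foot pulse transit time from the proximal to the distal sensor.

    Per-beat foot pairs are matched causally (0 < dt < 60% of the beat
    interval) and averaged; PWV = distance/dt.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if waveform_a.sample_rate != waveform_b.sample_rate:
        raise ValueError("waveforms must share a sample rate")
    fs = waveform_a.sample_rate
    feet_a = detect_feet(waveform_a.samples, fs)
    feet_b = detect_feet(waveform_b.samples, fs)
    t_a = waveform_a.t0 + feet_a / fs
    t_b = waveform_b.t0 + feet_b / fs
    beat = float(np.median(np.diff(t_a))) if len(t_a) > 1 else waveform_a.duration
    dts = []
    for ta in t_a:
        ahead = t_b[(t_b > ta) & (t_b - ta < 0.6 * beat)]
        if len(ahead):
            dts.append(float(ahead[0] - ta))
    if not dts:
        raise PTTError("no causal foot pairs found (delay zero, negative, or too large)")
    return PTTMeasurement(distance=distance, dt=float(np.mean(dts)))


def waveforms_to_frame(waveforms: Sequence[PressureWaveform]) -> pd.DataFrame:
    """Tidy table (time_s, sensor_position_m, pressure_mmHg) for CSV export."""
    frames = [
        pd.DataFrame(
            {
                "time_s": w.times,
                "sensor_position_m": w.sensor_position,
                "pressure_mmHg": w.samples,
            }
        )
        for w in waveforms
    ]
    return pd.concat(frames, ignore_index=True)
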