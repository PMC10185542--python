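"""Pulse-wave analysis of central aortic pressure waveforms.

Mirrors the acquisition chain of the hardware (30 Hz zero-phase low-pass,
matching the DAQ filter) and extracts the scalar indices used clinically:
systolic/diastolic pressure (per-beat max/min), pulse pressure, the two mean
arterial pressure conventions (true time average and the clinical
(SBP + 2.DBP)/3 formula), augmentation pressure and index, and the foot and
dicrotic-notch timings.  The augmentation pressure is the rise from the
systolic inflection point (the shoulder where the reflected wave joins the
forward wave) to the systolic peak; when no shoulder exists (no reflected
wave) it is reported as absent rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .wave_engine import PressureWaveform, detect_feet

LOWPASS_CUTOFF_DEFAULT_HZ = 30.0
CFPWV_TO_APWV = 0.87  # aortic path excludes the fast femoral section


class FeatureError(RuntimeError):
    """Waveform does not contain extractable beats."""


@dataclass(frozen=True)
class WaveformFeatures:
    """Beat-averaged scalar indices of one pressure waveform (mmHg, s, %)."""

    sbp: float
    dbp: float
    pp: float
    map_formula: float
    map_integral: float
    foot_time: float
    ap: float | None = None
    aix: float | None = None
    notch_time: float | None = None

    def to_dict(self) -> dict:
        return {
            "sbp_mmhg": round(self.sbp, 1),
            "dbp_mmhg": round(self.dbp, 1),
            "pp_mmhg": round(self.pp, 1),
            "map_formula_mmhg": round(self.map_formula, 1),
            "map_integral_mmhg": round(self.map_integral, 1),
            "foot_time_s": self.foot_time,
            "ap_mmhg": None if self.ap is None else round(self.ap, 1),
            "aix_percent": None if self.aix is None else round(self.aix, 1),
            "notch_time_s": self.notch_time,
        }


def lowpass_filter(
    waveform: PressureWaveform, cutoff: float = LOWPASS_CUTOFF_DEFAULT_HZ
) -> PressureWaveform:
    """Zero-phase 4th-order Butterworth low-pass; DC gain exactly 1."""
    if cutoff >= waveform.sample_rate / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    b, a = butter(4, cutoff, fs=waveform.sample_rate)
    y = filtfilt(b, a, waveform.samples)
    return PressureWaveform(y, waveform.sample_rate, waveform.sensor_position, waveform.t0)


def map_formula(sbp: float, dbp: float) -> float:
    """Clinical mean arterial pressure, (SBP + 2.DBP)/3."""
    if sbp < dbp:
        raise ValueError("SBP must be >= DBP")
    return (sbp + 2.0 * dbp) / 3.0


def aix(ap: float, pp: float) -> float:
    """Augmentation index, 100.AP/PP (percent)."""
    if pp <= 0:
        raise ValueError("pulse pressure must be positive")
    if not 0.0 <= ap <= pp:
        raise ValueError("augmentation pressure must lie in [0, PP]")
    return 100.0 * ap / pp


def cfpwv_to_apwv(cfpwv: float) -> float:
    """Aortic PWV estimated from carotid-femoral PWV (factor 0.87)."""
    if cfpwv <= 0:
        raise ValueError("cfPWV must be positive")
    return CFPWV_TO_APWV * cfpwv


def _shoulder_index(x: np.ndarray, dt: float, foot: int, peak: int) -> int | None:
    """Systolic shoulder (P1, the forward-wave peak) before the systolic peak.

    On waveforms where the reflected wave forms a distinct augmented peak the
    shoulder is the first local maximum of the upstroke limb.  When forward
    and reflected waves merge without a separate local maximum, the shoulder
    is the concave-to-convex zero crossing of the second derivative closest
    to the peak.  Returns None when no shoulder precedes the peak (no
    reflected-wave augmentation).
    """
    if peak - foot < 5:
        return None
    seg = x[foot:peak]
    local_max, _ = find_peaks(seg, prominence=0.02 * max(np.ptp(x), 1e-9))
    if len(local_max):
        return int(foot + local_max[0])
    d1 = np.gradient(x, dt)
    d2 = np.gradient(d1, dt)
    guard = max(3, int(round(0.01 / dt)))  # stay clear of the peak itself
    lo, hi = foot + 2, peak - guard
    if hi <= lo:
        return None
    s = d2[lo:hi]
    crossings = np.nonzero((s[:-1] < 0.0) & (s[1:] >= 0.0))[0]
    # a genuine shoulder sits in the deceleration phase, not on the upstroke
    slope_cap = 0.25 * np.max(d1[foot:peak])
    crossings = [i for i in crossings if d1[lo + i + 1] < slope_cap]
    if not crossings:
        return None
    return int(lo + crossings[-1] + 1)


def _notch_index(x: np.ndarray, peak: int, end: int) -> int | None:
    """First early-diastolic local minimum after the systolic peak, or None."""
    hi = peak + max(3, int(0.5 * (end - peak)))
    seg = x[peak:hi]
    if len(seg) < 5:
        return None
    mins, _ = find_peaks(-seg, prominence=0.01 * max(np.ptp(x), 1e-9))
    if len(mins) == 0:
        return None
    return int(peak + mins[0])


def extract_features(
    waveform: PressureWaveform,
    lowpass_cutoff: float | None = LOWPASS_CUTOFF_DEFAULT_HZ,
) -> WaveformFeatures:
    """Beat-averaged features of a (multi-beat) pressure waveform.

    The waveform is low-pass filtered (default 30 Hz, pass None to skip),
    segmented into beats by its feet, and per-beat features are averaged.
    Partial beats at the edges are discarded.
    """
    w = waveform if lowpass_cutoff is None else lowpass_filter(waveform, lowpass_cutoff)
    x = w.samples
    fs = w.sample_rate
    dt = 1.0 / fs
    try:
        feet = detect_feet(x, fs)
    except Exception as exc:  # noqa: BLE001 - re-raise with feature context
        raise FeatureError(f"no beats detected: {exc}") from exc
    if len(feet) < 2:
        raise FeatureError("need at least one full foot-to-foot beat")

    sbp_l, dbp_l, mapint_l, foot_l, ap_l, notch_l = [], [], [], [], [], []
    for lo, hi in zip(feet[:-1], feet[1:]):
        beat = x[lo:hi]
        peak = int(lo + np.argmax(beat))
        sbp_l.append(float(np.max(beat)))
        dbp_l.append(float(np.min(beat)))
        mapint_l.append(float(np.mean(beat)))
        foot_l.append(w.t0 + lo * dt)
        sh = _shoulder_index(x, dt, lo, peak)
        if sh is not None and x[peak] >= x[sh]:
            ap_l.append(float(x[peak] - x[sh]))
        notch = _notch_index(x, peak, hi)
        if notch is not None:
            notch_l.append(w.t0 + notch * dt)

    sbp = float(np.mean(sbp_l))
    dbp = float(np.mean(dbp_l))
    pp = sbp - dbp
    ap = float(np.mean(ap_l)) if len(ap_l) == len(sbp_l) else None
    return WaveformFeatures(
        sbp=sbp,
        dbp=dbp,
        pp=pp,
        map_formula=map_formula(sbp, dbp),
        map_integral=float(np.mean(mapint_l)),
        foot_time=float(foot_l[0]),
        ap=ap,
        aix=None if ap is None or pp <= 0 else aix(min(max(ap, 0.0), pp), pp),
        notch_time=float(np.mean(notch_l)) if notch_l else None,
    )


def read_waveform_csv(path) -> PressureWaveform:
    """Read a two-column (time_s, pressure_mmHg) CSV into a waveform."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    p = df.iloc[:, 1].to_numpy(dtype=float)
    steps = np.diff(t)
    if len(steps) == 0 or np.ptp(steps) > 1e-6 * np.mean(steps):
        raise ValueError("time column must be uniformly sampled")
    return PressureWaveform(p, 1.0 / float(np.mean(steps)), sensor_position=0.0, t0=float(t[0]))


def write_waveform_csv(waveform: PressureWaveform, path) -> None:
    pd.DataFrame({"time_s": waveform.times, "pressure_mmHg": waveform.samples}).to_csv(
        path, index=False
    )
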