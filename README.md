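# aortasim

A digital twin of a physiology-based hardware cardiovascular simulator: a
silicone replica of the human central aorta driven by a ventricular piston
pump, used to reproduce the human central blood-pressure waveform and its
response to cardiovascular parameters.  `aortasim` models the same physics in
software — forward and reflected pressure waves superposed on a delay line
travelled at the Moens–Korteweg speed, with a Windkessel terminal load — and
ships the full pulse-wave-analysis toolkit needed to analyse the output
(SBP/DBP/MAP/PP, augmentation pressure and index, foot-to-foot pulse transit
time and pulse wave velocity).

It is intended for people who study blood-pressure waveform genesis or who
develop pulse-wave algorithms and need a controllable, fully reproducible
source of central-aortic pressure signals with known ground truth.

## Model

The pressure wave speed in a thin-walled elastic tube of modulus *E*, wall
thickness *h*, diameter *D*, Poisson ratio *ν*, filled with fluid of density
*ρ_f*, is the Moens–Korteweg speed

    PWV = sqrt( E h / (ρ_f D (1 − ν²)) )

The artificial aorta is a 743 mm, 1:1-scale path (half-circle arch of 50 mm
radius at 28 mm bore, abdominal aorta tapering 26→16 mm over 512 mm, 14 mm
femoral branch past the 80° bifurcation, 2 mm wall).  A forward wave
Zc·(Q − Q̄), with Q the half-sine ventricular ejection and Zc = ρc/A the
characteristic impedance, rides on the ripple of a two-element Windkessel
(drainage resistance R, compliance C) and travels to the aortic bifurcation,
where it reflects with Γ = (R_AB − Zc)/(R_AB + Zc) against the junction
impedance; the closed aortic valve partially re-reflects returning waves
during diastole.  The silicone wall strain-softens: its modulus falls when
the transmural pressure TP = IVP − EVP is positive, which slows the waves —
a sealed compliance chamber holding TP = 0 keeps the wall at its zero-strain
stiffness (346 kPa, wave speed ≈ 6.5 m/s).

Mean arterial pressure uses the clinical formula MAP = (SBP + 2·DBP)/3; the
augmentation index is AIx = 100·AP/PP, with AP the rise from the systolic
shoulder (where the reflected wave joins) to the systolic peak.

## Worked example

```python
from aortasim import extract_features, measure_ptt, simulate_config, standard_config

config = standard_config()          # HR 75, SV 70 mL, 15% occlusion, TP = 0
g = config.geometry
root, aa, ab = simulate_config(config, sensor_positions=[0.0, g.aa_position, g.ab_position])

print(extract_features(root).to_dict())
ptt = measure_ptt(aa, ab, g.sensor_distance_aa_ab)
print(f"PTT {ptt.dt*1000:.1f} ms over 551 mm -> aPWV {ptt.pwv:.2f} m/s")
```

prints

```
{'sbp_mmhg': 120.0, 'dbp_mmhg': 80.0, 'pp_mmhg': 40.0,
 'map_formula_mmhg': 93.3, 'map_integral_mmhg': 100.5,
 'foot_time_s': 7.985, 'ap_mmhg': 5.3, 'aix_percent': 13.3,
 'notch_time_s': None}
PTT 84.0 ms over 551 mm -> aPWV 6.56 m/s
```

i.e. the calibrated standard configuration reproduces the human-standard
operating point: 120/80 mmHg, MAP 93.3 mmHg, pulse pressure 40 mmHg,
augmentation 5.3 mmHg (AIx 13.3%), and an aortic PWV within 0.05 m/s of the
6.54 m/s design target, measured exactly as on the bench (lowest-point foot
detection between the aortic-arch and bifurcation sensors 551 mm apart).

The same operations are available from the shell:

```
aortasim simulate --out-dir run/            # tidy CSV + per-sensor features
aortasim sweep --kind hr --out-dir run/     # bench parameter sweeps + trend checks
aortasim features --input run/wave.csv      # pulse-wave analysis of any waveform CSV
aortasim calibrate                          # refit the calibration constants
```

`aortasim sweep` reproduces the bench protocol: heart rate 60–100 beats/min,
stroke volume 60–80 mL, constant cardiac output 3.6 L/min, both raised
together, peripheral occlusion 5–25%, IVP = EVP levels 40–120 mmHg, and
transmural pressure 0–20 mmHg at fixed MAP 93 mmHg — and checks the
clinically expected directions of SBP, DBP, MAP, PP and PTT on each grid.

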