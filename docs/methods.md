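# Methods

## Scope and intent

`aortasim` is a lumped/1-D wave model of a hardware cardiovascular simulator
built around a silicone replica of the human central aorta.  The hardware
defines the physics to emulate: a piston pump ejects a stroke through a
one-way valve into the artificial aorta; the pressure wave travels to the
aortic bifurcation (AB), reflects against the peripheral load, and the
superposition of forward and reflected waves forms the central
blood-pressure waveform; a reservoir and a sealed compliance chamber set the
intravascular (IVP) and extravascular (EVP) pressures of the wall.  The
package reproduces the standard operating point (120/80 mmHg at 75 beats/min
and 70 mL, aortic PWV ≈ 6.5 m/s, AIx 13.3%) and the directional responses to
heart rate, stroke volume, peripheral resistance and transmural pressure.
It is deliberately not a discretised Navier–Stokes solver: the aorta is
lossless and inviscid (the large-bore aorta is inertia-dominated), and all
acceptance-level quantities are deterministic.

## Geometry

The vessel is a single 1-D path parameterised by arc length from the aortic
root: a half-circle arch (radius of curvature 50 mm, arc ≈ 157 mm, constant
28 mm bore — the half-circle is our reading of the anatomical arch, chosen so
the segment lengths sum close to the 743 mm total with a ~74 mm femoral
remainder), a 512 mm abdominal aorta tapering linearly 26→16 mm, and a 14 mm
femoral branch past the 80° bifurcation.  Wall thickness is 2 mm throughout.
The two iliac branches are symmetric; one is followed and the terminal load
stands for their parallel combination.  Sensors sit every 100 mm; the named
AA and AB sensors used for transit times are 551 mm apart.  Three published
lengths are deliberately kept as distinct constants (743 mm total path,
712 mm transit reference length, 551 mm sensor distance) because none of
them is derivable from another.  Simplified side branches (renal, right
subclavian) have no stated dimensions and are omitted.

## Wall mechanics

Wave speed uses the Moens–Korteweg relation.  Because the relation takes a
single diameter while the path tapers 28→16 mm, a pulse-averaged effective
diameter D_eff = 21.8 mm (configurable) is used for path-level speed; it
lies inside the physical taper range and makes the inverse relation at the
6.54 m/s design target return the 350 kPa design stiffness.  Poisson ratio
defaults to 0.5 (incompressible elastomer).

The cast silicone strain-softens.  Two closures are provided:

* **Measured table (default).**  A monotone (PCHIP) interpolant through the
  bench-measured (TP, modulus) knots (0, 346 kPa), (10, 248 kPa),
  (20, 80 kPa).  The measured knots are treated as ground truth rather than
  re-derived, because the bench's modulus estimates at TP > 0 fold in the
  (unreported) expanded diameter and are not consistent with a
  constant-diameter inversion of the wave-speed relation.
* **Laplace closure.**  For materials without tabulated data: hoop stress
  σ = TP·r/h, strain from the material's strain→modulus curve solved by a
  damped fixed point (tolerance 1e-8 on strain, 100 iterations max).

At TP = 0 both return exactly the zero-strain modulus: the compliance
chamber's role — matching EVP to IVP so the wall never strains — falls out
of the model for free, which is why equal IVP/EVP changes shift every
waveform by a pure constant with no timing change.

## Ventricular drive

The ejection template is a half-sine of area SV over a systolic interval
occupying a fixed 0.35 fraction of the beat (0.28 s at 75 beats/min): the
piston drive profile scales with the pulsation period, which is how a pump
controlled by its period behaves.  The aortic valve makes root flow
non-negative and diastolic refill bypasses the aorta, so the flow integrates
to exactly one stroke volume per beat — this conservation is exact, not
approximate, and is property-tested.

## Wave engine

The core is a linear lossless delay line from root to AB with:

* forward wave at the root F(t) = W(t) + a·Zc_root·(Q(t) − Q̄), where W is
  the zero-mean ripple of a two-element Windkessel (exact exponential
  stepping) and a is a calibrated gain;
* terminal reflection at the AB with Γ = (R_AB − Zc_AB)/(R_AB + Zc_AB)
  against the junction impedance R_AB, applied through a one-pole 30 ms
  memory ("compliant termination").  An instantaneous reflector makes the
  discrete reflected hump's beat-phase alignment visible as non-monotone
  SBP/MAP across the heart-rate grid — an interference artifact of the
  single-delay-line idealisation that a compliant junction disperses;
* partial re-reflection at the root while the valve is closed
  (coefficient 0.2), gated by a raised-cosine ramp over a 20 ms valve
  transition.  A hard gate launches step echoes that corrupt lowest-point
  foot detection downstream; the soft valve in the hardware closes over a
  finite time, and the ramp encodes that;
* a mean level IVP + Q̄·R set by the reservoir offset and the drainage
  resistance.

Two distinct terminal quantities represent the periphery.  The **drainage
resistance** (DC/Windkessel path, 0.15 mmHg·s/mL at the 15% reference
occlusion) scales with the ball-valve setting by the orifice law
R(o) = R_ref·((1−o_ref)/(1−o))².  The **junction impedance** at the AB
(3.61 mmHg·s/mL, Γ ≈ 0.87) is geometric and occlusion-independent: the AB is
the anatomical reflection site, and the valves sit 74 mm further downstream
near the reservoir.  A single occlusion-scaled resistance serving both roles
cannot simultaneously produce positive reflection (it must exceed Zc_AB)
and let a stroke-volume rise lower diastolic pressure (it must stay small),
and it drives pulse pressure in the wrong direction under occlusion changes.

Waves below 1e-9 of the forward amplitude are dropped; with |Γ·Γ_root| ≈ 0.17
a handful of round trips suffice.  Twelve beats are simulated and the first
nine discarded, enough for the slowest configuration (TP = 20 mmHg, round
trip 0.43 s) to reach periodicity below 0.1 mmHg.  The default sample rate
is 1 kHz (the 30 Hz analysis low-pass makes results insensitive to it);
the hardware's 8 kHz acquisition rate is a config switch and is used by the
acceptance script.  The simulator is fully deterministic; optional Gaussian
measurement noise takes an explicit seed.

## Calibration

Wave speed is fixed by material and geometry (346 kPa, D_eff 21.8 mm →
6.51 m/s) and is not a fitting degree of freedom.  The drainage resistance
and Windkessel compliance (4.21 mL/mmHg, diastolic time constant ≈ 0.63 s)
are set a priori by trend analysis: the resistance must stay below
≈0.2 mmHg·s/mL or raising stroke volume no longer lowers diastolic pressure,
and the compliance is the smallest value for which lowering the occlusion
still raises pulse pressure.  The two remaining constants — forward-wave
gain and junction impedance — are fitted by deterministic least squares so
the root waveform of the standard configuration reproduces PP = 40 mmHg and
AIx = 13.3%, after which the reservoir offset is set exactly so DBP = 80
(SBP = 120 then follows).  The fit goes through the identical feature
pipeline used for analysis (30 Hz zero-phase low-pass included), converges
to machine precision, and the fitted values ship as frozen defaults;
`aortasim calibrate` re-runs it.

## Pulse-wave analysis

Feature extraction mirrors the bench's acquisition chain: a 4th-order
zero-phase Butterworth low-pass at 30 Hz (DC gain exactly 1), beat
segmentation by feet, per-beat features averaged.  The foot is the per-beat
lowest point, matching the bench's definition; transit times pair feet
causally between sensors and PWV = distance/Δt.  Transit times are measured
on the raw simulated waveforms — the model output is already band-limited
and noise-free, so the filter is applied only where the bench applied it
for analysis.  The systolic shoulder (P1) is the first local maximum of the
upstroke limb before the systolic peak; when forward and reflected waves
merge without a separate maximum, the fallback is the concave-to-convex
zero crossing of the second derivative closest to the peak, restricted to
the deceleration phase (first derivative below a quarter of the peak
upstroke slope) so upstroke inflections are never mistaken for shoulders.
AP = peak − shoulder; when no shoulder exists (matched load, no reflection)
AP and AIx are reported absent, never zero.  AIx uses the AP/PP convention
(the convention consistent with the reported 5.3/40 = 13.3%).  Both MAP
conventions are reported: the true time average and the clinical
(SBP + 2·DBP)/3 formula; trend tables use the clinical formula.

## Sweeps and trend checks

`experiments.run_sweep` reproduces the bench grids (HR 60–100 by 10; SV
60–80 by 5; constant CO 3.6 L/min with SV = CO/HR; HR and SV raised
pairwise; occlusion 5–25% by 5%; IVP = EVP 40–120 by 20; TP 0–20 by 10 with
the mean pressure re-anchored to 93 mmHg by an exact additive correction).
`trend_report` asserts the clinically expected directions, including strict
monotonicity where the bench reported a clear ordering, and treats "X
maintained while Y changes" statements as span(X) ≤ half of span(Y).  The
full suite runs in well under a minute on one CPU.

## What the model does and does not capture

Passing trends show that the wave-superposition mechanism plus a Windkessel
load reproduce the *directions* of the bench's responses; the sweep
*magnitudes* away from the calibration anchors are not expected to match a
physical rig (notably, the pulse-pressure response to occlusion is much
weaker here than on the bench).  A single discrete reflection site plus a
lumped terminal cannot produce the smoothly distributed reflection of a
real arterial tree; the compliant-termination memory is a coarse surrogate.
There is no viscoelasticity, no anisotropy, no venous return dynamics (the
reservoir is a fixed-pressure boundary), no dicrotic-notch valve fluid
dynamics (a notch is reported only if the waveform happens to show one),
and negative transmural pressure (chamber over-pressurisation) is outside
the modelled range.  Ventricular pressure is not a modelled chamber.  The
measured-table softening curve is only as good as its three knots;
between-knot values are a monotone interpolation, not measurements.
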