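"""Unit boundary.

All internal computation is SI (Pa, m, s, kg/m^3) except pressures handed to
the user, which are mmHg, and hydraulic resistances/compliances, which use the
clinical mmHg.s/mL convention.  The mmHg<->Pa conversion factor lives here and
nowhere else.
"""

PA_PER_MMHG = 133.322


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG


def impedance_si_to_clinical(z_pa_s_per_m3: float) -> float:
    """Convert Pa.s/m^3 to mmHg.s/mL (1 m^3 = 1e6 mL)."""
    return z_pa_s_per_m3 / PA_PER_MMHG / 1e6


def impedance_clinical_to_si(z_mmhg_s_per_ml: float) -> float:
    return z_mmhg_s_per_ml * PA_PER_MMHG * 1e6
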