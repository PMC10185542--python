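"""Wall mechanics: Moens-Korteweg wave speed and the silicone softening model.

The pressure wave speed in a thin-walled elastic tube filled with
incompressible fluid is

    PWV = sqrt( E h / (rho_f D (1 - nu^2)) )

with wall modulus E, wall thickness h, inner diameter D, Poisson ratio nu and
fluid density rho_f.  For the tapered aorta a single pulse-averaged effective
diameter D_eff enters this relation; the calibrated default of 21.8 mm lies
inside the physical 16-28 mm taper range and makes the inverse relation at
the 6.54 m/s target reproduce the 350 kPa design stiffness.

Biomimetic silicone strain-softens: its modulus falls as the wall stretches.
When the compliance chamber holds the pulse-averaged transmural pressure
(TP = IVP - EVP) at zero the wall stays at zero strain and keeps its
zero-strain modulus E0.  At TP > 0 the wall expands and softens.  Two
closures are provided:

* ``tp_table`` (default): a monotone interpolant through measured
  (TP, modulus) knots -- the bench-measured softening of the standard aorta
  (346, 248, 80 kPa at TP = 0, 10, 20 mmHg).
* ``strain_softening``: a Laplace-law closure for materials without
  tabulated data -- hoop stress sigma = TP.r/h, strain from the material's
  strain->modulus curve solved self-consistently by damped fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .units import mmhg_to_pa

POISSON_DEFAULT = 0.5  # incompressible elastomer
E0_SORTACLEAR12_PA = 346e3  # measured zero-strain modulus of the cast silicone
E_TARGET_PA = 350e3  # design stiffness from the 6.54 m/s target
D_EFF_DEFAULT_M = 0.0218  # calibrated pulse-averaged effective diameter
FLUID_DENSITY_KG_M3 = 1000.0  # distilled water working fluid

#: Measured (TP mmHg, modulus Pa) softening knots of the standard aorta.
TP_MODULUS_KNOTS_DEFAULT = ((0.0, 346e3), (10.0, 248e3), (20.0, 80e3))


class ConvergenceError(RuntimeError):
    """Fixed-point iteration for the wall strain did not converge."""


@dataclass(frozen=True)
class ChamberPressures:
    """Reservoir (IVP) and compliance-chamber (EVP) pressurization, mmHg."""

    ivp_offset: float
    evp: float

    @property
    def tp(self) -> float:
        """Transmural pressure, IVP - EVP (mmHg)."""
        return self.ivp_offset - self.evp


@dataclass(frozen=True)
class WallMaterial:
    """Elastic wall with optional softening behaviour.

    ``behavior`` is one of ``constant``, ``tp_table``, ``strain_softening``
    or ``strain_hardening``.  ``tp_modulus_knots`` holds (TP mmHg, E Pa)
    pairs for ``tp_table``; ``strain_modulus_knots`` holds (strain, E Pa)
    pairs for the strain-coupled behaviours.
    """

    e0: float
    poisson_ratio: float = POISSON_DEFAULT
    behavior: str = "constant"
    tp_modulus_knots: tuple[tuple[float, float], ...] = ()
    strain_modulus_knots: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.e0 <= 0:
            raise ValueError("E0 must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.behavior not in ("constant", "tp_table", "strain_softening", "strain_hardening"):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.behavior == "tp_table":
            _validate_knots(self.tp_modulus_knots, self.e0, non_increasing=True, x_name="TP")
        if self.behavior == "strain_softening":
            _validate_knots(self.strain_modulus_knots, self.e0, non_increasing=True, x_name="strain")
        if self.behavior == "strain_hardening":
            _validate_knots(self.strain_modulus_knots, self.e0, non_increasing=False, x_name="strain")

    def to_dict(self) -> dict:
        """Serializable form; moduli in kPa, as in config files."""
        return {
            "e0_kpa": self.e0 / 1e3,
            "poisson_ratio": self.poisson_ratio,
            "behavior": self.behavior,
            "tp_modulus_knots": [[tp, e / 1e3] for tp, e in self.tp_modulus_knots],
            "strain_modulus_knots": [[s, e / 1e3] for s, e in self.strain_modulus_knots],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WallMaterial":
        return cls(
            e0=d["e0_kpa"] * 1e3,
            poisson_ratio=d["poisson_ratio"],
            behavior=d["behavior"],
            tp_modulus_knots=tuple((tp, e * 1e3) for tp, e in d.get("tp_modulus_knots", [])),
            strain_modulus_knots=tuple((s, e * 1e3) for s, e in d.get("strain_modulus_knots", [])),
        )


def _validate_knots(
    knots: Sequence[tuple[float, float]], e0: float, non_increasing: bool, x_name: str
) -> None:
    if not knots:
        raise ValueError(f"behavior requires ({x_name}, modulus) knots")
    xs = [x for x, _ in knots]
    es = [e for _, e in knots]
    if xs[0] != 0.0 or abs(es[0] - e0) > 1e-9 * e0:
        raise ValueError(f"knots must start at ({x_name}=0, E0)")
    if any(e <= 0 for e in es):
        raise ValueError("moduli must be positive")
    if any(x1 <= x0 for x0, x1 in zip(xs, xs[1:])):
        raise ValueError(f"{x_name} knots must be strictly increasing")
    pairs = zip(es, es[1:])
    if non_increasing and any(e1 > e0_ for e0_, e1 in pairs):
        raise ValueError("softening curve must be monotone non-increasing")
    if not non_increasing and any(e1 < e0_ for e0_, e1 in zip(es, es[1:])):
        raise ValueError("hardening curve must be monotone non-decreasing")


def _interp(knots: tuple[tuple[float, float], ...], x: float) -> float:
    """Monotone (PCHIP) interpolation, clamped beyond the last knot."""
    xs = np.array([k[0] for k in knots])
    es = np.array([k[1] for k in knots])
    if len(xs) == 1:
        return float(es[0])
    x_clamped = min(max(x, xs[0]), xs[-1])
    return float(PchipInterpolator(xs, es)(x_clamped))


def moens_pwv(E: float, h: float, rho: float, D: float, nu: float) -> float:
    """Moens-Korteweg pressure wave speed (m/s)."""
    if E <= 0 or h <= 0 or rho <= 0 or D <= 0:
        raise ValueError("E, h, rho and D must be positive")
    if not 0.0 <= nu < 1.0:
        raise ValueError("Poisson ratio must lie in [0, 1)")
    return math.sqrt(E * h / (rho * D * (1.0 - nu**2)))


def moens_inverse_E(pwv: float, h: float, rho: float, D: float, nu: float) -> float:
    """Wall modulus (Pa) required for a given wave speed; exact algebraic inverse."""
    if pwv <= 0:
        raise ValueError("PWV must be positive")
    if h <= 0 or rho <= 0 or D <= 0:
        raise ValueError("h, rho and D must be positive")
    if not 0.0 <= nu < 1.0:
        raise ValueError("Poisson ratio must lie in [0, 1)")
    return pwv**2 * rho * D * (1.0 - nu**2) / h


def softening_curve_from_table(points: Sequence[tuple[float, float]]) -> WallMaterial:
    """Material whose effective modulus interpolates measured (TP mmHg, E Pa) knots."""
    pts = tuple(sorted((float(tp), float(e)) for tp, e in points))
    if len(pts) == 1:
        if pts[0][0] != 0.0:
            raise ValueError("a single knot must be (0, E0)")
        return WallMaterial(e0=pts[0][1], behavior="constant")
    return WallMaterial(e0=pts[0][1], behavior="tp_table", tp_modulus_knots=pts)


def default_wall_material() -> WallMaterial:
    """Standard-aorta silicone: Table-knot softening anchored at 346 kPa."""
    return softening_curve_from_table(TP_MODULUS_KNOTS_DEFAULT)


def effective_modulus(
    material: WallMaterial,
    tp_mmhg: float,
    diameter: float = D_EFF_DEFAULT_M,
    wall_thickness: float = 0.002,
) -> float:
    """Pulse-averaged wall modulus (Pa) at transmural pressure TP (mmHg).

    TP = 0 returns exactly E0 for every behaviour; for softening behaviours
    the result is monotone non-increasing in TP.  Negative TP (chamber
    over-pressurization) is outside the modelled range.
    """
    if tp_mmhg < 0:
        raise ValueError("negative transmural pressure is not modelled")
    if material.behavior == "constant" or tp_mmhg == 0.0:
        return material.e0
    if material.behavior == "tp_table":
        return _interp(material.tp_modulus_knots, tp_mmhg)
    # Laplace-law closure: hoop stress sigma = TP.r/h, strain eps = sigma/E(eps)
    sigma = mmhg_to_pa(tp_mmhg) * (diameter / 2.0) / wall_thickness
    eps = sigma / material.e0
    damping = 0.5
    for _ in range(100):
        e_here = _interp(material.strain_modulus_knots, eps)
        eps_new = (1.0 - damping) * eps + damping * sigma / e_here
        if abs(eps_new - eps) < 1e-8:
            return _interp(material.strain_modulus_knots, eps_new)
        eps = eps_new
    raise ConvergenceError("wall strain fixed point did not converge in 100 iterations")
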