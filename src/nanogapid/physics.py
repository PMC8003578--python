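"""Direct-tunneling current model and single-level junction transmission.

The gap between two gold electrodes carries a tunneling current that decays
exponentially with the gap distance ``l``::

    I(l) = const * exp(-beta * l),    beta = (4*pi/h) * sqrt(2*m*w)

where ``h`` is the Planck constant, ``m`` the electron mass and ``w`` the
work function of the electrode metal.  Inverting the relation gives the gap
distance from a measured current, which is how a break-junction setup holds
a sub-nanometre gap under feedback.

When a molecule bridges the gap, the current is proportional to the
transmission of the single-level junction::

    tau = 4*G_L*G_R / (eps**2 + (G_L + G_R)**2)

with ``eps`` the alignment of the conducting orbital relative to the Fermi
level and ``G_L``, ``G_R`` the electrode couplings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EV_TO_J",
    "PLANCK_H",
    "ELECTRON_MASS_KG",
    "AU111_WORK_FUNCTION_EV",
    "TunnelParams",
    "JunctionCoupling",
    "decay_constant",
    "tunnel_current",
    "gap_distance_from_current",
    "gap_change_from_current_ratio",
    "transmission",
]

#: CODATA 2018 elementary charge; converts eV to J exactly.
EV_TO_J = 1.602176634e-19
#: CODATA 2018 Planck constant (J s), exact by SI definition.
PLANCK_H = 6.62607015e-34
#: Electron rest mass (kg), at the two-digit precision customary in
#: break-junction gap estimation.
ELECTRON_MASS_KG = 9.1e-31
#: Work function of the Au(111) surface (eV).
AU111_WORK_FUNCTION_EV = 5.1


@dataclass(frozen=True)
class TunnelParams:
    """Parameters of the direct-tunneling current model.

    Parameters
    ----------
    work_function_ev:
        Barrier height ``w`` in eV (converted internally to J).
    mass_kg:
        Tunneling carrier mass in kg.
    planck_js:
        Planck constant in J s.
    prefactor_a:
        The current scale ``const`` in A.  It depends on junction geometry
        and bias and is not fixed by the model, so it is a user parameter;
        gap estimation is also available in a ratio form that cancels it.
    """

    work_function_ev: float = AU111_WORK_FUNCTION_EV
    mass_kg: float = ELECTRON_MASS_KG
    planck_js: float = PLANCK_H
    prefactor_a: float = 1.0

    def __post_init__(self) -> None:
        for name in ("work_function_ev", "mass_kg", "planck_js", "prefactor_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class JunctionCoupling:
    """Single-level junction: orbital offset and electrode couplings (eV)."""

    epsilon_ev: float
    gamma_l_ev: float
    gamma_r_ev: float

    def __post_init__(self) -> None:
        if self.gamma_l_ev <= 0 or self.gamma_r_ev <= 0:
            raise ValueError("electrode couplings must be strictly positive")


def decay_constant(params: TunnelParams = TunnelParams()) -> float:
    """Exponential decay constant beta = (4*pi/h)*sqrt(2*m*w), in nm^-1.

    For gold electrodes (w = 5.1 eV) this is ~23.1 nm^-1: the current drops
    by roughly an order of magnitude per angstrom, which is what makes the
    tunneling current a sub-nanometre ruler.
    """
    w_j = params.work_function_ev * EV_TO_J
    beta_per_m = (4.0 * math.pi / params.planck_js) * math.sqrt(2.0 * params.mass_kg * w_j)
    return beta_per_m * 1e-9


def tunnel_current(gap_nm: float, params: TunnelParams = TunnelParams()) -> float:
    """Forward model: I = const * exp(-beta * l) in A, ``gap_nm`` in nm."""
    if gap_nm < 0:
        raise ValueError("gap distance must be non-negative")
    return params.prefactor_a * math.exp(-decay_constant(params) * gap_nm)


def gap_distance_from_current(current_a: float, params: TunnelParams = TunnelParams()) -> float:
    """Invert the tunneling law: l = ln(const / I) / beta, in nm.

    Requires ``0 < I <= const``; the inverse of :func:`tunnel_current` to
    machine precision.
    """
    if current_a <= 0:
        raise ValueError("current must be strictly positive")
    if current_a > params.prefactor_a:
        raise ValueError("current exceeds the zero-gap prefactor; no real gap solves it")
    return math.log(params.prefactor_a / current_a) / decay_constant(params)


def gap_change_from_current_ratio(
    current_a: float, reference_current_a: float, params: TunnelParams = TunnelParams()
) -> float:
    """Gap change (nm) implied by a current ratio; the prefactor cancels.

    Positive when the current dropped relative to the reference, i.e. the
    gap widened: dl = ln(I_ref / I) / beta.
    """
    if current_a <= 0 or reference_current_a <= 0:
        raise ValueError("currents must be strictly positive")
    return math.log(reference_current_a / current_a) / decay_constant(params)


def transmission(coupling: JunctionCoupling) -> float:
    """Landauer transmission of a symmetric-barrier single-level junction.

    tau = 4*G_L*G_R / (eps^2 + (G_L+G_R)^2); bounded by 1 (AM-GM), equal to
    1 only on resonance (eps=0) with symmetric couplings.
    """
    gl, gr = coupling.gamma_l_ev, coupling.gamma_r_ev
    return 4.0 * gl * gr / (coupling.epsilon_ev**2 + (gl + gr) ** 2)
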