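"""Instrument protocol and indenter-tip descriptions.

Units follow the instrument convention throughout the package: load in mN,
depth in nm, time in s, moduli in GPa.  The exact conversion between the two
systems is 1 mN/nm^2 = 1e6 GPa, exposed here as :data:`GPA_PER_MN_NM2`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: 1 mN/nm^2 expressed in GPa (exact).
GPA_PER_MN_NM2 = 1.0e6

#: 1 GPa expressed in mN/nm^2 (exact).
MN_NM2_PER_GPA = 1.0e-6

#: 1 mN*nm expressed in pJ (exact).
PJ_PER_MN_NM = 1.0


@dataclass(frozen=True)
class IndentationProtocol:
    """Displacement-controlled trapezoidal indentation protocol.

    The default values describe the four-phase bone protocol: load to a
    500 nm target depth at 0.25 mN/s, hold 60 s at maximum load for creep,
    unload to 10% of maximum load, then hold 100 s at that low load to
    estimate thermal drift.
    """

    target_depth: float = 500.0      # nm
    loading_rate: float = 0.25       # mN/s, also used for the unload ramp
    hold_s: float = 60.0             # s at P_max
    drift_hold_s: float = 100.0      # s at drift_hold_fraction * P_max
    drift_hold_fraction: float = 0.10
    sample_hz: float = 300.0         # acquisition rate for simulated curves

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if self.loading_rate <= 0:
            raise ValueError("loading_rate must be positive")
        if self.hold_s < 0 or self.drift_hold_s < 0:
            raise ValueError("hold durations must be non-negative")
        if not 0.0 < self.drift_hold_fraction < 1.0:
            raise ValueError("drift_hold_fraction must be in (0, 1)")
        if self.sample_hz <= 0:
            raise ValueError("sample_hz must be positive")


@dataclass(frozen=True)
class IndenterSpec:
    """Berkovich diamond tip and the contact-mechanics constants.

    Parameters
    ----------
    E_i, nu_i
        Elastic modulus (GPa) and Poisson ratio of the diamond indenter.
    epsilon
        Oliver–Pharr contact-depth geometry factor; 0.75 is the standard
        value for a Berkovich/paraboloid tip, 2(pi-2)/pi applies to an
        ideal cone.
    beta
        Stiffness correction factor (1.0 by default; 1.034 is a common
        Berkovich choice).
    area_coeffs
        Projected-area function coefficients ``(C0, C1, C2, ...)`` in
        ``A(h_c) = C0 h_c^2 + C1 h_c + C2 h_c^(1/2) + C3 h_c^(1/4) + ...``
        with h_c in nm and A in nm^2.  The ideal Berkovich value
        C0 = 24.5 is the default and no calibration terms are assumed.
    psi_deg
        Effective cone half-angle in degrees (70.3 for Berkovich).
    """

    E_i: float = 1141.0
    nu_i: float = 0.07
    epsilon: float = 0.75
    beta: float = 1.0
    area_coeffs: tuple[float, ...] = (24.5,)
    psi_deg: float = 70.3

    def __post_init__(self) -> None:
        if self.E_i <= 0:
            raise ValueError("indenter modulus must be positive")
        if not self.area_coeffs or self.area_coeffs[0] <= 0:
            raise ValueError("leading area coefficient C0 must be positive")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must be in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def C0(self) -> float:
        return self.area_coeffs[0]

    @property
    def tan_psi(self) -> float:
        return math.tan(math.radians(self.psi_deg))

    def area(self, h_c: float) -> float:
        """Projected contact area (nm^2) at contact depth h_c (nm)."""
        if h_c <= 0:
            raise ValueError("contact depth must be positive")
        a = self.area_coeffs[0] * h_c * h_c
        exponent = 1.0
        for c in self.area_coeffs[1:]:
            a += c * h_c ** exponent
            exponent /= 2.0
        return a

    def reduced_modulus(self, E_s: float, nu_s: float) -> float:
        """Specimen+indenter reduced modulus E_r (GPa) from specimen E, nu."""
        if E_s <= 0:
            raise ValueError("specimen modulus must be positive")
        inv = (1.0 - nu_s**2) / E_s + (1.0 - self.nu_i**2) / self.E_i
        return 1.0 / inv

    def specimen_modulus(self, E_r: float, nu_s: float) -> float:
        """Invert :meth:`reduced_modulus`: specimen E (GPa) from E_r."""
        inv = 1.0 / E_r - (1.0 - self.nu_i**2) / self.E_i
        if inv <= 0:
            raise ValueError(
                "reduced modulus exceeds the indenter-only limit; "
                "specimen modulus is undefined"
            )
        return (1.0 - nu_s**2) / inv


CONE_EPSILON = 2.0 * (math.pi - 2.0) / math.pi
"""Exact Oliver–Pharr geometry factor for a conical indenter (~0.7268)."""
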