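"""Acid-base speciation of the ammonium/ammonia couple.

Total ammonium (``NH_X``) in any aqueous pool is the sum of the neutral
species NH3 and the charged species NH4+.  With the Henderson-Hasselbalch
relation the mole fraction of NH3 at a given pH is

    f(pH) = 1 / (1 + 10^(pKa - pH))

so at biologically relevant pH (3-7, pKa 9.25) the pool is almost
entirely NH4+, and the NH3/NH4+ ratio is 10^(pH - pKa).  These two lines
of arithmetic carry essentially the whole compartmentalization analysis:
NH3 equilibrates across membranes by passive diffusion, while NH4+ is
"trapped" in acidic compartments in proportion to 10^(pKa - pH).

Concentrations are in mmol/L throughout (== mol/m^3); see
:mod:`ammoflux.constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    DEFAULT_PKA,
    DEFAULT_TEMPERATURE_K,
    FARADAY_C_PER_MOL,
    R_GAS_J_PER_MOL_K,
)
from .errors import DomainError

__all__ = [
    "AcidBaseParams",
    "nh3_fraction",
    "nh4_fraction",
    "speciate",
    "nernst_slope_mV",
]


@dataclass(frozen=True)
class AcidBaseParams:
    """Acid-base parameters of the ammonium couple.

    Parameters
    ----------
    pka:
        Acid dissociation exponent (dimensionless).  Default 9.25, used
        uncorrected at 30 degC (ideal-solution assumption; no activity
        coefficients, no implicit temperature correction).
    temperature_K:
        Absolute temperature in kelvin; only enters through the Nernst
        slope used by the uniport equilibrium model.
    """

    pka: float = DEFAULT_PKA
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not 0.0 < self.pka < 14.0:
            raise DomainError(f"pKa must lie in (0, 14), got {self.pka}")
        if self.temperature_K <= 0.0:
            raise DomainError(
                f"temperature must be positive kelvin, got {self.temperature_K}"
            )


def _check_ph(ph: float) -> None:
    if not 0.0 < ph < 14.0:
        raise DomainError(f"pH must lie in the open interval (0, 14), got {ph}")


def nh3_fraction(ph: float, params: AcidBaseParams | None = None) -> float:
    """Mole fraction of NH3 in a total NH_X pool at the given pH.

    ``f = 1 / (1 + 10^(pKa - pH))``; strictly increasing in pH and
    strictly decreasing in pKa, with ``f = 0.5`` at ``pH == pKa``.
    """
    params = params or AcidBaseParams()
    _check_ph(ph)
    return 1.0 / (1.0 + 10.0 ** (params.pka - ph))


def nh4_fraction(ph: float, params: AcidBaseParams | None = None) -> float:
    """Mole fraction of NH4+ (complement of :func:`nh3_fraction`)."""
    params = params or AcidBaseParams()
    _check_ph(ph)
    return 1.0 / (1.0 + 10.0 ** (ph - params.pka))


def speciate(
    total_nhx_mM: float, ph: float, params: AcidBaseParams | None = None
) -> tuple[float, float]:
    """Split a total NH_X concentration into (NH3, NH4+), both in mmol/L.

    Conservation is exact by construction: NH4+ is computed as the
    complement ``total - NH3``.
    """
    params = params or AcidBaseParams()
    if total_nhx_mM < 0.0:
        raise DomainError(f"total NH_X concentration must be >= 0, got {total_nhx_mM}")
    nh3 = total_nhx_mM * nh3_fraction(ph, params)
    return nh3, total_nhx_mM - nh3


def nernst_slope_mV(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Nernst slope Z = ln(10) R T / F, in millivolt.

    Z is the membrane-potential change equivalent to one pH unit or one
    decade of ion accumulation; about 60.15 mV at 30 degC.
    """
    if temperature_K <= 0.0:
        raise DomainError(f"temperature must be positive kelvin, got {temperature_K}")
    return (
        math.log(10.0)
        * R_GAS_J_PER_MOL_K
        * temperature_K
        / FARADAY_C_PER_MOL
        * 1000.0
    )
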