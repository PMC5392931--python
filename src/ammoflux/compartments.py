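"""Three-compartment equilibrium model of intracellular NH_X.

Whole-cell ("intracellular", IC) NH_X measurements average over
compartments with very different pH.  Assuming passive NH3 diffusion
equilibrates the *free NH3* concentration across all compartments, each
compartment i (volume fraction V_i of total cell volume, pH_i) holds

    NHX_i = NH3_free * (1 + 10^(pKa - pH_i))

so the whole-cell concentration per litre of cell is

    NHX_IC = NH3_free * sum_i V_i * (1 + 10^(pKa - pH_i))
           = NH3_free * retention_factor(model).

The retention factor is dominated by the acidic vacuole: at vacuolar
pH 4.5 one micromole of free NH3 per litre is accompanied by tens of
millimoles of trapped NH4+ per litre of vacuole.  Inverting the relation
("deconvolution") recovers the cytosolic free NH3 that the transport
analysis needs from a whole-cell measurement.

Two candidate plasma-membrane uptake mechanisms predict very different
equilibrium IC/EC ratios:

* NH3 diffusion: NH3_cyt = NH3_EC at equilibrium, so
  ``IC/EC = retention_factor / (1 + 10^(pKa - pH_EC))`` - independent of
  the membrane potential.
* NH4+ uniport: NH4+ equilibrates with the electrical driving force,
  ``[NH4+]_cyt/[NH4+]_EC = 10^(-dPsi/Z)`` with
  ``dPsi = pmf + Z (pH_cyt - pH_EC)``, giving ratios two or more orders
  of magnitude larger.

The sensitivity box spans the plausible ranges of vacuolar volume
(14-25%), cytosolic pH (6-7) and vacuolar pH (4-5.5); because each ratio
is monotone in every box coordinate, the extrema are attained at corners
of the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import pandas as pd

from .constants import DEFAULT_PMF_MV
from .errors import ConfigurationError, DomainError, UsageError
from .speciation import AcidBaseParams, nernst_slope_mV

__all__ = [
    "Compartment",
    "CellModel",
    "SensitivityBox",
    "MembraneEnergetics",
    "retention_factor",
    "free_nh3_from_wholecell",
    "wholecell_from_free_nh3",
    "compartment_profile",
    "predicted_ratio_diffusion",
    "predicted_ratio_uniport",
    "RatioBounds",
    "ratio_bounds",
]


@dataclass(frozen=True)
class Compartment:
    """A cellular compartment: name, volume fraction of total cell
    volume (dry matter included), and pH."""

    name: str
    volume_fraction: float
    ph: float

    def __post_init__(self) -> None:
        if not 0.0 < self.volume_fraction <= 1.0:
            raise DomainError(
                f"volume_fraction of {self.name!r} must lie in (0, 1], "
                f"got {self.volume_fraction}"
            )
        if not 0.0 < self.ph < 14.0:
            raise DomainError(
                f"pH of {self.name!r} must lie in (0, 14), got {self.ph}"
            )


@dataclass(frozen=True)
class CellModel:
    """Ordered collection of compartments plus acid-base parameters.

    The default model is cytosol 70% at pH 6.5, vacuole 14% at pH 4.5
    and mitochondria 1% at pH 7.5; the remaining ~15% of cell volume
    (mostly dry matter) is assumed NH_X-free.  The cytosolic pH default
    is the midpoint of the 6-7 sensitivity range, and the mitochondrial
    pH (not critical: <0.01% of the retention factor) is configurable.
    """

    compartments: tuple[Compartment, ...]
    acid_base: AcidBaseParams = field(default_factory=AcidBaseParams)

    def __post_init__(self) -> None:
        if not self.compartments:
            raise DomainError("a CellModel needs at least one compartment")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"compartment names must be unique: {names}")
        total = sum(c.volume_fraction for c in self.compartments)
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"compartment volume fractions sum to {total:.4f} > 1"
            )

    @classmethod
    def default(cls, acid_base: AcidBaseParams | None = None) -> "CellModel":
        return cls(
            compartments=(
                Compartment("cytosol", 0.70, 6.5),
                Compartment("vacuole", 0.14, 4.5),
                Compartment("mitochondria", 0.01, 7.5),
            ),
            acid_base=acid_base or AcidBaseParams(),
        )

    def get(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise ConfigurationError(f"no compartment named {name!r} in model")

    def replace_compartment(self, name: str, **changes) -> "CellModel":
        """Return a copy with one compartment's fields replaced."""
        new = tuple(
            replace(c, **changes) if c.name == name else c for c in self.compartments
        )
        if all(c.name != name for c in self.compartments):
            raise ConfigurationError(f"no compartment named {name!r} in model")
        return replace(self, compartments=new)


@dataclass(frozen=True)
class SensitivityBox:
    """Parameter box for the ratio sensitivity analysis.

    Ranges are (lo, hi) pairs for the vacuolar volume fraction, the
    cytosolic pH and the vacuolar pH.
    """

    vacuole_fraction: tuple[float, float] = (0.14, 0.25)
    cytosol_ph: tuple[float, float] = (6.0, 7.0)
    vacuole_ph: tuple[float, float] = (4.0, 5.5)

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("vacuole_fraction", self.vacuole_fraction),
            ("cytosol_ph", self.cytosol_ph),
            ("vacuole_ph", self.vacuole_ph),
        ):
            if lo > hi:
                raise DomainError(f"{label} range has lo > hi: ({lo}, {hi})")
        if not 0.0 < self.vacuole_fraction[0]:
            raise DomainError("vacuole_fraction lower bound must be positive")
        if self.vacuole_fraction[1] > 1.0:
            raise DomainError("vacuole_fraction upper bound must be <= 1")
        for lo, hi in (self.cytosol_ph, self.vacuole_ph):
            if not (0.0 < lo and hi < 14.0):
                raise DomainError("pH ranges must lie within (0, 14)")

    def corners(self) -> Iterator[tuple[float, float, float]]:
        """Corners in lexicographic (V_vac, pH_cyt, pH_vac) order."""
        for v in self.vacuole_fraction:
            for pc in self.cytosol_ph:
                for pv in self.vacuole_ph:
                    yield (v, pc, pv)

    def model_at(
        self, base: CellModel, vacuole_fraction: float, cytosol_ph: float,
        vacuole_ph: float,
    ) -> CellModel:
        """Base model with the three box coordinates substituted."""
        m = base.replace_compartment("cytosol", ph=cytosol_ph)
        return m.replace_compartment(
            "vacuole", volume_fraction=vacuole_fraction, ph=vacuole_ph
        )


@dataclass(frozen=True)
class MembraneEnergetics:
    """Plasma-membrane energetics for the NH4+ uniport model.

    ``pmf_mV`` is the proton motive force (negative inside); the
    membrane potential follows as ``dPsi = pmf + Z (pH_cyt - pH_EC)``.
    The default -200 mV is a model choice, not a measurement (see
    docs/methods.md).
    """

    pmf_mV: float = DEFAULT_PMF_MV
    z_mV: float = field(default_factory=nernst_slope_mV)

    def __post_init__(self) -> None:
        if self.pmf_mV > 0.0:
            raise DomainError(
                f"pmf must be <= 0 mV (negative inside), got {self.pmf_mV}"
            )
        if self.z_mV <= 0.0:
            raise DomainError(f"Nernst slope must be positive, got {self.z_mV}")

    def delta_psi_mV(self, ph_cyt: float, ph_ec: float) -> float:
        """Membrane potential implied by the pmf and the pH gradient."""
        return self.pmf_mV + self.z_mV * (ph_cyt - ph_ec)


def retention_factor(model: CellModel) -> float:
    """Volume-weighted sum of per-compartment speciation factors.

    ``sum_i V_i (1 + 10^(pKa - pH_i))`` - the ratio of whole-cell NH_X
    (per litre of cell) to the equilibrated free NH3 concentration.
    Always >= the summed volume fractions; strictly decreasing in every
    compartment pH.  The "+1" terms are kept exact rather than using the
    ``10^(pKa - pH)`` approximation.
    """
    pka = model.acid_base.pka
    return sum(
        c.volume_fraction * (1.0 + 10.0 ** (pka - c.ph)) for c in model.compartments
    )


def free_nh3_from_wholecell(wholecell_nhx_mM: float, model: CellModel) -> float:
    """Equilibrated free NH3 (mmol/L) from a whole-cell NH_X measurement
    (mmol per litre of cell volume)."""
    if wholecell_nhx_mM < 0.0:
        raise DomainError(
            f"whole-cell NH_X must be >= 0, got {wholecell_nhx_mM}"
        )
    return wholecell_nhx_mM / retention_factor(model)


def wholecell_from_free_nh3(nh3_free_mM: float, model: CellModel) -> float:
    """Forward direction of the same equilibrium; exact inverse of
    :func:`free_nh3_from_wholecell`."""
    if nh3_free_mM < 0.0:
        raise DomainError(f"free NH3 must be >= 0, got {nh3_free_mM}")
    return nh3_free_mM * retention_factor(model)


def compartment_profile(nh3_free_mM: float, model: CellModel) -> pd.DataFrame:
    """Per-compartment NH3/NH4+/NH_X concentrations (mmol/L) at a given
    equilibrated free NH3 concentration.

    NH3 is identical in every compartment; NH4+ follows from each
    compartment's pH.  The volume-weighted NH_X total equals
    :func:`wholecell_from_free_nh3` to machine precision.
    """
    if nh3_free_mM < 0.0:
        raise DomainError(f"free NH3 must be >= 0, got {nh3_free_mM}")
    pka = model.acid_base.pka
    rows = []
    for c in model.compartments:
        nh4 = nh3_free_mM * 10.0 ** (pka - c.ph)
        rows.append(
            {
                "compartment": c.name,
                "volume_fraction": c.volume_fraction,
                "ph": c.ph,
                "nh3_mM": nh3_free_mM,
                "nh4_mM": nh4,
                "nhx_mM": nh3_free_mM + nh4,
            }
        )
    return pd.DataFrame(rows).set_index("compartment")


def predicted_ratio_diffusion(ph_ec: float, model: CellModel) -> float:
    """Equilibrium IC/EC NH_X ratio if NH3 diffusion is the only uptake
    route.

    At equilibrium NH3_cyt = NH3_EC, so the ratio is independent of the
    concentration level and of the membrane potential:
    ``retention_factor / (1 + 10^(pKa - pH_EC))``.
    """
    if not 0.0 < ph_ec < 14.0:
        raise DomainError(f"extracellular pH must lie in (0, 14), got {ph_ec}")
    pka = model.acid_base.pka
    return retention_factor(model) / (1.0 + 10.0 ** (pka - ph_ec))


def predicted_ratio_uniport(
    ph_ec: float,
    model: CellModel,
    energetics: MembraneEnergetics | None = None,
) -> float:
    """Equilibrium IC/EC NH_X ratio if NH4+ uniport is the only uptake
    route.

    NH4+ equilibrates with the electrical gradient,
    ``[NH4+]_cyt/[NH4+]_EC = 10^(-dPsi/Z)``; the cytosolic free NH3 then
    follows from cytosolic speciation and the whole-cell pool from the
    retention factor.  Because dPsi = pmf + Z (pH_cyt - pH_EC), the
    cytosolic pH cancels except through the retention factor, and the
    ratio rises tenfold per unit of extracellular pH.
    """
    if not 0.0 < ph_ec < 14.0:
        raise DomainError(f"extracellular pH must lie in (0, 14), got {ph_ec}")
    energetics = energetics or MembraneEnergetics()
    ph_cyt = model.get("cytosol").ph  # raises ConfigurationError if absent
    pka = model.acid_base.pka
    dpsi = energetics.delta_psi_mV(ph_cyt, ph_ec)
    nh4_accumulation = 10.0 ** (-dpsi / energetics.z_mV)
    return (
        nh4_accumulation
        * 10.0 ** (ph_cyt - pka)
        * retention_factor(model)
        / (1.0 + 10.0 ** (ph_ec - pka))
    )


@dataclass(frozen=True)
class RatioBounds:
    """Result of a sensitivity-box corner search."""

    minimum: float
    maximum: float
    argmin: tuple[float, float, float]
    argmax: tuple[float, float, float]

    def __iter__(self):  # allows  lo, hi = ratio_bounds(...)
        return iter((self.minimum, self.maximum))


def ratio_bounds(
    mechanism: Literal["diffusion", "uniport"],
    ph_ec: float,
    box: SensitivityBox,
    base_model: CellModel,
    energetics: MembraneEnergetics | None = None,
) -> RatioBounds:
    """Min/max predicted IC/EC ratio over the sensitivity box.

    The ratio is monotone in each box coordinate (vacuolar fraction up,
    compartment pHs down increase retention), so the extrema are
    attained at corners; corners are scanned in lexicographic
    (V_vac, pH_cyt, pH_vac) order and ties keep the first corner.
    """
    if mechanism == "diffusion":
        def evaluate(m: CellModel) -> float:
            return predicted_ratio_diffusion(ph_ec, m)
    elif mechanism == "uniport":
        def evaluate(m: CellModel) -> float:
            return predicted_ratio_uniport(ph_ec, m, energetics)
    else:
        raise UsageError(
            f"unknown mechanism {mechanism!r}: expected 'diffusion' or 'uniport'"
        )

    best_min = best_max = None
    arg_min = arg_max = None
    for corner in box.corners():
        value = evaluate(box.model_at(base_model, *corner))
        if best_min is None or value < best_min:
            best_min, arg_min = value, corner
        if best_max is None or value > best_max:
            best_max, arg_max = value, corner
    return RatioBounds(best_min, best_max, arg_min, arg_max)
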