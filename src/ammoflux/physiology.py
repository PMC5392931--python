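"""Chemostat rate bookkeeping: ATP accounting, yields and consistency.

A steady-state chemostat observation carries biomass-specific rates
(q-rates, mmol/g_CDW/h) and concentrations for one strain x pH
condition.  All rates are stored as non-negative magnitudes with the
direction fixed by the field semantics: glucose, oxygen and nitrogen
are consumed; CO2 and ethanol are produced.

Derived quantities:

* ``q_ATP = 1.9 q_O2 + 1.0 q_EtOH`` (respirofermentative ATP accounting:
  oxidative phosphorylation plus substrate-level ATP from alcoholic
  fermentation),
* biomass yield ``Y_XS = mu / (q_S M_glucose)`` (g_CDW/g glucose),
* carbon/nitrogen consumption ratio ``C/N = 6 q_S / q_N`` (glucose
  carbon only; co-consumed feed ethanol is excluded, consistent with
  the tabulated values),
* ATP cost per assimilated nitrogen ``q_ATP / q_N`` (mol ATP/mol N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    DEFAULT_ATP_PER_ETHANOL,
    DEFAULT_ATP_PER_O2,
    GLUCOSE_MOLAR_MASS_G_PER_MOL,
)
from .errors import DomainError

__all__ = [
    "ChemostatObservation",
    "ATPStoichiometry",
    "PhysiologySummary",
    "ValidationReport",
    "atp_rate",
    "physiology_summary",
    "cellular_concentration",
    "measured_ic_ec_ratio",
    "validate_observation",
]

#: g per mmol, for the yield computation
_M_GLUCOSE_G_PER_MMOL = GLUCOSE_MOLAR_MASS_G_PER_MOL / 1000.0


@dataclass(frozen=True)
class ATPStoichiometry:
    """mol ATP per mol O2 respired and per mol ethanol fermented."""

    atp_per_o2: float = DEFAULT_ATP_PER_O2
    atp_per_ethanol: float = DEFAULT_ATP_PER_ETHANOL

    def __post_init__(self) -> None:
        if self.atp_per_o2 < 0.0 or self.atp_per_ethanol < 0.0:
            raise DomainError("ATP stoichiometries must be >= 0")


@dataclass(frozen=True)
class PhysiologySummary:
    """Derived physiology of one chemostat steady state."""

    y_xs: float  # g_CDW / g glucose
    cn_ratio: float  # C-mol / N-mol consumed
    q_atp: float  # mmol ATP / g_CDW / h
    qatp_per_qn: float  # mol ATP / mol N

    def __post_init__(self) -> None:
        for name in ("y_xs", "cn_ratio", "q_atp", "qatp_per_qn"):
            if getattr(self, name) < 0.0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ChemostatObservation:
    """One steady state's measured rates and concentrations.

    Rates in mmol/g_CDW/h (magnitudes); ``n_content`` in mmol N/g_CDW;
    ``biomass_conc`` in g_CDW/L; ``cell_volume`` in mL/g_CDW;
    ``nhx_ic``/``nhx_ec`` in mmol/L of cell volume and of supernatant.
    ``reported`` optionally carries tabulated derived columns for
    cross-checking against recomputation.
    """

    strain: str
    ph_ec: float
    mu: float
    q_s: float
    q_o2: float
    q_co2: float
    q_etoh: float
    q_n: float
    n_content: float
    biomass_conc: float
    cell_volume: float
    nhx_ic: float
    nhx_ec: float
    dilution_rate: float = 0.05
    reported: PhysiologySummary | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.ph_ec < 14.0:
            raise DomainError(
                f"extracellular pH must lie in (0, 14), got {self.ph_ec}"
            )
        if self.cell_volume <= 0.0:
            raise DomainError(f"cell_volume must be > 0, got {self.cell_volume}")
        for name in (
            "mu", "q_s", "q_o2", "q_co2", "q_etoh", "q_n",
            "n_content", "biomass_conc", "nhx_ic", "nhx_ec", "dilution_rate",
        ):
            if getattr(self, name) < 0.0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")


def atp_rate(
    q_o2: float, q_etoh: float, stoich: ATPStoichiometry | None = None
) -> float:
    """ATP production rate, mmol/g_CDW/h, from respiration and
    fermentation magnitudes."""
    stoich = stoich or ATPStoichiometry()
    if q_o2 < 0.0 or q_etoh < 0.0:
        raise DomainError("q_O2 and q_EtOH magnitudes must be >= 0")
    return stoich.atp_per_o2 * q_o2 + stoich.atp_per_ethanol * q_etoh


def physiology_summary(
    obs: ChemostatObservation, stoich: ATPStoichiometry | None = None
) -> PhysiologySummary:
    """Recompute the derived physiology columns from the measured ones."""
    if obs.q_s <= 0.0:
        raise DomainError("q_s must be > 0 to compute a yield")
    if obs.q_n <= 0.0:
        raise DomainError("q_n must be > 0 to compute C/N and ATP per N")
    q_atp = atp_rate(obs.q_o2, obs.q_etoh, stoich)
    return PhysiologySummary(
        y_xs=obs.mu / (obs.q_s * _M_GLUCOSE_G_PER_MMOL),
        cn_ratio=6.0 * obs.q_s / obs.q_n,
        q_atp=q_atp,
        qatp_per_qn=q_atp / obs.q_n,
    )


def cellular_concentration(content_umol_per_g: float, cell_volume_mL_per_g: float) -> float:
    """Convert a biomass-specific content (umol/g_CDW) to a cellular
    concentration (mmol/L) using the cell volume (mL/g_CDW);
    umol/mL == mmol/L."""
    if cell_volume_mL_per_g <= 0.0:
        raise DomainError(f"cell volume must be > 0, got {cell_volume_mL_per_g}")
    return content_umol_per_g / cell_volume_mL_per_g


def measured_ic_ec_ratio(nhx_ic_mM: float, nhx_ec_mM: float) -> float:
    """Plain quotient of whole-cell over extracellular NH_X."""
    if nhx_ec_mM <= 0.0:
        raise DomainError(
            f"extracellular NH_X must be > 0 to form a ratio, got {nhx_ec_mM}"
        )
    return nhx_ic_mM / nhx_ec_mM


@dataclass(frozen=True)
class ValidationReport:
    """Report-only consistency check of one observation."""

    strain: str
    ph_ec: float
    flags: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.flags


def validate_observation(
    obs: ChemostatObservation,
    tolerance: float = 0.02,
    stoich: ATPStoichiometry | None = None,
) -> ValidationReport:
    """Flag internal inconsistencies of a chemostat observation.

    Checks the nitrogen balance ``q_N == mu * n_content`` and, when the
    observation carries tabulated derived columns, compares them against
    recomputation.  Never mutates data; returns a report.
    """
    flags: list[str] = []
    if obs.q_n > 0.0:
        n_balance = abs(obs.q_n - obs.mu * obs.n_content) / obs.q_n
        if n_balance > tolerance:
            flags.append(
                f"q_N={obs.q_n:.3f} vs mu*n_content="
                f"{obs.mu * obs.n_content:.3f} (rel dev {n_balance:.1%})"
            )
    if obs.reported is not None:
        computed = physiology_summary(obs, stoich)
        for name in ("y_xs", "cn_ratio", "q_atp", "qatp_per_qn"):
            ref = getattr(obs.reported, name)
            got = getattr(computed, name)
            if ref > 0.0 and abs(got - ref) / ref > tolerance:
                flags.append(
                    f"{name}: reported {ref:.4g} vs recomputed {got:.4g} "
                    f"(rel dev {abs(got - ref) / ref:.1%})"
                )
    return ValidationReport(strain=obs.strain, ph_ec=obs.ph_ec, flags=tuple(flags))
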