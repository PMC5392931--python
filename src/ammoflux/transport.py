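"""Flux-permeability relations for passive NH3 uptake.

The diffusion law across the plasma membrane is

    -q_N = P * a_m * ([NH3]_EC - [NH3]_cyt)

with P the apparent permeability coefficient (m/h), a_m the
biomass-specific membrane area (m^2/g_CDW) and concentrations in
mmol/L == mol/m^3.  The raw product is therefore mol/g_CDW/h; q-rates
are reported in mmol/g_CDW/h, so a single explicit factor of 1000
appears here and nowhere else.

Under nitrogen limitation the growth rate follows from the uptake flux
through the biomass nitrogen content chi_N (mol N/g_CDW):

    mu = (-q_N) / chi_N,      -q_N = P * a_m * [NH3]_EC

where the cytosolic term is neglected for batch assays because the
extracellular NH3 concentration is far above the cytosolic one.  An
optional ceiling mu_max models saturation of growth at high NH3.

Steady-state estimation (:func:`solve_steady_state`) combines
extracellular speciation, compartmental deconvolution of the whole-cell
measurement, and inversion of the flux law.  When the printed default
cell model yields a non-positive gradient, the solver searches the
sensitivity box for the smallest assumption change that restores a
positive gradient (vacuolar volume up first, then vacuolar pH down) and
records the adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .compartments import (
    CellModel,
    SensitivityBox,
    free_nh3_from_wholecell,
)
from .constants import (
    DEFAULT_BIOMASS_N_MOL_PER_G,
    DEFAULT_MEMBRANE_AREA_M2_PER_G,
)
from .errors import (
    ConfigurationError,
    DomainError,
    EstimationError,
    InfeasibleGradientError,
    UsageError,
)
from .physiology import ChemostatObservation
from .speciation import nh3_fraction

__all__ = [
    "TransportParams",
    "SteadyStateSolution",
    "diffusion_flux",
    "estimate_permeability",
    "solve_steady_state",
    "growth_rate_from_nh3",
    "fit_permeability_from_growth",
    "GrowthFit",
]

_MOL_TO_MMOL = 1000.0


@dataclass(frozen=True)
class TransportParams:
    """Membrane-transport parameters.

    a_m: biomass-specific membrane area, m^2/g_CDW.
    chi_n: biomass nitrogen content, mol N/g_CDW (batch growth law).
    mu_max: optional growth-rate ceiling, 1/h.
    """

    a_m: float = DEFAULT_MEMBRANE_AREA_M2_PER_G
    chi_n: float = DEFAULT_BIOMASS_N_MOL_PER_G
    mu_max: float | None = None

    def __post_init__(self) -> None:
        if self.a_m <= 0.0 or self.chi_n <= 0.0:
            raise DomainError("a_m and chi_n must be strictly positive")
        if self.mu_max is not None and self.mu_max <= 0.0:
            raise DomainError(f"mu_max must be > 0 if set, got {self.mu_max}")


@dataclass(frozen=True)
class SteadyStateSolution:
    """Estimated cytosolic/extracellular free NH3 (umol/L), apparent
    permeability (m/h) and the assumption set that made the algebraic
    system feasible."""

    strain: str
    ph_ec: float
    nh3_cyt_umol: float
    nh3_ec_umol: float
    permeability: float | None
    model_used: CellModel
    adjusted: str | None
    feasible: bool

    def __post_init__(self) -> None:
        if self.feasible:
            if not self.nh3_ec_umol > self.nh3_cyt_umol:
                raise DomainError(
                    "feasible solution requires NH3_EC > NH3_cyt"
                )
            if self.permeability is None or self.permeability <= 0.0:
                raise DomainError("feasible solution requires permeability > 0")


def diffusion_flux(
    permeability: float,
    nh3_ec_mM: float,
    nh3_cyt_mM: float,
    params: TransportParams | None = None,
) -> float:
    """Passive NH3 uptake rate -q_N in mmol/g_CDW/h.

    Positive when the gradient points inward; linear in every argument.
    """
    params = params or TransportParams()
    if permeability < 0.0:
        raise DomainError(f"permeability must be >= 0, got {permeability}")
    return _MOL_TO_MMOL * permeability * params.a_m * (nh3_ec_mM - nh3_cyt_mM)


def estimate_permeability(
    q_n: float,
    nh3_ec_mM: float,
    nh3_cyt_mM: float,
    params: TransportParams | None = None,
) -> float:
    """Invert the diffusion law: P = q_N / (a_m (NH3_EC - NH3_cyt)).

    ``q_n`` is the uptake magnitude in mmol/g_CDW/h.  Raises
    :class:`InfeasibleGradientError` when the gradient is non-positive;
    use :func:`solve_steady_state` to search for a feasible assumption
    set in that case.
    """
    params = params or TransportParams()
    if q_n <= 0.0:
        raise DomainError(f"q_N must be > 0, got {q_n}")
    gradient = nh3_ec_mM - nh3_cyt_mM
    if gradient <= 0.0:
        raise InfeasibleGradientError(
            f"non-positive NH3 gradient ({nh3_ec_mM:.4g} - {nh3_cyt_mM:.4g} "
            "mmol/L): the default compartment assumptions admit no inward "
            "diffusion; use solve_steady_state's adjustment path"
        )
    return q_n / (_MOL_TO_MMOL * params.a_m * gradient)


def _vacuole_search_path(
    model: CellModel, box: SensitivityBox,
    fraction_step: float = 0.01, ph_step: float = 0.1,
) -> Iterable[tuple[float, float, str]]:
    """Lattice of vacuolar (fraction, pH) candidates ordered by
    increasing deviation from the default: fraction raised first, then
    pH lowered at the maximal fraction."""
    vac = model.get("vacuole")
    hi_frac = box.vacuole_fraction[1]
    lo_ph = box.vacuole_ph[0]
    n_frac = int(round((hi_frac - vac.volume_fraction) / fraction_step))
    for i in range(1, n_frac + 1):
        frac = round(vac.volume_fraction + i * fraction_step, 10)
        yield frac, vac.ph, f"vacuole fraction {frac:.2f}"
    n_ph = int(round((vac.ph - lo_ph) / ph_step))
    for j in range(1, n_ph + 1):
        ph = round(vac.ph - j * ph_step, 10)
        yield hi_frac, ph, f"vacuole fraction {hi_frac:.2f}, pH {ph:.1f}"


def solve_steady_state(
    obs: ChemostatObservation,
    model: CellModel | None = None,
    params: TransportParams | None = None,
    box: SensitivityBox | None = None,
) -> SteadyStateSolution:
    """Estimate cytosolic NH3, extracellular NH3 and the apparent
    permeability for one chemostat steady state.

    The extracellular free NH3 follows from speciation of the residual
    NH_X at the culture pH; the cytosolic free NH3 from compartmental
    deconvolution of the whole-cell measurement.  If the gradient is
    non-positive under the given model, vacuolar assumptions are
    adjusted within the sensitivity box (fraction up on a 0.01 lattice,
    then pH down on a 0.1 lattice) until inward diffusion is possible;
    the adjustment is recorded.  If no lattice point is feasible the
    result carries ``feasible=False`` and a diagnostic instead of
    raising.
    """
    model = model or CellModel.default()
    params = params or TransportParams()
    box = box or SensitivityBox()

    nh3_ec = obs.nhx_ec * nh3_fraction(obs.ph_ec, model.acid_base)

    def attempt(m: CellModel) -> tuple[float, float]:
        nh3_cyt = free_nh3_from_wholecell(obs.nhx_ic, m)
        return nh3_cyt, nh3_ec - nh3_cyt

    nh3_cyt, gradient = attempt(model)
    adjusted: str | None = None
    model_used = model
    if gradient <= 0.0:
        for frac, ph, description in _vacuole_search_path(model, box):
            candidate = model.replace_compartment(
                "vacuole", volume_fraction=frac, ph=ph
            )
            nh3_cyt_c, gradient_c = attempt(candidate)
            if gradient_c > 0.0:
                model_used = candidate
                nh3_cyt, gradient = nh3_cyt_c, gradient_c
                adjusted = description
                break
        else:
            return SteadyStateSolution(
                strain=obs.strain,
                ph_ec=obs.ph_ec,
                nh3_cyt_umol=nh3_cyt * 1000.0,
                nh3_ec_umol=nh3_ec * 1000.0,
                permeability=None,
                model_used=model,
                adjusted=(
                    "no vacuolar assumption within the sensitivity box "
                    "yields a positive NH3 gradient"
                ),
                feasible=False,
            )
    permeability = estimate_permeability(obs.q_n, nh3_ec, nh3_cyt, params)
    return SteadyStateSolution(
        strain=obs.strain,
        ph_ec=obs.ph_ec,
        nh3_cyt_umol=nh3_cyt * 1000.0,
        nh3_ec_umol=nh3_ec * 1000.0,
        permeability=permeability,
        model_used=model_used,
        adjusted=adjusted,
        feasible=True,
    )


def growth_rate_from_nh3(
    nh3_ec_mM: float,
    permeability: float,
    params: TransportParams | None = None,
) -> float:
    """Diffusion-limited growth rate, 1/h.

    ``mu = P a_m [NH3]_EC / chi_N`` (cytosolic NH3 neglected), capped at
    ``mu_max`` when the ceiling is set.  Linear in the concentration
    below the ceiling.
    """
    params = params or TransportParams()
    if nh3_ec_mM < 0.0 or permeability < 0.0:
        raise DomainError("NH3 concentration and permeability must be >= 0")
    mu = permeability * params.a_m * nh3_ec_mM / params.chi_n
    if params.mu_max is not None:
        mu = min(mu, params.mu_max)
    return mu


@dataclass(frozen=True)
class GrowthFit:
    """Result of a batch permeability fit."""

    permeability: float
    r_squared: float
    slope: float  # L/mmol/h, mu per unit NH3
    n_points: int
    selected: tuple[bool, ...]  # mask over the input points


def _origin_ols(c: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Least squares through the origin; returns (slope, uncentered R^2)."""
    slope = float(np.dot(c, mu) / np.dot(c, c))
    residual = mu - slope * c
    ss_tot = float(np.dot(mu, mu))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.dot(residual, residual)) / ss_tot
    return slope, r2


def fit_permeability_from_growth(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    params: TransportParams | None = None,
    linear_region_rule: str | tuple | Callable[[np.ndarray, np.ndarray], np.ndarray] = "half-mu-max",
) -> GrowthFit:
    """Estimate the apparent permeability from (NH3_EC, mu) pairs.

    Ordinary least squares of mu on [NH3]_EC through the origin,
    restricted to the linear (unsaturated) region, then
    ``P = slope * chi_N / a_m``.

    ``linear_region_rule`` selects that region:

    * ``"half-mu-max"`` (default): iteratively keep points below the
      concentration at which the fitted line predicts 0.5 mu_max
      (requires ``params.mu_max``);
    * ``("mu-cap", f)``: drop points with mu > f * mu_max;
    * ``("max-nh3", c)``: explicit concentration window [0, c];
    * ``"all"``: no restriction;
    * a callable ``rule(c, mu) -> bool mask``.
    """
    params = params or TransportParams()
    if isinstance(points, pd.DataFrame):
        c = points.iloc[:, 0].to_numpy(dtype=float)
        mu = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise DomainError("points must be (nh3_ec, mu) pairs")
        c, mu = arr[:, 0], arr[:, 1]
    if np.any(c < 0.0) or np.any(mu < 0.0):
        raise DomainError("concentrations and growth rates must be >= 0")

    def needs_mu_max() -> float:
        if params.mu_max is None:
            raise ConfigurationError(
                "this linear-region rule needs params.mu_max"
            )
        return params.mu_max

    if callable(linear_region_rule):
        mask = np.asarray(linear_region_rule(c, mu), dtype=bool)
    elif linear_region_rule == "all":
        mask = np.ones_like(c, dtype=bool)
    elif linear_region_rule == "half-mu-max":
        mu_max = needs_mu_max()
        mask = c > 0.0  # origin-only points carry no slope information
        for _ in range(50):
            if mask.sum() < 2:
                break
            slope, _ = _origin_ols(c[mask], mu[mask])
            if slope <= 0.0:
                break
            c_half = 0.5 * mu_max / slope
            new_mask = (c > 0.0) & (c <= c_half)
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
    elif isinstance(linear_region_rule, tuple) and len(linear_region_rule) == 2:
        kind, value = linear_region_rule
        if kind == "mu-cap":
            mask = mu <= float(value) * needs_mu_max()
        elif kind == "max-nh3":
            mask = c <= float(value)
        else:
            raise UsageError(f"unknown linear-region rule {linear_region_rule!r}")
    else:
        raise UsageError(f"unknown linear-region rule {linear_region_rule!r}")

    if mask.sum() < 2:
        raise EstimationError(
            f"fewer than 2 points in the selected linear region "
            f"({int(mask.sum())} of {len(c)})"
        )
    slope, r2 = _origin_ols(c[mask], mu[mask])
    if slope <= 0.0:
        raise EstimationError("non-positive slope: no growth response to NH3")
    return GrowthFit(
        permeability=slope * params.chi_n / params.a_m,
        r_squared=r2,
        slope=slope,
        n_points=int(mask.sum()),
        selected=tuple(bool(b) for b in mask),
    )
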