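"""Flux-permeability relations and steady-state estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ammoflux import (
    ChemostatObservation,
    TransportParams,
    diffusion_flux,
    estimate_permeability,
    fit_permeability_from_growth,
    free_nh3_from_wholecell,
    growth_rate_from_nh3,
    solve_steady_state,
    wholecell_from_free_nh3,
)
from ammoflux.errors import (
    ConfigurationError,
    DomainError,
    EstimationError,
    InfeasibleGradientError,
)
from ammoflux.speciation import nh3_fraction


def make_observation(ph_ec, nhx_ic, nhx_ec, q_n, strain="IMZ351"):
    return ChemostatObservation(
        strain=strain, ph_ec=ph_ec, mu=0.047, q_s=3.0, q_o2=1.2, q_co2=5.0,
        q_etoh=4.0, q_n=q_n, n_content=q_n / 0.047, biomass_conc=7.0,
        cell_volume=2.0, nhx_ic=nhx_ic, nhx_ec=nhx_ec,
    )


class TestDiffusionFlux:
    def test_reference_magnitude(self):
        # P=0.37 m/h over a 0.16 umol/L gradient sustains ~0.19 mmol N/g/h
        q = diffusion_flux(0.37, 1.6e-4, 0.0)
        assert q == pytest.approx(0.19, rel=0.01)

    def test_zero_gradient_zero_flux(self):
        assert diffusion_flux(1.0, 0.5, 0.5) == 0.0

    @given(
        p=st.floats(min_value=1e-3, max_value=10.0),
        ec=st.floats(min_value=0.0, max_value=10.0),
        cyt=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_linearity_and_sign(self, p, ec, cyt):
        q = diffusion_flux(p, ec, cyt)
        assert diffusion_flux(2 * p, ec, cyt) == pytest.approx(2 * q, rel=1e-12)
        assert np.sign(q) == np.sign(ec - cyt)

    def test_negative_permeability_rejected(self):
        with pytest.raises(DomainError):
            diffusion_flux(-0.1, 1.0, 0.0)


class TestEstimatePermeability:
    def test_reference_ph6(self):
        p = estimate_permeability(0.183, 1.47e-3, 1.31e-3)
        assert p == pytest.approx(0.36, abs=0.01)

    def test_reference_ph7(self):
        p = estimate_permeability(0.187, 3.16e-3, 0.90e-3)
        assert p == pytest.approx(0.026, abs=0.001)

    @given(
        p=st.floats(min_value=1e-3, max_value=10.0),
        ec=st.floats(min_value=1e-4, max_value=10.0),
        frac=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_round_trip_with_flux(self, p, ec, frac):
        cyt = frac * ec
        q = diffusion_flux(p, ec, cyt)
        assert estimate_permeability(q, ec, cyt) == pytest.approx(p, rel=1e-12)

    def test_non_positive_gradient_raises_infeasible(self):
        with pytest.raises(InfeasibleGradientError, match="solve_steady_state"):
            estimate_permeability(0.2, 1.0, 1.5)


class TestSolveSteadyState:
    def test_reference_ph6_no_adjustment(self, default_model):
        obs = make_observation(6.0, nhx_ic=10.9, nhx_ec=2.61, q_n=0.183)
        sol = solve_steady_state(obs, default_model)
        assert sol.feasible and sol.adjusted is None
        assert sol.permeability == pytest.approx(0.37, rel=0.05)

    def test_reference_ph5_triggers_vacuole_adjustment(self, default_model):
        obs = make_observation(5.0, nhx_ic=10.5, nhx_ec=6.99, q_n=0.190)
        sol = solve_steady_state(obs, default_model)
        assert sol.feasible
        vac = sol.model_used.get("vacuole")
        assert vac.volume_fraction == pytest.approx(0.25)
        assert vac.ph == pytest.approx(4.2)
        assert "vacuole" in sol.adjusted

    def test_forward_inverse_consistency(self, default_model):
        """An observation generated from the forward model with known
        permeability is recovered exactly."""
        p_true, ph, nh3_cyt, q_n = 1.0, 6.0, 5e-4, 0.19
        gradient = q_n / (1000.0 * p_true * 3.22)
        nh3_ec = nh3_cyt + gradient
        obs = make_observation(
            ph,
            nhx_ic=wholecell_from_free_nh3(nh3_cyt, default_model),
            nhx_ec=nh3_ec / nh3_fraction(ph),
            q_n=q_n,
        )
        sol = solve_steady_state(obs, default_model)
        assert sol.adjusted is None
        assert sol.permeability == pytest.approx(p_true, rel=1e-9)

    def test_hopeless_system_reports_infeasible(self, default_model):
        # essentially no residual NH_X outside: no assumption helps
        obs = make_observation(5.0, nhx_ic=10.5, nhx_ec=1e-4, q_n=0.190)
        sol = solve_steady_state(obs, default_model)
        assert not sol.feasible
        assert sol.permeability is None
        assert "sensitivity box" in sol.adjusted

    def test_feasibility_monotonicity(self, default_model):
        """Raising vacuolar volume or lowering vacuolar pH never raises
        the cytosolic estimate: both drive toward a positive gradient."""
        wholecell = 10.5
        base = free_nh3_from_wholecell(wholecell, default_model)
        previous = base
        for frac in np.arange(0.15, 0.26, 0.01):
            m = default_model.replace_compartment("vacuole", volume_fraction=frac)
            value = free_nh3_from_wholecell(wholecell, m)
            assert value <= previous
            previous = value
        previous = base
        for ph in np.arange(4.4, 3.9, -0.1):
            m = default_model.replace_compartment("vacuole", ph=float(ph))
            value = free_nh3_from_wholecell(wholecell, m)
            assert value <= previous
            previous = value


class TestGrowthLaw:
    def test_slope_matches_batch_line(self):
        # P = 0.0115 m/h -> mu/[NH3] = P a_m / chi_N = 6.61 L/mmol/h
        mu = growth_rate_from_nh3(1.0, 0.0115)
        assert mu == pytest.approx(6.61, rel=0.002)

    def test_zero_concentration_zero_growth(self):
        assert growth_rate_from_nh3(0.0, 0.0115) == 0.0

    def test_ceiling_applies(self):
        params = TransportParams(mu_max=0.21)
        assert growth_rate_from_nh3(10.0, 0.0115, params) == 0.21


class TestFitPermeability:
    def test_noiseless_points_recover_batch_value(self):
        params = TransportParams(mu_max=0.21)
        c = np.linspace(0.001, 0.01, 10)
        points = [(ci, 6.6125 * ci) for ci in c]
        fit = fit_permeability_from_growth(points, params)
        assert fit.permeability == pytest.approx(0.0115, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_saturated_point_excluded_by_mu_cap_rule(self):
        params = TransportParams(mu_max=0.21)
        points = [(c, 6.6125 * c) for c in np.linspace(0.001, 0.01, 10)]
        points.append((0.5, 0.21))  # saturated well
        fit = fit_permeability_from_growth(points, params, ("mu-cap", 0.8))
        assert fit.permeability == pytest.approx(0.0115, rel=1e-6)
        assert fit.n_points == 10

    def test_half_mu_max_rule_drops_saturated_points(self):
        params = TransportParams(mu_max=0.21)
        points = [(c, min(6.6125 * c, 0.21)) for c in np.geomspace(1e-3, 0.5, 20)]
        fit = fit_permeability_from_growth(points, params)
        assert fit.permeability == pytest.approx(0.0115, rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(11)
        c = np.tile(np.geomspace(5e-4, 1.4e-2, 12), 2)  # n = 24
        mu = 6.6125 * c * np.exp(rng.normal(0.0, 0.10, c.size))
        fit = fit_permeability_from_growth(
            list(zip(c, mu)), TransportParams(mu_max=0.21)
        )
        assert fit.permeability == pytest.approx(0.0115, rel=0.15)

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            fit_permeability_from_growth([(0.01, 0.05)], TransportParams(mu_max=0.21))

    def test_rule_requires_mu_max(self):
        with pytest.raises(ConfigurationError):
            fit_permeability_from_growth([(0.01, 0.05), (0.02, 0.1)], TransportParams())
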