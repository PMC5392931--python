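"""Three-compartment equilibrium model and ratio sensitivity bounds."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ammoflux import (
    AcidBaseParams,
    CellModel,
    Compartment,
    MembraneEnergetics,
    SensitivityBox,
    compartment_profile,
    free_nh3_from_wholecell,
    predicted_ratio_diffusion,
    predicted_ratio_uniport,
    ratio_bounds,
    retention_factor,
    wholecell_from_free_nh3,
)
from ammoflux.errors import ConfigurationError, DomainError, UsageError


def single_compartment(ph: float, fraction: float = 1.0) -> CellModel:
    return CellModel(compartments=(Compartment("cytosol", fraction, ph),))


class TestRetentionFactor:
    def test_default_model_value(self, default_model):
        # 0.70*(1+10^2.75) + 0.14*(1+10^4.75) + 0.01*(1+10^1.75)
        assert retention_factor(default_model) == pytest.approx(8.268e3, rel=1e-3)

    def test_adjusted_vacuole_value(self, default_model):
        adjusted = default_model.replace_compartment(
            "vacuole", volume_fraction=0.25, ph=4.2
        )
        assert retention_factor(adjusted) == pytest.approx(2.845e4, rel=1e-3)

    def test_single_compartment_at_pka(self):
        model = single_compartment(9.25)
        assert retention_factor(model) == pytest.approx(2.0)

    @given(ph_shift=st.floats(min_value=0.05, max_value=2.0))
    def test_decreasing_in_compartment_ph(self, default_model, ph_shift):
        vac = default_model.get("vacuole")
        raised = default_model.replace_compartment("vacuole", ph=vac.ph + ph_shift)
        assert retention_factor(raised) < retention_factor(default_model)

    def test_at_least_total_volume(self, default_model):
        total = sum(c.volume_fraction for c in default_model.compartments)
        assert retention_factor(default_model) >= total


class TestDeconvolution:
    @pytest.mark.parametrize(
        "wholecell, expected_umol",
        [(10.9, 1.32), (7.48, 0.90)],  # reference whole-cell pools, pH 6/7
    )
    def test_reference_cytosolic_nh3(self, default_model, wholecell, expected_umol):
        nh3 = free_nh3_from_wholecell(wholecell, default_model)
        assert nh3 * 1000.0 == pytest.approx(expected_umol, rel=0.01)

    def test_zero_maps_to_zero(self, default_model):
        assert free_nh3_from_wholecell(0.0, default_model) == 0.0
        assert wholecell_from_free_nh3(0.0, default_model) == 0.0

    @given(nh3=st.floats(min_value=1e-9, max_value=10.0))
    def test_round_trip_identity(self, default_model, nh3):
        back = free_nh3_from_wholecell(
            wholecell_from_free_nh3(nh3, default_model), default_model
        )
        assert back == pytest.approx(nh3, rel=1e-12)

    def test_negative_input_rejected(self, default_model):
        with pytest.raises(DomainError):
            free_nh3_from_wholecell(-0.1, default_model)


class TestCompartmentProfile:
    def test_vacuolar_trapping_magnitude(self, default_model):
        # 1 umol/L free NH3 at vacuolar pH 4.5 -> 56 mM NH4+ trapped
        profile = compartment_profile(1e-3, default_model)
        assert profile.loc["vacuole", "nh4_mM"] == pytest.approx(56.23, rel=1e-3)

    def test_cytosolic_speciation_ratio(self, default_model):
        profile = compartment_profile(1e-3, default_model)
        ratio = profile.loc["cytosol", "nh4_mM"] / profile.loc["cytosol", "nh3_mM"]
        assert ratio == pytest.approx(10.0 ** 2.75, rel=1e-9)

    def test_zero_free_nh3_gives_all_zeros(self, default_model):
        profile = compartment_profile(0.0, default_model)
        assert (profile[["nh3_mM", "nh4_mM", "nhx_mM"]] == 0.0).all().all()

    @given(nh3=st.floats(min_value=0.0, max_value=1.0))
    def test_mass_consistency_with_wholecell(self, default_model, nh3):
        profile = compartment_profile(nh3, default_model)
        weighted = float((profile["volume_fraction"] * profile["nhx_mM"]).sum())
        assert weighted == pytest.approx(
            wholecell_from_free_nh3(nh3, default_model), rel=1e-12, abs=1e-300
        )


class TestPredictedRatios:
    def test_diffusion_max_corner_ph5(self, default_model, default_box):
        model = default_box.model_at(default_model, 0.25, 6.0, 4.0)
        assert predicted_ratio_diffusion(5.0, model) == pytest.approx(2.57, abs=0.005)

    def test_diffusion_max_corner_ph6(self, default_model, default_box):
        model = default_box.model_at(default_model, 0.25, 6.0, 4.0)
        assert predicted_ratio_diffusion(6.0, model) == pytest.approx(25.7, abs=0.05)

    def test_diffusion_identity_when_inside_matches_outside(self):
        model = single_compartment(5.5)
        assert predicted_ratio_diffusion(5.5, model) == pytest.approx(1.0)

    def test_diffusion_level_independence(self, default_model):
        # ratio is a pure model property; no concentration argument exists
        assert predicted_ratio_diffusion(6.0, default_model) > 0.0

    @given(ph=st.floats(min_value=3.0, max_value=6.25))
    def test_tenfold_increase_per_ph_unit(self, default_model, ph):
        """Far below the pKa the diffusion ratio rises tenfold per unit
        of extracellular pH (the quotient degrades once pH_EC + 1
        approaches pKa - 2)."""
        quotient = predicted_ratio_diffusion(ph + 1.0, default_model) / (
            predicted_ratio_diffusion(ph, default_model)
        )
        assert 9.9 <= quotient <= 10.0

    def test_uniport_corner_values_ph5(self, default_model, default_box):
        energetics = MembraneEnergetics(pmf_mV=-200.0)
        hi = default_box.model_at(default_model, 0.25, 6.0, 4.0)
        lo = default_box.model_at(default_model, 0.14, 7.0, 5.5)
        assert predicted_ratio_uniport(5.0, hi, energetics) == pytest.approx(
            5.44e3, rel=0.01
        )
        assert predicted_ratio_uniport(5.0, lo, energetics) == pytest.approx(
            108.0, rel=0.01
        )

    def test_uniport_no_driving_force_no_trapping(self):
        model = single_compartment(5.0)
        energetics = MembraneEnergetics(pmf_mV=0.0)
        assert predicted_ratio_uniport(5.0, model, energetics) == pytest.approx(1.0)

    def test_uniport_requires_cytosol(self):
        model = CellModel(compartments=(Compartment("vacuole", 0.14, 4.5),))
        with pytest.raises(ConfigurationError):
            predicted_ratio_uniport(5.0, model)

    @given(ph=st.floats(min_value=3.0, max_value=6.0))
    def test_uniport_tenfold_per_ph_unit(self, default_model, ph):
        quotient = predicted_ratio_uniport(ph + 1.0, default_model) / (
            predicted_ratio_uniport(ph, default_model)
        )
        assert quotient == pytest.approx(10.0, rel=0.01)


class TestRatioBounds:
    def test_unknown_mechanism_rejected(self, default_model, default_box):
        with pytest.raises(UsageError):
            ratio_bounds("osmosis", 5.0, default_box, default_model)

    def test_degenerate_box_collapses(self, default_model):
        box = SensitivityBox(
            vacuole_fraction=(0.14, 0.14), cytosol_ph=(6.5, 6.5), vacuole_ph=(4.5, 4.5)
        )
        bounds = ratio_bounds("diffusion", 6.0, box, default_model)
        assert bounds.minimum == bounds.maximum

    def test_nominal_model_within_bounds(self, default_model, default_box):
        for mechanism in ("diffusion", "uniport"):
            bounds = ratio_bounds(mechanism, 6.0, default_box, default_model)
            if mechanism == "diffusion":
                nominal = predicted_ratio_diffusion(6.0, default_model)
            else:
                nominal = predicted_ratio_uniport(6.0, default_model)
            assert bounds.minimum <= nominal <= bounds.maximum

    def test_corner_search_equals_dense_grid_oracle(self, default_model):
        """Corner extremes equal an exhaustive 21^3 grid search on 50
        random boxes (the ratio is monotone in each coordinate)."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            v_lo, v_hi = sorted(rng.uniform(0.05, 0.28, 2))
            pc_lo, pc_hi = sorted(rng.uniform(5.5, 7.5, 2))
            pv_lo, pv_hi = sorted(rng.uniform(3.5, 6.0, 2))
            box = SensitivityBox(
                vacuole_fraction=(v_lo, v_hi),
                cytosol_ph=(pc_lo, pc_hi),
                vacuole_ph=(pv_lo, pv_hi),
            )
            mechanism = "diffusion" if rng.uniform() < 0.5 else "uniport"
            ph = float(rng.uniform(4.0, 7.0))
            bounds = ratio_bounds(mechanism, ph, box, default_model)
            values = []
            for v in np.linspace(v_lo, v_hi, 21):
                for pc in np.linspace(pc_lo, pc_hi, 21):
                    for pv in np.linspace(pv_lo, pv_hi, 21):
                        model = box.model_at(default_model, v, pc, pv)
                        if mechanism == "diffusion":
                            values.append(predicted_ratio_diffusion(ph, model))
                        else:
                            values.append(predicted_ratio_uniport(ph, model))
            assert bounds.minimum == pytest.approx(min(values), rel=1e-12)
            assert bounds.maximum == pytest.approx(max(values), rel=1e-12)

    def test_mechanism_separation(self, default_model, default_box):
        """The uniport minimum exceeds the diffusion maximum at every
        culture pH: the two uptake mechanisms are discriminable from
        measured IC/EC ratios even under compartment uncertainty."""
        for ph in (5.0, 6.0, 7.0):
            diffusion = ratio_bounds("diffusion", ph, default_box, default_model)
            uniport = ratio_bounds("uniport", ph, default_box, default_model)
            assert uniport.minimum > diffusion.maximum


class TestModelValidation:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError):
            CellModel(
                compartments=(
                    Compartment("cytosol", 0.5, 6.5),
                    Compartment("cytosol", 0.2, 4.5),
                )
            )

    def test_volume_overflow_rejected(self):
        with pytest.raises(ConfigurationError):
            CellModel(
                compartments=(
                    Compartment("cytosol", 0.7, 6.5),
                    Compartment("vacuole", 0.4, 4.5),
                )
            )

    def test_empty_model_rejected(self):
        with pytest.raises(DomainError):
            CellModel(compartments=())

    def test_pka_override_flows_through(self):
        model = CellModel.default(AcidBaseParams(pka=8.25))
        assert retention_factor(model) < retention_factor(CellModel.default())
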