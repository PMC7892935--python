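"""Property-model unit tests: mixture rules, isotherm, saturation, pores."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from injeradry import properties as P


def table_with(density=None, specific_heat=None, conductivity=None):
    """A constant-coefficient component table for closed-form checks."""
    models = {}
    comps = set()
    for prop in (density or {}), (specific_heat or {}), (conductivity or {}):
        comps |= set(prop)
    for c in comps:
        coeffs = {}
        if density and c in density:
            coeffs["density"] = (density[c],)
        if specific_heat and c in specific_heat:
            coeffs["specific_heat"] = (specific_heat[c],)
        if conductivity and c in conductivity:
            coeffs["conductivity"] = (conductivity[c],)
        models[c] = P.ComponentPropertyModel(c, coeffs)
    return P.ComponentTable(models)


def comp_two(water, carbohydrate):
    return P.Composition(water=water, carbohydrate=carbohydrate,
                         protein=0, fat=0, fiber=0, ash=0)


class TestMixtureRules:
    def test_density_single_component_identity(self):
        t = table_with(density={"water": 998.0})
        c = comp_two(1.0, 0.0)
        assert P.mixture_density(c, 300.0, t) == pytest.approx(998.0)

    def test_density_harmonic_mean_two_components(self):
        t = table_with(density={"water": 1000.0, "carbohydrate": 2000.0})
        c = comp_two(0.5, 0.5)
        assert P.mixture_density(c, 300.0, t) == pytest.approx(
            1.0 / (0.5 / 1000 + 0.5 / 2000))  # 1333.33

    def test_density_reference_composition(self):
        rho = P.mixture_density(P.INJERA_COMPOSITION, 323.15)
        assert rho == pytest.approx(1136.49, rel=0.02)

    def test_density_decreases_with_temperature(self):
        rhos = [P.mixture_density(P.INJERA_COMPOSITION, T)
                for T in (313.15, 323.15, 333.15)]
        assert rhos[0] > rhos[1] > rhos[2]

    def test_specific_heat_single_component(self):
        t = table_with(density={"water": 998.0},
                       specific_heat={"water": 4180.0})
        assert P.mixture_specific_heat(comp_two(1, 0), 300.0, t) == \
            pytest.approx(4180.0)

    def test_specific_heat_weighted_mean(self):
        t = table_with(specific_heat={"water": 4180.0, "carbohydrate": 1600.0})
        assert P.mixture_specific_heat(comp_two(0.6, 0.4), 300.0, t) == \
            pytest.approx(3148.0)

    def test_specific_heat_bounded_by_components(self):
        cp = P.mixture_specific_heat(P.INJERA_COMPOSITION, 323.15)
        tab = P.component_table()
        cps = [tab.evaluate(c, "specific_heat", 323.15)
               for c in ("water", "carbohydrate", "protein", "fat",
                         "fiber", "ash")]
        assert min(cps) < cp < max(cps)

    def test_conductivity_single_component(self):
        t = table_with(density={"water": 998.0}, conductivity={"water": 0.6})
        assert P.mixture_conductivity(comp_two(1, 0), 300.0, t) == \
            pytest.approx(0.6)

    def test_conductivity_equal_densities_mass_weighted(self):
        t = table_with(density={"water": 1000.0, "carbohydrate": 1000.0},
                       conductivity={"water": 0.6, "carbohydrate": 0.2})
        assert P.mixture_conductivity(comp_two(0.5, 0.5), 300.0, t) == \
            pytest.approx(0.4)

    def test_volume_fractions_sum_to_one(self):
        E = P.volume_fractions(P.INJERA_COMPOSITION, 323.15)
        assert sum(E.values()) == pytest.approx(1.0, abs=1e-12)

    def test_temperature_out_of_range_names_component(self):
        with pytest.raises(P.PropertyRangeError, match="water"):
            P.component_table().evaluate("water", "density", 500.0)

    def test_unknown_component(self):
        with pytest.raises(KeyError, match="gluten"):
            P.component_table().evaluate("gluten", "density", 300.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.05, 1.0), min_size=6, max_size=6))
    def test_density_matches_term_by_term_oracle(self, raw):
        total = sum(raw)
        x = [v / total for v in raw]
        comp = P.Composition(water=x[0], carbohydrate=x[1], protein=x[2],
                             fat=x[3], fiber=x[4], ash=x[5])
        tab = P.component_table()
        # independent oracle: explicit sum over the coefficient table
        acc = 0.0
        for name, frac in comp.as_dict().items():
            coeffs = tab.models[name].coefficients["density"]
            t = 323.15 - 273.15
            rho_i = sum(a * t**k for k, a in enumerate(coeffs))
            acc += frac / rho_i
        assert P.mixture_density(comp, 323.15) == pytest.approx(1.0 / acc,
                                                                rel=1e-12)


class TestComposition:
    def test_rejects_bad_sum(self):
        with pytest.raises(ValueError, match="sum"):
            P.Composition(water=0.5, carbohydrate=0.2, protein=0.1,
                          fat=0.05, fiber=0.05, ash=0.05)

    def test_rejects_negative_fraction(self):
        with pytest.raises(ValueError):
            P.Composition(water=-0.1, carbohydrate=1.1, protein=0,
                          fat=0, fiber=0, ash=0)

    def test_normalized_sums_to_one(self):
        assert P.INJERA_COMPOSITION.normalized().total() == \
            pytest.approx(1.0, abs=1e-12)


class TestPorosity:
    def test_equal_densities_give_zero(self):
        assert P.porosity(1000.0, 1000.0) == 0.0

    def test_algebraic_inversion(self):
        assert P.porosity(260.0, 1000.0) == pytest.approx(0.74)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError, match="porosity"):
            P.porosity(1200.0, 1000.0)
        with pytest.raises(ValueError, match="positive"):
            P.porosity(-1.0, 1000.0)


class TestWaterActivity:
    def test_limits(self):
        assert P.water_activity(100.0) > 0.999
        assert P.water_activity(0.01) < 1e-6

    def test_reference_point(self):
        # direct term-by-term evaluation at the initial dry-basis moisture
        assert P.water_activity(1.551) == pytest.approx(0.98996, abs=2e-4)

    def test_strictly_increasing(self):
        x = np.logspace(np.log10(0.01), 2, 400)
        aw = P.water_activity(x)
        assert np.all(np.diff(aw) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            P.water_activity(0.0)

    def test_equilibrium_moisture_inverts_isotherm(self):
        for target in (0.11, 0.157, 0.5):
            x = P.equilibrium_moisture(target)
            assert P.water_activity(x) == pytest.approx(target, rel=1e-10)


class TestSaturationState:
    def test_boiling_point_value(self):
        pv, _ = P.saturation_state(373.15)
        assert pv == pytest.approx(1.032e5, rel=0.01)   # correlation value
        assert pv == pytest.approx(101325.0, rel=0.03)  # steam-table sanity

    def test_ideal_gas_identity(self):
        pv, cv = P.saturation_state(310.0)
        assert cv * P.CONSTANTS.R * 310.0 == pytest.approx(pv, rel=1e-12)

    def test_monotone_and_smooth(self):
        T = np.linspace(283.15, 373.15, 500)
        pv, cv = P.saturation_state(T)
        assert np.all(np.diff(pv) > 0) and np.all(np.diff(cv) > 0)
        d1 = np.gradient(pv, T)
        assert np.all(np.abs(np.diff(d1) / np.diff(T)[0]) < 1e4)  # C1 smooth

    def test_range_error(self):
        with pytest.raises(P.PropertyRangeError):
            P.saturation_state(250.0)


class TestMoistureConversions:
    def test_zero_is_zero(self):
        assert P.concentration_to_wet_basis(0.0, 1136.0) == 0.0
        assert P.concentration_to_dry_basis(0.0, 0.74, 1136.0) == 0.0

    def test_round_trip_exact(self):
        c = 38371.6
        x = P.concentration_to_dry_basis(c, 0.74, 1136.0)
        assert P.dry_basis_to_concentration(x, 0.74, 1136.0) == \
            pytest.approx(c, rel=1e-12)

    def test_adopted_convention_value(self):
        c = P.wet_basis_to_concentration(0.608, 1136.0)
        assert P.concentration_to_dry_basis(c, 0.74, 1136.0) == \
            pytest.approx(2.338, abs=5e-3)

    def test_full_porosity_error(self):
        with pytest.raises(ValueError, match="porosity"):
            P.concentration_to_dry_basis(100.0, 1.0, 1136.0)


class TestPoreStructure:
    def test_gas_diffusivity_endpoints(self):
        assert P.effective_gas_diffusivity(0.74, 0.0) == 0.0
        assert P.effective_gas_diffusivity(1.0, 1.0, 2.6e-5) == \
            pytest.approx(2.6e-5)

    def test_gas_diffusivity_reference(self):
        assert P.effective_gas_diffusivity(0.74, 1.0, 2.6e-5) == \
            pytest.approx(2.075e-5, rel=1e-3)

    def test_permeability_endpoints(self):
        assert P.permeabilities(0.005, 0.005)[0] == 0.0
        kwr, kgr = P.permeabilities(1.0, 0.005)
        assert kwr == pytest.approx(1.0) and kgr == 0.0

    def test_permeability_reference_values(self):
        kwr, kgr = P.permeabilities(0.5, 0.005)
        assert kwr == pytest.approx(0.1231, abs=1e-3)
        assert kgr == pytest.approx(0.45, abs=1e-12)

    def test_permeability_grid_bounds(self):
        sw = np.linspace(0, 1, 101)
        for sir in (0.0, 0.005, 0.2):
            kwr, kgr = P.permeabilities(sw, sir)
            assert np.all((kwr >= 0) & (kwr <= 1))
            assert np.all((kgr >= 0) & (kgr <= 1))
            assert np.all(kwr + kgr <= 1.12 + 1e-12)

    def test_irreducible_saturation_reference(self):
        assert P.irreducible_saturation(0.74, 298.15) == \
            pytest.approx(0.00543, abs=1e-4)

    def test_irreducible_saturation_limits(self):
        assert P.irreducible_saturation(0.999999, 298.15) < 1e-3
        eps = np.linspace(0.3, 0.95, 20)
        sir = [P.irreducible_saturation(e, 298.15) for e in eps]
        assert np.all(np.diff(sir) < 0)


class TestEffectiveThermal:
    def test_fluid_blend_endpoints(self):
        C = P.CONSTANTS
        eff0 = P.effective_thermal_mixture(1136, 3200, 0.45, 0.74, 0.0)
        assert (eff0.k_f, eff0.rho_f, eff0.cp_f) == \
            (C.K_WATER, C.RHO_WATER, C.CP_WATER)
        eff1 = P.effective_thermal_mixture(1136, 3200, 0.45, 0.74, 1.0)
        assert eff1.k_f == pytest.approx(C.K_AIR, rel=1e-12)
        assert eff1.rho_f == pytest.approx(C.RHO_AIR, rel=1e-12)
        assert eff1.cp_f == pytest.approx(C.CP_AIR, rel=1e-12)

    def test_as_printed_conductivity_rule(self):
        eff = P.effective_thermal_mixture(1136, 3200, 0.40, 0.74, 0.95)
        assert eff.k_eff == pytest.approx(0.311, abs=1.5e-3)

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            P.effective_thermal_mixture(1136, 3200, 0.4, 0.74, 0.5, "bogus")

    @pytest.mark.parametrize("T", [313.15, 323.15, 333.15])
    def test_bundle_positive_and_finite(self, T):
        b = P.evaluate_bundle(P.INJERA_COMPOSITION, T, 49750.0)
        for name, v in b.as_dict().items():
            assert np.isfinite(v), name
            if name not in ("Sg", "kgr", "kwr", "Sir", "Xv", "D_gas"):
                assert v > 0, name
        assert 0 < b.aw <= 1
        assert 0 <= b.Sw <= 1 and 0 <= b.Sg <= 1
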