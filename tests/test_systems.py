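"""Composite deconstruction, pressure gradients and complex-system splits."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from osmocalc import (
    CompositeOsmosisSystem,
    Membrane,
    SimpleOsmosisSystem,
    SoluteMolecule,
    SolutionComposition,
    SystemCoefficient,
    ThermodynamicContext,
    composite_gradient,
    deconstruct_composite,
    extended_gradient,
    oc0_molecule_based,
    split_complex,
)

from conftest import contexts, membranes_for, solutions

IDEAL = Membrane()
WATER = SolutionComposition()


def _simple_pair(c1: float, c2: float, ctx=None):
    ctx = ctx or ThermodynamicContext(295.15, "bar", gas_constant=0.08314)
    mol = SoluteMolecule.nonelectrolyte("solute")
    s1 = SolutionComposition(((mol, c1),))
    s2 = SolutionComposition(((mol, c2),))
    return CompositeOsmosisSystem(s1, IDEAL, s2, ctx)


composite_systems = st.tuples(solutions(), solutions(), contexts).flatmap(
    lambda t: st.tuples(
        st.just(t[0]), st.just(t[1]), st.just(t[2]), membranes_for(t[0])
    )
).map(lambda t: CompositeOsmosisSystem(t[0], t[3], t[1], t[2]))


class TestDeconstruction:
    def test_mirrored_halves_share_membrane_and_context(self):
        system = _simple_pair(0.3, 0.1)
        s1, s2 = deconstruct_composite(system)
        assert s1.solution is system.solution_1
        assert s2.solution is system.solution_2
        assert s1.membrane is s2.membrane is system.membrane
        assert s1.context is s2.context is system.context

    def test_water_second_compartment_reduces_to_simple(self):
        mol = SoluteMolecule.nonelectrolyte("glucose")
        system = CompositeOsmosisSystem(
            SolutionComposition(((mol, 0.1),)), IDEAL, WATER,
            ThermodynamicContext(),
        )
        _, s2 = deconstruct_composite(system)
        assert s2.oc0() == 0.0
        grad = composite_gradient(system)
        assert grad.delta_pi == pytest.approx(
            SimpleOsmosisSystem(system.solution_1, IDEAL, system.context)
            .pressure().value
        )

    def test_swap_swaps_the_pair(self):
        system = _simple_pair(0.3, 0.1)
        a, b = deconstruct_composite(system)
        b2, a2 = deconstruct_composite(system.swapped())
        assert a.solution is a2.solution and b.solution is b2.solution

    @given(composite_systems)
    def test_gradient_equals_difference_of_mirrored_simple_pressures(self, system):
        s1, s2 = deconstruct_composite(system)
        grad = composite_gradient(system)
        expected = s1.pressure().value - s2.pressure().value
        assert grad.delta_pi == pytest.approx(expected, rel=1e-12, abs=1e-9)


class TestCompositeGradient:
    def test_hand_computed_gradient_and_direction(self):
        # OC0 0.3 vs 0.1 at RT = 24.54 -> 4.908 bar toward compartment 1
        grad = composite_gradient(_simple_pair(0.3, 0.1))
        assert grad.delta_pi == pytest.approx(0.2 * 0.08314 * 295.15, rel=1e-12)
        assert grad.delta_pi == pytest.approx(4.908, abs=1e-3)
        assert grad.direction == "compartment_1"
        assert (grad.oc0_1, grad.oc0_2) == (pytest.approx(0.3), pytest.approx(0.1))

    def test_equal_compartments_give_zero_and_none(self):
        grad = composite_gradient(_simple_pair(0.2, 0.2))
        assert grad.delta_pi == 0.0
        assert grad.direction == "none"

    @given(composite_systems)
    def test_antisymmetric_under_compartment_swap(self, system):
        fwd = composite_gradient(system)
        rev = composite_gradient(system.swapped())
        assert fwd.delta_pi == pytest.approx(-rev.delta_pi, rel=1e-12, abs=1e-12)
        if fwd.direction != "none":
            assert {fwd.direction, rev.direction} == {
                "compartment_1", "compartment_2"
            }

    @given(composite_systems)
    def test_direction_consistent_with_sign(self, system):
        grad = composite_gradient(system)
        if grad.delta_pi > 0:
            assert grad.direction == "compartment_1"
        elif grad.delta_pi < 0:
            assert grad.direction == "compartment_2"
        else:
            assert grad.direction == "none"


class TestExtendedGradient:
    def test_unit_theta_reduces_to_ideal_law_on_ctsp(self):
        system = _simple_pair(0.3, 0.1)
        grad = extended_gradient(system, SystemCoefficient(1.0))
        assert grad.delta_pi == pytest.approx(composite_gradient(system).delta_pi)

    def test_body_fluid_scale_gradient(self):
        ctx = ThermodynamicContext(310.15, "mmHg", gas_constant=62.3637)
        mol = SoluteMolecule.nonelectrolyte("mix")
        system = CompositeOsmosisSystem(
            SolutionComposition(((mol, 299.8e-3),)), IDEAL,
            SolutionComposition(((mol, 281.0e-3),)), ctx,
        )
        grad = extended_gradient(system, SystemCoefficient(0.94))
        # 0.94 * 18.8 mOsm/L * 19.3421 mmHg per mOsm/L
        assert grad.delta_pi == pytest.approx(0.94 * 18.8e-3 * ctx.rt, rel=1e-12)
        assert grad.delta_pi == pytest.approx(341.8, abs=0.1)

    def test_equal_ctsp_gives_zero(self):
        grad = extended_gradient(_simple_pair(0.2, 0.2), SystemCoefficient(0.9))
        assert grad.delta_pi == 0.0


class TestSplitComplex:
    def _inulin_urea(self):
        inulin = SoluteMolecule.nonelectrolyte("inulin")
        urea = SoluteMolecule.nonelectrolyte("urea")
        sol = SolutionComposition(((inulin, 0.002), (urea, 0.005)))
        membrane = Membrane(sigma_by_molecule={"inulin": 1.0, "urea": 0.05})
        return sol, membrane

    def test_inulin_retained_urea_diffuses(self):
        sol, membrane = self._inulin_urea()
        decomp = split_complex(sol, membrane, 0.95)
        retained = [m.name for m, _ in decomp.osmosis_subsystem.solution.components]
        permeant = [m.name for m, _ in decomp.diffusion_subsystem]
        assert retained == ["inulin"] and permeant == ["urea"]
        assert decomp.cutoff_used == 0.95

    def test_ideal_membrane_leaves_diffusion_empty(self, saline_mix):
        decomp = split_complex(saline_mix, IDEAL)
        assert decomp.diffusion_subsystem == ()

    def test_fully_permeable_membrane_empties_osmosis_side(self, saline_mix):
        decomp = split_complex(saline_mix, Membrane(default_sigma=0.0))
        assert decomp.osmosis_subsystem.solution.components == ()
        assert decomp.osmosis_subsystem.oc0() == 0.0

    def test_cutoff_bounds_enforced(self, saline_mix):
        with pytest.raises(ValueError, match="cutoff"):
            split_complex(saline_mix, IDEAL, sigma_cutoff=0.0)
        with pytest.raises(ValueError, match="cutoff"):
            split_complex(saline_mix, IDEAL, sigma_cutoff=1.2)

    @given(solutions().flatmap(
        lambda sol: st.tuples(st.just(sol), membranes_for(sol))
    ), st.floats(0.05, 1.0))
    def test_partition_is_exhaustive_and_disjoint(self, sol_membrane, cutoff):
        sol, membrane = sol_membrane
        decomp = split_complex(sol, membrane, cutoff)
        merged = sorted(
            list(decomp.osmosis_subsystem.solution.components)
            + list(decomp.diffusion_subsystem),
            key=lambda pair: pair[0].name,
        )
        assert merged == sorted(sol.components, key=lambda pair: pair[0].name)

    def test_osmosis_subsystem_oc0_matches_masked_membrane_oracle(self):
        """The split's OC0 equals the full solution under a 0/1-masked membrane."""
        sol, membrane = self._inulin_urea()
        decomp = split_complex(sol, membrane, 0.95)
        masked = Membrane(sigma_by_molecule={"inulin": 1.0, "urea": 0.0})
        assert decomp.osmosis_subsystem.oc0() == pytest.approx(
            oc0_molecule_based(sol, masked)
        )
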