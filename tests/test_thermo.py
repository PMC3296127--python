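"""NET analysis: feasibility verdicts, range estimation, transport terms."""

import math

import numpy as np
import pytest

from thermoefm.errors import ConfigurationError, StateError, ValidationError
from thermoefm.fixtures import check_witness, grid_feasibility
from thermoefm.model_io import (
    Compartment,
    DirectionClass,
    DirectionConstraintSet,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from thermoefm.thermo import (
    FARADAY,
    R_GAS,
    ActivityPattern,
    ConcentrationSet,
    Pool,
    ThermoData,
    TransportedSpecies,
    derive_direction_constraints,
    estimate_ranges,
    net_feasibility,
    transform_formation_energy,
    transport_delta_g,
)

RT = R_GAS * 298.15


class TestNetFeasibility:
    def test_planted_infeasible_pair(self, toy6):
        res = net_feasibility(
            toy6.model, ActivityPattern({"R2": 1, "R3": 1}), toy6.conc, toy6.thermo
        )
        assert res.verdict == "infeasible"

    def test_empty_pattern_feasible(self, toy6):
        assert net_feasibility(toy6.model, ActivityPattern(), toy6.conc, toy6.thermo).verdict == "feasible"

    def test_single_exergonic_reaction_with_witness(self, toy6):
        res = net_feasibility(toy6.model, ActivityPattern({"R1": 1}), toy6.conc, toy6.thermo)
        assert res.verdict == "feasible"
        assert check_witness(toy6.model, {"R1": 1}, res.witness_mm, toy6.conc, toy6.thermo)
        # c_A = c_B = 1 mM is a witness: dG = -10 + RT ln 1 < 0
        assert check_witness(
            toy6.model, {"R1": 1}, {"A": 1.0, "B": 1.0}, toy6.conc, toy6.thermo
        )

    def test_unannotated_reaction_rejected(self, toy6):
        with pytest.raises(ConfigurationError):
            net_feasibility(toy6.model, ActivityPattern({"T_A": 1}), toy6.conc, toy6.thermo)

    def test_bad_sign_rejected(self):
        with pytest.raises(ValidationError):
            ActivityPattern({"R1": 2})

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValidationError):
            ConcentrationSet(species_bounds_mm={"A": (0.0, 1.0)})


class TestOracleEquivalence:
    """Solver verdicts against the exhaustive grid oracle on every fixture
    whose pattern touches few enough species."""

    def _patterns(self, fx):
        out = []
        for pat in fx.expected_sign_patterns:
            constrained = {
                r: s for r, s in pat.items() if fx.thermo.is_constrained(r)
            }
            if constrained:
                out.append(constrained)
        return out

    def test_verdicts_match_grid_oracle(self, all_fixtures):
        checked = 0
        for fx in all_fixtures:
            for pat in self._patterns(fx):
                res = net_feasibility(fx.model, ActivityPattern(pat), fx.conc, fx.thermo)
                oracle_witness = grid_feasibility(fx.model, pat, fx.conc, fx.thermo)
                if res.verdict == "infeasible":
                    assert oracle_witness is None, (
                        f"solver infeasible but grid found {oracle_witness} for {pat}"
                    )
                if res.verdict == "feasible":
                    assert check_witness(
                        fx.model, pat, res.witness_mm, fx.conc, fx.thermo
                    ), f"witness fails exact constraints for {pat}"
                checked += 1
        assert checked >= 10

    def test_anti_symmetry_single_reactions(self, toy6):
        """A single activity and its reverse cannot both be infeasible under
        nondegenerate bounds and finite dG0'."""
        for rid in ("R1", "R2", "R3"):
            fwd = net_feasibility(toy6.model, ActivityPattern({rid: 1}), toy6.conc, toy6.thermo)
            bwd = net_feasibility(toy6.model, ActivityPattern({rid: -1}), toy6.conc, toy6.thermo)
            assert fwd.feasible or bwd.feasible

    def test_widening_bounds_never_flips_to_infeasible(self, toy6):
        wide = ConcentrationSet(
            species_bounds_mm={
                sid: (lo / 10.0, hi * 10.0)
                for sid, (lo, hi) in toy6.conc.species_bounds_mm.items()
            }
        )
        for pat in ({"R1": 1}, {"R2": 1}, {"R3": 1}, {"R2": 1, "R3": 1}):
            before = net_feasibility(toy6.model, ActivityPattern(pat), toy6.conc, toy6.thermo)
            after = net_feasibility(toy6.model, ActivityPattern(pat), wide, toy6.thermo)
            if before.feasible:
                assert after.feasible


class TestEstimateRanges:
    def test_endergonic_step_caps_product(self, toy6):
        """R2 forward (dG0' = +5) forces c_C < c_A exp(-5/RT) <= 0.133 mM."""
        res = estimate_ranges(toy6.model, ActivityPattern({"R2": 1}), toy6.conc, toy6.thermo)
        expected_cap = 1.0 * math.exp(-5.0 / RT)
        assert res.species_ranges_mm["C"][1] == pytest.approx(expected_cap, rel=1e-3)
        # grid oracle confirms a witness exists near the cap
        w = grid_feasibility(toy6.model, {"R2": 1}, toy6.conc, toy6.thermo)
        assert w is not None and w["C"] <= expected_cap * 1.01

    def test_ranges_contain_witness_and_stay_in_bounds(self, toy6):
        res = estimate_ranges(toy6.model, ActivityPattern({"R1": 1}), toy6.conc, toy6.thermo)
        for sid, (lo, hi) in res.species_ranges_mm.items():
            blo, bhi = toy6.conc.bounds_for(sid)
            assert blo * (1 - 1e-9) <= lo <= hi <= bhi * (1 + 1e-9)
            assert lo * (1 - 1e-9) <= res.witness_mm[sid] <= hi * (1 + 1e-9)

    def test_dg_ranges_respect_sign(self, toy6):
        res = estimate_ranges(toy6.model, ActivityPattern({"R1": 1}), toy6.conc, toy6.thermo)
        assert res.dg_ranges["R1"][1] < 0  # forward activity: dG' < 0 throughout

    def test_untouched_species_keeps_input_bounds(self, toy6):
        res = estimate_ranges(toy6.model, ActivityPattern({"R1": 1}), toy6.conc, toy6.thermo)
        # B appears in R1 with coefficient +1 but only the A/B ratio is
        # constrained; B's own range must stay within its input bounds
        assert res.species_ranges_mm["B"][0] >= 1.0 * (1 - 1e-9)
        assert res.species_ranges_mm["B"][1] <= 10.0 * (1 + 1e-9)

    def test_infeasible_pattern_raises_state_error(self, toy6):
        with pytest.raises(StateError):
            estimate_ranges(
                toy6.model, ActivityPattern({"R2": 1, "R3": 1}), toy6.conc, toy6.thermo
            )


class TestCompartmentPools:
    @pytest.fixture()
    def two_compartment(self):
        comps = {
            "cyt": Compartment("cyt", volume_fraction=0.35, ph=6.5),
            "mit": Compartment("mit", volume_fraction=0.1, ph=7.0),
        }
        mets = {
            "X_c": Metabolite("X_c", "cyt"),
            "X_m": Metabolite("X_m", "mit"),
            "Y_c": Metabolite("Y_c", "cyt"),
        }
        rxns = [
            Reaction("R_cm", {"X_c": -1.0, "X_m": 1.0}, reversible=True),
            Reaction("R_xy", {"X_c": -1.0, "Y_c": 1.0}, reversible=True),
        ]
        model = MetabolicModel(
            metabolites=mets, reactions=rxns, compartments=comps
        )
        thermo = ThermoData(dg0_prime={"R_cm": 0.0, "R_xy": 2.0})
        return model, thermo

    def test_pool_constrains_weighted_sum(self, two_compartment):
        model, thermo = two_compartment
        conc = ConcentrationSet(
            pools={"X": Pool(members=["X_c", "X_m"], bounds_mm=(0.45, 0.45))},
            species_bounds_mm={"Y_c": (0.001, 120.0)},
        )
        res = net_feasibility(model, ActivityPattern({"R_cm": 1}), conc, thermo)
        assert res.feasible
        if res.verdict == "feasible":
            total = 0.35 * res.witness_mm["X_c"] + 0.1 * res.witness_mm["X_m"]
            assert total == pytest.approx(0.45, rel=1e-6)

    def test_pool_agreement_with_grid_oracle(self, two_compartment):
        model, thermo = two_compartment
        conc = ConcentrationSet(
            species_bounds_mm={
                "X_c": (0.01, 10.0),
                "X_m": (0.01, 10.0),
                "Y_c": (0.01, 10.0),
            },
            pools={"X": Pool(members=["X_c", "X_m"], bounds_mm=(0.5, 2.0))},
        )
        for pat in ({"R_cm": 1}, {"R_cm": -1}, {"R_xy": 1}, {"R_cm": 1, "R_xy": 1}):
            res = net_feasibility(model, ActivityPattern(pat), conc, thermo)
            oracle = grid_feasibility(model, pat, conc, thermo)
            if res.verdict == "infeasible":
                assert oracle is None
            if res.verdict == "feasible":
                assert check_witness(model, pat, res.witness_mm, conc, thermo)


class TestTransportDeltaG:
    def test_uncharged_no_protons_is_zero(self, toy6):
        thermo = ThermoData(
            transport={"T_A": [TransportedSpecies("A", 0.0, 0.0, "ext", "cyt")]}
        )
        assert transport_delta_g("T_A", thermo, toy6.model) == 0.0

    def test_proton_chemical_gradient(self):
        model = MetabolicModel(
            metabolites={"H_e": Metabolite("H_e", "ext"), "H_c": Metabolite("H_c", "cyt")},
            compartments={
                "ext": Compartment("ext", ph=5.0),
                "cyt": Compartment("cyt", ph=6.5),
            },
            reactions=[Reaction("T_H", {"H_e": -1.0, "H_c": 1.0}, reversible=True)],
        )
        thermo = ThermoData(
            transport={"T_H": [TransportedSpecies("H", 0.0, 1.0, "ext", "cyt")]}
        )
        expected = RT * math.log(10.0) * (5.0 - 6.5)
        assert transport_delta_g("T_H", thermo, model) == pytest.approx(expected)
        assert expected == pytest.approx(-8.56, abs=0.01)

    def test_charge_across_membrane_potential(self, toy6):
        thermo = ThermoData(
            transport={"T_A": [TransportedSpecies("A", 1.0, 0.0, "ext", "cyt")]},
            membrane_potential={("ext", "cyt"): 100.0},
        )
        assert transport_delta_g("T_A", thermo, toy6.model) == pytest.approx(
            FARADAY * 0.1
        )
        assert FARADAY * 0.1 == pytest.approx(9.65, abs=0.01)

    def test_missing_charge_annotation_rejected(self, toy6):
        thermo = ThermoData(
            transport={"T_A": [TransportedSpecies("A", None, 0.0, "ext", "cyt")]}
        )
        with pytest.raises(ConfigurationError):
            transport_delta_g("T_A", thermo, toy6.model)


class TestTransformFormationEnergy:
    def test_identity_when_all_corrections_vanish(self):
        assert transform_formation_energy(-100.0, 0, 0, 7.0, 0.0) == -100.0

    def test_proton_term(self):
        out = transform_formation_energy(0.0, 1, 0, 7.0, 0.0)
        assert out == pytest.approx(RT * math.log(10.0) * 7.0)
        assert out == pytest.approx(39.96, abs=0.01)

    def test_ionic_strength_isolated_in_debye_hueckel_term(self):
        at_zero = transform_formation_energy(0.0, 2, -1, 7.0, 0.0)
        at_150 = transform_formation_energy(0.0, 2, -1, 7.0, 0.15)
        sqrt_i = math.sqrt(0.15)
        dh = RT * 1.17582 * ((-1) ** 2 - 2) * sqrt_i / (1 + 1.6 * sqrt_i)
        assert at_150 - at_zero == pytest.approx(-dh)


class TestDeriveDirectionConstraints:
    def test_cycle_closure_forces_direction(self, toy6):
        """With R2 and R3 always active forward and c_B's lower bound relaxed
        so that pair is feasible on its own, running R1 backward closes a
        thermodynamic cycle (sum of dG' = 0 around A->C->B->A) and is
        infeasible; the derivation pins R1 forward."""
        relaxed = ConcentrationSet(
            species_bounds_mm={"A": (0.001, 1.0), "B": (0.001, 10.0), "C": (0.001, 10.0)}
        )
        # precondition: the base pattern alone is feasible under relaxed bounds
        assert grid_feasibility(toy6.model, {"R2": 1, "R3": 1}, relaxed, toy6.thermo)
        always = DirectionConstraintSet()
        always.set("R2", DirectionClass.ALWAYS_FORWARD, "FVA")
        always.set("R3", DirectionClass.ALWAYS_FORWARD, "FVA")
        derived = derive_direction_constraints(toy6.model, always, relaxed, toy6.thermo)
        assert derived.entries == {"R1": DirectionClass.FORWARD_ONLY}
        assert derived.provenance["R1"] == "NET"

    def test_unconstrained_concentrations_yield_nothing(self, toy6):
        huge = ConcentrationSet(default_bounds_mm=(1e-9, 1e9))
        derived = derive_direction_constraints(
            toy6.model, DirectionConstraintSet(), huge, toy6.thermo
        )
        assert len(derived) == 0
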