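"""EFM enumeration: completeness, elementarity, cycle removal,
normalization."""

import copy
from fractions import Fraction

import numpy as np
import pytest

from thermoefm.efm import (
    EFM,
    enumerate_efms,
    normalize_to_substrate,
    remove_internal_cycles,
)
from thermoefm.errors import CapacityError
from thermoefm.fixtures import make_random_network
from thermoefm.model_io import (
    Compartment,
    MetabolicModel,
    Metabolite,
    Reaction,
)


def sign_sets(efms):
    return {frozenset(e.sign_pattern().items()) for e in efms}


class TestEnumeration:
    def test_toy6_three_modes(self, toy6):
        es = enumerate_efms(toy6.model)
        assert len(es) == 3
        assert sign_sets(es) == {
            frozenset(p.items()) for p in toy6.expected_sign_patterns
        }

    def test_matches_brute_force_on_random_networks(self, random_net):
        es = enumerate_efms(random_net.model)
        assert sign_sets(es) == {
            frozenset(p.items()) for p in random_net.expected_sign_patterns
        }

    def test_single_linear_chain(self):
        model = MetabolicModel(
            metabolites={
                "A": Metabolite("A", "c"),
                "B": Metabolite("B", "c"),
                "C": Metabolite("C", "c"),
            },
            compartments={"c": Compartment("c")},
            reactions=[
                Reaction("T_in", {"A": 1.0}, reversible=False),
                Reaction("R_ab", {"A": -1.0, "B": 1.0}, reversible=False),
                Reaction("R_bc", {"B": -1.0, "C": 1.0}, reversible=False),
                Reaction("T_out", {"C": -1.0}, reversible=False),
            ],
            substrate_id="T_in",
        )
        es = enumerate_efms(model)
        assert len(es) == 1
        assert es.efms[0].support == {"T_in", "R_ab", "R_bc", "T_out"}

    def test_every_mode_exactly_balanced(self, toy6, random_net):
        for fx in (toy6, random_net):
            S, _, rxn_ids = fx.model.stoichiometric_matrix()
            for e in enumerate_efms(fx.model):
                v = e.vector(fx.model)
                assert np.allclose(S @ v, 0.0, atol=1e-9)
                # exact rational balance as well
                for i in range(S.shape[0]):
                    total = sum(
                        Fraction(S[i, j]).limit_denominator(10**9) * e[rxn_ids[j]]
                        for j in range(len(rxn_ids))
                    )
                    assert total == 0

    def test_irreversible_entries_nonnegative(self, random_net):
        for e in enumerate_efms(random_net.model):
            for rid, coeff in e.coefficients.items():
                rxn = random_net.model.reaction(rid)
                if rxn.lower_bound >= 0:
                    assert coeff > 0

    def test_elementarity_nullity_one(self, toy6, random_net):
        import sympy

        for fx in (toy6, random_net):
            S, _, rxn_ids = fx.model.stoichiometric_matrix()
            for e in enumerate_efms(fx.model):
                idx = [rxn_ids.index(r) for r in e.support]
                sub = sympy.Matrix(S)[:, idx]
                assert len(sub.nullspace()) == 1

    def test_supports_invariant_to_row_scaling(self, toy6):
        scaled = copy.copy(toy6.model)
        # double every coefficient of species A (scales one row of S)
        scaled.reactions = [
            Reaction(
                r.id,
                {m: (2.0 * c if m == "A" else c) for m, c in r.stoichiometry.items()},
                reversible=r.reversible,
                flux_cap=r.flux_cap,
            )
            for r in toy6.model.reactions
        ]
        assert {frozenset(e.support) for e in enumerate_efms(scaled)} == {
            frozenset(e.support) for e in enumerate_efms(toy6.model)
        }

    def test_mode_cap_raises_capacity_error(self, toy6):
        with pytest.raises(CapacityError):
            enumerate_efms(toy6.model, max_modes=1)

    def test_vertex_coverage_of_normalized_polytope(self, toy6):
        """Every vertex of {S v = 0, direction bounds, v_substrate = 1}
        coincides with a substrate-normalized EFM (checked by LP optimality
        over random objectives on a cycle-free model)."""
        from scipy.optimize import linprog

        model = copy.copy(toy6.model)
        model.reactions = [  # pin R1 forward: no internal cycle
            Reaction(r.id, r.stoichiometry, reversible=False, flux_cap=r.flux_cap)
            for r in toy6.model.reactions
        ]
        S, _, rxn_ids = model.stoichiometric_matrix()
        sub_j = model.reaction_index("T_A")
        bounds = [list(b) for b in model.bounds()]
        bounds[sub_j] = [1.0, 1.0]
        normalized = {
            tuple(
                round(float(normalize_to_substrate(e, "T_A")[r]), 9) for r in rxn_ids
            )
            for e in enumerate_efms(model)
        }
        rng = np.random.default_rng(7)
        for _ in range(20):
            c = rng.normal(size=len(rxn_ids))
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
            assert res.status == 0
            vertex = tuple(round(float(x), 9) for x in res.x)
            assert vertex in normalized


class TestCycleRemoval:
    def test_toy6_cycle_removed(self, toy6):
        es = enumerate_efms(toy6.model)
        kept = remove_internal_cycles(es, "T_A")
        assert len(kept) == 2
        assert all(e["T_A"] != 0 for e in kept)

    def test_no_cycles_identity(self, toy6):
        es = remove_internal_cycles(enumerate_efms(toy6.model), "T_A")
        again = remove_internal_cycles(es, "T_A")
        assert sign_sets(again) == sign_sets(es)

    def test_only_cycles_empty(self):
        # A closed loop with no exchange at all
        model = MetabolicModel(
            metabolites={"A": Metabolite("A", "c"), "B": Metabolite("B", "c")},
            compartments={"c": Compartment("c")},
            reactions=[
                Reaction("F", {"A": -1.0, "B": 1.0}, reversible=False),
                Reaction("G", {"B": -1.0, "A": 1.0}, reversible=False),
                Reaction("T", {"A": -1.0}, reversible=False),
            ],
            substrate_id="T",
        )
        es = enumerate_efms(model)
        # T cannot run (nothing feeds A), so all modes are the internal loop
        assert len(remove_internal_cycles(es, "T")) == 0


class TestNormalization:
    def test_scalar_division(self):
        e = EFM(coefficients={"S": Fraction(2), "R": Fraction(5)})
        n = normalize_to_substrate(e, "S")
        assert n["S"] == 1 and n["R"] == Fraction(5, 2)

    def test_idempotent(self, toy6):
        es = remove_internal_cycles(enumerate_efms(toy6.model), "T_A")
        for e in es:
            once = normalize_to_substrate(e, "T_A")
            assert normalize_to_substrate(once, "T_A").coefficients == once.coefficients

    def test_unit_chain_mode_all_ones(self, toy6):
        es = remove_internal_cycles(enumerate_efms(toy6.model), "T_A")
        chain = next(e for e in es if "R2" in e.support)
        n = normalize_to_substrate(chain, "T_A")
        assert all(v == 1 for v in n.coefficients.values())

    def test_zero_substrate_rejected(self, toy6):
        cycle = next(
            e for e in enumerate_efms(toy6.model) if e["T_A"] == 0
        )
        with pytest.raises(ZeroDivisionError):
            normalize_to_substrate(cycle, "T_A")
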