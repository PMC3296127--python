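"""Deterministic toy networks with planted thermodynamic structure, plus the
independent oracles used to verify every downstream module.

Two oracles live here and are deliberately implementation-free:

* :func:`brute_force_efms` enumerates elementary modes by testing every
  support subset with an exact rank/kernel criterion (a support T carries an
  EFM iff S restricted to T has nullity one and the kernel vector can be
  signed consistently with the irreversibilities while covering all of T).
* :func:`grid_feasibility` decides thermodynamic feasibility of an activity
  pattern by exhaustive search over a log-concentration grid (50 points per
  decade by default); it is meant for problems with at most ~6 free species.

The canonical fixture TOY6 is a miniature of the two-route-plus-cycle
topology that drives the full analysis: one route is exergonic, the parallel
two-step route is blocked because its two positive standard Gibbs energies
cannot both be overcome within the concentration bounds, and reversing the
first route against the second closes an internal cycle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import sympy

from .errors import ValidationError
from .model_io import Compartment, MetabolicModel, Metabolite, Reaction
from .thermo import (
    C_REF_MM,
    ActivityPattern,
    ConcentrationSet,
    ThermoData,
    transport_delta_g,
)

GRID_POINTS_PER_DECADE = 50


@dataclass
class ToyFixture:
    """A model bundled with thermodynamic data and oracle-verified
    expectations."""

    model: MetabolicModel
    thermo: ThermoData
    conc: ConcentrationSet
    expected_sign_patterns: list[dict[str, int]]  # one per EFM, oracle-computed
    expected_labels: dict[frozenset, str] | None = None  # sign-pattern -> label
    expected_patterns: list[dict[str, int]] = field(default_factory=list)

    @property
    def expected_supports(self) -> set[frozenset]:
        return {frozenset(p) for p in self.expected_sign_patterns}


# ---------------------------------------------------------------------------
# Oracle 1: brute-force EFM enumeration over support subsets
# ---------------------------------------------------------------------------


def brute_force_efms(model: MetabolicModel) -> list[dict[str, int]]:
    """All EFM sign patterns by exhaustive support-subset enumeration.

    Exact (rational) linear algebra; exponential in the reaction count, so
    restricted to fixtures (documented for <= 20 reactions).
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    S_rat = sympy.Matrix([[sympy.Rational(x).limit_denominator(10**9) for x in row] for row in S])
    n = len(rxn_ids)
    active = [j for j in range(n) if model.reactions[j].upper_bound > 0 or model.reactions[j].lower_bound < 0]
    out: list[dict[str, int]] = []
    for size in range(1, len(active) + 1):
        for T in itertools.combinations(active, size):
            sub = S_rat[:, list(T)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            k = null[0]
            if any(k[i] == 0 for i in range(size)):
                continue  # support smaller than T; counted at its own size
            valid_signs = []
            for s in (1, -1):
                ok = True
                for i, j in enumerate(T):
                    rxn = model.reactions[j]
                    if s * k[i] > 0 and rxn.upper_bound <= 0:
                        ok = False
                        break
                    if s * k[i] < 0 and rxn.lower_bound >= 0:
                        ok = False
                        break
                if ok:
                    valid_signs.append(s)
            if not valid_signs:
                continue
            if len(valid_signs) == 2:
                # fully reversible support: canonical direction only
                first = min(range(size), key=lambda i: rxn_ids[T[i]])
                valid_signs = [1 if k[first] > 0 else -1]
            s = valid_signs[0]
            out.append(
                {rxn_ids[j]: (1 if s * k[i] > 0 else -1) for i, j in enumerate(T)}
            )
    return out


# ---------------------------------------------------------------------------
# Oracle 2: grid search over log-concentrations
# ---------------------------------------------------------------------------


def grid_feasibility(
    model: MetabolicModel,
    pattern: ActivityPattern | dict[str, int],
    conc: ConcentrationSet,
    thermo: ThermoData,
    points_per_decade: int = GRID_POINTS_PER_DECADE,
) -> dict[str, float] | None:
    """Exhaustive feasibility check: returns a witness concentration vector
    (mM) if some grid point satisfies every sign constraint and pool
    constraint strictly, else None.

    Grid resolution is ``points_per_decade`` per log10 decade per species;
    this is the oracle's documented precision.  Intended for <= 6 species.
    """
    pattern = dict(pattern)
    species: list[str] = []
    for rid in pattern:
        for sid in model.reaction(rid).stoichiometry:
            if sid not in species and sid not in thermo.excluded_species:
                species.append(sid)
    pools = {
        pid: pool
        for pid, pool in conc.pools.items()
        if any(m in species for m in pool.members)
    }
    for pool in pools.values():
        for m in pool.members:
            if m not in species:
                species.append(m)
    if not species:
        return {}

    axes = []
    for sid in species:
        lo, hi = conc.bounds_for(sid)
        decades = np.log10(hi) - np.log10(lo)
        npts = max(2, int(round(decades * points_per_decade)) + 1)
        axes.append(np.log(np.logspace(np.log10(lo), np.log10(hi), npts) / C_REF_MM))

    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    mask = np.ones((), dtype=bool)
    rt = thermo.rt
    for rid, sigma in pattern.items():
        rxn = model.reaction(rid)
        dg = thermo.dg0_prime.get(rid, 0.0) + transport_delta_g(rid, thermo, model)
        expr = np.zeros(())
        for sid, coeff in rxn.stoichiometry.items():
            if sid in species:
                expr = expr + coeff * grids[species.index(sid)]
        mask = mask & (sigma * (dg + rt * expr) < 0)
    for pool in pools.values():
        total = np.zeros(())
        for m in pool.members:
            f = model.compartments[model.metabolites[m].compartment].volume_fraction
            total = total + f * np.exp(grids[species.index(m)]) * C_REF_MM
        mask = mask & (total >= pool.bounds_mm[0]) & (total <= pool.bounds_mm[1])

    mask = np.broadcast_to(mask, tuple(len(a) for a in axes))
    hits = np.argwhere(mask)
    if hits.size == 0:
        return None
    idx = hits[0]
    return {
        sid: float(np.exp(axes[d][idx[d]]) * C_REF_MM) for d, sid in enumerate(species)
    }


def check_witness(
    model: MetabolicModel,
    pattern: ActivityPattern | dict[str, int],
    witness_mm: dict[str, float],
    conc: ConcentrationSet,
    thermo: ThermoData,
    tol: float = 1e-7,
) -> bool:
    """Verify a claimed witness against the exact constraints."""
    rt = thermo.rt
    for rid, sigma in dict(pattern).items():
        rxn = model.reaction(rid)
        dg = thermo.dg0_prime.get(rid, 0.0) + transport_delta_g(rid, thermo, model)
        for sid, coeff in rxn.stoichiometry.items():
            if sid in witness_mm:
                dg += rt * coeff * np.log(witness_mm[sid] / C_REF_MM)
        if sigma * dg >= 0:
            return False
    for sid, c in witness_mm.items():
        lo, hi = conc.bounds_for(sid)
        pooled = any(sid in p.members for p in conc.pools.values())
        if not pooled and not (lo * (1 - tol) <= c <= hi * (1 + tol)):
            return False
    for pool in conc.pools.values():
        if not all(m in witness_mm for m in pool.members):
            continue
        total = sum(
            model.compartments[model.metabolites[m].compartment].volume_fraction
            * witness_mm[m]
            for m in pool.members
        )
        if not (pool.bounds_mm[0] * (1 - tol) <= total <= pool.bounds_mm[1] * (1 + tol)):
            return False
    return True


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def make_toy6() -> ToyFixture:
    """The canonical 5-reaction fixture.

    Metabolites Aext, A, B, C, Bext; reactions T_A: Aext->A (irreversible,
    substrate), R1: A<->B, R2: A->C, R3: C->B, T_B: B->Bext.  Standard
    energies (kJ/mol): R1 = -10, R2 = +5, R3 = +5; transporters
    thermodynamically unconstrained.  Concentration bounds (mM):
    A [0.001, 1], B [1, 10], C [0.001, 10].

    The joint forward activity of R2 and R3 needs
    c_B < c_A * exp(-10/RT), i.e. c_B/c_A < 0.018, while the bounds force
    c_B/c_A >= 1 — the planted infeasibility.
    """
    comp = {"ext": Compartment(id="ext", ph=7.0), "cyt": Compartment(id="cyt", ph=7.0)}
    mets = {
        "Aext": Metabolite("Aext", "ext", boundary=True),
        "A": Metabolite("A", "cyt"),
        "B": Metabolite("B", "cyt"),
        "C": Metabolite("C", "cyt"),
        "Bext": Metabolite("Bext", "ext", boundary=True),
    }
    rxns = [
        Reaction("T_A", {"Aext": -1.0, "A": 1.0}, reversible=False),
        Reaction("R1", {"A": -1.0, "B": 1.0}, reversible=True),
        Reaction("R2", {"A": -1.0, "C": 1.0}, reversible=False),
        Reaction("R3", {"C": -1.0, "B": 1.0}, reversible=False),
        Reaction("T_B", {"B": -1.0, "Bext": 1.0}, reversible=False),
    ]
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        compartments=comp,
        exchange_ids=frozenset({"T_A", "T_B"}),
        substrate_id="T_A",
    )
    thermo = ThermoData(dg0_prime={"R1": -10.0, "R2": 5.0, "R3": 5.0})
    conc = ConcentrationSet(
        species_bounds_mm={"A": (0.001, 1.0), "B": (1.0, 10.0), "C": (0.001, 10.0)}
    )

    expected = brute_force_efms(model)
    labels: dict[frozenset, str] = {}
    for pat in expected:
        if pat.get("T_A", 0) == 0:
            continue  # internal cycle, removed before classification
        constrained = {r: s for r, s in pat.items() if thermo.is_constrained(r)}
        witness = grid_feasibility(model, constrained, conc, thermo)
        labels[frozenset(pat.items())] = "feasible" if witness is not None else "infeasible"

    return ToyFixture(
        model=model,
        thermo=thermo,
        conc=conc,
        expected_sign_patterns=expected,
        expected_labels=labels,
        expected_patterns=[{"R2": 1, "R3": 1}],
    )


@lru_cache(maxsize=64)
def make_random_network(
    n_mets: int, n_rxns: int, seed: int, acyclic: bool = False
) -> ToyFixture:
    """A connected random network with one substrate uptake and at least one
    secretion; expected EFMs come from the brute-force oracle.

    The same seed always yields the identical fixture.  Enumerable size only
    (n_rxns <= 20 documented).  Thermodynamic data: every internal reaction
    gets a random standard energy in [-15, 15] kJ/mol; species bounds are
    [0.1, 10] mM so the grid oracle stays tractable; expected feasibility
    labels are stored only when at most 6 species are involved.

    With ``acyclic=True`` every reaction is irreversible and oriented along
    the chain ordering, so the network is a DAG and has no internal cycles
    (needed where LP flux bounds must coincide with EFM extremes).
    """
    if n_mets < 2 or n_rxns < n_mets:
        raise ValidationError("need n_rxns >= n_mets >= 2")
    if n_rxns < n_mets + 1:
        raise ValidationError("too few reactions to form an uptake-to-secretion path")
    rng = np.random.default_rng(seed)

    comp = {"cyt": Compartment(id="cyt")}
    met_ids = [f"M{i}" for i in range(1, n_mets + 1)]
    mets = {m: Metabolite(m, "cyt") for m in met_ids}

    rxns: list[Reaction] = [Reaction("T_in", {met_ids[0]: 1.0}, reversible=False)]
    for i in range(n_mets - 1):
        rev = (not acyclic) and bool(rng.random() < 0.4)
        rxns.append(
            Reaction(f"R{i + 1}", {met_ids[i]: -1.0, met_ids[i + 1]: 1.0}, reversible=rev)
        )
    rxns.append(Reaction("T_out", {met_ids[-1]: -1.0}, reversible=False))
    extra = n_rxns - len(rxns)
    for k in range(extra):
        a, b = sorted(rng.choice(n_mets, size=2, replace=False))
        if not acyclic and rng.random() < 0.5:
            a, b = b, a
        rev = (not acyclic) and bool(rng.random() < 0.4)
        rxns.append(
            Reaction(f"X{k + 1}", {met_ids[a]: -1.0, met_ids[b]: 1.0}, reversible=rev)
        )

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        compartments=comp,
        exchange_ids=frozenset({"T_in", "T_out"}),
        substrate_id="T_in",
    )
    internal = [r.id for r in rxns if r.id not in ("T_in", "T_out")]
    thermo = ThermoData(
        dg0_prime={rid: float(rng.uniform(-15, 15)) for rid in internal}
    )
    conc = ConcentrationSet(
        species_bounds_mm={m: (0.1, 10.0) for m in met_ids},
        default_bounds_mm=(0.1, 10.0),
    )

    expected = brute_force_efms(model)
    labels = None
    # The grid oracle's memory grows as points^n_species (101 points per
    # 2-decade box); store labels only where that stays ~1e8 cells.
    if n_mets <= 4:
        labels = {}
        for pat in expected:
            if pat.get("T_in", 0) == 0:
                continue
            constrained = {r: s for r, s in pat.items() if thermo.is_constrained(r)}
            witness = grid_feasibility(model, constrained, conc, thermo)
            labels[frozenset(pat.items())] = (
                "feasible" if witness is not None else "infeasible"
            )
    return ToyFixture(
        model=model,
        thermo=thermo,
        conc=conc,
        expected_sign_patterns=expected,
        expected_labels=labels,
    )
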