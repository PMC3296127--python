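"""Compartmentalized stoichiometric models: containers, SBML I/O, and
condition-specific direction constraints.

The model container is deliberately small: a list of metabolites with
compartment assignments, reactions as signed stoichiometry maps (negative for
substrates, positive for products; the forward direction is the written
direction), per-compartment physical parameters, and bookkeeping for exchange
reactions and the designated substrate (glucose-uptake) reaction.

Fluxes are in mmol gDW^-1 h^-1 throughout.  Reactions without an explicit cap
are bounded at ``DEFAULT_FLUX_CAP`` so that flux variability analysis is
always a bounded LP.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConflictError, FormatError, ValidationError

DEFAULT_FLUX_CAP = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    boundary: bool = False  # SBML boundaryCondition: excluded from mass balance


@dataclass(frozen=True)
class Compartment:
    id: str
    volume_fraction: float = 1.0  # fraction of total cell volume, in (0, 1]
    ph: float = 7.0
    ionic_strength: float = 0.15  # M

    def __post_init__(self):
        if not (0.0 < self.volume_fraction <= 1.0):
            raise ValidationError(
                f"compartment {self.id!r}: volume fraction must be in (0, 1], "
                f"got {self.volume_fraction}"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = substrate, positive =
    product; the forward flux direction is the written direction).

    Bounds default to [-cap, cap] for reversible and [0, cap] for
    irreversible reactions; explicit ``lb``/``ub`` overrides encode
    condition-specific narrowing (backward-only: [-cap, 0]; inactive:
    [0, 0]) without touching the stoichiometry, so the sign convention of
    standard Gibbs energies is preserved.
    """

    id: str
    stoichiometry: dict[str, float]  # metabolite id -> signed coefficient
    reversible: bool
    flux_cap: float = DEFAULT_FLUX_CAP
    lb: float | None = None
    ub: float | None = None

    def __post_init__(self):
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValidationError(f"reaction {self.id!r}: zero stoichiometric coefficient")
        if self.flux_cap <= 0:
            raise ValidationError(f"reaction {self.id!r}: flux cap must be positive")
        if self.lb is not None and self.ub is not None and self.lb > self.ub:
            raise ValidationError(f"reaction {self.id!r}: lb > ub")

    @property
    def lower_bound(self) -> float:
        if self.lb is not None:
            return self.lb
        return -self.flux_cap if self.reversible else 0.0

    @property
    def upper_bound(self) -> float:
        if self.ub is not None:
            return self.ub
        return self.flux_cap


class DirectionClass(enum.Enum):
    FORWARD_ONLY = "forward_only"
    BACKWARD_ONLY = "backward_only"
    REVERSIBLE = "reversible"
    INACTIVE = "inactive"
    ALWAYS_FORWARD = "always_forward"
    ALWAYS_BACKWARD = "always_backward"

    @property
    def is_forward(self) -> bool:
        return self in (DirectionClass.FORWARD_ONLY, DirectionClass.ALWAYS_FORWARD)

    @property
    def is_backward(self) -> bool:
        return self in (DirectionClass.BACKWARD_ONLY, DirectionClass.ALWAYS_BACKWARD)

    @property
    def is_always_active(self) -> bool:
        return self in (DirectionClass.ALWAYS_FORWARD, DirectionClass.ALWAYS_BACKWARD)


@dataclass
class DirectionConstraintSet:
    """Map reaction id -> direction class, with per-entry provenance.

    Provenance records at which analysis stage a constraint was introduced:
    ``"model"`` (reversibility as written), ``"FVA"`` (flux variability
    analysis) or ``"NET"`` (thermodynamic direction derivation).
    """

    entries: dict[str, DirectionClass] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, reaction_id: str, cls: DirectionClass, provenance: str) -> None:
        self.entries[reaction_id] = cls
        self.provenance[reaction_id] = provenance

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.entries

    def items(self):
        return self.entries.items()

    def always_active(self) -> dict[str, int]:
        """Signs (+1/-1) of the reactions active in every flux distribution."""
        out = {}
        for rid, cls in self.entries.items():
            if cls is DirectionClass.ALWAYS_FORWARD:
                out[rid] = +1
            elif cls is DirectionClass.ALWAYS_BACKWARD:
                out[rid] = -1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": list(self.entries),
                "class": [c.value for c in self.entries.values()],
                "provenance": [self.provenance.get(r, "") for r in self.entries],
            }
        )


@dataclass
class PhysiologyData:
    """Measured exchange-rate intervals [lo, hi] per exchange reaction.

    Exact measurements are represented as zero-width intervals.  The growth
    rate (h^-1) is carried alongside when a biomass reaction is constrained.
    """

    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    growth_rate: tuple[float, float] | None = None

    def __post_init__(self):
        for rid, (lo, hi) in self.rates.items():
            if lo > hi:
                raise ValidationError(f"physiology for {rid!r}: lo {lo} > hi {hi}")
        if self.growth_rate is not None and self.growth_rate[0] > self.growth_rate[1]:
            raise ValidationError("growth rate interval: lo > hi")


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    compartments: dict[str, Compartment]
    exchange_ids: frozenset[str] = frozenset()
    substrate_id: str | None = None

    def __post_init__(self):
        if not self.reactions:
            raise ValidationError("model has zero reactions")
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown species {met!r}"
                    )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ValidationError(
                    f"species {met.id!r} in undeclared compartment {met.compartment!r}"
                )
        if self.substrate_id is not None and self.substrate_id not in seen:
            raise ValidationError(f"substrate reaction {self.substrate_id!r} not in model")

    # -- indexing helpers -------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise ValidationError(f"unknown reaction {reaction_id!r}")

    def reaction_index(self, reaction_id: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == reaction_id:
                return i
        raise ValidationError(f"unknown reaction {reaction_id!r}")

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.boundary]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S over mass-balanced (non-boundary) species.

        Returns (S, metabolite ids, reaction ids) with S[i, j] the signed
        coefficient of species i in reaction j.
        """
        met_ids = self.internal_metabolite_ids
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                if met in met_index:
                    S[met_index[met], j] = coeff
        return S, met_ids, self.reaction_ids

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def fingerprint(self) -> str:
        """Stable hash of stoichiometry, reversibility and bounds."""
        import hashlib

        h = hashlib.sha256()
        for rxn in sorted(self.reactions, key=lambda r: r.id):
            h.update(rxn.id.encode())
            h.update(repr(sorted(rxn.stoichiometry.items())).encode())
            h.update(repr((rxn.reversible, rxn.flux_cap)).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------


def _detect_exchanges(metabolites: dict[str, Metabolite], reactions: list[Reaction]) -> frozenset[str]:
    # Exchange reactions touch a boundary species, or have one-sided
    # stoichiometry (pure source/sink as written).
    out = set()
    for rxn in reactions:
        coeffs = list(rxn.stoichiometry.values())
        one_sided = all(c < 0 for c in coeffs) or all(c > 0 for c in coeffs)
        touches_boundary = any(metabolites[m].boundary for m in rxn.stoichiometry)
        if one_sided or touches_boundary:
            out.add(rxn.id)
    return frozenset(out)


def read_sbml(path: str, substrate_id: str | None = None) -> MetabolicModel:
    """Read an SBML Level 2/3 model.

    Reversibility is taken from the SBML ``reversible`` attribute.  Species
    flagged ``boundaryCondition`` are excluded from mass balance.  Compartment
    volume fractions / pH / ionic strength are not part of SBML core and
    default to 1.0 / 7.0 / 0.15 M; override via :class:`Compartment` after
    reading or through the pipeline configuration.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"SBML parse failure in {path}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no model element")

    compartments = {}
    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        compartments[c.getId()] = Compartment(id=c.getId())
    if not compartments:
        compartments["default"] = Compartment(id="default")

    metabolites = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        comp = s.getCompartment() or next(iter(compartments))
        metabolites[s.getId()] = Metabolite(
            id=s.getId(), compartment=comp, boundary=bool(s.getBoundaryCondition())
        )

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        for m in stoich:
            if m not in metabolites:
                raise ValidationError(f"reaction {r.getId()!r} references unknown species {m!r}")
        reversible = r.getReversible() if r.isSetReversible() else True
        reactions.append(Reaction(id=r.getId(), stoichiometry=stoich, reversible=bool(reversible)))

    if not reactions:
        raise ValidationError(f"{path}: model has zero reactions")

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        exchange_ids=_detect_exchanges(metabolites, reactions),
        substrate_id=substrate_id,
    )


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 Version 1 (roundtrips with read_sbml)."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId("model")
    for comp in model.compartments.values():
        c = m.createCompartment()
        c.setId(comp.id)
        c.setConstant(True)
    for met in model.metabolites.values():
        s = m.createSpecies()
        s.setId(met.id)
        s.setCompartment(met.compartment)
        s.setBoundaryCondition(met.boundary)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
    for rxn in model.reactions:
        r = m.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                sr = r.createReactant()
                sr.setSpecies(met)
                sr.setStoichiometry(-coeff)
            else:
                sr = r.createProduct()
                sr.setSpecies(met)
                sr.setStoichiometry(coeff)
            sr.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Direction constraints
# ---------------------------------------------------------------------------


def apply_direction_constraints(
    model: MetabolicModel, constraints: DirectionConstraintSet
) -> MetabolicModel:
    """Return a copy of the model with reversibility/bounds narrowed.

    ``forward_only``/``always_forward`` restrict flux to [0, cap];
    ``backward_only``/``always_backward`` to [-cap, 0]; ``inactive`` removes
    flux capacity entirely ([0, 0]).  Stoichiometry is never rewritten, so
    the written direction of every reaction (and with it the sign convention
    of standard Gibbs energies) is preserved.  The input model is not
    modified.  Contradictory narrowing (forward_only on a reaction with no
    forward capacity, or vice versa) raises :class:`ConflictError`.
    """
    new_reactions = []
    for rxn in model.reactions:
        if rxn.id not in constraints:
            new_reactions.append(rxn)
            continue
        cls = constraints.entries[rxn.id]
        if cls is DirectionClass.REVERSIBLE:
            new_reactions.append(rxn)
        elif cls.is_forward:
            if rxn.upper_bound <= 0:
                raise ConflictError(
                    f"{rxn.id}: forward_only conflicts with existing backward-only direction"
                )
            new_reactions.append(replace(rxn, reversible=False, lb=0.0, ub=rxn.upper_bound))
        elif cls.is_backward:
            if rxn.lower_bound >= 0:
                raise ConflictError(
                    f"{rxn.id}: backward_only conflicts with existing forward-only direction"
                )
            new_reactions.append(replace(rxn, lb=rxn.lower_bound, ub=0.0))
        elif cls is DirectionClass.INACTIVE:
            new_reactions.append(replace(rxn, reversible=False, lb=0.0, ub=0.0))
        else:  # pragma: no cover
            raise ConflictError(f"unhandled direction class {cls}")
    out = copy.copy(model)
    out.reactions = new_reactions
    return out


# ---------------------------------------------------------------------------
# Tabular condition data
# ---------------------------------------------------------------------------


def read_physiology_tsv(path: str) -> PhysiologyData:
    """TSV with columns reaction_id, lo, hi (mmol gDW^-1 h^-1)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"reaction_id", "lo", "hi"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rates = {
        str(row.reaction_id): (float(row.lo), float(row.hi)) for row in df.itertuples()
    }
    return PhysiologyData(rates=rates)


def read_direction_constraints_tsv(path: str) -> DirectionConstraintSet:
    """TSV with columns reaction_id, class, provenance."""
    df = pd.read_csv(path, sep="\t")
    missing = {"reaction_id", "class"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = DirectionConstraintSet()
    for _, row in df.iterrows():
        try:
            cls = DirectionClass(str(row["class"]))
        except ValueError as exc:
            raise FormatError(f"{path}: unknown direction class for {row['reaction_id']}") from exc
        out.set(str(row["reaction_id"]), cls, str(row.get("provenance", "model")))
    return out


def count_reversible(model: MetabolicModel) -> int:
    """Reactions with capacity in both directions."""
    return sum(1 for r in model.reactions if r.lower_bound < 0 < r.upper_bound)
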