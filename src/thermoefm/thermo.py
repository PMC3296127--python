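"""Network-embedded thermodynamic (NET) analysis.

Decides whether a set of reaction direction assignments (an *activity
pattern*) is compatible with quantitative metabolite concentration ranges.
A reaction carrying flux in direction sigma (+1 forward, -1 backward) must
have sigma * dG' < 0 with

    dG' = dG0' + dG_transport + RT * sum_j s_ij * ln(c_j / c_ref)

where dG0' is the standard transformed Gibbs energy at the compartment's pH
and ionic strength, and the transport term collects the concentration-
independent membrane contributions (charge translocation across the membrane
potential, the chemical part of proton translocation between compartments of
different pH).

In log-concentration space x = ln c these sign constraints are linear.
Species bounds are boxes in x.  Metabolites measured as cell averages but
present in several compartments are constrained as volume-weighted pools,
sum_k f_k * c_k in [c_min, c_max] with f_k the compartment volume fractions:
the upper bound is convex in x, the lower bound is not.  Feasibility is
decided by branch and bound on the pooled variables with linear outer
approximations (tangents under exp for the upper bound, chords over exp for
the lower bound), so an *infeasible* verdict is always certified by an
infeasible linear relaxation — no truly feasible pattern is discarded.  If
the branching depth cap is reached the verdict is *undetermined*, which
downstream classification conservatively pools with feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import (
    ConfigurationError,
    ModelInconsistencyError,
    StateError,
    ValidationError,
)
from .model_io import DirectionClass, DirectionConstraintSet, MetabolicModel

R_GAS = 8.31446261815324e-3  # kJ mol^-1 K^-1
FARADAY = 96.485  # kJ mol^-1 V^-1
DEFAULT_TEMPERATURE = 298.15  # K
C_REF_MM = 1.0  # reference concentration for the ln term, in mM
STRICT_EPS = 1e-6  # sigma*dG' <= -eps operationalizes the strict inequality
DEFAULT_BOUNDS_MM = (1e-4, 120.0)  # default species concentration range, mM
_BNB_DEPTH_CAP = 20


@dataclass(frozen=True)
class TransportedSpecies:
    """One species moved across a membrane by a transport reaction."""

    species: str
    charge: float
    protons: float
    source: str  # compartment id
    dest: str


@dataclass
class ThermoData:
    """Reaction-level standard transformed Gibbs energies and compartment
    physical chemistry.

    Reactions absent from ``dg0_prime`` and ``transport`` are
    thermodynamically unconstrained (typical for transporters with unknown
    mechanism) and contribute no constraint to NET analysis.
    """

    dg0_prime: dict[str, float] = field(default_factory=dict)  # kJ/mol
    temperature: float = DEFAULT_TEMPERATURE  # K
    membrane_potential: dict[tuple[str, str], float] = field(default_factory=dict)  # mV, dest-minus-source
    transport: dict[str, list[TransportedSpecies]] = field(default_factory=dict)
    excluded_species: frozenset[str] = frozenset()  # protons/water: fixed by pH convention

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        for rid, dg in self.dg0_prime.items():
            if not math.isfinite(dg):
                raise ValidationError(f"non-finite dG0' for reaction {rid!r}")

    @property
    def rt(self) -> float:
        return R_GAS * self.temperature

    def is_constrained(self, reaction_id: str) -> bool:
        return reaction_id in self.dg0_prime or reaction_id in self.transport

    def delta_psi(self, source: str, dest: str) -> float:
        """Membrane potential (mV) of dest relative to source."""
        if (source, dest) in self.membrane_potential:
            return self.membrane_potential[(source, dest)]
        if (dest, source) in self.membrane_potential:
            return -self.membrane_potential[(dest, source)]
        return 0.0


@dataclass
class Pool:
    """A measured cell-average metabolite spanning several compartments."""

    members: list[str]  # compartment-specific species ids
    bounds_mm: tuple[float, float]


@dataclass
class ConcentrationSet:
    """Concentration bounds in mM: direct per-species bounds, volume-weighted
    pools for multi-compartment metabolites, and a default range for
    everything unmeasured."""

    species_bounds_mm: dict[str, tuple[float, float]] = field(default_factory=dict)
    pools: dict[str, Pool] = field(default_factory=dict)
    default_bounds_mm: tuple[float, float] = DEFAULT_BOUNDS_MM

    def __post_init__(self):
        for sid, (lo, hi) in self.species_bounds_mm.items():
            if not (0 < lo <= hi):
                raise ValidationError(f"bounds for {sid!r} must satisfy 0 < min <= max")
        for pid, pool in self.pools.items():
            lo, hi = pool.bounds_mm
            if not (0 < lo <= hi):
                raise ValidationError(f"pool {pid!r} bounds must satisfy 0 < min <= max")

    def bounds_for(self, species_id: str) -> tuple[float, float]:
        return self.species_bounds_mm.get(species_id, self.default_bounds_mm)


class ActivityPattern(dict):
    """Map reaction id -> direction sign in {-1, +1}.

    Reactions absent from the map are unconstrained.  Zero signs are never
    stored.
    """

    def __init__(self, signs: dict[str, int] | None = None):
        super().__init__()
        for rid, s in (signs or {}).items():
            if s not in (-1, 1):
                raise ValidationError(f"activity sign for {rid!r} must be -1 or +1, got {s}")
            self[rid] = int(s)

    @classmethod
    def from_flux(cls, flux: dict[str, float], tol: float = 1e-6) -> "ActivityPattern":
        return cls({rid: (1 if v > tol else -1) for rid, v in flux.items() if abs(v) > tol})

    def key(self) -> tuple[tuple[str, int], ...]:
        """Canonical hashable form (sorted (reaction, sign) tuples)."""
        return tuple(sorted(self.items()))


@dataclass
class NETResult:
    verdict: str  # feasible | infeasible | undetermined
    witness_mm: dict[str, float] | None = None  # concentrations, mM
    species_ranges_mm: dict[str, tuple[float, float]] | None = None
    dg_ranges: dict[str, tuple[float, float]] | None = None  # kJ/mol
    diagnostics: dict = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        """Conservative reading: undetermined counts as feasible."""
        return self.verdict in ("feasible", "undetermined")


# ---------------------------------------------------------------------------
# Transport and formation-energy helpers
# ---------------------------------------------------------------------------


def transport_delta_g(reaction_id: str, thermo: ThermoData, model: MetabolicModel) -> float:
    """Concentration-independent membrane contribution to dG' (kJ/mol).

    Per translocated charge: z * F * delta_psi.  Per translocated proton the
    chemical part of the gradient: RT * ln(10) * (pH_source - pH_dest).  The
    RT*ln(c_dest/c_src) part of transport is carried by the ordinary
    stoichiometric term and is not included here.
    """
    total = 0.0
    for ts in thermo.transport.get(reaction_id, []):
        if ts.charge is None:
            raise ConfigurationError(
                f"transport reaction {reaction_id!r}: missing charge for {ts.species!r}"
            )
        dpsi_v = thermo.delta_psi(ts.source, ts.dest) / 1000.0  # mV -> V
        total += ts.charge * FARADAY * dpsi_v
        if ts.protons:
            ph_src = model.compartments[ts.source].ph
            ph_dest = model.compartments[ts.dest].ph
            total += ts.protons * thermo.rt * math.log(10.0) * (ph_src - ph_dest)
    return total


def transform_formation_energy(
    dgf: float,
    n_h: float,
    charge: float,
    ph: float,
    ionic_strength: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Legendre-transformed, ionic-strength-corrected standard formation
    energy (kJ/mol), Alberty convention.

    dGf' = dGf + nH*RT*ln(10)*pH - RT*alpha*(z^2 - nH)*sqrt(I)/(1 + B*sqrt(I))

    with the extended Debye-Hueckel parameters alpha = 1.17582 kg^1/2 mol^-1/2
    and B = 1.6 kg^1/2 mol^-1/2.
    """
    if ionic_strength < 0:
        raise ValidationError("ionic strength must be >= 0")
    rt = R_GAS * temperature
    out = dgf + n_h * rt * math.log(10.0) * ph
    if ionic_strength > 0:
        sqrt_i = math.sqrt(ionic_strength)
        out -= rt * 1.17582 * (charge**2 - n_h) * sqrt_i / (1.0 + 1.6 * sqrt_i)
    return out


# ---------------------------------------------------------------------------
# Constraint-system assembly
# ---------------------------------------------------------------------------


class _NetSystem:
    """Linear(ized) constraint system in x = ln(c / c_ref).

    Holds the static sign constraints and species boxes; pool constraints are
    linearized per branch-and-bound node.
    """

    def __init__(
        self,
        model: MetabolicModel,
        pattern: ActivityPattern,
        conc: ConcentrationSet,
        thermo: ThermoData,
    ):
        self.model = model
        self.thermo = thermo
        self.conc = conc
        self.rt = thermo.rt

        for rid in pattern:
            model.reaction_index(rid)  # raises on unknown reaction
            if not thermo.is_constrained(rid):
                raise ConfigurationError(
                    f"reaction {rid!r} in pattern has no dG0' and no transport model"
                )

        # Species variables: every non-excluded species touched by a
        # constrained pattern reaction, plus all pool members.
        species: list[str] = []
        seen: set[str] = set()

        def add(sid: str) -> None:
            if sid not in seen and sid not in thermo.excluded_species:
                seen.add(sid)
                species.append(sid)

        self.pattern = ActivityPattern({r: s for r, s in pattern.items()})
        for rid in self.pattern:
            for sid in model.reaction(rid).stoichiometry:
                add(sid)
        self.active_pools = {}
        for pid, pool in conc.pools.items():
            if any(m in seen for m in pool.members):
                self.active_pools[pid] = pool
                for m in pool.members:
                    add(m)
        self.species = species
        self.index = {s: i for i, s in enumerate(species)}
        self.n = len(species)

        # Static boxes in x (mM converted to units of c_ref).
        self.x_lo = np.empty(self.n)
        self.x_hi = np.empty(self.n)
        pooled = {m for p in self.active_pools.values() for m in p.members}
        for i, sid in enumerate(species):
            if sid in pooled and sid not in conc.species_bounds_mm:
                # Pool members default to the widest box consistent with the
                # pool total: c_k <= c_max / f_k (relaxed further below).
                lo_mm, hi_mm = 1e-12, max(
                    p.bounds_mm[1] for p in self.active_pools.values() if sid in p.members
                )
                f = model.compartments[model.metabolites[sid].compartment].volume_fraction
                hi_mm = hi_mm / f
            else:
                lo_mm, hi_mm = conc.bounds_for(sid)
            self.x_lo[i] = math.log(lo_mm / C_REF_MM)
            self.x_hi[i] = math.log(hi_mm / C_REF_MM)

        # Sign constraints: rows a, rhs b with a.x <= b.
        rows, rhs, labels = [], [], []
        for rid, sigma in self.pattern.items():
            rxn = model.reaction(rid)
            a = np.zeros(self.n)
            for sid, coeff in rxn.stoichiometry.items():
                if sid in self.index:
                    a[self.index[sid]] += coeff
            dg0 = thermo.dg0_prime.get(rid, 0.0)
            dg0 += transport_delta_g(rid, thermo, model)
            # sigma*(dg0 + RT * a.x) <= -eps
            rows.append(sigma * self.rt * a)
            rhs.append(-STRICT_EPS - sigma * dg0)
            labels.append(rid)
        self.A_sign = np.array(rows) if rows else np.zeros((0, self.n))
        self.b_sign = np.array(rhs)
        self.sign_labels = labels

        self.pool_fractions = {
            pid: np.array(
                [
                    model.compartments[model.metabolites[m].compartment].volume_fraction
                    for m in pool.members
                ]
            )
            for pid, pool in self.active_pools.items()
        }

    # -- pool linearizations ---------------------------------------------

    def _pool_rows(self, lo: np.ndarray, hi: np.ndarray):
        """Outer-approximation rows for pool constraints on box [lo, hi].

        Upper bound sum f*exp(x) <= c_max: tangents of exp (underestimators)
        at the box corners and midpoint give valid <= rows.  Lower bound
        sum f*exp(x) >= c_min: the chord of exp over [lo_k, hi_k]
        overestimates exp, so requiring the chord-sum >= c_min is a valid
        relaxation.
        """
        rows, rhs = [], []
        for pid, pool in self.active_pools.items():
            idx = np.array([self.index[m] for m in pool.members])
            f = self.pool_fractions[pid]
            c_lo, c_hi = pool.bounds_mm[0] / C_REF_MM, pool.bounds_mm[1] / C_REF_MM
            l, u = lo[idx], hi[idx]
            # upper bound via tangents at l, mid, u: exp(x) >= e^p (1 + x - p)
            for p in (l, (l + u) / 2.0, u):
                ep = np.exp(p)
                a = np.zeros(self.n)
                a[idx] = f * ep
                rows.append(a)
                rhs.append(c_hi - float(np.sum(f * ep * (1.0 - p))))
            # lower bound via chords: exp(x) <= e^l + slope*(x-l), slope=(e^u-e^l)/(u-l)
            with np.errstate(invalid="ignore", divide="ignore"):
                slope = np.where(u > l, (np.exp(u) - np.exp(l)) / np.where(u > l, u - l, 1.0), np.exp(l))
            const = np.exp(l) - slope * l
            a = np.zeros(self.n)
            a[idx] = -f * slope  # -(sum f*(const + slope*x)) <= -c_min
            rows.append(a)
            rhs.append(float(np.sum(f * const)) - c_lo)
        return rows, rhs

    def _solve_lp(self, lo, hi, objective=None, maximize=False):
        prows, prhs = self._pool_rows(lo, hi)
        # margin variable s pushes the witness strictly inside the sign
        # constraints: sigma*dG' <= -eps - s, maximize s in [0, 1].
        m_sign = self.A_sign.shape[0]
        n_tot = self.n + 1
        A_ub = np.zeros((m_sign + len(prows), n_tot))
        b_ub = np.zeros(m_sign + len(prows))
        if m_sign:
            A_ub[:m_sign, : self.n] = self.A_sign
            A_ub[:m_sign, self.n] = 1.0
            b_ub[:m_sign] = self.b_sign
        for k, (a, b) in enumerate(zip(prows, prhs)):
            A_ub[m_sign + k, : self.n] = a
            b_ub[m_sign + k] = b
        if objective is None:
            c = np.zeros(n_tot)
            c[self.n] = -1.0  # maximize margin
        else:
            c = np.zeros(n_tot)
            c[: self.n] = -objective if maximize else objective
        bounds = [(float(a), float(b)) for a, b in zip(lo, hi)] + [(0.0, 1.0)]
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        return res

    def _pool_violation(self, x: np.ndarray) -> tuple[float, int | None]:
        """Worst true-constraint violation at x and the pooled variable index
        most responsible (for branching)."""
        worst, branch_var = 0.0, None
        for pid, pool in self.active_pools.items():
            idx = np.array([self.index[m] for m in pool.members])
            f = self.pool_fractions[pid]
            total = float(np.sum(f * np.exp(x[idx])))
            c_lo, c_hi = pool.bounds_mm[0] / C_REF_MM, pool.bounds_mm[1] / C_REF_MM
            viol = max(total - c_hi, c_lo - total, 0.0)
            if viol > worst:
                worst = viol
                branch_var = int(idx[np.argmax(f * np.exp(x[idx]))])
        return worst, branch_var

    # -- feasibility ------------------------------------------------------

    def decide(self) -> NETResult:
        pooled_idx = sorted(
            {self.index[m] for p in self.active_pools.values() for m in p.members}
        )
        stack = [(self.x_lo.copy(), self.x_hi.copy(), 0)]
        max_depth_hit = False
        n_nodes = 0
        while stack:
            lo, hi, depth = stack.pop()
            n_nodes += 1
            res = self._solve_lp(lo, hi)
            if res.status == 2:  # node relaxation infeasible: prune
                continue
            if res.status != 0:
                raise StateError(f"LP solver failure (status {res.status})")
            x = res.x[: self.n]
            viol, branch_var = self._pool_violation(x)
            if not self.active_pools or viol <= 1e-9:
                return self._feasible_result(x, n_nodes)
            if depth >= _BNB_DEPTH_CAP:
                max_depth_hit = True
                continue
            if branch_var is None:
                branch_var = max(pooled_idx, key=lambda i: hi[i] - lo[i])
            mid = 0.5 * (lo[branch_var] + hi[branch_var])
            for half in (0, 1):
                lo2, hi2 = lo.copy(), hi.copy()
                if half == 0:
                    hi2[branch_var] = mid
                else:
                    lo2[branch_var] = mid
                stack.append((lo2, hi2, depth + 1))
        if max_depth_hit:
            return NETResult(verdict="undetermined", diagnostics={"nodes": n_nodes})
        return NETResult(verdict="infeasible", diagnostics={"nodes": n_nodes})

    def _feasible_result(self, x: np.ndarray, n_nodes: int) -> NETResult:
        witness = {
            sid: float(math.exp(x[i]) * C_REF_MM) for sid, i in self.index.items()
        }
        return NETResult(
            verdict="feasible",
            witness_mm=witness,
            diagnostics={"nodes": n_nodes},
        )

    # -- range estimation --------------------------------------------------

    def ranges(self) -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]]]:
        """Outer bounds on attainable concentrations and reaction dG' over the
        root relaxation (valid envelopes: every feasible point lies inside)."""
        species_ranges: dict[str, tuple[float, float]] = {}
        lo, hi = self.x_lo, self.x_hi
        for sid, i in self.index.items():
            obj = np.zeros(self.n)
            obj[i] = 1.0
            res_min = self._solve_lp(lo, hi, objective=obj, maximize=False)
            res_max = self._solve_lp(lo, hi, objective=obj, maximize=True)
            if res_min.status != 0 or res_max.status != 0:
                raise StateError("range LP failed on a feasible system")
            x_min = max(res_min.x[i], lo[i])
            x_max = min(res_max.x[i], hi[i])
            species_ranges[sid] = (
                float(math.exp(x_min) * C_REF_MM),
                float(math.exp(x_max) * C_REF_MM),
            )
        dg_ranges: dict[str, tuple[float, float]] = {}
        for rid in self.pattern:
            rxn = self.model.reaction(rid)
            a = np.zeros(self.n)
            for sid, coeff in rxn.stoichiometry.items():
                if sid in self.index:
                    a[self.index[sid]] += coeff
            dg0 = self.thermo.dg0_prime.get(rid, 0.0) + transport_delta_g(
                rid, self.thermo, self.model
            )
            res_min = self._solve_lp(lo, hi, objective=self.rt * a, maximize=False)
            res_max = self._solve_lp(lo, hi, objective=self.rt * a, maximize=True)
            if res_min.status != 0 or res_max.status != 0:
                raise StateError("range LP failed on a feasible system")
            dg_ranges[rid] = (
                dg0 + self.rt * float(a @ res_min.x[: self.n]),
                dg0 + self.rt * float(a @ res_max.x[: self.n]),
            )
        return species_ranges, dg_ranges


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def net_feasibility(
    model: MetabolicModel,
    pattern: ActivityPattern,
    conc: ConcentrationSet,
    thermo: ThermoData,
) -> NETResult:
    """Decide thermodynamic feasibility of an activity pattern.

    Returns a :class:`NETResult` whose verdict is ``feasible`` (with a
    witness concentration vector in mM), ``infeasible`` (certified: even the
    linear outer relaxation of the constraint system is empty), or
    ``undetermined`` (branch-and-bound depth cap reached).
    """
    if not pattern:
        return NETResult(verdict="feasible", witness_mm={})
    system = _NetSystem(model, pattern, conc, thermo)
    return system.decide()


def estimate_ranges(
    model: MetabolicModel,
    pattern: ActivityPattern,
    conc: ConcentrationSet,
    thermo: ThermoData,
) -> NETResult:
    """Attainable concentration and dG' envelopes under the pattern's
    constraints.  Requires the pattern to be feasible."""
    base = net_feasibility(model, pattern, conc, thermo)
    if base.verdict == "infeasible":
        raise StateError("estimate_ranges called on an infeasible pattern")
    if not pattern:
        return NETResult(verdict="feasible", witness_mm={}, species_ranges_mm={}, dg_ranges={})
    system = _NetSystem(model, pattern, conc, thermo)
    species_ranges, dg_ranges = system.ranges()
    return NETResult(
        verdict=base.verdict,
        witness_mm=base.witness_mm,
        species_ranges_mm=species_ranges,
        dg_ranges=dg_ranges,
        diagnostics=base.diagnostics,
    )


def read_dg0_tsv(path: str) -> dict[str, float]:
    """TSV with columns reaction_id, dg0_prime_kj_mol.  Blank or 'NA' energy
    means thermodynamically unconstrained (row omitted from the result)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = {"reaction_id", "dg0_prime_kj_mol"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        val = row["dg0_prime_kj_mol"]
        if val is None or (isinstance(val, float) and math.isnan(val)) or str(val).upper() == "NA":
            continue
        out[str(row["reaction_id"])] = float(val)
    return out


def read_concentrations_tsv(path: str) -> ConcentrationSet:
    """TSV with columns pool_id, min_mM, max_mM, members.

    ``members`` is a semicolon-separated list of compartment-specific
    species ids; a single member makes a direct species bound, several make
    a volume-weighted pool.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = {"pool_id", "min_mM", "max_mM", "members"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    species_bounds, pools = {}, {}
    for _, row in df.iterrows():
        members = [m.strip() for m in str(row["members"]).split(";") if m.strip()]
        bounds = (float(row["min_mM"]), float(row["max_mM"]))
        if len(members) == 1:
            species_bounds[members[0]] = bounds
        else:
            pools[str(row["pool_id"])] = Pool(members=members, bounds_mm=bounds)
    return ConcentrationSet(species_bounds_mm=species_bounds, pools=pools)


def derive_direction_constraints(
    model: MetabolicModel,
    always_active: DirectionConstraintSet,
    conc: ConcentrationSet,
    thermo: ThermoData,
) -> DirectionConstraintSet:
    """NET-based direction derivation.

    Against the backdrop of the reactions that are active in every flux
    distribution (fixed signs from FVA), each remaining reversible reaction
    is tested in both directions; if exactly one direction is feasible the
    corresponding ``*_only`` constraint is emitted with provenance ``NET``.
    Both directions infeasible flags a model/data inconsistency.
    """
    base_signs = {
        rid: s
        for rid, s in always_active.always_active().items()
        if thermo.is_constrained(rid)
    }
    out = DirectionConstraintSet()
    for rxn in model.reactions:
        if not (rxn.lower_bound < 0 < rxn.upper_bound) or rxn.id in base_signs:
            continue
        if not thermo.is_constrained(rxn.id):
            continue
        fwd = net_feasibility(
            model, ActivityPattern({**base_signs, rxn.id: +1}), conc, thermo
        ).feasible
        bwd = net_feasibility(
            model, ActivityPattern({**base_signs, rxn.id: -1}), conc, thermo
        ).feasible
        if fwd and not bwd:
            out.set(rxn.id, DirectionClass.FORWARD_ONLY, "NET")
        elif bwd and not fwd:
            out.set(rxn.id, DirectionClass.BACKWARD_ONLY, "NET")
        elif not fwd and not bwd:
            raise ModelInconsistencyError(
                f"both directions of {rxn.id!r} are thermodynamically infeasible"
            )
    return out
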