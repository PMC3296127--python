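"""Flux-cone decomposition, FBA cross-checks, and pooled rate profiles.

The decomposition utility tests cone membership: a flux vector v lies in the
non-negative span of a set of EFMs iff the LP {alpha >= 0 : E alpha = v} is
feasible.  The central theorem this package leans on — a thermodynamically
feasible flux distribution is a non-negative combination of the
thermodynamically *feasible* EFMs alone — becomes a property test through
this LP.  Non-membership is certified by a separating hyperplane y with
y.E <= 0 for every mode but y.v > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .efm import EFMSet, normalize_to_substrate
from .errors import SolverStatusError, ValidationError
from .model_io import MetabolicModel, PhysiologyData
from .patterns import InfeasibilityPattern
from .thermo import ActivityPattern

SIGN_TOL = 1e-6  # |v_r| above this counts as active (same family as FVA tol)


@dataclass
class Decomposition:
    """Non-negative combination of EFMs reproducing a target flux vector,
    or a separating certificate that none exists."""

    member: bool
    coefficients: dict[int, float] = field(default_factory=dict)  # EFM index -> alpha
    residual: float = float("inf")
    certificate: np.ndarray | None = None  # y with y.E <= 0, y.v > 0


def decompose_flux(
    v: np.ndarray, efms: EFMSet, model: MetabolicModel, tol: float = 1e-8
) -> Decomposition:
    """Express v as sum(alpha_i e_i), alpha >= 0, or certify v outside the
    cone of the given modes."""
    v = np.asarray(v, dtype=float)
    if v.shape != (len(model.reactions),):
        raise ValidationError(
            f"flux vector has dimension {v.shape}, model has {len(model.reactions)} reactions"
        )
    if len(efms) == 0:
        E = np.zeros((len(model.reactions), 0))
    else:
        E = np.column_stack([e.vector(model) for e in efms])
    k = E.shape[1]

    # Feasibility LP with elastic slack: min sum(s+ + s-) s.t. E a + s+ - s- = v.
    n_rows = E.shape[0]
    c = np.concatenate([np.zeros(k), np.ones(2 * n_rows)])
    A_eq = np.hstack([E, np.eye(n_rows), -np.eye(n_rows)])
    res = linprog(c, A_eq=A_eq, b_eq=v, bounds=[(0, None)] * (k + 2 * n_rows), method="highs")
    if res.status != 0:
        raise SolverStatusError(f"decomposition LP status {res.status}")
    slack = float(res.fun)
    if slack <= tol * max(1.0, float(np.abs(v).sum())):
        alpha = res.x[:k]
        residual = float(np.abs(E @ alpha - v).max()) if k else float(np.abs(v).max())
        return Decomposition(
            member=True,
            coefficients={i: float(a) for i, a in enumerate(alpha) if a > tol},
            residual=residual,
        )

    # Separating hyperplane: max y.v s.t. y.E <= 0, |y| <= 1.
    if k:
        res2 = linprog(
            -v,
            A_ub=E.T,
            b_ub=np.zeros(k),
            bounds=[(-1.0, 1.0)] * n_rows,
            method="highs",
        )
        certificate = res2.x if res2.status == 0 and -res2.fun > tol else None
    else:
        certificate = v / max(np.abs(v).max(), 1.0)
    return Decomposition(member=False, residual=slack, certificate=certificate)


# ---------------------------------------------------------------------------
# Pooled rate profiles
# ---------------------------------------------------------------------------


@dataclass
class RateProfile:
    """Per-EFM contributions of designated reactions to a pooled quantity
    (e.g. cytosolic NADH oxidation), per mol substrate."""

    contributions: list[dict[str, float]]  # one dict per EFM
    totals: list[float]
    labels: list[str | None]

    def max_total(self, label_filter: str | None = None) -> float:
        vals = [
            t
            for t, l in zip(self.totals, self.labels)
            if label_filter is None or l in (label_filter, "undetermined")
        ]
        return max(vals) if vals else float("nan")

    def max_member(self, rid: str, label_filter: str | None = None) -> float:
        vals = [
            c[rid]
            for c, l in zip(self.contributions, self.labels)
            if label_filter is None or l in (label_filter, "undetermined")
        ]
        return max(vals) if vals else float("nan")


def reaction_rate_profile(
    efms: EFMSet,
    pooled_reactions: list[tuple[str, float]],
    substrate: str,
    model: MetabolicModel,
) -> RateProfile:
    """Contributions of weighted member reactions to a pooled rate, per mol
    substrate, for every EFM.  Weights carry the stoichiometry of the pooled
    species in each member reaction (e.g. mol NADH oxidized per unit flux)."""
    known = set(model.reaction_ids)
    for rid, _ in pooled_reactions:
        if rid not in known:
            raise ValidationError(f"unknown reaction {rid!r} in pooled list")
    contributions, totals = [], []
    for e in efms:
        norm = normalize_to_substrate(e, substrate)
        contrib = {rid: w * float(norm[rid]) for rid, w in pooled_reactions}
        contributions.append(contrib)
        totals.append(sum(contrib.values()))
    return RateProfile(contributions=contributions, totals=totals, labels=list(efms.labels))


# ---------------------------------------------------------------------------
# Flux balance analysis
# ---------------------------------------------------------------------------


def fba(
    model: MetabolicModel,
    objective: str,
    phys: PhysiologyData | None = None,
    maximize: bool = True,
) -> dict[str, float]:
    """Linear FBA: optimize the flux of one reaction under mass balance,
    bounds, and measured exchange intervals.  Returns the optimal flux
    vector as a reaction->flux map."""
    from .fva import _condition_bounds

    S, _, rxn_ids = model.stoichiometric_matrix()
    j = model.reaction_index(objective)
    bounds = _condition_bounds(model, phys)
    c = np.zeros(S.shape[1])
    c[j] = -1.0 if maximize else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        raise SolverStatusError("FBA constraints are infeasible")
    if res.status == 3:
        raise SolverStatusError("FBA objective is unbounded")
    if res.status != 0:
        raise SolverStatusError(f"FBA LP status {res.status}")
    return dict(zip(rxn_ids, map(float, res.x)))


def check_patterns_in_flux(
    v: dict[str, float] | np.ndarray,
    patterns: list[InfeasibilityPattern],
    model: MetabolicModel | None = None,
    tol: float = SIGN_TOL,
) -> list[InfeasibilityPattern]:
    """Patterns whose every (reaction, sign) activity matches the sign of
    the flux vector (|flux| > tol defines active).  A nonempty result flags
    the flux distribution as thermodynamically suspect."""
    if not isinstance(v, dict):
        if model is None:
            raise ValidationError("model required when v is an array")
        v = dict(zip(model.reaction_ids, np.asarray(v, dtype=float)))
    signs = dict(ActivityPattern.from_flux(v, tol=tol))
    return [p for p in patterns if p.matches(signs)]
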