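"""Flux variability analysis (FVA) and condition-specific direction classes.

For each reaction the minimum and maximum steady-state flux is computed over
{v : S v = 0, direction bounds, flux caps, measured exchange intervals}.
The resulting range determines the reaction's direction class under the
measured condition: spanning zero means reversible; a one-signed range means
unidirectional; a range bounded away from zero means the reaction is active
in every admissible flux distribution ("always active"), which is what the
subsequent thermodynamic direction derivation keys on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import InfeasibleSystemError, SolverStatusError
from .model_io import (
    DirectionClass,
    DirectionConstraintSet,
    MetabolicModel,
    PhysiologyData,
)

DEFAULT_TOL = 1e-6  # mmol gDW^-1 h^-1, sign-classification tolerance


@dataclass
class FluxRangeTable:
    """Per-reaction achievable flux interval [min, max] with an at-cap flag
    when an extreme sits on the model's artificial flux cap."""

    ranges: dict[str, tuple[float, float]]
    at_cap: dict[str, bool]

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": list(self.ranges),
                "min": [r[0] for r in self.ranges.values()],
                "max": [r[1] for r in self.ranges.values()],
                "at_cap": [self.at_cap[r] for r in self.ranges],
            }
        )


def _condition_bounds(
    model: MetabolicModel, phys: PhysiologyData | None
) -> list[tuple[float, float]]:
    bounds = [list(b) for b in model.bounds()]
    if phys is not None:
        for rid, (lo, hi) in phys.rates.items():
            j = model.reaction_index(rid)
            bounds[j][0] = max(bounds[j][0], lo)
            bounds[j][1] = min(bounds[j][1], hi)
            if bounds[j][0] > bounds[j][1]:
                raise InfeasibleSystemError(
                    f"measured interval for {rid!r} conflicts with model bounds",
                    implicated=(rid,),
                )
    return [tuple(b) for b in bounds]


def _diagnose_infeasibility(
    model: MetabolicModel, phys: PhysiologyData, S, bounds
) -> tuple[str, ...]:
    """Relaxation report: drop one measured exchange at a time; constraints
    whose removal restores feasibility are implicated."""
    implicated = []
    for rid in phys.rates:
        relaxed = PhysiologyData(rates={r: iv for r, iv in phys.rates.items() if r != rid})
        b = _condition_bounds(model, relaxed)
        res = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=b, method="highs")
        if res.status == 0:
            implicated.append(rid)
    return tuple(implicated)


def run_fva(model: MetabolicModel, phys: PhysiologyData | None = None) -> FluxRangeTable:
    """Minimum and maximum achievable flux per reaction.

    Raises :class:`InfeasibleSystemError` naming the violated measured
    exchange constraints (single-constraint relaxation heuristic) when the
    constrained system is empty.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    bounds = _condition_bounds(model, phys)
    b_eq = np.zeros(S.shape[0])

    probe = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
    if probe.status == 2:
        implicated = _diagnose_infeasibility(model, phys, S, bounds) if phys else ()
        raise InfeasibleSystemError(
            "constrained flux space is empty"
            + (f"; implicated exchanges: {', '.join(implicated)}" if implicated else ""),
            implicated=implicated,
        )
    if probe.status != 0:
        raise SolverStatusError(f"LP status {probe.status} on feasibility probe")

    ranges: dict[str, tuple[float, float]] = {}
    at_cap: dict[str, bool] = {}
    n = S.shape[1]
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(n)
        c[j] = 1.0
        lo_res = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        hi_res = linprog(-c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        if lo_res.status != 0 or hi_res.status != 0:
            raise SolverStatusError(f"FVA LP failed for {rid!r}")
        lo, hi = float(lo_res.fun), float(-hi_res.fun)
        ranges[rid] = (lo, hi)
        at_cap[rid] = bool(
            np.isclose(lo, bounds[j][0]) and bounds[j][0] <= -model.reactions[j].flux_cap + 1e-9
            or np.isclose(hi, bounds[j][1]) and bounds[j][1] >= model.reactions[j].flux_cap - 1e-9
        )
    return FluxRangeTable(ranges=ranges, at_cap=at_cap)


def classify_activities(
    ranges: FluxRangeTable, tol: float = DEFAULT_TOL
) -> DirectionConstraintSet:
    """Direction class per reaction from its FVA range.

    Spanning zero -> reversible; within +/-tol of zero -> inactive; a
    nonnegative range -> forward_only, upgraded to always_forward when the
    minimum is strictly positive (the reaction cannot be inactive); the
    mirror images for backward.  The classification is total.
    """
    out = DirectionConstraintSet()
    for rid, (lo, hi) in ranges.ranges.items():
        if lo < -tol and hi > tol:
            cls = DirectionClass.REVERSIBLE
        elif -tol <= lo and hi <= tol:
            cls = DirectionClass.INACTIVE
        elif lo >= -tol:
            cls = DirectionClass.ALWAYS_FORWARD if lo > tol else DirectionClass.FORWARD_ONLY
        else:
            cls = DirectionClass.ALWAYS_BACKWARD if hi < -tol else DirectionClass.BACKWARD_ONLY
        out.set(rid, cls, "FVA")
    return out


def iterate_fva_net(
    model: MetabolicModel,
    phys: PhysiologyData | None,
    conc,
    thermo,
    tol: float = DEFAULT_TOL,
    max_iterations: int = 10,
):
    """Alternate FVA and NET direction derivation until no new constraint
    appears (fixpoint), with an iteration cap.

    Returns (constrained model, merged DirectionConstraintSet, iterations).
    """
    from .model_io import apply_direction_constraints
    from .thermo import derive_direction_constraints

    current = model
    merged = DirectionConstraintSet()
    for iteration in range(1, max_iterations + 1):
        table = run_fva(current, phys)
        fva_cls = classify_activities(table, tol=tol)
        new = DirectionConstraintSet()
        for rid, cls in fva_cls.items():
            rxn = current.reaction(rid)
            two_way = rxn.lower_bound < 0 < rxn.upper_bound
            narrows = (
                (cls.is_forward and two_way)
                or (cls.is_backward and two_way)
                or (
                    cls is DirectionClass.INACTIVE
                    and (rxn.upper_bound > 0 or rxn.lower_bound < 0)
                )
            )
            if narrows and rid not in merged:
                new.set(rid, cls, "FVA")
        net_cls = derive_direction_constraints(
            apply_direction_constraints(current, new), fva_cls, conc, thermo
        )
        for rid, cls in net_cls.items():
            if rid not in merged and rid not in new:
                new.set(rid, cls, "NET")
        if len(new) == 0:
            return current, merged, iteration
        for rid, cls in new.items():
            merged.set(rid, cls, new.provenance[rid])
        current = apply_direction_constraints(current, new)
    return current, merged, max_iterations
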