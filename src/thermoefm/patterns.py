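"""Mining minimal infeasible reaction-activity patterns.

An infeasible EFM carries a set of reaction activities that is
thermodynamically impossible only as a whole — no single activity is
impossible by itself (single-reaction infeasibilities are already removed by
the direction-derivation step before enumeration).  The miner walks the
activities of an infeasible mode in a given order, removing each activity in
turn: if removal makes the remainder feasible, the activity belongs to the
pattern and is kept; otherwise it stays removed.  One pass yields a minimal
infeasible subset, whose minimality is re-verified before it is returned.
The order of removal determines which of possibly several minimal patterns
is found; random restarts with different orders can surface alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efm import EFM, EFMSet
from .errors import StateError, ThermoEFMError
from .model_io import MetabolicModel
from .thermo import ActivityPattern, ConcentrationSet, ThermoData, net_feasibility


@dataclass(frozen=True)
class InfeasibilityPattern:
    """A minimal jointly-infeasible set of reaction activities."""

    activities: tuple[tuple[str, int], ...]  # sorted (reaction id, sign)
    efm_count: int = 0
    infeasible_fraction: float = 0.0

    @property
    def pattern(self) -> ActivityPattern:
        return ActivityPattern(dict(self.activities))

    def __len__(self) -> int:
        return len(self.activities)

    def matches(self, signs: dict[str, int]) -> bool:
        """True if every activity of the pattern is present in `signs`."""
        return all(signs.get(rid) == s for rid, s in self.activities)


def _feasible(model, signs: dict[str, int], conc, thermo) -> bool:
    return net_feasibility(model, ActivityPattern(signs), conc, thermo).feasible


def find_pattern(
    efm: EFM,
    model: MetabolicModel,
    conc: ConcentrationSet,
    thermo: ThermoData,
    order: list[str] | None = None,
) -> InfeasibilityPattern:
    """One minimal infeasible subset of an infeasible EFM's activities.

    `order` fixes the removal sequence (default: model reaction order).
    Raises :class:`StateError` when called on a feasible mode, and surfaces a
    consistency error if the minimality re-verification fails (a solver
    tolerance problem that must not be returned silently).
    """
    signs = {
        rid: s for rid, s in efm.sign_pattern().items() if thermo.is_constrained(rid)
    }
    return find_pattern_for_signs(signs, model, conc, thermo, order=order)


def find_pattern_for_signs(
    signs: dict[str, int],
    model: MetabolicModel,
    conc: ConcentrationSet,
    thermo: ThermoData,
    order: list[str] | None = None,
) -> InfeasibilityPattern:
    if _feasible(model, signs, conc, thermo):
        raise StateError("find_pattern called on a feasible activity pattern")
    if order is None:
        order = [r.id for r in model.reactions]
    ordered = [rid for rid in order if rid in signs]
    ordered += [rid for rid in signs if rid not in ordered]

    kept: dict[str, int] = dict(signs)
    identified: set[str] = set()
    for rid in ordered:
        trial = {r: s for r, s in kept.items() if r != rid}
        if _feasible(model, trial, conc, thermo):
            identified.add(rid)  # removal breaks infeasibility: part of pattern
        else:
            kept = trial
    pattern = {rid: signs[rid] for rid in identified}

    # Verification: the pattern is infeasible, every one-smaller subset feasible.
    if _feasible(model, pattern, conc, thermo):
        raise ThermoEFMError(
            "pattern verification failed: mined pattern is feasible "
            "(solver tolerance inconsistency)"
        )
    for rid in pattern:
        if not _feasible(model, {r: s for r, s in pattern.items() if r != rid}, conc, thermo):
            raise ThermoEFMError(
                f"pattern verification failed: removing {rid!r} still infeasible "
                "(not minimal; solver tolerance inconsistency)"
            )
    return InfeasibilityPattern(activities=tuple(sorted(pattern.items())))


def aggregate_patterns(
    efms: EFMSet,
    model: MetabolicModel,
    conc: ConcentrationSet,
    thermo: ThermoData,
    n_random_orders: int = 0,
    seed: int = 0,
) -> list[InfeasibilityPattern]:
    """Deduplicated minimal patterns over all infeasible modes of a
    classified set, with occurrence counts.

    Mining runs once per distinct constrained sign pattern (not per EFM) and
    counts are mapped back.  With ``n_random_orders`` > 0, each distinct sign
    pattern is additionally mined under seeded random removal orders to
    surface alternative minimal patterns.  Every infeasible EFM contains at
    least one returned pattern.
    """
    if any(l is None for l in efms.labels):
        raise StateError("EFM set must be fully classified first")

    infeasible = [
        e for e, l in zip(efms.efms, efms.labels) if l == "infeasible"
    ]
    n_inf = len(infeasible)
    if n_inf == 0:
        return []

    distinct: dict[tuple, list[EFM]] = {}
    for e in infeasible:
        signs = {
            rid: s for rid, s in e.sign_pattern().items() if thermo.is_constrained(rid)
        }
        distinct.setdefault(tuple(sorted(signs.items())), []).append(e)

    rng = np.random.default_rng(seed)
    found: dict[tuple, set[tuple]] = {}  # sign key -> set of pattern activity tuples
    for key in distinct:
        signs = dict(key)
        pats = {find_pattern_for_signs(signs, model, conc, thermo).activities}
        for _ in range(n_random_orders):
            order = list(rng.permutation([r.id for r in model.reactions]))
            pats.add(find_pattern_for_signs(signs, model, conc, thermo, order=order).activities)
        found[key] = pats

    all_patterns = sorted({p for pats in found.values() for p in pats})
    out = []
    for acts in all_patterns:
        pat = InfeasibilityPattern(activities=acts)
        count = sum(
            len(members)
            for key, members in distinct.items()
            if pat.matches(dict(key))
        )
        out.append(
            InfeasibilityPattern(
                activities=acts, efm_count=count, infeasible_fraction=count / n_inf
            )
        )
    out.sort(key=lambda p: (-p.efm_count, p.activities))
    return out
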