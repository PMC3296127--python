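"""Elementary flux mode enumeration.

An elementary flux mode (EFM) is a steady-state flux vector (S v = 0) that
respects all irreversibilities and whose support is minimal: no other
balanced, direction-respecting vector has a support strictly contained in
it.  Every stoichiometrically possible flux distribution is a non-negative
combination of EFMs, which is what makes the set of EFMs a complete
description of the flux cone.

The enumerator is a double description method over exact rational
arithmetic: reversible reactions are split into forward/backward columns so
the flux cone becomes pointed ({w >= 0, S w = 0}), the mass-balance
hyperplanes are intersected one at a time while maintaining the extreme
rays, and candidate rays from positive/negative pairs are admitted only if
the pair is adjacent (no third ray's zero-set dominates theirs — the
combinatorial adjacency test).  Two-cycle artifacts of the splitting
(forward+backward of one reaction) map to the zero vector and are dropped;
modes supported entirely on reversible reactions appear once per sign and
are canonicalized.  Exact arithmetic (Fraction) makes S e = 0 hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np

from .errors import CapacityError, ValidationError
from .model_io import MetabolicModel

DEFAULT_MODE_CAP = 10**7


@dataclass(frozen=True)
class EFM:
    """One elementary mode: a sparse rational flux vector."""

    coefficients: dict[str, Fraction]  # reaction id -> flux (nonzero entries only)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    def sign_pattern(self) -> dict[str, int]:
        return {rid: (1 if v > 0 else -1) for rid, v in self.coefficients.items()}

    def vector(self, model: MetabolicModel) -> np.ndarray:
        v = np.zeros(len(model.reactions))
        for rid, coeff in self.coefficients.items():
            v[model.reaction_index(rid)] = float(coeff)
        return v

    def __getitem__(self, rid: str) -> Fraction:
        return self.coefficients.get(rid, Fraction(0))


@dataclass
class EFMSet:
    """Ordered collection of EFMs with a model fingerprint and per-mode
    feasibility label slots (None until classified)."""

    efms: list[EFM]
    fingerprint: str
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = [None] * len(self.efms)
        supports = [e.support for e in self.efms]
        if len(set(supports)) != len(supports):
            raise ValidationError("two EFMs share a support")

    def __len__(self) -> int:
        return len(self.efms)

    def __iter__(self):
        return iter(self.efms)

    def subset(self, keep: list[bool]) -> "EFMSet":
        return EFMSet(
            efms=[e for e, k in zip(self.efms, keep) if k],
            fingerprint=self.fingerprint,
            labels=[l for l, k in zip(self.labels, keep) if k],
        )

    def feasible_subset(self) -> "EFMSet":
        """Feasible + undetermined modes (conservative reading)."""
        return self.subset([l in ("feasible", "undetermined") for l in self.labels])

    def counts(self) -> dict[str, int]:
        out = {"total": len(self.efms)}
        for lab in ("feasible", "infeasible", "undetermined", None):
            key = "unclassified" if lab is None else lab
            out[key] = sum(1 for l in self.labels if l == lab)
        return out


# ---------------------------------------------------------------------------
# Double description enumeration
# ---------------------------------------------------------------------------


def _normalize_ray(ray: list[Fraction]) -> tuple[Fraction, ...]:
    """Scale to coprime integers (canonical representative of the ray)."""
    denom_lcm = 1
    for v in ray:
        if v != 0:
            denom_lcm = denom_lcm * v.denominator // gcd(denom_lcm, v.denominator)
    ints = [int(v * denom_lcm) for v in ray]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    return tuple(Fraction(v) for v in ints)


def _double_description(S_rows: list[list[Fraction]], n: int, cap: int) -> list[tuple[Fraction, ...]]:
    """Extreme rays of {w in R^n : w >= 0, S w = 0}."""
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(1) if j == i else Fraction(0) for j in range(n)) for i in range(n)
    ]
    # Process rows in a deterministic order that keeps intermediate ray
    # counts small: fewest sign-split pairs first (re-evaluated greedily).
    remaining = list(range(len(S_rows)))
    while remaining:
        best_row, best_cost = None, None
        for ri in remaining:
            row = S_rows[ri]
            npos = sum(1 for r in rays if sum(row[j] * r[j] for j in range(n)) > 0)
            nneg = sum(1 for r in rays if sum(row[j] * r[j] for j in range(n)) < 0)
            cost = npos * nneg
            if best_cost is None or cost < best_cost:
                best_row, best_cost = ri, cost
        remaining.remove(best_row)
        row = S_rows[best_row]

        dots = [sum(row[j] * r[j] for j in range(n)) for r in rays]
        zero = [r for r, d in zip(rays, dots) if d == 0]
        pos = [(r, d) for r, d in zip(rays, dots) if d > 0]
        neg = [(r, d) for r, d in zip(rays, dots) if d < 0]

        supports = {r: frozenset(j for j in range(n) if r[j] != 0) for r in rays}
        new_rays = list(zero)
        for rp, dp in pos:
            for rn, dn in neg:
                union = supports[rp] | supports[rn]
                adjacent = True
                for other in rays:
                    if other is rp or other is rn:
                        continue
                    if supports[other] <= union:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = [dp * rn[j] - dn * rp[j] for j in range(n)]
                new_rays.append(_normalize_ray(combo))
        rays = list(dict.fromkeys(new_rays))
        if len(rays) > cap:
            raise CapacityError(
                f"intermediate ray count {len(rays)} exceeds mode cap {cap}"
            )
    return rays


def enumerate_efms(model: MetabolicModel, max_modes: int = DEFAULT_MODE_CAP) -> EFMSet:
    """Enumerate all elementary flux modes of the model.

    Reactions pinned to zero capacity (direction class ``inactive``) are
    excluded from enumeration.  Raises :class:`CapacityError` if the ray
    count exceeds ``max_modes``.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    active = [j for j, r in enumerate(model.reactions) if r.upper_bound > 0 or r.lower_bound < 0]
    if not active:
        return EFMSet(efms=[], fingerprint=model.fingerprint())

    # Split two-way reactions into forward/backward columns.
    columns: list[tuple[int, int]] = []  # (reaction index, direction +1/-1)
    for j in active:
        if model.reactions[j].upper_bound > 0:
            columns.append((j, +1))
        if model.reactions[j].lower_bound < 0:
            columns.append((j, -1))

    n = len(columns)
    S_frac = [[Fraction(S[i, j]).limit_denominator(10**9) for j in range(S.shape[1])] for i in range(S.shape[0])]
    rows = []
    for i in range(S.shape[0]):
        row = [sign * S_frac[i][j] for (j, sign) in columns]
        if any(v != 0 for v in row):
            rows.append(row)

    rays = _double_description(rows, n, max_modes)

    seen: dict[frozenset, EFM] = {}
    order: list[frozenset] = []
    for ray in rays:
        coeffs: dict[str, Fraction] = {}
        for (j, sign), w in zip(columns, ray):
            if w != 0:
                coeffs[rxn_ids[j]] = coeffs.get(rxn_ids[j], Fraction(0)) + sign * w
        coeffs = {rid: v for rid, v in coeffs.items() if v != 0}
        if not coeffs:
            continue  # two-cycle artifact of the splitting
        # Canonical sign for modes supported entirely on two-way reactions
        # (they appear once per direction in the split cone).
        if all(model.reaction(rid).lower_bound < 0 < model.reaction(rid).upper_bound for rid in coeffs):
            first = min(coeffs)
            if coeffs[first] < 0:
                coeffs = {rid: -v for rid, v in coeffs.items()}
        key = frozenset(coeffs.items())
        if key not in seen:
            seen[key] = EFM(coefficients=coeffs)
            order.append(key)

    efms = [seen[k] for k in order]
    efms.sort(key=lambda e: sorted(e.support))
    return EFMSet(efms=efms, fingerprint=model.fingerprint())


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def remove_internal_cycles(efms: EFMSet, substrate: str) -> EFMSet:
    """Drop modes with zero substrate uptake (internal cycles, meaningless
    at steady state)."""
    return efms.subset([e[substrate] != 0 for e in efms])


def normalize_to_substrate(efm: EFM, substrate: str) -> EFM:
    """Rescale so the substrate flux is 1 (rates in mol per mol substrate)."""
    s = efm[substrate]
    if s == 0:
        raise ZeroDivisionError(
            f"EFM has zero flux through substrate reaction {substrate!r}; "
            "remove internal cycles first"
        )
    return EFM(coefficients={rid: v / s for rid, v in efm.coefficients.items()})
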